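"""Gated-graph encoder-decoder for fragment linking.

The generator grows a linker between two anchored fragments.  Fragment
atoms are embedded by type (with an anchor flag) and propagated through a
gated graph neural network (GGNN): per-bond-order message matrices feed a
gated recurrent update, repeated T steps.  A fixed number of expansion
nodes — candidate linker atoms — are added unconnected; each receives a
random hidden state and an atom type sampled from the softmax of a small
perceptron classifier over that state.  Decoding then proceeds breadth-first from
the two anchors: for the queue-head node v, a perceptron scores every
valence-legal partner u (plus a learned STOP sentinel) from the feature

    phi(v, u) = [h_v, h_u, d_vu, mean(H0), mean(Ht), I]

where d_vu is the graph distance, H0/Ht are the initial and current
hidden states, and I = (anchor distance, exit-vector angle).  A second
perceptron labels the chosen edge single/double/triple, masked to orders
that keep both endpoints valence-legal.  After a node finishes (STOP),
hidden states are recomputed from H0 over the current topology — earlier
states are discarded, so decoding depends only on the present graph.

Training follows a VAE: the latent code z is the average encoded hidden
state of the true linker atoms mapped to a low dimension; the
reconstruction term is the negative log-likelihood of the teacher-forced
decoding trace of the true molecule (atom-type, edge-selection and
edge-label decisions), and a KL term regularizes the posterior toward a
standard normal.  When several interchangeable expansion nodes (same
type, still unconnected) could serve as the target, their probabilities
are summed — the likelihood of the molecule, not of one labeling.

Everything runs on the package's own reverse-mode autodiff
(:mod:`fraglink.autodiff`); sampling runs the same code under ``no_grad``.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .autodiff import Adam, Tensor, no_grad
from .fragmenter import FragmentPair, TrainingExample
from .molgraph import (DEFAULT_REGISTRY, AtomTypeRegistry, MolecularGraph,
                       largest_component)

STOP = "STOP"


class ConfigurationError(ValueError):
    pass


class StateError(ValueError):
    pass


class TrainingError(RuntimeError):
    pass


@dataclass
class ModelParams:
    """Weights plus the structural hyperparameters they are shaped by."""

    registry: AtomTypeRegistry
    hidden_dim: int
    prop_steps: int
    latent_dim: int
    edge_hidden: int
    beta: float
    max_expansion: int
    weights: dict = field(default_factory=dict)

    @property
    def n_types(self) -> int:
        return self.registry.size

    @property
    def feature_dim(self) -> int:
        return 4 * self.hidden_dim + 3

    def save(self, path):
        """Single self-describing checkpoint: config + registry + weights."""
        meta = {
            "hidden_dim": self.hidden_dim, "prop_steps": self.prop_steps,
            "latent_dim": self.latent_dim, "edge_hidden": self.edge_hidden,
            "beta": self.beta, "max_expansion": self.max_expansion,
            "registry": [[t.symbol, t.charge, t.max_valence] for t in self.registry.entries],
        }
        arrays = {k: v.data for k, v in self.weights.items()}
        np.savez(path, __meta__=np.array(json.dumps(meta)), **arrays)

    @classmethod
    def load(cls, path) -> "ModelParams":
        from .molgraph import AtomType

        with np.load(path, allow_pickle=False) as f:
            meta = json.loads(str(f["__meta__"]))
            weights = {k: Tensor(f[k]) for k in f.files if k != "__meta__"}
        registry = AtomTypeRegistry([AtomType(s, int(c), int(v)) for s, c, v in meta["registry"]])
        p = cls(registry=registry, hidden_dim=meta["hidden_dim"],
                prop_steps=meta["prop_steps"], latent_dim=meta["latent_dim"],
                edge_hidden=meta["edge_hidden"], beta=meta["beta"],
                max_expansion=meta["max_expansion"], weights=weights)
        for w in p.weights.values():
            w.requires_grad = True
        return p


def init_params(registry: AtomTypeRegistry | None = None, hidden_dim: int = 32,
                prop_steps: int = 7, latent_dim: int = 8, edge_hidden: int = 32,
                beta: float = 1.0, max_expansion: int = 20,
                rng: np.random.Generator | None = None) -> ModelParams:
    registry = registry or DEFAULT_REGISTRY
    rng = rng if rng is not None else np.random.default_rng(0)
    d, L, he, nt = hidden_dim, latent_dim, edge_hidden, registry.size
    F = 4 * d + 3

    def W(*shape):
        return Tensor(rng.normal(0.0, 1.0 / np.sqrt(shape[0]), size=shape), requires_grad=True)

    def zeros(*shape):
        return Tensor(np.zeros(shape), requires_grad=True)

    w = {
        "type_emb": W(nt, d), "w_anchor": W(1, d),
        "W_msg1": W(d, d), "W_msg2": W(d, d), "W_msg3": W(d, d),
        "W_z": W(d, d), "U_z": W(d, d), "b_z": zeros(d),
        "W_r": W(d, d), "U_r": W(d, d), "b_r": zeros(d),
        "W_h": W(d, d), "U_h": W(d, d), "b_h": zeros(d),
        "W_f1": W(d, d), "b_f1": zeros(d), "W_f": W(d, nt), "b_f": zeros(nt),
        "W_c": W(d, d), "W_cI": W(2, d), "b_c": zeros(d),
        "W_rand": Tensor(rng.normal(0.0, 0.1 / np.sqrt(d), size=(d, d)), requires_grad=True),
        "W_lat": W(L, d), "W_ctx": W(d, d), "b_exp": zeros(d),
        "W_pos": W(max_expansion, d),
        "W_e1": W(F, he), "b_e1": zeros(he), "W_e2": W(he, 1), "b_e2": zeros(1),
        "phi_stop": W(1, F),
        "W_l1": W(F, he), "b_l1": zeros(he), "W_l2": W(he, 3), "b_l2": zeros(3),
        "W_mu": W(d, L), "b_mu": zeros(L), "W_lv": W(d, L), "b_lv": zeros(L),
    }
    return ModelParams(registry=registry, hidden_dim=hidden_dim, prop_steps=prop_steps,
                       latent_dim=latent_dim, edge_hidden=edge_hidden, beta=beta,
                       max_expansion=max_expansion, weights=w)


# ---------------------------------------------------------------------
# Propagation (GGNN)
# ---------------------------------------------------------------------

def _adjacency(graph: MolecularGraph) -> list[np.ndarray]:
    n = graph.n_atoms
    adj = [np.zeros((n, n)) for _ in range(3)]
    for i, j, order in graph.bond_list():
        adj[order - 1][i, j] = 1.0
        adj[order - 1][j, i] = 1.0
    return adj


def propagate(H: Tensor, adj: list[np.ndarray], params: ModelParams, steps: int) -> Tensor:
    """`steps` rounds of message passing with a gated recurrent update.

    Messages from bonded neighbors (one weight matrix per bond order) are
    summed; isolated nodes receive the zero message and still update.
    Zero steps returns the states unchanged.
    """
    w = params.weights
    for _ in range(steps):
        M = None
        for b in range(3):
            if adj[b].any():
                term = Tensor(adj[b]) @ (H @ w[f"W_msg{b + 1}"])
                M = term if M is None else M + term
        if M is None:
            M = Tensor(np.zeros(H.shape))
        zg = (M @ w["W_z"] + H @ w["U_z"] + w["b_z"]).sigmoid()
        rg = (M @ w["W_r"] + H @ w["U_r"] + w["b_r"]).sigmoid()
        hh = (M @ w["W_h"] + (rg * H) @ w["U_h"] + w["b_h"]).tanh()
        H = (1.0 - zg) * H + zg * hh
    return H


def _node_init(params: ModelParams, types: list[int], anchor_flags: np.ndarray) -> Tensor:
    """Initial hidden states for typed (fragment/target) atoms."""
    w = params.weights
    emb = w["type_emb"][np.asarray(types, dtype=int)]
    flags = Tensor(anchor_flags.reshape(-1, 1))
    return (emb + flags @ w["w_anchor"]).tanh()


def _context(params: ModelParams, frag_graph: MolecularGraph,
             anchor_flags: np.ndarray, info: np.ndarray) -> Tensor:
    """Fragment+geometry conditioning vector c (shared by both decoders)."""
    w = params.weights
    H0 = _node_init(params, frag_graph.atoms, anchor_flags)
    H = propagate(H0, _adjacency(frag_graph), params, params.prop_steps)
    pooled = H.mean(axis=0)
    return (pooled @ w["W_c"] + Tensor(info) @ w["W_cI"] + w["b_c"]).tanh()


# ---------------------------------------------------------------------
# Generation state
# ---------------------------------------------------------------------

@dataclass
class GenerationState:
    """Partial graph plus everything the decoder tracks while growing it."""

    graph: MolecularGraph
    H0: Tensor
    H: Tensor
    queue: deque
    expansion_ids: list[int]
    expansion_types: list[int]
    info: np.ndarray
    rng: np.random.Generator | None = None
    n_expansion: int = 0

    def refresh(self, params: ModelParams):
        """Recompute working states from H0 over the current topology,
        discarding the previous hidden states."""
        self.H = propagate(self.H0, _adjacency(self.graph), params, params.prop_steps)

    def step_states(self, params: ModelParams):
        """One incremental message-passing round after an edge addition."""
        self.H = propagate(self.H, _adjacency(self.graph), params, 1)


def _expansion_init(params: ModelParams, n_exp: int, z: Tensor, c: Tensor,
                    rng: np.random.Generator | None,
                    forced_types: list[int] | None = None,
                    deterministic: bool = False):
    """Hidden states and types for expansion nodes.

    Each node's conditioned slot state combines the latent code, the
    fragment context and a learned slot embedding; the atom type is
    sampled from the softmax of the perceptron classifier f over that
    state.  The slot embedding breaks the symmetry between otherwise
    identically conditioned expansion nodes, letting f resolve
    position-dependent types along the linker.  The random state
    z_v ~ N(0, I_d) perturbs the initial hidden state through a learned
    map, supplying sampling diversity downstream without blurring the
    type logits.
    Returns (types, H0_rows Tensor (n_exp, d), type_logits Tensor).
    """
    w = params.weights
    d = params.hidden_dim
    if deterministic or rng is None:
        zv = np.zeros((n_exp, d))
    else:
        zv = rng.standard_normal((n_exp, d))
    ones = Tensor(np.ones((n_exp, 1)))
    cond = (z @ w["W_lat"] + c @ w["W_ctx"] + w["b_exp"]).reshape(1, d)
    base = ones @ cond + w["W_pos"][np.arange(n_exp)]
    s = base.tanh()
    logits = (s @ w["W_f1"] + w["b_f1"]).tanh() @ w["W_f"] + w["b_f"]
    logp = logits - logits.logsumexp(axis=1).reshape(n_exp, 1)
    pre = Tensor(zv) @ w["W_rand"] + base
    if forced_types is not None:
        types = list(forced_types)
    else:
        probs = np.exp(logp.data)
        if deterministic:
            types = [int(np.argmax(p)) for p in probs]
        else:
            types = [int(rng.choice(params.n_types, p=p / p.sum())) for p in probs]
    h0 = (pre + w["type_emb"][np.asarray(types, dtype=int)]).tanh()
    return types, h0, logp


def init_generation(pair: FragmentPair, n_expansion: int, params: ModelParams,
                    rng: np.random.Generator | None,
                    z: Tensor | None = None,
                    deterministic: bool = False) -> GenerationState:
    """Embed the fragments, add `n_expansion` unconnected expansion nodes.

    The queue starts with the two anchors, fragment_a's anchor first.  The
    latent code defaults to the standard-normal prior draw (zeros when
    deterministic).
    """
    if not (0 < n_expansion <= params.max_expansion):
        raise ConfigurationError(
            f"n_expansion must be in 1..{params.max_expansion}, got {n_expansion}")
    if pair.info is None:
        raise ConfigurationError("fragment pair lacks structural info")
    info = pair.info.as_array()

    frag_a, frag_b = pair.fragment_a, pair.fragment_b
    graph = MolecularGraph(frag_a.registry)
    for t in frag_a.atoms:
        graph.add_atom(t)
    for i, j, o in frag_a.bond_list():
        graph.add_bond(i, j, o)
    off = frag_a.n_atoms
    for t in frag_b.atoms:
        graph.add_atom(t)
    for i, j, o in frag_b.bond_list():
        graph.add_bond(off + i, off + j, o)
    anchor_a = pair.anchor_a
    anchor_b = off + pair.anchor_b
    graph.anchors = {anchor_a, anchor_b}

    n_frag = graph.n_atoms
    flags = np.zeros(n_frag)
    flags[[anchor_a, anchor_b]] = 1.0
    c = _context(params, graph, flags, info)

    if z is None:
        if deterministic or rng is None:
            z = Tensor(np.zeros(params.latent_dim))
        else:
            z = Tensor(rng.standard_normal(params.latent_dim))

    types, h0_exp, _ = _expansion_init(params, n_expansion, z, c, rng,
                                       deterministic=deterministic)
    expansion_ids = []
    for t in types:
        expansion_ids.append(graph.add_atom(t))

    H0_frag = _node_init(params, graph.atoms[:n_frag], flags)
    H0 = Tensor.concat([H0_frag, h0_exp], axis=0)
    state = GenerationState(graph=graph, H0=H0, H=H0, queue=deque([anchor_a, anchor_b]),
                            expansion_ids=expansion_ids, expansion_types=types,
                            info=info, rng=rng, n_expansion=n_expansion)
    state.refresh(params)
    return state


# ---------------------------------------------------------------------
# Edge selection / labeling
# ---------------------------------------------------------------------

def _graph_distances(graph: MolecularGraph, v: int) -> np.ndarray:
    """BFS distances from v; unreachable nodes get (max finite distance) + 1."""
    n = graph.n_atoms
    dist = np.full(n, -1.0)
    dist[v] = 0
    q = deque([v])
    while q:
        x = q.popleft()
        for y in graph.neighbors(x):
            if dist[y] < 0:
                dist[y] = dist[x] + 1
                q.append(y)
    sentinel = dist.max() + 1.0
    dist[dist < 0] = sentinel
    return dist


def edge_candidates(state: GenerationState, v: int) -> list[int]:
    """Valence-legal partners for v: unbonded, both ends with free valence."""
    g = state.graph
    if g.free_valence(v) <= 0:
        return []
    return [u for u in range(g.n_atoms)
            if u != v and not g.has_bond(v, u) and g.free_valence(u) > 0]


def _edge_features(state: GenerationState, params: ModelParams, v: int,
                   cands: list[int]) -> Tensor:
    d = params.hidden_dim
    k = len(cands)
    dist = _graph_distances(state.graph, v)[cands].reshape(k, 1)
    ones = Tensor(np.ones((k, 1)))
    hv = ones @ state.H[v].reshape(1, d)
    hu = state.H[np.asarray(cands, dtype=int)]
    h0m = ones @ state.H0.mean(axis=0).reshape(1, d)
    htm = ones @ state.H.mean(axis=0).reshape(1, d)
    info = ones @ Tensor(state.info.reshape(1, 2))
    return Tensor.concat([hv, hu, Tensor(dist), h0m, htm, info], axis=1)


def edge_distribution(state: GenerationState, params: ModelParams, v: int,
                      temperature: float = 1.0):
    """Log-probabilities over candidates + STOP (STOP is the last entry).

    Masked partners (valence-illegal or already bonded) are simply absent:
    their probability is exactly zero.  With no legal partner the
    distribution is STOP with probability one.
    """
    if not (0 <= v < state.graph.n_atoms):
        raise StateError(f"node {v} not in graph")
    w = params.weights
    cands = edge_candidates(state, v)
    if not cands:
        return [], Tensor(np.zeros(1))
    feats = _edge_features(state, params, v, cands)
    feats = Tensor.concat([feats, w["phi_stop"]], axis=0)
    hidden = (feats @ w["W_e1"] + w["b_e1"]).tanh()
    scores = (hidden @ w["W_e2"] + w["b_e2"]).reshape(len(cands) + 1)
    if temperature != 1.0:
        scores = scores * (1.0 / temperature)
    logp = scores - scores.logsumexp()
    return cands, logp


def select_edge(state: GenerationState, v: int, params: ModelParams,
                rng: np.random.Generator | None = None, temperature: float = 1.0,
                deterministic: bool = False):
    """Sample (or argmax) a partner for v; returns node index or STOP."""
    cands, logp = edge_distribution(state, params, v, temperature)
    if not cands:
        return STOP
    p = np.exp(logp.data)
    p = p / p.sum()
    if deterministic or rng is None:
        idx = int(np.argmax(p))
    else:
        idx = int(rng.choice(len(p), p=p))
    return STOP if idx == len(cands) else cands[idx]


def _label_logp(state: GenerationState, params: ModelParams, v: int, u: int):
    """Masked log-probabilities over bond orders {1,2,3} for edge (v,u)."""
    w = params.weights
    g = state.graph
    max_order = min(3, g.free_valence(v), g.free_valence(u))
    if max_order < 1:
        raise StateError(f"edge ({v},{u}) has no legal bond order")
    feats = _edge_features(state, params, v, [u])
    hidden = (feats @ w["W_l1"] + w["b_l1"]).tanh()
    logits = (hidden @ w["W_l2"] + w["b_l2"]).reshape(3)
    legal = list(range(max_order))
    sub = logits[np.asarray(legal, dtype=int)]
    logp = sub - sub.logsumexp()
    return legal, logp


def label_edge(state: GenerationState, v: int, u: int, params: ModelParams,
               rng: np.random.Generator | None = None,
               deterministic: bool = False,
               forced_order: int | None = None) -> int:
    """Choose a valence-legal order for (v,u), update graph, queue and states."""
    legal, logp = _label_logp(state, params, v, u)
    if forced_order is not None:
        order = forced_order
        if order - 1 not in legal:
            raise StateError(f"forced order {order} illegal for edge ({v},{u})")
    else:
        p = np.exp(logp.data)
        p = p / p.sum()
        if deterministic or rng is None:
            order = legal[int(np.argmax(p))] + 1
        else:
            order = legal[int(rng.choice(len(p), p=p))] + 1
    newly_connected = len(state.graph.neighbors(u)) == 0
    state.graph.add_bond(v, u, order)
    if newly_connected:
        state.queue.append(u)
    state.step_states(params)
    return order


# ---------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------

def run_decoder(state: GenerationState, params: ModelParams,
                rng: np.random.Generator | None = None, temperature: float = 1.0,
                deterministic: bool = False, max_steps: int = 10_000):
    """Drive select/label/update until the queue empties."""
    steps = 0
    while state.queue:
        v = state.queue[0]
        while True:
            u = select_edge(state, v, params, rng, temperature, deterministic)
            if u == STOP:
                break
            label_edge(state, v, u, params, rng, deterministic)
            steps += 1
            if steps > max_steps:
                raise StateError("decoder exceeded step budget")
        state.queue.popleft()
        state.refresh(params)
    return state


def generate(params: ModelParams, pair: FragmentPair, n_samples: int,
             length_range: tuple = (3, 12), rng: np.random.Generator | None = None,
             temperature: float = 1.0, deterministic: bool = False) -> list[MolecularGraph]:
    """Sample molecules; the expansion budget is uniform over `length_range`.

    Unconnected leftover nodes are discarded and the largest intact
    component is returned for every sample — linkage failures are judged
    by the filter stage, not here.
    """
    lo, hi = length_range
    if lo < 1 or hi < lo:
        raise ConfigurationError("length_range must satisfy 1 <= min <= max")
    rng = rng if rng is not None else np.random.default_rng(0)
    out = []
    with no_grad():
        for _ in range(n_samples):
            if deterministic:
                n_exp = int(round((lo + hi) / 2))
            else:
                n_exp = int(rng.integers(lo, hi + 1))
            state = init_generation(pair, n_exp, params, rng, deterministic=deterministic)
            run_decoder(state, params, rng, temperature, deterministic)
            out.append(largest_component(state.graph))
    return out


# ---------------------------------------------------------------------
# Training (teacher-forced VAE)
# ---------------------------------------------------------------------

def _teacher_state(example: TrainingExample, params: ModelParams, z: Tensor,
                   rng: np.random.Generator | None) -> GenerationState:
    """Decoder state over Y's own atom indexing: fragment bonds present,
    linker atoms as typed, unconnected expansion nodes."""
    Y = example.target
    linker = example.linker_atoms
    graph = MolecularGraph(Y.registry)
    for t in Y.atoms:
        graph.add_atom(t)
    for i, j, o in Y.bond_list():
        if i not in linker and j not in linker:
            graph.add_bond(i, j, o)
    graph.anchors = {example.anchor_a_y, example.anchor_b_y}

    frag_atoms = sorted(set(range(Y.n_atoms)) - set(linker))
    frag_graph, remap = graph.subgraph(frag_atoms)
    flags_frag = np.zeros(frag_graph.n_atoms)
    flags_frag[[remap[example.anchor_a_y], remap[example.anchor_b_y]]] = 1.0
    info = example.pair.info.as_array()
    c = _context(params, frag_graph, flags_frag, info)

    exp_ids = sorted(linker)
    true_types = [Y.atoms[i] for i in exp_ids]
    types, h0_exp, type_logp = _expansion_init(params, len(exp_ids), z, c, rng,
                                               forced_types=true_types)

    flags_full = np.zeros(Y.n_atoms)
    flags_full[[example.anchor_a_y, example.anchor_b_y]] = 1.0
    H0_frag = _node_init(params, [Y.atoms[i] for i in frag_atoms], flags_full[frag_atoms])
    # scatter fragment and expansion rows back to Y ordering
    perm = np.zeros((Y.n_atoms, Y.n_atoms))
    for row, i in enumerate(frag_atoms):
        perm[i, row] = 1.0
    for row, i in enumerate(exp_ids):
        perm[i, len(frag_atoms) + row] = 1.0
    H0 = Tensor(perm) @ Tensor.concat([H0_frag, h0_exp], axis=0)

    state = GenerationState(graph=graph, H0=H0, H=H0,
                            queue=deque([example.anchor_a_y, example.anchor_b_y]),
                            expansion_ids=exp_ids, expansion_types=types,
                            info=info, rng=rng, n_expansion=len(exp_ids))
    state.refresh(params)
    # type reconstruction term: -log p(true type) per expansion node
    rows = np.arange(len(exp_ids))
    state.type_loss = -(type_logp[rows, np.asarray(true_types, dtype=int)].sum())
    return state


def _teacher_trace_loss(example: TrainingExample, params: ModelParams, z: Tensor,
                        rng: np.random.Generator | None) -> Tensor:
    """Negative log-likelihood of the teacher-forced decoding trace of Y."""
    Y = example.target
    linker = example.linker_atoms
    to_generate = {}
    for i, j, o in Y.bond_list():
        if i in linker or j in linker:
            to_generate[frozenset((i, j))] = o

    state = _teacher_state(example, params, z, rng)
    loss = state.type_loss
    while state.queue:
        v = state.queue[0]
        while True:
            targets = sorted(
                u for u in Y.neighbors(v)
                if frozenset((v, u)) in to_generate and not state.graph.has_bond(v, u)
            )
            cands, logp = edge_distribution(state, params, v)
            if not targets:
                if cands:  # learn to stop; with no candidates STOP is forced
                    loss = loss + (-logp[len(cands)])
                break
            u_star = targets[0]
            if state.graph.neighbors(u_star):
                equiv = [u_star]
            else:  # interchangeable: unconnected expansion nodes of the same type
                t_star = state.graph.atoms[u_star]
                equiv = [u for u in cands
                         if u in linker and not state.graph.neighbors(u)
                         and state.graph.atoms[u] == t_star]
            idx = np.asarray([cands.index(u) for u in equiv], dtype=int)
            loss = loss + (-(logp[idx].logsumexp()))
            order = to_generate[frozenset((v, u_star))]
            legal, label_logp = _label_logp(state, params, v, u_star)
            loss = loss + (-label_logp[legal.index(order - 1)])
            newly = len(state.graph.neighbors(u_star)) == 0
            state.graph.add_bond(v, u_star, order)
            if newly:
                state.queue.append(u_star)
            state.step_states(params)
        state.queue.popleft()
        state.refresh(params)
    return loss


def encode_latent(example: TrainingExample, params: ModelParams):
    """Latent posterior (mu, logvar) from the true molecule Y.

    Y is encoded by the GGNN, the hidden states of its linker atoms are
    averaged and mapped to the latent dimension.  Deterministic; the
    public latent code z is mu.
    """
    if not example.linker_atoms:
        raise ValueError("example has no linker atoms")
    w = params.weights
    Y = example.target
    flags = np.zeros(Y.n_atoms)
    flags[[example.anchor_a_y, example.anchor_b_y]] = 1.0
    H0 = _node_init(params, Y.atoms, flags)
    H = propagate(H0, _adjacency(Y), params, params.prop_steps)
    m = H[np.asarray(sorted(example.linker_atoms), dtype=int)].mean(axis=0)
    mu = m @ w["W_mu"] + w["b_mu"]
    logvar = m @ w["W_lv"] + w["b_lv"]
    return mu, logvar


def example_loss(example: TrainingExample, params: ModelParams,
                 rng: np.random.Generator | None):
    """(total, reconstruction, kl) Tensors for one example."""
    mu, logvar = encode_latent(example, params)
    if rng is None:
        z = mu
    else:
        eps = Tensor(rng.standard_normal(params.latent_dim))
        z = mu + (logvar * 0.5).exp() * eps
    recon = _teacher_trace_loss(example, params, z, rng)
    kl = 0.5 * (logvar.exp() + mu * mu - 1.0 - logvar).sum()
    total = recon + params.beta * kl
    return total, recon, kl


def vae_loss(batch: list[TrainingExample], params: ModelParams,
             rng: np.random.Generator | None = None):
    """Mean (total, reconstruction, kl) over a batch; total is a Tensor."""
    if not batch:
        raise ValueError("batch must be non-empty")
    total = recon = kl = None
    for ex in batch:
        t, r, k = example_loss(ex, params, rng)
        total = t if total is None else total + t
        recon = r if recon is None else recon + r
        kl = k if kl is None else kl + k
    n = float(len(batch))
    return total / n, recon.item() / n, kl.item() / n


def train(dataset: list[TrainingExample], config: dict | None = None) -> "LinkerVAE":
    """Functional wrapper over the LinkerVAE estimator."""
    model = LinkerVAE(**(config or {}))
    return model.fit(dataset)


# ---------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------

class LinkerVAE(BaseEstimator):
    """Gated-graph VAE linker generator, scikit-learn style.

    Parameters
    ----------
    hidden_dim : node hidden-state width d.
    prop_steps : message-passing rounds T per propagation.
    latent_dim : width of the latent code z.
    edge_hidden : hidden width of the edge/label perceptrons.
    beta : KL weight in the loss.
    max_expansion : hard cap on expansion nodes per sample.
    learning_rate, n_epochs, batch_size : Adam training schedule.
    random_state : seed for initialization, latent noise and sampling.

    Attributes (after fit)
    ----------------------
    params_ : ModelParams with trained weights.
    loss_history_ : per-epoch (total, reconstruction, kl) means.
    n_examples_ : training-set size.
    """

    def __init__(self, hidden_dim=32, prop_steps=7, latent_dim=8, edge_hidden=32,
                 beta=1.0, max_expansion=20, learning_rate=0.01, lr_decay=1.0,
                 n_epochs=100, batch_size=4, random_state=None, verbose=False):
        self.hidden_dim = hidden_dim
        self.prop_steps = prop_steps
        self.latent_dim = latent_dim
        self.edge_hidden = edge_hidden
        self.beta = beta
        self.max_expansion = max_expansion
        self.learning_rate = learning_rate
        self.lr_decay = lr_decay
        self.n_epochs = n_epochs
        self.batch_size = batch_size
        self.random_state = random_state
        self.verbose = verbose

    def fit(self, X: list[TrainingExample], y=None, validation=None):
        if not X:
            raise TrainingError("training dataset is empty")
        rng = np.random.default_rng(self.random_state)
        registry = X[0].target.registry
        params = init_params(registry=registry, hidden_dim=self.hidden_dim,
                             prop_steps=self.prop_steps, latent_dim=self.latent_dim,
                             edge_hidden=self.edge_hidden, beta=self.beta,
                             max_expansion=self.max_expansion, rng=rng)
        opt = Adam(params.weights, lr=self.learning_rate)
        history = []
        best = None
        for epoch in range(self.n_epochs):
            if self.lr_decay != 1.0 and self.n_epochs > 1:
                opt.lr = self.learning_rate * self.lr_decay ** (epoch / (self.n_epochs - 1))
            order = rng.permutation(len(X))
            tot = rec = kld = 0.0
            for start in range(0, len(X), self.batch_size):
                batch = [X[i] for i in order[start:start + self.batch_size]]
                opt.zero_grad()
                total, recon, kl = vae_loss(batch, params, rng)
                if not np.isfinite(total.item()):
                    raise TrainingError(f"loss diverged (NaN/inf) at epoch {epoch}")
                total.backward()
                opt.step()
                tot += total.item() * len(batch)
                rec += recon * len(batch)
                kld += kl * len(batch)
            n = len(X)
            history.append((tot / n, rec / n, kld / n))
            if self.verbose:
                print(f"epoch {epoch:4d}  total {tot / n:9.4f}  "
                      f"recon {rec / n:9.4f}  kl {kld / n:8.4f}")
            if validation:
                with no_grad():
                    vtot, _, _ = vae_loss(list(validation), params, rng=None)
                vloss = vtot.item()
                if best is None or vloss < best[0]:
                    best = (vloss, {k: v.data.copy() for k, v in params.weights.items()})
        if validation and best is not None:
            for k, v in params.weights.items():
                v.data = best[1][k]
        self.params_ = params
        self.loss_history_ = history
        self.n_examples_ = len(X)
        return self

    def sample(self, pair: FragmentPair, n_samples: int, length_range=(3, 12),
               rng=None, temperature: float = 1.0,
               deterministic: bool = False) -> list[MolecularGraph]:
        if not hasattr(self, "params_"):
            raise RuntimeError("model is not fitted")
        if rng is None:
            rng = np.random.default_rng(self.random_state)
        elif isinstance(rng, (int, np.integer)):
            rng = np.random.default_rng(rng)
        return generate(self.params_, pair, n_samples, length_range, rng,
                        temperature, deterministic)

    def save(self, path):
        self.params_.save(path)

    @classmethod
    def from_checkpoint(cls, path) -> "LinkerVAE":
        params = ModelParams.load(path)
        model = cls(hidden_dim=params.hidden_dim, prop_steps=params.prop_steps,
                    latent_dim=params.latent_dim, edge_hidden=params.edge_hidden,
                    beta=params.beta, max_expansion=params.max_expansion)
        model.params_ = params
        model.loss_history_ = []
        return model
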