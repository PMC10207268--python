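"""Gated-graph VAE: propagation, masking, sampling, loss bookkeeping.

The loss oracle at the bottom re-implements the whole teacher-forced
forward pass in plain NumPy — node embeddings, GRU propagation,
expansion-node initialization, edge feature assembly, scoring,
marginalized selection terms and KL — independently of the package's
autodiff tape, and must agree with `example_loss` to float precision.
"""

from collections import deque

import numpy as np
import pytest

from fraglink import fixtures
from fraglink.autodiff import Tensor, no_grad
from fraglink.model import (STOP, ConfigurationError,
                            LinkerVAE, TrainingError, _adjacency,
                            edge_distribution, encode_latent, example_loss,
                            generate, init_generation, init_params, propagate,
                            run_decoder, select_edge, vae_loss)
from fraglink.molgraph import (check_valence, is_connected, parse_structure,
                               write_canonical)


@pytest.fixture(scope="module")
def params():
    return init_params(hidden_dim=10, prop_steps=3, latent_dim=4, edge_hidden=8,
                       rng=np.random.default_rng(7))


@pytest.fixture(scope="module")
def pair():
    spec = fixtures.FixtureSpec(n_molecules=1, seed=3)
    return fixtures.make_fragment_pair(spec, seed=3)


@pytest.fixture(scope="module")
def tiny_examples():
    spec = fixtures.FixtureSpec(n_molecules=4, seed=9, chain_length=(3, 4), p_ring=0.0)
    return [fixtures.planted_example(e) for e in fixtures.make_library(spec)]


class TestPropagate:
    def test_zero_steps_is_identity(self, params, rng):
        g = parse_structure("CCO")
        H = Tensor(rng.normal(size=(3, params.hidden_dim)))
        out = propagate(H, _adjacency(g), params, steps=0)
        assert np.array_equal(out.data, H.data)

    def test_isolated_node_follows_zero_message_update(self, params, rng):
        g = parse_structure("C.C")  # two isolated atoms
        H = Tensor(rng.normal(size=(2, params.hidden_dim)))
        out = propagate(H, _adjacency(g), params, steps=1)
        w = params.weights
        M = np.zeros_like(H.data)
        zg = 1 / (1 + np.exp(-(M @ w["W_z"].data + H.data @ w["U_z"].data + w["b_z"].data)))
        rg = 1 / (1 + np.exp(-(M @ w["W_r"].data + H.data @ w["U_r"].data + w["b_r"].data)))
        hh = np.tanh(M @ w["W_h"].data + (rg * H.data) @ w["U_h"].data + w["b_h"].data)
        assert np.allclose(out.data, (1 - zg) * H.data + zg * hh, atol=1e-12)

    def test_permutation_equivariance(self, params, rng):
        g = parse_structure("CC(=O)NCCO")
        n = g.n_atoms
        H = rng.normal(size=(n, params.hidden_dim))
        out = propagate(Tensor(H), _adjacency(g), params, steps=3).data
        perm = rng.permutation(n)
        gp = g.copy()
        gp.atoms = [g.atoms[i] for i in np.argsort(perm)]
        gp.bonds = {}
        for i, j, o in g.bond_list():
            gp.add_bond(int(perm[i]), int(perm[j]), o)
        outp = propagate(Tensor(H[np.argsort(perm)]), _adjacency(gp), params, steps=3).data
        assert np.allclose(outp, out[np.argsort(perm)], atol=1e-10)


class TestInitGeneration:
    def test_adds_exactly_n_isolated_nodes(self, params, pair):
        n_frag = pair.fragment_a.n_atoms + pair.fragment_b.n_atoms
        state = init_generation(pair, 5, params, np.random.default_rng(0))
        assert state.graph.n_atoms == n_frag + 5
        assert all(state.graph.neighbors(i) == [] for i in state.expansion_ids)
        assert list(state.queue)[0] == pair.anchor_a

    def test_seeded_determinism(self, params, pair):
        a = init_generation(pair, 4, params, np.random.default_rng(5))
        b = init_generation(pair, 4, params, np.random.default_rng(5))
        assert a.expansion_types == b.expansion_types
        assert np.allclose(a.H0.data, b.H0.data)

    def test_budget_above_max_is_error(self, params, pair):
        with pytest.raises(ConfigurationError):
            init_generation(pair, params.max_expansion + 1, params,
                            np.random.default_rng(0))

    def test_type_sampling_matches_multinomial_with_uniform_logits(self, pair):
        """With zeroed classifier weights every type is equally likely."""
        p = init_params(hidden_dim=8, prop_steps=1, rng=np.random.default_rng(0))
        p.weights["W_f"].data[:] = 0.0
        p.weights["b_f"].data[:] = 0.0
        rng = np.random.default_rng(11)
        counts = np.zeros(p.n_types)
        draws = 0
        with no_grad():
            for _ in range(500):
                state = init_generation(pair, 20, p, rng)
                for t in state.expansion_types:
                    counts[t] += 1
                    draws += 1
        freq = counts / draws
        sigma = np.sqrt((1 / 14) * (13 / 14) / draws)
        assert np.all(np.abs(freq - 1 / 14) < 3 * sigma + 1e-12)


class TestEdgeSelection:
    def test_probabilities_sum_to_one_over_1000_random_states(self, params, pair, rng):
        """Normalization audit across randomly perturbed decoder states."""
        with no_grad():
            checked = 0
            while checked < 1000:
                state = init_generation(pair, int(rng.integers(2, 8)), params, rng)
                for v in list(state.queue):
                    state.H = Tensor(state.H.data + rng.normal(
                        scale=0.5, size=state.H.shape))
                    cands, logp = edge_distribution(state, params, v)
                    total = np.exp(logp.data).sum()
                    assert abs(total - 1.0) < 1e-9
                    checked += 1

    def test_masked_candidates_have_exactly_zero_probability(self, params, pair):
        with no_grad():
            state = init_generation(pair, 3, params, np.random.default_rng(2))
            v = state.queue[0]
            cands, logp = edge_distribution(state, params, v)
            legal = set(cands)
            g = state.graph
            for u in range(g.n_atoms):
                if u == v or g.has_bond(v, u) or g.free_valence(u) <= 0:
                    assert u not in legal

    def test_saturated_node_stops_with_probability_one(self, params, pair):
        with no_grad():
            state = init_generation(pair, 3, params, np.random.default_rng(0))
            v = state.queue[0]
            k = 0
            while state.graph.free_valence(v) > 0:  # saturate the queue head
                state.graph.add_bond(v, state.expansion_ids[k], 1)
                k += 1
            cands, logp = edge_distribution(state, params, v)
        assert cands == [] and np.exp(logp.data).tolist() == [1.0]
        assert select_edge(state, v, params, np.random.default_rng(0)) == STOP

    def test_uniform_scores_give_uniform_distribution(self, params, pair):
        p = init_params(hidden_dim=10, prop_steps=3, edge_hidden=8,
                        rng=np.random.default_rng(7))
        p.weights["W_e1"].data[:] = 0.0
        p.weights["b_e1"].data[:] = 0.0
        p.weights["b_e2"].data[:] = 0.0
        with no_grad():
            state = init_generation(pair, 4, p, np.random.default_rng(1))
            cands, logp = edge_distribution(state, p, state.queue[0])
        probs = np.exp(logp.data)
        assert np.allclose(probs, 1.0 / len(probs), atol=1e-12)


class TestGenerate:
    def test_sample_count_contract(self, params, pair):
        mols = generate(params, pair, 25, length_range=(3, 6),
                        rng=np.random.default_rng(4))
        assert len(mols) == 25

    def test_every_sample_valence_legal_and_connected(self, params, pair):
        mols = generate(params, pair, 40, length_range=(3, 8),
                        rng=np.random.default_rng(8))
        for m in mols:
            assert check_valence(m) == []
            assert is_connected(m)

    def test_emitted_bond_orders_always_legal_over_many_steps(self, params, pair):
        """Audit every decoder step: after each addition both endpoints
        must still satisfy the registry valence bound."""
        rng = np.random.default_rng(3)
        steps = 0
        with no_grad():
            while steps < 2000:
                n_exp = int(rng.integers(3, 9))
                state = init_generation(pair, n_exp, params, rng)
                run_decoder(state, params, rng)
                assert check_valence(state.graph) == []
                steps += len(state.graph.bonds)

    def test_deterministic_mode_reproducible(self, params, pair):
        a = generate(params, pair, 3, length_range=(4, 4), deterministic=True)
        b = generate(params, pair, 3, length_range=(4, 4), deterministic=True)
        assert [write_canonical(m) for m in a] == [write_canonical(m) for m in b]

    def test_bad_length_range_rejected(self, params, pair):
        with pytest.raises(ConfigurationError):
            generate(params, pair, 1, length_range=(5, 3))


class TestEncoderAndLoss:
    def test_encode_latent_deterministic_with_right_dim(self, params, tiny_examples):
        mu1, lv1 = encode_latent(tiny_examples[0], params)
        mu2, _ = encode_latent(tiny_examples[0], params)
        assert np.array_equal(mu1.data, mu2.data)
        assert mu1.shape == (params.latent_dim,) and lv1.shape == (params.latent_dim,)

    def test_encode_latent_invariant_to_atom_relabeling(self, params, tiny_examples):
        import copy

        ex = tiny_examples[0]
        n = ex.target.n_atoms
        rng = np.random.default_rng(0)
        perm = rng.permutation(n)
        inv = np.argsort(perm)
        g = ex.target
        gp = g.copy()
        gp.atoms = [g.atoms[i] for i in inv]
        gp.bonds = {}
        for i, j, o in g.bond_list():
            gp.add_bond(int(perm[i]), int(perm[j]), o)
        gp.positions = None
        exp = copy.copy(ex)
        exp.target = gp
        exp.linker_atoms = frozenset(int(perm[i]) for i in ex.linker_atoms)
        exp.anchor_a_y = int(perm[ex.anchor_a_y])
        exp.anchor_b_y = int(perm[ex.anchor_b_y])
        mu, _ = encode_latent(ex, params)
        mup, _ = encode_latent(exp, params)
        assert np.allclose(mu.data, mup.data, atol=1e-9)

    def test_kl_zero_when_posterior_equals_prior(self, tiny_examples):
        p = init_params(hidden_dim=10, prop_steps=2, latent_dim=4,
                        rng=np.random.default_rng(1))
        for k in ("W_mu", "b_mu", "W_lv", "b_lv"):
            p.weights[k].data[:] = 0.0
        _, _, kl = example_loss(tiny_examples[0], p, rng=None)
        assert kl.item() == pytest.approx(0.0, abs=1e-12)

    def test_loss_positive_and_reproducible(self, params, tiny_examples):
        t1, r1, k1 = vae_loss(tiny_examples, params, rng=None)
        t2, r2, k2 = vae_loss(tiny_examples, params, rng=None)
        assert t1.item() == t2.item() and r1 == r2 and k1 == k2
        assert r1 > 0 and k1 >= 0

    def test_empty_batch_rejected(self, params):
        with pytest.raises(ValueError):
            vae_loss([], params)


class TestTraining:
    def test_empty_dataset_is_error(self):
        with pytest.raises(TrainingError):
            LinkerVAE(n_epochs=1).fit([])

    def test_same_seed_identical_final_loss(self, tiny_examples):
        cfg = dict(hidden_dim=8, prop_steps=2, edge_hidden=8, n_epochs=3,
                   batch_size=2, random_state=5)
        a = LinkerVAE(**cfg).fit(tiny_examples)
        b = LinkerVAE(**cfg).fit(tiny_examples)
        assert a.loss_history_ == b.loss_history_

    def test_loss_decreases_over_first_epochs(self, tiny_examples):
        vae = LinkerVAE(hidden_dim=12, prop_steps=2, edge_hidden=12, n_epochs=5,
                        batch_size=1, learning_rate=0.01, random_state=0)
        vae.fit(tiny_examples)
        totals = [h[0] for h in vae.loss_history_]
        assert all(b < a for a, b in zip(totals, totals[1:]))

    def test_checkpoint_round_trip(self, tiny_examples, tmp_path):
        vae = LinkerVAE(hidden_dim=8, prop_steps=2, edge_hidden=8, n_epochs=2,
                        batch_size=2, random_state=1).fit(tiny_examples)
        path = tmp_path / "ckpt.npz"
        vae.save(path)
        back = LinkerVAE.from_checkpoint(path)
        pair = tiny_examples[0].pair
        a = back.sample(pair, 2, length_range=(3, 3), rng=2, deterministic=True)
        b = vae.sample(pair, 2, length_range=(3, 3), rng=2, deterministic=True)
        assert [write_canonical(m) for m in a] == [write_canonical(m) for m in b]

    def test_sklearn_param_interface(self):
        vae = LinkerVAE()
        assert vae.get_params()["hidden_dim"] == 32
        vae.set_params(hidden_dim=16)
        assert vae.hidden_dim == 16


# ---------------------------------------------------------------------
# Independent forward-pass oracle
# ---------------------------------------------------------------------

def numpy_example_loss(ex, params):
    """Plain-NumPy re-implementation of the deterministic (rng=None)
    teacher-forced VAE loss: z = mu, zero expansion noise."""
    w = {k: v.data for k, v in params.weights.items()}
    d, T = params.hidden_dim, params.prop_steps
    Y = ex.target
    linker = set(ex.linker_atoms)
    nY = Y.n_atoms

    def sigmoid(x):
        return 1 / (1 + np.exp(-x))

    def adj(bonds, n):
        A = [np.zeros((n, n)) for _ in range(3)]
        for i, j, o in bonds:
            A[o - 1][i, j] = A[o - 1][j, i] = 1
        return A

    def prop(H, A, steps):
        for _ in range(steps):
            M = sum(A[b] @ (H @ w[f"W_msg{b + 1}"]) for b in range(3))
            zg = sigmoid(M @ w["W_z"] + H @ w["U_z"] + w["b_z"])
            rg = sigmoid(M @ w["W_r"] + H @ w["U_r"] + w["b_r"])
            hh = np.tanh(M @ w["W_h"] + (rg * H) @ w["U_h"] + w["b_h"])
            H = (1 - zg) * H + zg * hh
        return H

    def logsoftmax(x):
        m = x.max()
        return x - m - np.log(np.exp(x - m).sum())

    # encoder: z = mu
    flags = np.zeros(nY)
    flags[[ex.anchor_a_y, ex.anchor_b_y]] = 1
    H0Y = np.tanh(w["type_emb"][Y.atoms] + flags[:, None] * w["w_anchor"][0])
    HY = prop(H0Y, adj(Y.bond_list(), nY), T)
    m_link = HY[sorted(linker)].mean(axis=0)
    mu = m_link @ w["W_mu"] + w["b_mu"]
    logvar = m_link @ w["W_lv"] + w["b_lv"]
    kl = 0.5 * np.sum(np.exp(logvar) + mu**2 - 1 - logvar)
    z = mu

    # decoder state
    frag_atoms = sorted(set(range(nY)) - linker)
    frag_bonds = [(i, j, o) for i, j, o in Y.bond_list()
                  if i not in linker and j not in linker]
    nf = len(frag_atoms)
    remap = {a: k for k, a in enumerate(frag_atoms)}
    fflags = np.array([1.0 if a in (ex.anchor_a_y, ex.anchor_b_y) else 0.0
                       for a in frag_atoms])
    H0f = np.tanh(w["type_emb"][[Y.atoms[a] for a in frag_atoms]]
                  + fflags[:, None] * w["w_anchor"][0])
    Af = adj([(remap[i], remap[j], o) for i, j, o in frag_bonds], nf)
    Hf = prop(H0f, Af, T)
    info = ex.pair.info.as_array()
    c = np.tanh(Hf.mean(axis=0) @ w["W_c"] + info @ w["W_cI"] + w["b_c"])

    exp_ids = sorted(linker)
    ne = len(exp_ids)
    cond = z @ w["W_lat"] + c @ w["W_ctx"] + w["b_exp"]
    pre = np.tile(cond, (ne, 1)) + w["W_pos"][:ne]
    s = np.tanh(pre)
    tlogits = np.tanh(s @ w["W_f1"] + w["b_f1"]) @ w["W_f"] + w["b_f"]
    loss = 0.0
    true_types = [Y.atoms[i] for i in exp_ids]
    for row, tt in enumerate(true_types):
        loss += -logsoftmax(tlogits[row])[tt]
    h0e = np.tanh(pre + w["type_emb"][true_types])

    H0 = np.zeros((nY, d))
    for k, a in enumerate(frag_atoms):
        H0[a] = H0f[k]
    for k, a in enumerate(exp_ids):
        H0[a] = h0e[k]

    bonds = list(frag_bonds)
    bond_set = {frozenset((i, j)) for i, j, _ in bonds}
    to_gen = {frozenset((i, j)): o for i, j, o in Y.bond_list()
              if i in linker or j in linker}
    maxval = {i: Y.registry[Y.atoms[i]].max_valence for i in range(nY)}

    def valence(i):
        return sum(o for a, b, o in bonds if i in (a, b))

    def neighbors(i):
        return sorted({b if a == i else a for a, b, o in bonds if i in (a, b)})

    def bfs_dist(v):
        dist = np.full(nY, -1.0)
        dist[v] = 0
        q = deque([v])
        while q:
            x = q.popleft()
            for y in neighbors(x):
                if dist[y] < 0:
                    dist[y] = dist[x] + 1
                    q.append(y)
        dist[dist < 0] = dist.max() + 1
        return dist

    H = prop(H0, adj(bonds, nY), T)

    def features(v, cands):
        dist = bfs_dist(v)
        rows = []
        for u in cands:
            rows.append(np.concatenate([H[v], H[u], [dist[u]],
                                        H0.mean(axis=0), H.mean(axis=0), info]))
        return np.vstack(rows + [w["phi_stop"][0]])

    queue = deque([ex.anchor_a_y, ex.anchor_b_y])
    while queue:
        v = queue[0]
        while True:
            targets = sorted(u for u in Y.neighbors(v)
                             if frozenset((v, u)) in to_gen
                             and frozenset((v, u)) not in bond_set)
            cands = ([u for u in range(nY)
                      if u != v and frozenset((v, u)) not in bond_set
                      and maxval[u] - valence(u) > 0]
                     if maxval[v] - valence(v) > 0 else [])
            if not targets:
                if cands:
                    feats = features(v, cands)
                    sc = (np.tanh(feats @ w["W_e1"] + w["b_e1"]) @ w["W_e2"]
                          + w["b_e2"]).ravel()
                    loss += -logsoftmax(sc)[len(cands)]
                break
            u_star = targets[0]
            if neighbors(u_star):
                equiv = [u_star]
            else:
                equiv = [u for u in cands if u in linker and not neighbors(u)
                         and Y.atoms[u] == Y.atoms[u_star]]
            feats = features(v, cands)
            sc = (np.tanh(feats @ w["W_e1"] + w["b_e1"]) @ w["W_e2"] + w["b_e2"]).ravel()
            lp = logsoftmax(sc)
            idx = [cands.index(u) for u in equiv]
            loss += -np.log(np.exp(lp[idx]).sum())
            order = to_gen[frozenset((v, u_star))]
            legal = list(range(min(3, maxval[v] - valence(v),
                                   maxval[u_star] - valence(u_star))))
            lf = features(v, [u_star])[:1]
            llog = (np.tanh(lf @ w["W_l1"] + w["b_l1"]) @ w["W_l2"] + w["b_l2"])[0]
            sub = llog[legal]
            loss += -logsoftmax(sub)[legal.index(order - 1)]
            newly = not neighbors(u_star)
            bonds.append((v, u_star, order))
            bond_set.add(frozenset((v, u_star)))
            if newly:
                queue.append(u_star)
            H = prop(H, adj(bonds, nY), 1)
        queue.popleft()
        H = prop(H0, adj(bonds, nY), T)
    return loss + params.beta * kl


class TestLossOracle:
    def test_matches_independent_numpy_forward(self, params, tiny_examples):
        for ex in tiny_examples:
            want = numpy_example_loss(ex, params)
            total, _, _ = example_loss(ex, params, rng=None)
            assert total.item() == pytest.approx(want, abs=1e-8)
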