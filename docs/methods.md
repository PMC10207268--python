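# Methods

## Problem and scope

`fraglink` addresses fragment linking: given two binding fragments with
marked attachment atoms (anchors) and the anchors' relative 3D geometry,
propose chemically sensible linkers that fuse the fragments into one
molecule. The motivating application is PROTAC design, where the linker
between a target-protein warhead and an E3-ligase ligand controls
ternary-complex geometry. The package covers generation, training-pair
construction, post-generation filtering, property profiling and the
pose/energy comparison arithmetic; it does not run docking, molecular
dynamics or free-energy simulations — those energies are consumed from
CSV produced by external tools.

## Molecular representation

Molecules are heavy-atom graphs. Atom types come from a 14-entry
registry of (element, formal charge, maximum valence): C, N, N+, O, O-,
F, S(2), S(4), S(6), Cl, Br, I, P(3), P(5). This is a standard
drug-like organic subset; the registry is a constructor argument, so an
alternative list drops in without code changes. Multi-valence elements
occupy one entry per valence state and an atom resolves to the smallest
state accommodating its explicit bonds. Bond orders are 1–3; aromatic
input is accepted but stored kekulized, because the decoder's label
alphabet is single/double/triple. Implicit hydrogens are not stored —
valence slack implies the hydrogen count. Stereochemistry is ignored
throughout.

## Training-pair construction

A training molecule Y is segmented by cutting exactly two distinct
acyclic single bonds such that the middle piece (the linker) has at
least 3 heavy atoms; ring bonds are never cut, so every ring survives
intact in one piece. All admissible cut pairs are enumerated; dataset
assembly caps them at 10 per molecule by seeded sampling to avoid
large-molecule bias. The minimum fragment size is 1 heavy atom: a
single-atom fragment is legitimate (the enumeration examples require
it), and its exit vector is taken along the cut bond, the only
geometric handle it has. The anchor descriptor I = (inter-anchor
distance in Å, exit-vector angle in radians) is always computed from
coordinates, never estimated from topology.

Dataset splitting is 90/10 via 10-fold cross-validation (shuffled
k-fold, seeded), matching the 1 − 1/k identity; a mismatched
`train_fraction`/`k_folds` combination is a configuration error.

## The gated-graph VAE

**Propagation.** Node states (width d, default 32) evolve by GGNN
message passing: per-bond-order message matrices, summed over bonded
neighbors, feed a gated recurrent (GRU-style) update; isolated nodes
receive the zero message and still update. Default T = 7 rounds.

**Initialization.** Fragment atoms embed by type plus a learned anchor
flag. A conditioning vector c is computed from the propagated
fragment-only graph (mean-pooled) and the descriptor I. Each of the n
expansion nodes gets a conditioned slot state — the latent code z, c
and a learned slot embedding through a linear map — and an atom type
sampled from the softmax of a small perceptron over that state. The
slot embedding breaks the symmetry between otherwise identically
conditioned expansion nodes so the classifier can express
position-dependent types along the linker. Each node also draws a
random state z_v ~ N(0, I_d) that perturbs its initial hidden state
through a learned map: sampling diversity flows into edge decisions
without blurring the type logits, which keeps type choices sharp once
the model is trained.

**Decoding.** Breadth-first from the two anchors (fragment A's anchor
first, FIFO queue). For the queue head v, candidates are all nodes not
yet bonded to v with free valence on both ends; masked candidates have
exactly zero probability. Scores come from a one-hidden-layer
perceptron over the edge feature

    phi(v,u) = [h_v, h_u, d_vu, mean(H^0), mean(H^t), I]

(length 4d+3); STOP is scored by the same network on a learned sentinel
feature. The graph distance d_vu for unreachable pairs uses the
sentinel value (max finite distance from v) + 1, keeping the feature
finite. A second perceptron labels the edge 1/2/3, masked to orders
legal for both endpoints. After each edge addition the states take one
incremental message-passing round; after a node finishes (STOP), states
are recomputed from H^0 over the current topology — prior states are
discarded, so decoding depends only on the present graph. When the
queue empties, unconnected leftovers are dropped and the largest intact
component (ties broken by lowest original atom index) is returned.
Samples that fail to link the fragments are returned anyway; the filter
stage judges them.

**Training.** The encoder propagates the full molecule Y, averages the
hidden states of its linker atoms and maps them to an 8-dimensional
Gaussian posterior (mu, log-variance). The reconstruction term is the
negative log-likelihood of the teacher-forced decoding trace of Y given
the fragments and z: atom-type terms, edge-selection terms and
edge-label terms, mirroring the exact refresh schedule of generation.
When several interchangeable expansion nodes (same type, still
unconnected) could serve as the selection target, their probabilities
are summed — the likelihood of the molecule rather than of one
arbitrary node labeling. The loss is reconstruction + beta·KL(posterior
|| N(0,I)), beta = 1 by default. Optimization is Adam (default lr 0.01,
optional exponential decay, minibatch 4), seeded and deterministic per
seed; a NaN loss raises a training error naming the epoch.

**Hyperparameter defaults** (d = 32, T = 7, latent 8, edge hidden 32,
beta = 1) are package choices exposed in configuration; the expansion
budget per sample is drawn uniformly from a user length range (default
3–12 atoms), since linker length between the anchors is a user-facing
control. Sampling temperature is 1.0; a deterministic mode replaces
every sampling site with its argmax (latent and node noise become
zeros, the budget becomes the midpoint of the range).

**Autodiff.** No GPU framework is used: the package carries a ~300-line
reverse-mode tape over NumPy arrays (`fraglink.autodiff`) providing
exactly the operations the model needs, audited against central
differences in the test suite. Sampling runs the same code with the
tape disabled.

## Post-generation filters

Stage 1 removes duplicates (first occurrence by canonical SMILES kept,
order-stable) and non-linked outputs: a molecule passes only if it is
one connected compound containing both fragments as node-induced
subgraphs on disjoint atom sets, with each fragment's anchor bonded to
at least one linker atom. Stage 2 drops molecules whose linker region
(linker atoms plus their anchor bonds — the warheads are fixed user
input and are not penalized) matches any unwanted motif:

- acid halide `[CX3](=O)[F,Cl,Br,I]`, disulfide `[#16]-[#16]`,
  peroxide `[#8]-[#8]` — from an editable plain-text SMARTS registry;
- strained small-ring alkene: C=C inside a 3- or 4-membered ring
  (cyclopropene/cyclobutene class), by ring analysis — a SMARTS on ring
  membership alone would also hit exocyclic alkenes between two rings;
- Bredt-rule violation: ring pairs sharing ≥ 3 atoms form a bridged
  (not merely fused) system; the bridgeheads are shared atoms with a
  neighbor outside the shared path; a C=C at a bridgehead is flagged
  when every ring through the atom has ≤ 7 members, since large bridged
  rings accommodate the planar center.

The learned "drug-lead feasibility" idea sometimes attached to such
pipelines is deliberately not implemented; the filter is a
deterministic pattern registry.

## Property profiling

The Rule of Three is applied to the extracted linker with attachment
points hydrogen-capped, not to the full PROTAC: MW < 300 Da, cLogP ≤ 3,
HBD ≤ 3, HBA ≤ 3, extended with topological PSA ≤ 60 Å². Descriptors
use the standard published schemes — Wildman–Crippen atom contributions
(cLogP), Ertl fragment contributions (TPSA), Lipinski N/O counting
(HBD/HBA) — via RDKit; the test suite checks cLogP/TPSA against an
independently coded contribution-table oracle on fixture chemistry.
Ring statistics use the smallest-set-of-smallest-rings basis; the
">6-membered" bucket means a ring of size ≥ 7, and a molecule counts
once per ring-size bucket regardless of how many rings of that size it
has (incidence per molecule). Generation metrics: valid = valence-legal
and linked at the designated anchors; unique = distinct canonical forms
among valid; novel = unique valid molecules whose extracted linker is
absent from the training linker set (computed on the unique set only).

## Validation arithmetic

RMSD over index-corresponding atoms, optionally after least-squares
superposition (Kabsch SVD with the determinant sign corrected —
reflections disallowed). Relative binding energy is pose minus
reference (the crystal pose), so a negative ΔΔG means the pose binds
more favorably than the reference. FEP ΔΔG per run is ΔG_complex −
ΔG_ligand; repeat runs aggregate as mean ± sample SD (n − 1
denominator), rounded to 2 decimals only at report time.

## Synthetic data

The fixture generator emulates the warhead–linker–warhead construction
of real training libraries: two fragments from an 8-entry vocabulary of
warhead-like aromatics/amides (plain-text SMILES list), joined by a
linker from a grammar of alkyl chains (3–8 backbone atoms) with
per-position O/N substitution probability 0.2 (never two adjacent
heteroatoms, which would immediately trip the peroxide/disulfide
filters) and probability 0.25 of expanding one backbone carbon into a
para-linked cyclohexane. These chemotypes — PEG-like/alkyl chains with
amines and ethers, occasionally carbocycles — are the dominant linker
classes in real PROTACs. Coordinates are idealized (1.5 Å bonds,
near-tetrahedral angles, seeded dihedrals), sufficient for the
distance/angle descriptor; ring closures are approximate, and no
force-field embedding or property-distribution matching of real
libraries is attempted. Consequently, passing tests demonstrate the
pipeline's correctness and the model's capacity to learn the
fragment-to-linker mapping at toy scale — not chemical coverage of real
PROTAC space. Fragment pairs for generation place anchors at a uniform
distance in [4, 12] Å and exit-vector angle in [0, π].

## Scaled-down problem sizes

Full-scale training (hundreds of thousands of molecules) is out of
scope. The learning check trains on 20 synthetic pairs with chain
lengths 3–6 and ring probability 0.2, model width 24, T = 4, 700 epochs
of Adam (lr 0.01 decaying exponentially to 0.001, batch 1), then samples 100
molecules per pair with the expansion budget pinned to the true linker
length — linker length is a user-facing control, and pinning it asks
the model to reproduce the right linker at the right size. Recovery is
scored by canonical-SMILES identity of the whole molecule against the
planted one.

## Numerical and degenerate-case choices

- Edge/label distributions are exact softmaxes over the unmasked set;
  normalization is audited to 1e-9 in tests.
- A queue head with zero free valence or no legal partner STOPs with
  probability one.
- Argmax (deterministic) mode breaks ties toward the lowest node index;
  STOP is ordered after all candidates.
- `largest_component` breaks size ties by lowest contained original
  atom index.
- Kabsch superposition clamps to proper rotations; arccos inputs are
  clipped to [-1, 1].
- Zero-length exit vectors raise a degenerate-geometry error rather
  than returning NaN.

## Known limitations

- The decoder never emits aromatic-flagged bonds; aromatic rings can
  only arise as kekulized alternating patterns, which the toy-scale
  model rarely produces.
- The canonical-form equality used for dedup/novelty is exact
  structural identity; tautomers and resonance forms are distinct.
- The anchor-linkage check enumerates induced subgraph embeddings
  (VF2); for pathological self-similar fragments this can be slow,
  though typical warheads are small.
- Idealized fixture geometry does not close rings exactly; only anchor
  distances/angles are geometrically meaningful.
- The Bredt rule implemented is the classic small-bicyclic heuristic,
  not a strain-energy calculation.
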