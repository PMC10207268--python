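# fraglink

Graph-generative fragment linking for PROTAC linker design.

A PROTAC (proteolysis-targeting chimera) joins a target-protein warhead
and an E3-ligase ligand through a linker. Given the two warhead
fragments — each with a marked attachment atom (anchor) and the anchors'
relative geometry — `fraglink` grows candidate linkers atom by atom with
a gated-graph variational autoencoder, then screens the output with
medicinal-chemistry filters and profiles it with fragment-likeness and
ring statistics. It also implements the structural/energetic comparison
arithmetic used to rank docked candidate poses (RMSD, relative binding
free energies, FEP aggregation).

## The model

Fragments are heavy-atom graphs; atom types come from a restricted
registry of 14 (element, charge, max valence) entries. A gated graph
neural network (GGNN) propagates node states `h_v` over the molecular
graph for `T` rounds using one message matrix per bond order and a gated
recurrent update. Generation starts from the two embedded fragments plus
`n` unconnected *expansion nodes*, each with a random hidden state and an
atom type sampled from a learned classifier. Decoding is breadth-first
from the two anchors: for the queue head `v`, every valence-legal
partner `u` (plus a STOP sentinel) is scored from the feature

    phi(v, u) = [h_v, h_u, d_vu, mean(H^0), mean(H^t), I]

where `d_vu` is the graph distance and `I = (anchor distance,
exit-vector angle)`; a second scorer labels the new edge single, double
or triple, masked to valence-legal orders. Training is a VAE: the latent
code `z` is the averaged encoded state of the true linker atoms, the
reconstruction term is the negative log-likelihood of the teacher-forced
decoding trace, and a KL term (weight `beta`) regularizes the posterior
toward a standard normal:

    L(theta, phi) = E_q [ -log p_phi(Y | X, z) ] + beta * KL( q_theta(z | Y) || N(0, I) )

Sampled molecules are valence-legal by construction (illegal partners
and bond orders receive exactly zero probability); whether they link the
two fragments at the designated anchors is judged by the filter stage.

The network runs on a small reverse-mode autodiff engine written for
this package (`fraglink.autodiff`) — plain NumPy underneath, no GPU.

## Worked example

Train a toy model on a synthetic library and sample linkers for a
fragment pair (the synthetic generator emulates the
warhead–linker–warhead construction of real training sets):

```python
import numpy as np
from fraglink import fixtures, LinkerVAE, run_pipeline, rule_of_three_report
from fraglink.postfilter import extract_linker

lib = fixtures.make_library(fixtures.FixtureSpec(n_molecules=20, seed=0,
                                                 chain_length=(3, 6), p_ring=0.2))
examples = [fixtures.planted_example(e) for e in lib]

vae = LinkerVAE(hidden_dim=24, prop_steps=4, edge_hidden=24, n_epochs=700,
                learning_rate=0.01, lr_decay=0.1, batch_size=1, random_state=0)
vae.fit(examples)

pair = examples[0].pair
mols = vae.sample(pair, 100, length_range=(3, 8), rng=np.random.default_rng(1))
kept, report = run_pipeline(mols, pair)
print(report.summary())
linkers = [extract_linker(m, pair) for m in kept]
print(rule_of_three_report(linkers))
```

Output (seed 0):

```
raw: 100
after dedup + linkage filter: 8
after substructure filter: 8
{'mw': 100, 'clogp': 100, 'hbd': 100, 'hba': 100, 'psa': 100}
```

The three filter counts are the pipeline's shape — raw samples, then
unique molecules actually linked at both anchors, then those whose
linker region is free of reactive/strained motifs. The sharp drop at
dedup is expected for a model overfit to 20 pairs: most samples repeat
the same few linkers. The final dict is the Rule-of-Three report: the
percentage of kept linkers passing each fragment-likeness threshold
(MW < 300 Da, cLogP <= 3, HBD <= 3, HBA <= 3, PSA <= 60 A^2).

The same pipeline is scriptable from the shell:

```bash
fraglink fixtures -n 100 --seed 0 -o out/fix
fraglink train out/fix/library.sdf --epochs 50 -o out/model
fraglink generate out/model/checkpoint.npz \
    --fragment-a '[*]c1ccccc1' --fragment-b '[*]c1ccncc1' \
    --distance 6.0 --angle 1.5 -n 200 -o out/gen
fraglink filter out/gen/generated.csv \
    --fragment-a '[*]c1ccccc1' --fragment-b '[*]c1ccncc1' -o out/filt
fraglink profile out/filt/filtered.csv -o out/prof
```

## Layout

- `fraglink.molgraph` — graph data model, atom-type registry, SMILES/SDF I/O
- `fraglink.fragmenter` — two-cut training-pair construction, anchor geometry, k-fold splits
- `fraglink.model` — the gated-graph VAE (`LinkerVAE`), sampling and training
- `fraglink.autodiff` — the reverse-mode tape the model trains on
- `fraglink.postfilter` — dedup, anchor-linkage check, substructure filters
- `fraglink.chemprops` — Rule of Three, ring statistics, generation metrics
- `fraglink.validate` — RMSD (Kabsch), ddG arithmetic, mean +/- SD aggregation
- `fraglink.fixtures` — seeded synthetic warhead-linker-warhead libraries
- `fraglink.cli` — the `fraglink` command

See `docs/methods.md` for modeling assumptions, parameter choices and
known limitations.
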