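# bindgraph

Prediction of protein–ligand **binding residues** from 3D structure, for
structural bioinformaticians who want to know not just *where* a ligand
binds but *how much the structure itself contributes* to that prediction.

A protein chain is turned into a residue proximity graph — nodes are
residues, and an edge connects residues whose alpha-carbon distance is
below a cutoff (4, 6, 8, 10 Å). Node features are per-residue vectors:
either context-independent physicochemical properties or externally
computed protein-language-model embeddings. A graph attention network
(GAT), a graph convolutional network (GCN) or a structure-blind multilayer
perceptron (the sequence baseline) then classifies every residue as
binding / non-binding through a two-way softmax.

Because the MLP sees *exactly* the same node features with the edge set
ignored, and a matched-density **random-graph baseline** sees the same
model with scrambled topology, the package can measure the contribution of
structure directly:

```
Δabs = MCC_model − MCC_baseline        Δrel = Δabs / MCC_baseline
```

with per-fold values and a one-sample t-test of Δrel against zero. MCC is
the Matthews Correlation Coefficient, the imbalance-robust headline metric
(binding residues are typically only a few percent of a chain). The
package also includes multi-cutoff majority-vote ensembling, attention
extraction with PyMOL coloring scripts, leakage-safe dataset splitting
(40% sequence-identity and 40% ligand-Tanimoto cluster splits with an
exhaustive audit), and a synthetic-data generator that plants a spatial
binding signal so the whole pipeline is testable without any downloads.

The neural networks run on a compact NumPy autodiff engine included in the
package — no deep-learning framework required.

## Worked example

```python
import numpy as np
import bindgraph as bg

# 120 synthetic complexes: self-avoiding CA traces, a ligand placed at a
# spatial pocket, labels = residues within 6 A of the ligand, node
# features = noisy one-hot residue identity (partial signal only)
spec = bg.SyntheticSpec(seed=100)
chains, features, ligands = bg.generate_dataset(spec)

out = bg.run_ablation_suite(chains, features, seeds=(0, 1, 2, 3, 4),
                            cutoff=8.0, epochs=150)
seq, top = out["sequence_ablation"], out["topology_ablation"]
print("GAT  best-val MCC per seed:", [round(x, 3) for x in out["gat"]])
print("MLP  best-val MCC per seed:", [round(x, 3) for x in out["mlp"]])
print("random-graph GAT per seed :", [round(x, 3) for x in out["gat_random"]])
print(f"structure vs sequence: d_abs={seq.delta_abs:.3f} "
      f"d_rel={seq.delta_rel:.3f} p={seq.p_value:.4f}")
print(f"true vs random topology: d_abs={top.delta_abs:.3f} p={top.p_value:.4f}")
```

Output (about 8 minutes on one core):

```
GAT  best-val MCC per seed: [0.207, 0.199, 0.192, 0.14, 0.204]
MLP  best-val MCC per seed: [0.123, 0.144, 0.116, 0.108, 0.145]
random-graph GAT per seed : [0.105, 0.117, 0.114, 0.106, 0.139]
structure vs sequence: d_abs=0.061 d_rel=0.486 p=0.0033
true vs random topology: d_abs=0.072 p=0.0047
```

Read: the GAT beats the sequence baseline in all five seeds (mean relative
improvement 49%, significant at the 0.01 threshold), and the advantage
disappears when the true contact topology is replaced by random edges of
the same density — the structural signal, not message passing per se, is
what the model exploits. Absolute MCCs are modest by design: the synthetic
features carry deliberately partial signal.

The same machinery works on real structures:

```python
chain = bg.parse_structure("complex.pdb", "A")          # CA trace + sequence
ligand = bg.extract_ligand("complex.pdb", "ATP")
chain.labels = bg.label_binding_residues(chain, ligand, radius=10.0)
graph = bg.build_residue_graph(chain, cutoff=8.0)
bg.attach_features(graph, bg.aaindex_features(chain.sequence))
```

A command-line interface mirrors the pipeline stages
(`bindgraph extract / build-graphs / featurize / train / predict /
ensemble / split / synth`); run `bindgraph --help`.

## Documentation

`docs/methods.md` describes the model, the ablation statistics, the split
procedure, what the synthetic generator does and does not emulate, and the
package's numerical conventions.
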