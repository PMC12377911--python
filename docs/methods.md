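# Methods

## Problem and model

`bindgraph` predicts, per residue, whether a protein residue binds a small
molecule or ion. The unit of computation is a single chain represented as a
**residue proximity graph**: nodes are residues, and two residues are
connected when the distance between their alpha carbons is *strictly less*
than a cutoff (4, 6, 8 or 10 Å; "GAT8" denotes the attention model on 8 Å
graphs). Labels, by contrast, use an *inclusive* comparison — a residue is a
binding residue when any of its considered atoms lies *within* the labeling
radius (10 Å by convention) of any ligand atom. The asymmetry (strict for
edges, inclusive for labels) is deliberate and documented at both call
sites.

Three classifiers share a two-way softmax head per residue:

* **GAT** — multi-head graph attention (additive scoring with LeakyReLU
  slope 0.2, per-neighborhood softmax). Head outputs are concatenated, so a
  512-unit layer with 4 heads carries 128 units per head. Residual
  connections use a learned projection when dimensions differ. A
  self-connection is added at forward time so attention is defined on
  isolated nodes.
* **GCN** — graph convolution with the symmetric normalized adjacency
  D^-1/2 (A + I) D^-1/2, batch normalization after each convolution and
  before the ReLU, plus residuals.
* **MLP** — the sequence baseline: identical node features, the edge set
  ignored entirely. Any advantage of the graph models over this baseline is
  attributable to structure.

Defaults follow the benchmark protocol: 512 hidden units, dropout 0.5 for
the graph models and 0.1 for the MLP, ReLU activations, AdamW with learning
rate 3e-4 and weight decay 1e-5, batches of 32 graphs, class-weighted
cross-entropy with w_c = N / (2 N_c) computed on the training set. Training
runs a fixed number of epochs and returns the weight snapshot from the
epoch with the highest validation MCC (no patience rule); with a
single-class validation set the selection falls back to minimum validation
loss, with a warning.

The networks, a reverse-mode autodiff engine, and AdamW are implemented
directly on NumPy (`_nn.py`). Graphs here are small (tens to a few hundred
nodes), so attention is computed densely over an L×L masked score matrix;
all arithmetic is float64 and evaluation mode is exactly deterministic.
Numerical choices: the fused log-sum-exp loss needs no probability
clamping; the standalone probability-space loss clamps at 1e-12; MCC
returns 0 on a zero denominator; ensemble majority votes break exact ties
toward the positive class (binding recall is at a premium; the rule is
overridable).

## Ablation statistics

Structure contribution is quantified per fold (or seed) as

    Δabs = MCC_model − MCC_baseline
    Δrel = Δabs / MCC_baseline

with a two-sided one-sample t-test of the per-fold Δrel against zero
(reporting threshold 0.01). Folds with a baseline MCC of exactly 0 are
excluded from Δrel and flagged. Two baselines isolate two questions: the
MLP (is structure informative at all?) and the **random-graph baseline** —
the same GAT on a graph with the *same edge count* but edges sampled
uniformly from pairs absent in the true graph (is it the real topology, or
mere message passing?). Matching the edge count means only topology, not
density, differs.

## Attention inspection

For a chosen residue, the first GAT layer's attention over its
in-neighborhood (self-connection included) is extracted per head and
averaged arithmetically across heads. The self-connection is reported
separately rather than folded into the neighbor ranking, where it would
dominate silently; relative contributions are renormalized over neighbors
only. The PyMOL script colors the center residue yellow and neighbors on a
linear green (highest attention) → red (lowest) gradient, making neighbors
below a configurable contribution quantile (default 0.25) half transparent.

## Leakage-safe splits

Sequences are clustered so that any pair above 40% global-alignment
identity (matches / alignment length, match +1, mismatch −1, gap open −2,
extend −0.5) shares a cluster; the built-in backend takes connected
components of the identity > 0.40 graph, which is exactly the transitive
closure an external greedy clusterer guarantees, and the backend is
pluggable. Ligands are clustered on ECFP4 (Morgan radius 2, 1024-bit)
Tanimoto similarity with *single-linkage* hierarchical clustering cut at
similarity 0.40 — single linkage is chosen because it guarantees no
cross-cluster pair exceeds the cutoff, the precise property the audit
checks. The 40% ligand cutoff is interpreted on the similarity scale (cut
at cophenetic distance 0.6), consistent with the sequence-cutoff phrasing.
Whole sequence clusters are assigned to train/validation/test by seeded
randomization; chains in validation/test whose ligand cluster occurs in
train are purged, then test chains whose ligand cluster occurs in
validation. The audit exhaustively recomputes cross-split maxima of
sequence identity and ligand Tanimoto and passes iff both are ≤ 0.40.

## Synthetic data: what it emulates, and what it does not

The generator produces the statistical structure the method assumes,
nothing more. Chains are 3D self-avoiding random walks with consecutive
CA spacing fixed at 3.8 Å (the physical CA–CA virtual bond) and a 4 Å
excluded-volume radius. A 3-atom point ligand is placed 4 Å from an anchor
residue, in the direction of a spatial contact of that anchor at least 10
sequence positions away; labels follow the proximity rule at a 6 Å pocket
radius (smaller than the 10 Å convention, keeping positives rare at
desk-scale chain lengths of 50–70 residues; both are parameters). Draws
are rejected until the positive fraction lands in (0.02, 0.15) and at
least one positive pair is ≥ 10 positions apart in sequence. Observed mean
positive fraction under the defaults is ≈ 0.11.

The planted signal is calibrated to create a measurable gap between
sequence and structure: binding residues are resampled so that with
probability 0.35 they come from a fixed 5-residue "pocket" alphabet. A
composition-only classifier therefore sits near ROC-AUC ≈ 0.63
(theoretical optimum for this mixture), while the spatial rule determines
labels exactly. Node features are 20-dim one-hot identities plus Gaussian
noise (sd 0.3) — the "simple embedding" regime in which structure's
relative contribution is largest — or the 566-dim property features.

What synthetic data does *not* model: real fold geometry, side chains and
rotamers, chemically meaningful ligand poses, and context-dependent
embedding semantics. Passing the ablation tests on this data shows the
pipeline recovers a planted structural signal under realistic imbalance; it
does not certify benchmark-level accuracy on experimental structures.

The bundled 566-property amino-acid table is likewise a deterministic
synthetic stand-in for an external physicochemical index collection: it
reproduces the contract that matters for the pipeline (dimensionality,
per-property z-scoring over the 20-letter alphabet, imputation of missing
entries with the property mean, constant properties mapping to zero, 'X'
residues to the alphabet mean) without shipping the database. Property
*values* carry no biochemical meaning; a real table in the same TSV layout
can be dropped in via `load_property_table`.

## Experiment sizes

Desk-scale experiments (tests and the acceptance script) use 120 chains of
50–70 residues, a 70/30 train/validation split, 150 training epochs, and 5
seeds per comparison — sizes chosen so the full ablation suite completes in
minutes on one core while the seed-level win counts and t-tests remain
interpretable. Validation MCC is evaluated every epoch; comparisons use
each run's best validation MCC, the quantity fivefold-CV ablation studies
report.

## Known limitations

* Multi-chain pockets are out of scope; one chain, one graph.
* mmCIF input is not parsed; PDB only.
* The embedding *computation* is external by design: the package consumes
  per-residue matrices (NPZ keyed by chain id, or TSV) and validates row
  counts against chain length, but never runs a language model.
* Edge features (e.g. distances) and k-NN graphs are not implemented.
* The sequence-identity backend is a self-consistent global-alignment
  definition; an external tool substituted through the backend hook may
  cluster borderline pairs slightly differently.
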