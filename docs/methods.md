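# Methods

## Problem and model

Protein–DNA binding-site prediction is cast as binary node classification on
a residue graph. A protein chain of length L becomes a graph G = (X, E, A):

* **Nodes** are residues, carrying a feature vector x_i ∈ R^6524 (eight
  concatenated blocks, below) and a 3-D coordinate (the CA atom by default;
  the side-chain centroid is a config switch).
* **Edges** connect residues whose *side-chain centroids* lie strictly
  closer than 17 Å (the centroid is the unweighted mean of heavy
  side-chain atoms; glycine falls back to CA). Each edge carries two scalars:
  the Euclidean distance between the node coordinates and the cosine of the
  angle between the two residues' CA→side-chain-centroid orientation
  vectors. A degenerate (zero-length) orientation vector yields cosine 0.
* **Labels**: residue i binds iff its smallest atomic distance to any DNA
  atom is below a cutoff (default 0.5 Å, following the benchmark datasets'
  printed definition; the parameter is exposed because 5 Å is the
  conventional value for a minimum-atomic-distance criterion and the printed
  one is physically implausible — we do not guess the intent, we expose the
  knob).

Two encoders read the same graph:

**GCNII branch** (local). Four layers, hidden width 128, of

    H^(l+1) = σ( ((1−α) P H^(l) + α H^(0)) ((1−β_l) I + β_l W^(l)) ),
    β_l = ln(λ/l + 1),

with P = D̃^(−1/2)(A+I)D̃^(−1/2) the symmetric renormalized adjacency,
H^(0) the linearly projected input features, σ = ReLU. The initial residual
(α) and identity mapping (β_l, shrinking with depth) prevent over-smoothing.

**EGNN branch** (global, E(3)-equivariant). Two equivariant graph
convolution layers (EGCL), hidden width 512. Per edge,

    m_ij = Φ_e(h_i, h_j, ‖x_i − x_j‖², e_ij),

coordinates update equivariantly with C = 1/(M−1), M = L,

    x_i ← x_i + C Σ_{j≠i} (x_i − x_j) Φ_x(m_ij),

and the aggregated message m_i = Σ_{j≠i} m_ij enters Φ_h(h_i, m_i), whose
output takes the place of the smoothed term in the same
residual/identity update used by GCNII. This placement is a design choice:
the update is written in matrix form over H only, so it is applied to the
node-feature pathway and the coordinate update is left untouched.
Φ_e/Φ_x/Φ_h are two-layer SiLU perceptrons (Φ_x ends in one scalar); these
depths/activations are unspecified in the source description and follow
common EGNN practice. Because geometry enters only through squared
distances, node embeddings are invariant — and internal coordinates
equivariant — under all rigid motions including reflections; this is tested
over 100 random transforms at 1e−4 relative tolerance.

**Gated attention fusion.** The branch embeddings concatenate to
f ∈ R^{L×640} (GCNII block first), serving as Q, K and V for H = 16
attention heads per block:

    Attention_i = softmax((Q W_i^Q)(K W_i^K)^T / √d_k),  d_k = 640/16 = 40,

(the transpose is required for an L×L attention matrix and is implemented
accordingly). A per-head logistic gate G = σ(f W^G + b^G) ∈ (0,1)^{L×d_k}
multiplies each head's output elementwise; heads concatenate and mix
through an output weight. N = 8 such blocks, independently parameterized,
run on the same f; their outputs stack to [L, 640, 8] and flatten to
[L, 5120] (mean-over-blocks is a config alternative) before a 5120→256→1
ReLU/logistic head yields per-residue binding probabilities. Per-head gates
(W^G of shape [640, d_k], one per head) are a design choice; the sharing
scheme is not specified in the source description.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| contact cutoff | 17 Å | side-chain-centroid adjacency radius (strict `<`) |
| label cutoff | 0.5 Å | min atomic distance defining a binding residue |
| α | 0.1 | initial-residual weight, both branches |
| λ | 0.5 | identity-mapping decay, β_l = ln(λ/l + 1), natural log |
| EGNN | 2 × 512 | layers × hidden width |
| GCNII | 4 × 128 | layers × hidden width |
| H, N | 16, 8 | attention heads per block, independent blocks |
| learning rate | 1e−3 | Adam, one protein graph per step |
| weight decay | 1e−3 | decoupled L2 shrinkage per step |
| gradient clip | 1.0 | global-norm ceiling; tames chaotic attention updates |
| LR schedule | cosine | anneals to 0 over the epoch budget |
| class weighting | inverse frequency | counters PN ratios near 0.1 |
| dist_scale | 17 Å | squared distances enter Φ_e as (d/dist_scale)² |

α and λ follow the usual GCNII conventions since the source description
leaves them unstated; both are config keys. The learning rate is 1e−3
because desk-scale models trained for ≲200 epochs need the larger Adam step;
1e−4 is one config key away. Optional Gaussian input-noise injection
(`TrainConfig.input_noise`, default off) is available as a ridge-like
regularizer.

## Numerical and implementation choices

* All network code runs on a small reverse-mode autodiff engine over
  float64 NumPy arrays, written for this package and gradient-checked
  against central finite differences. No GPU framework is required.
* Softmax rows are max-shifted; the training loss is class-weighted binary
  cross-entropy computed from logits via log1p(exp) so extreme logits at
  initialization cannot overflow.
* Undirected edges are stored once (i < j) and expanded to both directions
  for message passing. No self-loops exist in A; self-loops enter only
  inside the adjacency normalization.
* Single-node graphs skip the coordinate update (C = 1/(M−1) undefined);
  zero-edge graphs propagate pure node terms.
* The geometric input to Φ_e is the squared distance divided by a fixed
  length scale (17 Å, the contact cutoff) — a reparameterization of Φ_e's
  first layer that keeps geometry commensurate with the embedding inputs —
  and Φ_x's output layer starts at zero so coordinate updates begin at the
  identity. Both markedly improve trainability without changing the
  function class or the equivariance properties.
* Cross-validation selects its operating threshold (max-MCC) on a held-out
  calibration split of ~1/8 of the training proteins, excluded from
  fitting: in-sample predictions saturate and their optimal threshold does
  not transfer.
* Ties in threshold selection resolve to the smallest MCC-optimal
  threshold; metric ratios with zero denominators are reported as 0. AUC is
  the tie-corrected Mann–Whitney rank statistic; AUPR is step-integrated
  average precision. Both are cross-checked against scikit-learn in tests
  but computed independently.
* Cross-validation folds split at the protein level; repeats reshuffle with
  seeds 0..9 by default. Every random draw (weights, fold shuffles,
  fixtures) flows from explicit seeds, so end-to-end runs are bit-identical
  given the same seed.

## What the synthetic generator emulates — and what it does not

Real inputs (crystal structures, PSI-BLAST/HHsuite profiles, language-model
embeddings) are large and externally computed. The generator emulates:

* geometry: residues on an ideal α-helix (rise 1.5 Å, 100° turn, radius
  2.3 Å, consecutive CA ≈ 3.8 Å) with backbone plus 1–4 pseudo-side-chain
  atoms; DNA pseudo-atoms scattered in a pocket ball anchored just outside a
  *randomly chosen* residue. A fixed mid-chain pocket would let the shared
  helix geometry alone reveal the labels (a structure-only model reached
  AUC ≈ 0.88 with zero feature signal), destroying the no-signal control;
  the random anchor restores a chance-level control.
* labels: produced by the same minimum-atomic-distance rule as real data,
  with the per-protein cutoff placed so the positive fraction matches the
  requested value (default 0.1, the benchmark-scale imbalance).
* features: all eight blocks at their true widths, standard normal, with a
  class-conditional mean shift along one fixed random unit direction per
  block, shared corpus-wide. The default strength 1.75 is calibrated so a
  features-only ridge-logistic probe reaches AUC ≈ 0.94 on held-out
  proteins — matching the reported ablation in which language-model
  features alone support AUC ≈ 0.94 — rather than chosen for any
  downstream test.

It does **not** emulate: realistic side-chain rotamers or DNA geometry,
sequence-dependent feature structure (beyond the one-hot block), inter-block
correlations, or chain breaks. Passing tests on this corpus therefore
demonstrate that the architecture can extract a spatially clustered,
linearly embedded signal under realistic imbalance — not benchmark-level
accuracy on real proteins, which additionally requires the external feature
pipelines and full-scale training.

## Problem sizes used in tests and the acceptance script

Learning checks run a reduced configuration (EGNN 2×32, GCNII 4×16, 4 heads,
2 blocks — `ModelConfig.small()`) on corpora of 20 proteins × ~100 residues
(≈2000 residues, the corpus scale the synthetic generator targets), chosen
as this package's own desk-scale study size. The full-size 512/128/16/8
configuration is exercised shape-wise and in the fused-embedding checks.
Single-protein memorization uses 40 residues and 200 epochs;
cross-validation uses 5 folds at 40 epochs.

## Known limitations

* The printed ESM-2 width (5153) matches no published embedding size; the
  block is treated as an opaque [L, 5153] input. Likewise the 256-dim MSA
  feature and the 7-dim atomic / 14-dim secondary-structure blocks are
  consumed as precomputed tables.
* PSSM (logistic) and HMM (2^(−v/1000)) normalizations follow the
  GraphBind-lineage conventions; the source description says only
  "normalized". Both are isolated behind their readers.
* PDB input only (first model, ATOM records, highest-occupancy altloc);
  no mmCIF, no multi-model ensembles, no protein–RNA labelling.
* Training at the published benchmark scale (hundreds of proteins, full
  512/128 widths) is out of desk-scale reach; no attempt is made to
  reproduce benchmark test-set metrics.
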