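# Methods

## Scope and tasks

`epiconv` models two binary classification tasks over (MHC-II allele,
peptide) pairs: *presentation* (was the peptide eluted from the cell
surface?) and *immunogenicity* (did it activate T cells in a wet-lab
assay?).  One architecture serves both; only the training table differs.
All inputs are β-chain alleles in two-field nomenclature
(`GENE*f1:f2`, genes DRB1/DRB3/DRB4/DRB5/DPB1/DQB1) and peptides of 9–25
standard residues.

## Allele encoding

The nomenclature is treated as a three-level hierarchy: gene (layer 0),
field 1 (layer 1), field 2 (layer 2).  Each layer token indexes a 99 × 128
embedding table (field values are bounded at 98 by the two-digit
nomenclature fields; out-of-range values are rejected rather than hashed,
so a collision can never silently merge two alleles).  Gene tokens use a
fixed injective map (DRB1=0, DRB3=1, DRB4=2, DRB5=3, DPB1=4, DQB1=5).
Identical symbols share rows, so two alleles agreeing on a prefix of the
nomenclature share exactly those embedding rows — the mechanism by which
data-poor subtypes inherit information from relatives.

Three fusion variants collapse the 3 × 128 layer matrix to the 1 × 128
head: `add` (per-layer 128 × 128 transfer matrices, summed, then a
nonlinearity, ReLU by default), `concat` (a learned depthwise kernel over
the layer axis — the default), and `shared-concat` (concat with a single
embedding table shared by all three layers, for very sparse allele
inventories).  A one-hot encoder (one orthogonal indicator per distinct
allele, projected to 128) and a no-allele mode exist solely as ablation
baselines.

## Normalization

The layer matrix is normalized before fusion.  The scheme built for this
encoder (`hlan`) standardizes each *sample* with mean and variance pooled
over all 3 × 128 entries, then applies a learnable affine `·α + β`
(scalars by default; per-dimension selectable):

* unlike batch normalization, a sample's output never depends on its
  batch companions (asserted both ways in the tests);
* unlike row-wise layer normalization, between-layer offsets survive,
  because the statistics pool across layers; the two coincide exactly
  when all three rows share mean and variance.

ε defaults to 1e-5.  A per-layer-statistics variant is selectable by
configuration but makes no claim beyond being an alternative reading.
Batch and layer normalization are implemented as ablation baselines with
the standard contracts (running statistics for batch-norm inference;
training-mode batches of one are rejected).

## Peptide encoding and pair fusion

Peptides are right-padded to 25 with the pad symbol `J` (right-padding
keeps position 1 aligned with the N-terminus), tokenized against the
21-symbol vocabulary `[J, A, C, …, Y]`, and embedded through a trainable
21 × 128 table initialized from a seeded standard normal (rows checked
pairwise-distinct at construction).  Non-standard residues (B, X, Z, U,
O, lowercase) are rejected rather than mapped to the pad, so "unknown"
and "padding" can never be conflated.  The allele head is stacked on top
of the peptide matrix (26 × 128, `concat` pair fusion, default) or added
to every peptide row (`add` pair fusion, ablation).

## Scoring network

"BlockConv": an optional 1 × 1 input projection (identity when the
embedding width equals the channel count), then `n_blocks` residual
blocks `x + conv(relu(conv(x)))` with same-padded width-3 kernels,
a width-2/stride-2 pooling layer after each block (alternating max and
average under the default `pooling="both"`), global max+mean pooling, and
a dense sigmoid head.  Outputs are probabilities in (0, 1).  The `plain`
architecture drops only the skip connections (ablation).  Defaults are
3 blocks × 128 channels; the depth/width are configuration values, not
claims.  Training loss is binary cross-entropy by default with MSE always
reported as a metric; an MSE-loss mode exists because squared error is
also a defensible training objective for probability targets.

All of this runs on `epiconv.autodiff`, a small tape-based reverse-mode
engine over float64 NumPy arrays.  Convolution and pooling are single
fused graph nodes with closed-form backward passes; every operation and
the full composed model are validated against central finite differences
(the end-to-end check demands 1e-4 relative agreement and observes ~1e-6).

## Decoy generation

For each positive peptide P with a source protein F, all |F|−|P|+1
windows of length |P| are candidates.  Each candidate's dissimilarity is
the negated best ungapped BLOSUM62 score against *any* peptide of the
positive set over all offsets (the substitution matrix is swappable).
After an optional binding filter (a pluggable callable; the default null
filter passes everything — external elution predictors can be slotted in
as a scorer with a percentile cutoff) and exact-duplicate removal, the
k = 10 most dissimilar survivors are kept, ties broken lexicographically
so the selection is independent of candidate order.  Datasets at a fixed
positive:negative ratio (1:1, 1:5, …) are assembled by seeded sampling
without replacement from the decoy pool.

## Curation

Raw tabular records pass through six audited filters in a fixed order:
allele (two-field β-chain), peptide length/symbols (9–25, standard
residues), wet-lab basis (immunogenicity tables only), conflicting
(allele, peptide) outcome pairs removed on both sides, exact duplicates
collapsed, and subtypes with fewer than 10 *distinct* peptides dropped.
Record-level filters run before the subtype-count filter so the ≥10
threshold counts otherwise-valid peptides.  Every dropped row carries a
reason code and |input| = |output| + Σ drops holds identically; curation
is idempotent.

## Synthetic ligandome

The generator emulates the statistical structure the hierarchical encoder
exploits, not binding physics:

* **Hierarchy.**  For each (gene, field1) parent, anchor residue
  preferences are drawn at the canonical MHC-II groove pockets
  P1/P4/P6/P7/P9 of the 9-mer core (each anchor column concentrates 0.85
  probability on one residue).  Each child subtype (field2) copies every
  anchor column, independently resampling it with probability δ
  (default 0.15): δ=0 gives identical siblings, δ=1 independent ones.
  Non-anchor columns are mild Dirichlet(5) draws per child.
* **Ligands.**  Length uniform on [9, 25]; a 9-mer core drawn from the
  motif sits at a uniform random offset with uniform flanks.  The offset
  is *not* recorded — as with real elution data, the model must locate
  the core itself.
* **Decoys.**  Windows of random i.i.d.-residue proteins, rejected if
  their best-offset motif log-likelihood ratio exceeds the 10th
  percentile of ligand scores, making separability explicit and
  controllable.  Optionally, a fraction of a subtype's negatives can be
  replaced by ligands of a *different gene's* subtypes
  (`frac_cross_negatives`), which makes the label depend on the allele —
  used by the ablation study to ensure the no-allele control is
  information-starved by construction.  The default is 0 (pure decoys).
* **Immunogenicity labels.**  A hidden rule thresholds a linear score of
  residue properties (Kyte–Doolittle hydropathy, charge, aromaticity) at
  three TCR-contact core positions (2, 4, 7), with flip noise η
  (default 0.05).  The threshold is set by quantile so positives:negatives
  ≈ 1.62:1, the prevalence of the curated T-cell corpus.

All randomness flows from one manifest seed through named substreams;
a corpus regenerates bitwise from its manifest.  What the generator does
**not** model: biophysical binding energies, mass-spec detectability
bias, peptide-length/motif correlations, or real allele frequencies — so
passing tests demonstrate that the machinery can recover planted
structure, not field performance on real immunopeptidomes.

## Training and evaluation

10-fold cross-validation: folds are disjoint, sizes differ by at most
one, stratified by (label, subtype) by default (plain random splits are
available).  Each fold serves once as the validation set; training runs
a fixed epoch budget (default 100) with Adam (default lr 1e-3, batch
128), and the best-validation checkpoint is kept — selection on
validation AUC by default, since accuracy at 0.5 is brittle under class
imbalance (a strict-accuracy mode exists).  Reports carry MSE, rank AUC,
PR (average precision by default; precision-at-threshold selectable),
and PPV/sensitivity/specificity from the confusion matrix at the stated
threshold; single-class inputs flag AUC/PR undefined but keep the
confusion metrics.  The cross-validated report is the arithmetic mean of
the fold reports.

## Benchmark studies (desk scale)

The two study designs in `epiconv.benchmarks` run the whole pipeline at
sizes chosen for a single CPU — 32-dim embeddings, 2 blocks × 32
channels, 8–15 epochs at lr 3e-3 — while the 128-dim encoder constants
remain the package defaults everywhere else:

* **Learning sanity**: eight subtypes × (200 ligands + 200 decoys),
  10-fold CV, against an identically trained label-permuted control.
  The real fit must clear the control by far more than the cross-fold
  spread (observed: AUC ≈ 0.94 vs ≈ 0.54, margin ≈ 40 standard
  deviations).
* **Ablation direction**: a corpus whose subtype DRB1*01:02 has only 15
  training ligands while sibling DRB1*01:01 has 100, half of all
  negatives drawn from the other gene's ligands; hierarchical vs one-hot
  vs no-allele encodings over three replicate corpora.  Expected (and
  observed) ordering: hierarchical rescues the sparse subtype where
  one-hot cannot, and the no-allele control is strictly worst overall.

## Numerical and design notes

* Tie-breaks are lexicographic wherever a ranking feeds a selection, so
  results are platform-independent.
* ε-guards: normalization 1e-5, BCE clamping 1e-12, Adam 1e-8.
* Degenerate inputs fail loudly: empty positive sets, single-class
  validation folds, singleton batch-norm batches, out-of-range tokens.
* Checkpoints are a binary `.npz` of weights plus a plain-text JSON
  sidecar (configuration, vocabulary hash, allele inventory for the
  one-hot encoder).
* Known limitations: no α-chain or αβ-pair modelling, no 3/4-field
  nomenclature, no gapped alignment in decoy scoring, no attention
  variants, and the synthetic generator's realism limits listed above.
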