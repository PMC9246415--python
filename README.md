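# epiconv

Prediction of MHC class II epitope **presentation** and **immunogenicity**
from an HLA allele name and a peptide sequence, built around a
*hierarchical* encoding of the HLA class II nomenclature.

## The problem

CD4⁺ T cells recognize 9–25-mer peptides displayed by MHC-II molecules.
Selecting vaccine epitopes therefore needs two predictions per
(allele, peptide) pair: will the peptide be presented on the cell surface
(eluted-ligand data), and, if presented, will it actually trigger a T-cell
response (wet-lab T-cell assay data)?  Most tools answer only the first
question.  Both tasks are allele-specific, and the alleles are not
independent categories: `DRB1*01:01` and `DRB1*01:09` share most of their
ligandome, which a one-hot allele encoding throws away.

## The model

An allele name `GENE*f1:f2` is read as a three-level tree node.  Each
level indexes its own 99 × 128 embedding table:

```
E = [ e_gene ; e_field1 ; e_field2 ]   ∈ ℝ^(3×128)
```

`E` is normalized per sample by pooling mean and variance over all 3 × 128
entries ("HLAN" — batch-independent, but sensitive to between-layer
offsets, unlike ordinary layer norm):

```
HLAN(x) = (x − μ) / √(σ² + ε) · α + β ,   μ, σ² over all C·H entries
```

and collapsed to a 1 × 128 head vector, either as `e = σ(Σᵢ Eᵢ Wᵢ)` (add
fusion) or by a learned convolution over the layer axis (concat fusion,
the default).  The head is stacked on top of the 25 × 128 embedded,
J-padded peptide, giving a 26 × 128 matrix scored by a residual
1-D convolutional network ("BlockConv": blocks of conv→ReLU→conv with
identity skips, interleaved pooling, global pooling, sigmoid head).

Because related alleles share embedding rows, subtypes with almost no
training data borrow statistical strength from data-rich siblings — the
package's ablation study measures exactly this transfer against one-hot
and no-allele baselines.

Around the core model the package provides:

* `epiconv.curation` — audited filters for raw assay tables (β-chain
  two-field alleles, 9–25-mer length, wet-lab basis, conflict removal,
  deduplication, ≥10 peptides per subtype);
* `epiconv.negatives` — decoy generation: all same-length windows of a
  positive's source protein, ranked by BLOSUM62 dissimilarity against the
  whole positive set, top-10 kept per positive, plus 1:1 / 1:5 dataset
  assembly;
* `epiconv.simdata` — a fully seeded synthetic ligandome (subtype
  hierarchy with shared anchor preferences, motif-emitted ligands,
  decoys, hidden-rule immunogenicity labels) so every mechanism is
  testable without any database download;
* `epiconv.trainer` / `epiconv.api` — 10-fold cross-validated training
  with best-validation checkpointing and an `EpitopeModel.fit()` →
  results-object interface;
* a command-line interface: `epiconv curate | negatives | simulate |
  train | predict | evaluate | ablation`.

## Worked example

```python
from epiconv import EpitopeModel, ScorerConfig, BlockConvConfig, build_corpus

corpus = build_corpus(seed=42, ligands_per_subtype=100, decoys_per_subtype=100)
config = ScorerConfig(dim=32,
                      blockconv=BlockConvConfig(n_blocks=2, channels=32, seed=0),
                      seed=0)
model = EpitopeModel(corpus.presentation, config=config, task="presentation")
results = model.fit(k=5, epochs=10, batch_size=128, lr=3e-3, seed=0)
print(results.summary())
```

```
Epitope classifier — cross-validated fit
========================================================
task:            presentation
records:         1600  (folds: 5)
encoding:        hierarchical / norm: hlan
layer fusion:    concat / pair fusion: concat
architecture:    blockconv (2 blocks, 32 ch)
--------------------------------------------------------
metric              mean   sd over folds
mse               0.1190          0.0173
auc               0.9128          0.0209
pr                0.9136          0.0221
ppv               0.8339          0.0409
sensitivity       0.8512          0.0448
specificity       0.8263          0.0600
========================================================
```

The corpus is eight synthetic MHC-II subtypes with 100 motif-emitted
ligands and 100 protein-window decoys each; the fit is 5-fold
cross-validation, and every row of the table is the mean (and spread) of
the held-out fold metrics.  An AUC of 0.91 means the model has recovered
most of the motif structure the generator planted.  Scoring new pairs:

```python
print(results.predict(corpus.presentation.sample(4, random_state=1)))
```

```
    allele                  peptide  label    score   model_kind
DRB1*01:01      YVEVAMQMPYCEFDCSAVT      1 0.805669 presentation
DPB1*02:01        ACFGRKMPEMSFELFNH      1 0.926567 presentation
DRB1*02:01 RLYCWAINPITVMRALTWRDGYEQ      1 0.763418 presentation
DPB1*02:01      KNVKIVELSFKLEHMHTST      1 0.960592 presentation
```

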