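"""Curation filters for tabular assay records.

Raw presentation (eluted-ligand) and immunogenicity (T-cell assay) tables
are filtered in a fixed, audited order:

1. allele — two-field β-chain nomenclature only (α chains dropped);
2. length — peptides restricted to 9–25 residues with standard symbols;
3. wet-lab — T-cell records must come from wet-lab assays, not predictions;
4. conflict — (allele, peptide) pairs with both positive and negative
   outcomes are removed entirely;
5. duplicate — repeated (allele, peptide, label) rows collapse to one;
6. sparse subtype — subtypes with fewer than 10 distinct peptides left
   after the record-level filters are dropped.

Every dropped row is logged with a reason code, so the audit identity
|input| = |output| + Σ drops holds on every run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .alleles import parse_allele
from .peptides import validate_peptide

__all__ = ["CuratedDataset", "curate", "summarize", "MIN_PEPTIDES_PER_SUBTYPE"]

MIN_PEPTIDES_PER_SUBTYPE = 10

REQUIRED_COLUMNS = ("allele", "peptide", "outcome")


@dataclass
class CuratedDataset:
    """Curated records plus the per-reason drop log."""

    records: pd.DataFrame
    drop_log: pd.DataFrame
    kind: str = "presentation"

    @property
    def counts_by_subtype(self) -> pd.Series:
        if self.records.empty:
            return pd.Series(dtype=int)
        return self.records.groupby("allele").size().sort_values(ascending=False)


def _outcome_to_label(v) -> int:
    s = str(v).strip().lower()
    if s in ("1", "positive", "pos", "true"):
        return 1
    if s in ("0", "negative", "neg", "false"):
        return 0
    raise ValueError(f"unrecognized outcome {v!r}")


def curate(records: pd.DataFrame, kind: str = "presentation") -> CuratedDataset:
    """Apply the curation criteria in order; return dataset + drop log.

    ``kind`` is "presentation" (elution) or "immunogenicity" (t-cell); the
    wet-lab filter applies only to the latter and uses the ``assay_basis``
    column when present.
    """
    if kind not in ("presentation", "immunogenicity"):
        raise ValueError(f"unknown dataset kind {kind!r}")
    for col in ("allele", "peptide"):
        if col not in records.columns:
            raise ValueError(f"missing required column {col!r}")
    if "outcome" not in records.columns:
        if "label" in records.columns:  # re-ingest of curated output
            records = records.assign(outcome=records["label"])
        else:
            raise ValueError("missing required column 'outcome'")

    df = records.reset_index(drop=True).copy()
    drops: list[dict] = []

    def drop(mask, reason: str):
        nonlocal df
        mask = mask.astype(bool)  # empty frames yield object-dtype masks
        for i in df.index[mask]:
            drops.append(
                {"row": int(i), "allele": df.at[i, "allele"],
                 "peptide": df.at[i, "peptide"], "reason": reason}
            )
        df = df[~mask]

    # 1. allele filter (β-chain, two-field, in-range)
    def allele_ok(a):
        try:
            parse_allele(str(a))
            return True
        except ValueError:
            return False

    drop(~df["allele"].map(allele_ok), "bad_allele")
    df["allele"] = df["allele"].map(lambda a: str(parse_allele(str(a))))

    # 2. peptide length / symbol filter
    def peptide_ok(p):
        try:
            validate_peptide(str(p))
            return True
        except ValueError:
            return False

    drop(~df["peptide"].map(peptide_ok), "length")

    # 3. wet-lab basis filter (immunogenicity only)
    if kind == "immunogenicity" and "assay_basis" in df.columns:
        basis = df["assay_basis"].astype(str).str.strip().str.lower()
        drop(basis != "wet-lab", "not_wetlab")

    df["label"] = df["outcome"].map(_outcome_to_label)

    # 4. conflicting (allele, peptide) pairs — both sides removed
    n_labels = df.groupby(["allele", "peptide"])["label"].transform("nunique")
    drop(n_labels > 1, "conflict")

    # 5. exact duplicates
    drop(df.duplicated(subset=["allele", "peptide", "label"], keep="first"),
         "duplicate")

    # 6. sparse subtypes (< 10 distinct peptides)
    if not df.empty:
        n_pep = df.groupby("allele")["peptide"].transform("nunique")
        drop(n_pep < MIN_PEPTIDES_PER_SUBTYPE, "sparse_subtype")

    if df.empty:
        import warnings

        warnings.warn("curation produced an empty dataset", stacklevel=2)
    drop_log = pd.DataFrame(drops, columns=["row", "allele", "peptide", "reason"])
    keep_cols = [c for c in
                 ("allele", "peptide", "label", "assay_kind", "accession")
                 if c in df.columns]
    return CuratedDataset(df[keep_cols].reset_index(drop=True), drop_log, kind)


def summarize(dataset: CuratedDataset) -> dict:
    """Per-subtype counts plus the overall positive:negative ratio."""
    df = dataset.records
    n_pos = int((df["label"] == 1).sum()) if not df.empty else 0
    n_neg = int((df["label"] == 0).sum()) if not df.empty else 0
    if n_neg > 0:
        ratio = round(n_pos / n_neg, 2)
        ratio_str = f"{ratio}:1"
    else:
        ratio, ratio_str = None, "undefined"
    return {
        "n_records": int(len(df)),
        "n_subtypes": int(df["allele"].nunique()) if not df.empty else 0,
        "n_positive": n_pos,
        "n_negative": n_neg,
        "pos_neg_ratio": ratio,
        "pos_neg_ratio_str": ratio_str,
        "counts_by_subtype": {
            k: int(v) for k, v in dataset.counts_by_subtype.items()
        },
    }
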