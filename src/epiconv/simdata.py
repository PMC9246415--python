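"""Synthetic ligandome generator.

Emulates the statistical structure the hierarchical allele encoding
exploits, at desk scale and with full reproducibility:

* a subtype hierarchy (gene / field1 / field2) in which siblings that
  share gene and field1 inherit the parent's anchor-position preferences,
  perturbed by ``delta`` (0 = identical anchors, 1 = independent);
* each leaf subtype emits 9–25-mer ligands as a 9-mer core drawn from its
  position-specific motif plus uniform flanks at a random, unrecorded
  core offset — as in real elution data, the model must locate the core;
* decoys cut from random proteins, rejected when they score like ligands;
* immunogenicity labels from a hidden logistic rule over residue
  properties at three TCR-contact core positions, with optional flip
  noise.

All randomness flows from one manifest seed through named substreams, so
a corpus regenerates bitwise from its manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alleles import HlaAllele, parse_allele
from .peptides import AMINO_ACIDS

__all__ = [
    "SubtypeMotifModel",
    "SyntheticCorpus",
    "ImmunogenicityRule",
    "simulate_hierarchy",
    "sample_ligands",
    "sample_decoys",
    "random_proteome",
    "label_immunogenicity",
    "motif_score",
    "build_corpus",
]

CORE_LEN = 9
_AA = np.array(list(AMINO_ACIDS))
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

# Kyte–Doolittle hydropathy, unit net charge at pH 7, aromaticity flag
_HYDRO = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8, "G": -0.4,
    "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8, "M": 1.9, "N": -3.5,
    "P": -1.6, "Q": -3.5, "R": -4.5, "S": -0.8, "T": -0.7, "V": 4.2,
    "W": -0.9, "Y": -1.3,
}
_CHARGE = {a: (1.0 if a in "KR" else (-1.0 if a in "DE" else 0.0))
           for a in AMINO_ACIDS}
_AROMATIC = {a: (1.0 if a in "FWY" else 0.0) for a in AMINO_ACIDS}

# substream tags so every stage draws from an independent, named stream
_STREAM = {"hierarchy": 11, "ligands": 22, "proteome": 33, "decoys": 44,
           "labels": 55, "assembly": 66}


def _rng(seed: int, stage: str, *extra: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAM[stage], *map(int, extra)])


@dataclass
class SubtypeMotifModel:
    """Per-subtype position-specific scoring motif with linked anchors."""

    subtype: HlaAllele
    pwm: np.ndarray  # (9, 20) position probabilities
    anchors: tuple[int, ...]
    seed: int = 0

    def __post_init__(self):
        if self.pwm.shape != (CORE_LEN, 20):
            raise ValueError("pwm must be 9 x 20")
        if not np.allclose(self.pwm.sum(axis=1), 1.0):
            raise ValueError("pwm rows must sum to 1")


def _anchor_column(rng, concentration: float = 0.85) -> np.ndarray:
    """A concentrated residue preference for one anchor position."""
    preferred = rng.integers(20)
    col = np.full(20, (1.0 - concentration) / 19.0)
    col[preferred] = concentration
    return col


def simulate_hierarchy(
    n_f1_per_gene: int,
    n_f2_per_f1: int,
    delta: float,
    seed: int = 0,
    genes: tuple[str, ...] = ("DRB1", "DPB1"),
    anchor_positions: tuple[int, ...] = (0, 3, 5, 6, 8),
    anchor_concentration: float = 0.85,
) -> dict[str, SubtypeMotifModel]:
    """One motif per leaf subtype; siblings inherit parent anchors.

    Anchor positions default to the canonical MHC-II binding-groove
    pockets P1/P4/P6/P7/P9 of the 9-mer core.  For each (gene, field1)
    parent the anchor residue preferences are drawn once; each child
    (field2) copies every anchor column, resampling it independently with
    probability ``delta``.  Non-anchor columns are mildly-informative
    Dirichlet draws per child.
    """
    if n_f1_per_gene < 1 or n_f2_per_f1 < 1:
        raise ValueError("hierarchy counts must be >= 1")
    if not (0.0 <= delta <= 1.0):
        raise ValueError(f"delta must lie in [0, 1], got {delta}")
    if any(not (0 <= p < CORE_LEN) for p in anchor_positions):
        raise ValueError("anchor positions must lie in the 9-mer core")
    models: dict[str, SubtypeMotifModel] = {}
    for gi, gene in enumerate(genes):
        for f1 in range(1, n_f1_per_gene + 1):
            prng = _rng(seed, "hierarchy", gi, f1)
            anchors = tuple(sorted(anchor_positions))
            parent_cols = {
                a: _anchor_column(prng, anchor_concentration) for a in anchors
            }
            for f2 in range(1, n_f2_per_f1 + 1):
                crng = _rng(seed, "hierarchy", gi, f1, f2)
                pwm = crng.dirichlet(np.full(20, 5.0), size=CORE_LEN)
                for a in anchors:
                    if crng.random() < delta:
                        pwm[a] = _anchor_column(crng, anchor_concentration)
                    else:
                        pwm[a] = parent_cols[a]
                allele = HlaAllele(gene, f1, f2)
                models[str(allele)] = SubtypeMotifModel(
                    subtype=allele, pwm=pwm, anchors=anchors, seed=seed
                )
    return models


def sample_ligands(
    motif: SubtypeMotifModel,
    n: int,
    length_range: tuple[int, int] = (9, 25),
    seed: int = 0,
    return_offsets: bool = False,
):
    """Draw n ligands: uniform flanks around a motif-sampled 9-mer core."""
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = length_range
    if lo < CORE_LEN or hi > 25 or lo > hi:
        raise ValueError(f"invalid length range {length_range}")
    rng = _rng(seed, "ligands", *_subtype_tag(motif.subtype))
    peptides, offsets = [], []
    for _ in range(n):
        L = int(rng.integers(lo, hi + 1))
        off = int(rng.integers(0, L - CORE_LEN + 1))
        core = [
            _AA[rng.choice(20, p=motif.pwm[pos])] for pos in range(CORE_LEN)
        ]
        flank_n = rng.choice(20, size=off)
        flank_c = rng.choice(20, size=L - CORE_LEN - off)
        seq = (
            "".join(_AA[flank_n]) + "".join(core) + "".join(_AA[flank_c])
        )
        peptides.append(seq)
        offsets.append(off)
    if return_offsets:
        return peptides, offsets
    return peptides


def _subtype_tag(a: HlaAllele) -> tuple[int, int, int]:
    from .alleles import GENE_INDEX

    return (GENE_INDEX[a.gene], a.field1, a.field2)


def motif_score(peptide: str, motif: SubtypeMotifModel) -> float:
    """Best-offset log-likelihood ratio of the 9-mer core vs background."""
    idx = np.array([_AA_INDEX[c] for c in peptide])
    logp = np.log(motif.pwm) - np.log(1.0 / 20.0)
    best = -np.inf
    for off in range(len(peptide) - CORE_LEN + 1):
        s = float(logp[np.arange(CORE_LEN), idx[off : off + CORE_LEN]].sum())
        best = max(best, s)
    return best


def random_proteome(
    n_proteins: int = 30, length: int = 400, seed: int = 0
) -> list[str]:
    """Random i.i.d.-residue proteins used as decoy source material."""
    rng = _rng(seed, "proteome")
    return [
        "".join(_AA[rng.integers(0, 20, size=length)])
        for _ in range(n_proteins)
    ]


def sample_decoys(
    proteome: list[str],
    motif: SubtypeMotifModel,
    n: int,
    seed: int = 0,
    length_range: tuple[int, int] = (9, 25),
    reject: bool = True,
    reference_ligands: int = 200,
) -> list[str]:
    """Protein windows that do *not* look like the motif's ligands.

    A window is rejected when its motif score exceeds the 10th percentile
    of scores of freshly sampled ligands (the rejection threshold is part
    of the generative condition, seeded).  With ``reject=False`` windows
    are taken as they come and their scores straddle the ligand range.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed, "decoys", *_subtype_tag(motif.subtype))
    threshold = np.inf
    if reject:
        ref = sample_ligands(
            motif, reference_ligands, length_range, seed=seed ^ 0x5EED
        )
        threshold = float(
            np.percentile([motif_score(p, motif) for p in ref], 10)
        )
    lo, hi = length_range
    decoys: list[str] = []
    attempts = 0
    max_attempts = 200 * n
    while len(decoys) < n and attempts < max_attempts:
        attempts += 1
        prot = proteome[rng.integers(len(proteome))]
        L = int(rng.integers(lo, hi + 1))
        if len(prot) < L:
            continue
        start = int(rng.integers(0, len(prot) - L + 1))
        win = prot[start : start + L]
        if motif_score(win, motif) <= threshold:
            decoys.append(win)
    if len(decoys) < n:
        raise RuntimeError(
            f"decoy rejection exhausted after {attempts} attempts "
            f"({len(decoys)}/{n})"
        )
    return decoys


@dataclass
class ImmunogenicityRule:
    """Hidden labelling rule: logistic score over residue properties at
    three TCR-contact core positions, thresholded, with flip noise eta."""

    contact_positions: tuple[int, int, int] = (2, 4, 7)
    w_hydro: float = 1.0
    w_charge: float = 1.5
    w_aromatic: float = 2.0
    threshold: float = 0.0
    eta: float = 0.0

    def raw_score(self, peptide: str, core_offset: int) -> float:
        core = peptide[core_offset : core_offset + CORE_LEN]
        s = 0.0
        for pos in self.contact_positions:
            aa = core[pos]
            s += (
                self.w_hydro * _HYDRO[aa] / 4.5
                + self.w_charge * _CHARGE[aa]
                + self.w_aromatic * _AROMATIC[aa]
            )
        return s

    def to_dict(self) -> dict:
        return {
            "contact_positions": list(self.contact_positions),
            "w_hydro": self.w_hydro,
            "w_charge": self.w_charge,
            "w_aromatic": self.w_aromatic,
            "threshold": self.threshold,
            "eta": self.eta,
        }


def label_immunogenicity(
    peptide: str,
    rule: ImmunogenicityRule,
    core_offset: int,
    seed: int = 0,
    record_id: int = 0,
) -> int:
    """Deterministic threshold label, flipped with probability eta."""
    label = int(rule.raw_score(peptide, core_offset) > rule.threshold)
    if rule.eta > 0:
        rng = _rng(seed, "labels", record_id)
        if rng.random() < rule.eta:
            label = 1 - label
    return label


def threshold_for_ratio(scores: np.ndarray, pos_neg_ratio: float) -> float:
    """Score threshold giving the requested positive:negative prevalence."""
    frac_pos = pos_neg_ratio / (1.0 + pos_neg_ratio)
    return float(np.quantile(scores, 1.0 - frac_pos))


@dataclass
class SyntheticCorpus:
    """Motifs, labelled record tables and the regeneration manifest."""

    motifs: dict[str, SubtypeMotifModel]
    presentation: pd.DataFrame  # allele, peptide, label
    immunogenicity: pd.DataFrame  # allele, peptide, label
    proteins: list[str]
    manifest: dict = field(default_factory=dict)

    @classmethod
    def from_manifest(cls, manifest: dict) -> "SyntheticCorpus":
        kw = {k: v for k, v in manifest.items() if k != "immuno_rule"}
        return build_corpus(**kw)


def build_corpus(
    genes: tuple[str, ...] = ("DRB1", "DPB1"),
    n_f1_per_gene: int = 2,
    n_f2_per_f1: int = 2,
    delta: float = 0.15,
    ligands_per_subtype: int = 200,
    decoys_per_subtype: int = 200,
    length_range: tuple[int, int] = (9, 25),
    seed: int = 0,
    anchor_concentration: float = 0.85,
    frac_cross_negatives: float = 0.0,
    ligand_overrides: dict | None = None,
    decoy_overrides: dict | None = None,
    immuno_pos_neg_ratio: float = 1.62,
    immuno_eta: float = 0.05,
    n_proteins: int = 30,
    protein_length: int = 400,
) -> SyntheticCorpus:
    """Full corpus: presentation and immunogenicity tables plus manifest.

    ``ligand_overrides`` maps allele strings to per-subtype ligand counts
    (e.g. to create a deliberately data-sparse subtype).
    ``frac_cross_negatives`` replaces that fraction of each subtype's
    decoys with ligands of a subtype of a *different* gene, making the
    presentation label depend on the allele, not the peptide alone.
    """
    manifest = {
        "genes": tuple(genes),
        "n_f1_per_gene": n_f1_per_gene,
        "n_f2_per_f1": n_f2_per_f1,
        "delta": delta,
        "ligands_per_subtype": ligands_per_subtype,
        "decoys_per_subtype": decoys_per_subtype,
        "length_range": tuple(length_range),
        "seed": seed,
        "anchor_concentration": anchor_concentration,
        "frac_cross_negatives": frac_cross_negatives,
        "ligand_overrides": dict(ligand_overrides) if ligand_overrides else None,
        "decoy_overrides": dict(decoy_overrides) if decoy_overrides else None,
        "immuno_pos_neg_ratio": immuno_pos_neg_ratio,
        "immuno_eta": immuno_eta,
        "n_proteins": n_proteins,
        "protein_length": protein_length,
    }
    motifs = simulate_hierarchy(
        n_f1_per_gene, n_f2_per_f1, delta, seed=seed, genes=genes,
        anchor_concentration=anchor_concentration,
    )
    proteome = random_proteome(n_proteins, protein_length, seed=seed)

    ligands: dict[str, list[str]] = {}
    offsets: dict[str, list[int]] = {}
    decoys: dict[str, list[str]] = {}
    for name, motif in motifs.items():
        n_lig = ligands_per_subtype
        if ligand_overrides and name in ligand_overrides:
            n_lig = int(ligand_overrides[name])
        ligands[name], offsets[name] = sample_ligands(
            motif, n_lig, length_range, seed=seed, return_offsets=True
        )
        n_dec = decoys_per_subtype
        if decoy_overrides and name in decoy_overrides:
            n_dec = int(decoy_overrides[name])
        decoys[name] = sample_decoys(
            proteome, motif, n_dec, seed=seed,
            length_range=length_range,
        )

    # presentation table, optionally with cross-subtype hard negatives
    rows = []
    arng = _rng(seed, "assembly")
    names = list(motifs)
    for name in names:
        for pep in ligands[name]:
            rows.append((name, pep, 1))
        negs = list(decoys[name])
        n_cross = int(round(frac_cross_negatives * len(negs)))
        if n_cross:
            gene = parse_allele(name).gene
            others = [m for m in names if parse_allele(m).gene != gene]
            own = set(ligands[name])
            cross = []
            while len(cross) < n_cross:
                other = others[arng.integers(len(others))]
                cand = ligands[other][arng.integers(len(ligands[other]))]
                if cand not in own:
                    cross.append(cand)
            negs = negs[: len(negs) - n_cross] + cross
        for pep in negs:
            rows.append((name, pep, 0))
    presentation = pd.DataFrame(rows, columns=["allele", "peptide", "label"])

    # immunogenicity table: hidden-rule labels over all ligands
    rule = ImmunogenicityRule(eta=immuno_eta)
    all_scores = []
    for name in names:
        for pep, off in zip(ligands[name], offsets[name]):
            all_scores.append(rule.raw_score(pep, off))
    rule.threshold = threshold_for_ratio(
        np.array(all_scores), immuno_pos_neg_ratio
    )
    irows = []
    rid = 0
    for name in names:
        for pep, off in zip(ligands[name], offsets[name]):
            lab = label_immunogenicity(pep, rule, off, seed=seed, record_id=rid)
            irows.append((name, pep, lab))
            rid += 1
    immunogenicity = pd.DataFrame(
        irows, columns=["allele", "peptide", "label"]
    )
    manifest["immuno_rule"] = rule.to_dict()
    return SyntheticCorpus(
        motifs=motifs,
        presentation=presentation,
        immunogenicity=immunogenicity,
        proteins=proteome,
        manifest=manifest,
    )
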