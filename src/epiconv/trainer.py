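"""Cross-validated training, evaluation metrics and the ablation suite.

Training follows a 10-fold protocol: the records are partitioned into ten
non-overlapping folds (stratified by label and subtype by default); each
fold serves once as the validation set while the rest train the model; the
per-fold best-validation checkpoint is retained and the fold reports are
averaged.  Checkpoint selection uses validation AUC by default (accuracy
at a fixed threshold is brittle under class imbalance); a strict-accuracy
mode is available.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .alleles import HlaAllele, parse_allele
from .autodiff import Adam
from .network import PairScorer, ScorerConfig

__all__ = [
    "FoldPlan",
    "EvalReport",
    "kfold_split",
    "evaluate_scores",
    "evaluate",
    "train_single",
    "train_cv",
    "CVResult",
    "ablation_suite",
]


@dataclass
class FoldPlan:
    """k pairwise-disjoint index sets covering all records."""

    folds: list[np.ndarray]
    seed: int
    stratified: bool

    def __post_init__(self):
        allidx = np.concatenate(self.folds)
        if len(np.unique(allidx)) != len(allidx):
            raise ValueError("folds overlap")
        sizes = [len(f) for f in self.folds]
        if max(sizes) - min(sizes) > 1:
            raise ValueError(f"fold sizes differ by more than 1: {sizes}")


def kfold_split(
    records: pd.DataFrame, k: int = 10, seed: int = 0, stratify: bool = True
) -> FoldPlan:
    """Random k-fold partition; sizes differ by at most one.

    Stratification interleaves each (label, allele) stratum across folds
    round-robin (after a seeded shuffle), which balances both global fold
    sizes and class composition.
    """
    n = len(records)
    if n < k:
        raise ValueError(f"{n} records cannot fill {k} folds")
    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=int)
    if stratify and "label" in records.columns:
        strata_keys = list(
            zip(records["label"].to_numpy(), records["allele"].to_numpy())
        )
        order = sorted(range(n), key=lambda i: (str(strata_keys[i]), i))
        grouped: dict = {}
        for i in order:
            grouped.setdefault(strata_keys[i], []).append(i)
        cursor = 0
        for key in sorted(grouped, key=str):
            idxs = np.array(grouped[key])
            rng.shuffle(idxs)
            for i in idxs:
                assignment[i] = cursor % k
                cursor += 1
    else:
        perm = rng.permutation(n)
        for pos, i in enumerate(perm):
            assignment[i] = pos % k
    folds = [np.flatnonzero(assignment == j) for j in range(k)]
    return FoldPlan(folds=folds, seed=seed, stratified=stratify)


@dataclass
class EvalReport:
    """Scalar evaluation metrics at a fixed decision threshold."""

    mse: float
    auc: float | None
    pr: float | None
    ppv: float | None
    sensitivity: float | None
    specificity: float | None
    accuracy: float
    threshold: float
    n_pos: int
    n_neg: int
    flags: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return asdict(self)


def evaluate_scores(
    scores: np.ndarray,
    labels: np.ndarray,
    threshold: float = 0.5,
    pr_mode: str = "average_precision",
) -> EvalReport:
    """Metrics from raw scores: MSE, rank AUC, PR and confusion rates.

    ``pr_mode`` selects average precision (default) or precision at the
    threshold for the PR column.  Single-class inputs flag AUC/PR as
    undefined but still return confusion-matrix metrics.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    mse = float(np.mean((scores - labels) ** 2))
    flags = []
    if n_pos and n_neg:
        auc = float(roc_auc_score(labels, scores))
        if pr_mode == "average_precision":
            pr = float(average_precision_score(labels, scores))
        else:
            pred = scores >= threshold
            pr = float(labels[pred].mean()) if pred.any() else None
    else:
        auc = pr = None
        flags.append("single_class: auc/pr undefined")
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    ppv = tp / (tp + fp) if (tp + fp) else None
    sens = tp / (tp + fn) if (tp + fn) else None
    spec = tn / (tn + fp) if (tn + fp) else None
    acc = (tp + tn) / max(len(labels), 1)
    return EvalReport(
        mse=mse, auc=auc, pr=pr, ppv=ppv, sensitivity=sens,
        specificity=spec, accuracy=float(acc), threshold=threshold,
        n_pos=n_pos, n_neg=n_neg, flags=flags,
    )


def _prepare(records: pd.DataFrame):
    alleles = [parse_allele(a) for a in records["allele"]]
    peptides = list(records["peptide"])
    labels = records["label"].to_numpy(dtype=float)
    return alleles, peptides, labels


def score_records(scorer: PairScorer, records: pd.DataFrame,
                  batch_size: int = 512) -> np.ndarray:
    alleles, peptides, _ = _prepare(records)
    scorer.train_mode(False)
    out = []
    for s in range(0, len(peptides), batch_size):
        probs = scorer.forward(
            alleles[s : s + batch_size], peptides[s : s + batch_size]
        )
        out.append(probs.data)
    return np.concatenate(out) if out else np.array([])


def evaluate(
    scorer: PairScorer, records: pd.DataFrame, threshold: float = 0.5
) -> EvalReport:
    """Score labelled records with a trained model and compute metrics."""
    scores = score_records(scorer, records)
    return evaluate_scores(scores, records["label"].to_numpy(), threshold)


def _snapshot(scorer: PairScorer) -> list[np.ndarray]:
    return [p.data.copy() for p in scorer.params()]


def _restore(scorer: PairScorer, snap: list[np.ndarray]):
    for p, d in zip(scorer.params(), snap):
        p.data[...] = d


def train_single(
    scorer: PairScorer,
    train: pd.DataFrame,
    val: pd.DataFrame,
    epochs: int = 100,
    batch_size: int = 128,
    lr: float = 1e-3,
    seed: int = 0,
    checkpoint_metric: str = "auc",
) -> dict:
    """Train one model; keep the best-validation checkpoint.

    Returns a history dict; the scorer is left holding the checkpointed
    parameters (validation metric = max over the epoch trajectory).
    """
    if checkpoint_metric not in ("auc", "accuracy"):
        raise ValueError(f"unknown checkpoint metric {checkpoint_metric!r}")
    tr_all, tr_pep, tr_lab = _prepare(train)
    rng = np.random.default_rng(seed)
    opt = Adam(scorer.params(), lr=lr)
    best_metric, best_snap = -np.inf, _snapshot(scorer)
    history = {"val_metric": [], "train_loss": []}
    n = len(tr_pep)
    for _epoch in range(epochs):
        scorer.train_mode(True)
        perm = rng.permutation(n)
        losses = []
        for s in range(0, n, batch_size):
            idx = perm[s : s + batch_size]
            if len(idx) < 2 and scorer.config.norm == "batch":
                continue  # batch statistics undefined on a singleton
            probs = scorer.forward(
                [tr_all[i] for i in idx], [tr_pep[i] for i in idx]
            )
            loss = scorer.loss(probs, tr_lab[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        rep = evaluate(scorer, val)
        metric = rep.auc if checkpoint_metric == "auc" else rep.accuracy
        if metric is None:
            raise ValueError(
                "validation fold has a single class; use stratified folds"
            )
        history["val_metric"].append(float(metric))
        history["train_loss"].append(float(np.mean(losses)) if losses else None)
        if metric > best_metric:
            best_metric = metric
            best_snap = _snapshot(scorer)
    _restore(scorer, best_snap)
    history["best_val_metric"] = float(best_metric)
    return history


@dataclass
class CVResult:
    """Per-fold reports and models plus their arithmetic mean."""

    fold_reports: list[EvalReport]
    mean_report: dict
    plan: FoldPlan
    scorers: list[PairScorer]
    histories: list[dict]
    manifest: dict

    def summary_frame(self) -> pd.DataFrame:
        rows = [r.as_dict() for r in self.fold_reports]
        df = pd.DataFrame(rows)
        return df.drop(columns=["flags"])


def _mean_report(reports: list[EvalReport]) -> dict:
    keys = ("mse", "auc", "pr", "ppv", "sensitivity", "specificity",
            "accuracy")
    out = {}
    for k in keys:
        vals = [getattr(r, k) for r in reports if getattr(r, k) is not None]
        out[k] = float(np.mean(vals)) if vals else None
        out[k + "_sd"] = float(np.std(vals)) if vals else None
    return out


def train_cv(
    dataset: pd.DataFrame,
    config: ScorerConfig,
    k: int = 10,
    epochs: int = 100,
    batch_size: int = 128,
    lr: float = 1e-3,
    seed: int = 0,
    stratify: bool = True,
    checkpoint_metric: str = "auc",
    plan: FoldPlan | None = None,
) -> CVResult:
    """k-fold cross-validated training; reports averaged over folds."""
    dataset = dataset.reset_index(drop=True)
    if plan is None:
        plan = kfold_split(dataset, k=k, seed=seed, stratify=stratify)
    labels = dataset["label"].to_numpy()
    for j, fold in enumerate(plan.folds):
        if len(np.unique(labels[fold])) < 2:
            raise ValueError(
                f"fold {j} has a single class; enable stratification"
            )
    inventory = [parse_allele(a) for a in dataset["allele"].unique()]
    reports, scorers, histories = [], [], []
    for j, fold in enumerate(plan.folds):
        train_idx = np.setdiff1d(np.arange(len(dataset)), fold)
        scorer = PairScorer(
            copy.deepcopy(config), alleles=inventory
        )
        hist = train_single(
            scorer,
            dataset.iloc[train_idx],
            dataset.iloc[fold],
            epochs=epochs,
            batch_size=batch_size,
            lr=lr,
            seed=seed + 1000 + j,
            checkpoint_metric=checkpoint_metric,
        )
        reports.append(evaluate(scorer, dataset.iloc[fold]))
        scorers.append(scorer)
        histories.append(hist)
    manifest = {
        "config": config.to_dict(),
        "k": k,
        "epochs": epochs,
        "batch_size": batch_size,
        "lr": lr,
        "seed": seed,
        "stratify": stratify,
        "checkpoint_metric": checkpoint_metric,
        "n_records": int(len(dataset)),
    }
    return CVResult(
        fold_reports=reports,
        mean_report=_mean_report(reports),
        plan=plan,
        scorers=scorers,
        histories=histories,
        manifest=manifest,
    )


def ablation_suite(
    dataset: pd.DataFrame,
    configs: dict[str, ScorerConfig],
    k: int = 10,
    epochs: int = 20,
    batch_size: int = 128,
    lr: float = 1e-3,
    seed: int = 0,
    holdout: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Run each config variant on identical folds and seeds.

    Returns a comparison table (one row per variant) of mean-over-fold
    metrics; when ``holdout`` records are given, each variant's fold
    models also score them and the mean holdout AUC is appended.
    """
    dataset = dataset.reset_index(drop=True)
    plan = kfold_split(dataset, k=k, seed=seed, stratify=True)
    rows = []
    for name, cfg in configs.items():
        res = train_cv(
            dataset, cfg, k=k, epochs=epochs, batch_size=batch_size,
            lr=lr, seed=seed, plan=plan,
        )
        row = {"method": name}
        row.update({k_: v for k_, v in res.mean_report.items()})
        if holdout is not None:
            h_scores = np.mean(
                [score_records(s, holdout) for s in res.scorers], axis=0
            )
            h_rep = evaluate_scores(h_scores, holdout["label"].to_numpy())
            row["holdout_auc"] = h_rep.auc
            row["holdout_pr"] = h_rep.pr
        rows.append(row)
    return pd.DataFrame(rows)
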