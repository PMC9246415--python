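"""High-level modelling interface.

:class:`EpitopeModel` is built from a labelled record table (allele,
peptide, label) and a scorer configuration; :meth:`EpitopeModel.fit` runs
the cross-validated training protocol and returns an
:class:`EpitopeResults` carrying per-fold metrics, their dispersion, the
fold models and a ``summary()`` table.  Prediction on new records averages
the fold models' scores.

Two fitted instances of the same architecture cover the two tasks: a
presentation model (eluted-ligand positives vs decoys) and an
immunogenicity model (wet-lab T-cell assay labels).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .network import ScorerConfig
from .trainer import CVResult, evaluate_scores, score_records, train_cv

__all__ = ["EpitopeModel", "EpitopeResults"]


class EpitopeModel:
    """An allele–peptide classifier specified by data plus configuration."""

    def __init__(
        self,
        records: pd.DataFrame,
        config: ScorerConfig | None = None,
        task: str = "presentation",
    ):
        if task not in ("presentation", "immunogenicity"):
            raise ValueError(f"unknown task {task!r}")
        for col in ("allele", "peptide", "label"):
            if col not in records.columns:
                raise ValueError(f"records need column {col!r}")
        self.records = records.reset_index(drop=True)
        self.config = config if config is not None else ScorerConfig()
        self.task = task

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, config: ScorerConfig | None = None,
        task: str = "presentation",
    ) -> "EpitopeModel":
        return cls(df, config=config, task=task)

    def fit(
        self,
        k: int = 10,
        epochs: int = 100,
        batch_size: int = 128,
        lr: float = 1e-3,
        seed: int = 0,
        **kw,
    ) -> "EpitopeResults":
        res = train_cv(
            self.records, self.config, k=k, epochs=epochs,
            batch_size=batch_size, lr=lr, seed=seed, **kw,
        )
        return EpitopeResults(self, res)


class EpitopeResults:
    """Cross-validated fit: estimates, dispersion, diagnostics."""

    def __init__(self, model: EpitopeModel, cv: CVResult):
        self.model = model
        self.cv = cv
        self.metrics = cv.mean_report

    @property
    def fold_reports(self):
        return self.cv.fold_reports

    def predict(self, records: pd.DataFrame) -> pd.DataFrame:
        """Mean-over-fold-model scores for new (allele, peptide) records."""
        scores = np.mean(
            [score_records(s, records) for s in self.cv.scorers], axis=0
        )
        out = records.copy()
        out["score"] = scores
        out["model_kind"] = self.model.task
        return out

    def evaluate(self, records: pd.DataFrame, threshold: float = 0.5):
        pred = self.predict(records)
        return evaluate_scores(
            pred["score"].to_numpy(), records["label"].to_numpy(), threshold
        )

    def summary(self) -> str:
        """A plain-text fit summary: task, data, config, fold metrics."""
        m = self.metrics
        lines = [
            "Epitope classifier — cross-validated fit",
            "=" * 56,
            f"task:            {self.model.task}",
            f"records:         {self.cv.manifest['n_records']}"
            f"  (folds: {self.cv.manifest['k']})",
            f"encoding:        {self.model.config.encoding}"
            f" / norm: {self.model.config.norm}",
            f"layer fusion:    {self.model.config.layer_fusion}"
            f" / pair fusion: {self.model.config.pair_fusion}",
            f"architecture:    {self.model.config.architecture}"
            f" ({self.model.config.blockconv.n_blocks} blocks, "
            f"{self.model.config.blockconv.channels} ch)",
            "-" * 56,
            f"{'metric':<14}{'mean':>10}{'sd over folds':>16}",
        ]
        for key in ("mse", "auc", "pr", "ppv", "sensitivity", "specificity"):
            mean, sd = m.get(key), m.get(key + "_sd")
            if mean is None:
                lines.append(f"{key:<14}{'n/a':>10}")
            else:
                lines.append(f"{key:<14}{mean:>10.4f}{sd:>16.4f}")
        lines.append("=" * 56)
        return "\n".join(lines)
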