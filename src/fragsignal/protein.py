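"""Plasma protein score over the 17-analyte cancer panel.

Concentrations are log10(x + 1)-transformed and standardized per analyte
with training statistics, then scored by a Gaussian-kernel SVM whose
margin is mapped to [0, 1] by a sigmoid fitted on out-of-fold margins.
Positivity is at the control quantile for the target specificity.  The
model stores the canonical analyte order, so scoring is invariant to the
column order of the input table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import calibrate_threshold
from .io import PROTEIN_ANALYTES, ProteinTable
from .signal import SvmScorer, fit_svm_scorer

__all__ = ["ProteinModel", "train_protein17", "score_protein17"]


@dataclass
class ProteinModel:
    analytes: list[str]
    log_mean: np.ndarray
    log_scale: np.ndarray
    svm: SvmScorer
    threshold: float

    def __post_init__(self) -> None:
        if len(self.analytes) != 17:
            raise ValueError("the protein panel has exactly 17 analytes")
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")

    def to_jsonable(self) -> dict:
        return {
            "analytes": list(self.analytes),
            "log_mean": self.log_mean.tolist(),
            "log_scale": self.log_scale.tolist(),
            "svm": self.svm.to_jsonable(),
            "threshold": float(self.threshold),
        }

    @classmethod
    def from_jsonable(cls, d: dict) -> "ProteinModel":
        return cls(
            analytes=list(d["analytes"]),
            log_mean=np.asarray(d["log_mean"], dtype=float),
            log_scale=np.asarray(d["log_scale"], dtype=float),
            svm=SvmScorer.from_jsonable(d["svm"]),
            threshold=float(d["threshold"]),
        )


def _transform(proteins: ProteinTable) -> pd.DataFrame:
    mat = proteins.matrix()
    return np.log10(mat + 1.0)


def train_protein17(
    proteins: ProteinTable,
    labels,
    specificity: float = 0.995,
    gamma: float | str = "scale",
    c: float = 1.0,
    folds: int = 5,
    seed: int = 0,
) -> ProteinModel:
    """Train the 17-protein score on a labelled cohort (1 = cancer)."""
    labels = np.asarray(labels).astype(bool)
    logs = _transform(proteins)
    if logs.shape[0] != len(labels):
        raise ValueError("labels and protein table are misaligned")
    x = logs.to_numpy()
    mean = x.mean(axis=0)
    scale = x.std(axis=0)
    scale[scale == 0] = 1.0
    xs = (x - mean) / scale
    svm, oof_scores = fit_svm_scorer(xs, labels, gamma=gamma, c=c, folds=folds, seed=seed)
    threshold = calibrate_threshold(oof_scores[~labels], specificity)
    return ProteinModel(
        analytes=list(PROTEIN_ANALYTES),
        log_mean=mean,
        log_scale=scale,
        svm=svm,
        threshold=threshold,
    )


def score_protein17(model: ProteinModel, proteins: ProteinTable) -> pd.Series:
    """Score samples; the analyte columns are reordered canonically."""
    logs = _transform(proteins)[model.analytes]
    xs = (logs.to_numpy() - model.log_mean) / model.log_scale
    return pd.Series(model.svm.score(xs), index=logs.index, name="protein17_score")
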