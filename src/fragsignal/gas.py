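"""Global aneuploidy score (GAS) from arm-level amplicon representation.

Chromosome-arm gains and losses shift the fraction of a sample's reads
that originate from each arm.  Each sample is summarized by its per-arm
count fractions and their z-scores against training-control statistics;
a Gaussian-kernel SVM trained on euploid controls, cancers, and in
silico-generated aneuploid samples (controls with simulated arm
gains/losses at known tumor fractions) produces a score in [0, 1], with
positivity at the control quantile for the target specificity.  Sex
chromosome arms are excluded from the feature set to avoid sex
confounding.  Because fractions are used, the score is invariant to
sequencing depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import calibrate_threshold
from .io import AmpliconPanel, CountMatrix
from .signal import SvmScorer

__all__ = [
    "ArmProfile",
    "GasModel",
    "arm_fractions",
    "arm_profile",
    "make_insilico_aneuploid",
    "generate_insilico_set",
    "train_gas",
    "score_gas",
]

SEX_ARMS = {"Xp", "Xq", "Yp", "Yq"}


def _autosomal_arms(panel: AmpliconPanel) -> list[str]:
    return [a for a in panel.arms if a not in SEX_ARMS]


def arm_fractions(counts: pd.DataFrame | CountMatrix, panel: AmpliconPanel) -> pd.DataFrame:
    """Per-arm fraction of each sample's total counts (rows sum to 1)."""
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    arm_of = panel.arm_of()
    arms = _autosomal_arms(panel)
    cols = {arm: [a for a in counts.columns if arm_of.get(a) == arm] for arm in arms}
    empty = [arm for arm, c in cols.items() if not c]
    if empty:
        raise ValueError(f"arms without amplicons in the matrix: {empty}")
    per_arm = pd.DataFrame(
        {arm: counts[c].sum(axis=1) for arm, c in cols.items()}, index=counts.index
    )
    totals = per_arm.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("sample with zero total counts")
    return per_arm.div(totals, axis=0)


@dataclass
class ArmProfile:
    """Per-arm fractions and z-scores against control statistics."""

    fractions: pd.DataFrame
    z: pd.DataFrame

    def __post_init__(self) -> None:
        if not np.allclose(self.fractions.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("arm fractions must sum to 1 per sample")
        if not np.isfinite(self.z.to_numpy()).all():
            raise ValueError("non-finite arm z-score")


def arm_profile(
    counts: pd.DataFrame | CountMatrix,
    panel: AmpliconPanel,
    ctrl_mean: pd.Series | None = None,
    ctrl_sd: pd.Series | None = None,
) -> ArmProfile:
    """Arm fractions plus z-scores.

    Without stored control statistics, the mean/SD of the supplied
    samples themselves are used (appropriate for a control population).
    """
    frac = arm_fractions(counts, panel)
    if ctrl_mean is None:
        ctrl_mean = frac.mean(axis=0)
    if ctrl_sd is None:
        ctrl_sd = frac.std(axis=0, ddof=1)
    sd = ctrl_sd.replace(0, np.nan)
    z = (frac - ctrl_mean) / sd
    z = z.fillna(0.0)
    return ArmProfile(fractions=frac, z=z)


def make_insilico_aneuploid(
    counts_row: pd.Series,
    arms_to_alter,
    gain_or_loss: str,
    tumor_fraction: float,
    panel: AmpliconPanel,
    rng: np.random.Generator,
) -> pd.Series:
    """Simulate an aneuploid sample from a euploid control's counts.

    Counts on altered arms are multiplied by ``1 + t/2`` (single-copy
    gain) or ``1 - t/2`` (single-copy loss) at tumor fraction ``t``, then
    the sample is multinomially re-sampled to its original depth so the
    result is an integer count vector at unchanged coverage.
    """
    if not 0.0 <= tumor_fraction <= 1.0:
        raise ValueError("tumor_fraction must be in [0, 1]")
    if gain_or_loss not in {"gain", "loss"}:
        raise ValueError("gain_or_loss must be 'gain' or 'loss'")
    mult = 1.0 + tumor_fraction / 2.0 if gain_or_loss == "gain" else 1.0 - tumor_fraction / 2.0
    if mult <= 0:
        raise ValueError("loss multiplier must remain positive")
    arm_of = panel.arm_of()
    arms_to_alter = set(arms_to_alter)
    unknown = arms_to_alter - set(panel.arms)
    if unknown:
        raise ValueError(f"unknown arms: {sorted(unknown)}")
    weights = counts_row.astype(float).copy()
    altered = [a for a in weights.index if arm_of.get(a) in arms_to_alter]
    weights[altered] *= mult
    total = int(counts_row.sum())
    p = weights.to_numpy() / weights.sum()
    resampled = rng.multinomial(total, p)
    return pd.Series(resampled, index=counts_row.index)


def generate_insilico_set(
    controls: pd.DataFrame,
    panel: AmpliconPanel,
    n: int = 216,
    tumor_fractions=(0.01, 0.02, 0.05, 0.1, 0.2),
    max_arms: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """In silico aneuploid training samples drawn from euploid controls.

    Each sample picks a random control, a tumor fraction from the grid,
    1..``max_arms`` random autosomal arms, and gain or loss.
    """
    rng = np.random.default_rng(seed)
    arms = _autosomal_arms(panel)
    rows, names = [], []
    for i in range(n):
        src = controls.index[rng.integers(len(controls.index))]
        t = float(rng.choice(tumor_fractions))
        k = int(rng.integers(1, max_arms + 1))
        chosen = list(rng.choice(arms, size=min(k, len(arms)), replace=False))
        direction = "gain" if rng.random() < 0.5 else "loss"
        rows.append(
            make_insilico_aneuploid(controls.loc[src], chosen, direction, t, panel, rng)
        )
        names.append(f"insilico_{i}")
    return pd.DataFrame(rows, index=names)


@dataclass
class GasModel:
    """Trained aneuploidy scorer: control arm statistics, SVM, threshold."""

    arms: list[str]
    ctrl_mean: pd.Series
    ctrl_sd: pd.Series
    svm: SvmScorer
    threshold: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")

    def to_jsonable(self) -> dict:
        return {
            "arms": list(self.arms),
            "ctrl_mean": self.ctrl_mean.tolist(),
            "ctrl_sd": self.ctrl_sd.tolist(),
            "svm": self.svm.to_jsonable(),
            "threshold": float(self.threshold),
        }

    @classmethod
    def from_jsonable(cls, d: dict) -> "GasModel":
        arms = list(d["arms"])
        return cls(
            arms=arms,
            ctrl_mean=pd.Series(d["ctrl_mean"], index=arms),
            ctrl_sd=pd.Series(d["ctrl_sd"], index=arms),
            svm=SvmScorer.from_jsonable(d["svm"]),
            threshold=float(d["threshold"]),
        )


def train_gas(
    cm: CountMatrix,
    panel: AmpliconPanel,
    labels,
    n_insilico: int = 216,
    specificity: float = 0.995,
    gamma: float | str = "scale",
    c: float = 1.0,
    folds: int = 5,
    seed: int = 0,
) -> GasModel:
    """Train the aneuploidy scorer on controls and cancers, augmented
    with in silico aneuploid samples generated from the controls.

    The positivity threshold is calibrated on out-of-fold control scores
    at the target specificity.
    """
    labels = np.asarray(labels).astype(bool)
    ctrl_counts = cm.counts.loc[~labels]
    if ctrl_counts.shape[0] < 5 or labels.sum() < 5:
        raise ValueError("need >= 5 controls and >= 5 cancers")
    frac_ctrl = arm_fractions(ctrl_counts, panel)
    ctrl_mean = frac_ctrl.mean(axis=0)
    ctrl_sd = frac_ctrl.std(axis=0, ddof=1).replace(0, 1.0)

    # Out-of-fold margins for threshold calibration.  In silico samples
    # are re-generated inside each training fold from that fold's
    # controls only: an aneuploid twin of a held-out control shares its
    # noise realization and would leak it into training.
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import StratifiedKFold
    from sklearn.svm import SVC

    prof_real = arm_profile(cm.counts, panel, ctrl_mean, ctrl_sd)
    x_real = prof_real.z.to_numpy()
    y_real = labels.astype(int)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    oof_margin = np.empty(len(y_real))
    for fold_i, (tr_idx, te_idx) in enumerate(skf.split(x_real, y_real)):
        fold_ctrl = cm.counts.iloc[tr_idx][~labels[tr_idx]]
        fold_ins = generate_insilico_set(
            fold_ctrl, panel, n=n_insilico, seed=seed * 1000 + fold_i
        )
        ins_z = arm_profile(fold_ins, panel, ctrl_mean, ctrl_sd).z.to_numpy()
        x_tr = np.vstack([x_real[tr_idx], ins_z])
        y_tr = np.concatenate([y_real[tr_idx], np.ones(len(ins_z), dtype=int)])
        svc = SVC(kernel="rbf", gamma=gamma, C=c, random_state=seed)
        svc.fit(x_tr, y_tr)
        oof_margin[te_idx] = svc.decision_function(x_real[te_idx])
    lr = LogisticRegression(C=1e6, solver="lbfgs")
    lr.fit(oof_margin.reshape(-1, 1), y_real)
    platt_a = float(lr.coef_[0, 0])
    platt_b = float(lr.intercept_[0])
    oof_scores = 1.0 / (1.0 + np.exp(-(platt_a * oof_margin + platt_b)))
    threshold = calibrate_threshold(oof_scores[~labels], specificity)

    insilico = generate_insilico_set(ctrl_counts, panel, n=n_insilico, seed=seed)
    ins_z = arm_profile(insilico, panel, ctrl_mean, ctrl_sd).z.to_numpy()
    x_all = np.vstack([x_real, ins_z])
    y_all = np.concatenate([y_real, np.ones(len(ins_z), dtype=int)])
    svc = SVC(kernel="rbf", gamma=gamma, C=c, random_state=seed)
    svc.fit(x_all, y_all)
    svm = SvmScorer(
        support_vectors=svc.support_vectors_.copy(),
        dual_coef=svc.dual_coef_.copy(),
        intercept=float(svc.intercept_[0]),
        gamma=float(svc._gamma),
        platt_a=platt_a,
        platt_b=platt_b,
    )
    return GasModel(
        arms=list(prof_real.z.columns),
        ctrl_mean=ctrl_mean,
        ctrl_sd=ctrl_sd,
        svm=svm,
        threshold=threshold,
    )


def score_gas(model: GasModel, counts: pd.DataFrame | CountMatrix, panel: AmpliconPanel) -> pd.Series:
    """Score samples with a trained aneuploidy model."""
    prof = arm_profile(counts, panel, model.ctrl_mean, model.ctrl_sd)
    z = prof.z[model.arms]
    return pd.Series(model.svm.score(z.to_numpy()), index=z.index, name="gas_score")
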