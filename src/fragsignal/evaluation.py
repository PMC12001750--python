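"""Threshold calibration, assay combination, and diagnostic evaluation.

Positivity for each blood assay is defined by a score threshold calibrated
on an independent training population so that a stated fraction of
controls (default 0.5%) exceeds it.  Assays are combined by the
"any-positive" rule: a combination is positive iff at least one member
assay is positive.  Sensitivities and specificities are reported with
Wilson score 95% confidence intervals.

Two comparison modes are supported when applying thresholds:

* ``raw_strict`` -- positive iff ``score > threshold`` (the rule applied
  to full-precision scores);
* ``printed_rounded`` -- positive iff the score rounded to two decimals is
  ``>= threshold``, the convention needed to re-score tables published at
  two-decimal precision, where a rounded tie (e.g. a printed 0.96 against
  a 0.96 threshold) counts as positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import CohortTable

__all__ = [
    "EvalConfig",
    "DEFAULT_THRESHOLDS",
    "LITERATURE_COMPARATORS",
    "ASSAYS",
    "COMBINATIONS",
    "wilson_ci",
    "round_half_away",
    "calibrate_threshold",
    "classify",
    "combine",
    "sens_spec",
    "subgroup_partition",
    "subgroup_report",
    "literature_comparator",
    "comparator_report",
    "reproducibility",
]

#: Published positivity thresholds at 99.5% training-set specificity.
DEFAULT_THRESHOLDS = {"signal": 0.78, "gas": 0.71, "protein17": 0.96}

ASSAYS = ["signal", "gas", "protein17"]

#: The any-positive combinations evaluated in the study, in report order.
COMBINATIONS = [
    ("signal",),
    ("protein17",),
    ("gas",),
    ("signal", "protein17"),
    ("signal", "gas"),
    ("protein17", "gas"),
    ("signal", "protein17", "gas"),
]

#: Stool-test sensitivities (percent) by adenoma subgroup
#: (HGD, >=2 cm, >=1 to <2 cm) and their specificities, from the published
#: prospective screening studies used as external benchmarks.
LITERATURE_COMPARATORS = {
    "fit": {"sens": (46.0, 42.0, 21.0), "specificity": 96.0},
    "mt_sdna": {"sens": (69.0, 68.0, 38.0), "specificity": 90.0},
    "mt_sdna_next_gen": {"sens": (74.6, 68.0, 38.0), "specificity": 92.7},
}

SUBGROUPS = ["hgd", "ge2cm", "ge1lt2cm"]


@dataclass
class EvalConfig:
    """Evaluation settings: thresholds, comparison mode, CI level."""

    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    target_specificity: float = 0.995
    mode: str = "printed_rounded"
    level: float = 0.95

    def __post_init__(self) -> None:
        for name, t in self.thresholds.items():
            if not 0.0 <= t <= 1.0:
                raise ValueError(f"threshold for {name} outside [0,1]: {t}")
        if self.mode not in {"raw_strict", "printed_rounded"}:
            raise ValueError(f"unknown comparison mode: {self.mode}")


def round_half_away(x, ndigits: int = 1):
    """Round half away from zero (printed-table convention)."""
    x = np.asarray(x, dtype=float)
    factor = 10.0 ** ndigits
    out = np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor
    return out.item() if out.ndim == 0 else out


def wilson_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for ``k`` successes in ``n`` trials, in percent.

    No continuity correction; the normal quantile at the default level is
    z = 1.959964.  Returned bounds are full precision; round to one
    decimal for table display.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    z = stats.norm.ppf(0.5 + level / 2.0)
    p = k / n
    denom = 1.0 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return (100.0 * (center - half), 100.0 * (center + half))


def calibrate_threshold(control_scores, specificity: float = 0.995) -> float:
    """Score threshold achieving the target specificity on a control set.

    With ``n`` controls, ``m = ceil(n * (1 - specificity))`` exceedances
    are allowed and the threshold is the ``(n - m)``-th order statistic,
    i.e. the largest control score with at most ``m`` controls strictly
    above it.  ``specificity=1.0`` returns the control maximum.  Fewer
    than ``1 / (1 - specificity)`` controls make the calibration coarse;
    a warning is emitted in that regime.
    """
    scores = np.sort(np.asarray(list(control_scores), dtype=float))
    n = scores.size
    if n == 0:
        raise ValueError("cannot calibrate a threshold on zero controls")
    if not 0.0 < specificity <= 1.0:
        raise ValueError("specificity must be in (0, 1]")
    if specificity < 1.0 and n < 1.0 / (1.0 - specificity):
        import warnings

        warnings.warn(
            f"only {n} controls for specificity {specificity}: threshold is coarse",
            stacklevel=2,
        )
    m = int(math.ceil(n * (1.0 - specificity) - 1e-12))
    m = min(m, n - 1)
    return float(scores[n - 1 - m])


def _score_columns(scores: pd.DataFrame) -> pd.DataFrame:
    cols = {a: f"{a}_score" for a in ASSAYS}
    missing = [c for c in cols.values() if c not in scores.columns]
    if missing:
        raise ValueError(f"score table missing columns: {missing}")
    return scores


def classify(scores: pd.DataFrame, config: EvalConfig | None = None) -> pd.DataFrame:
    """Per-assay positivity calls for a score table.

    ``scores`` needs ``sample_id`` plus ``signal_score``, ``gas_score``,
    ``protein17_score`` columns (NaN = assay not run; the call is NaN).
    Returns a boolean frame indexed by sample with one column per assay.
    """
    config = config or EvalConfig()
    scores = _score_columns(scores)
    out = {}
    for assay in ASSAYS:
        s = pd.to_numeric(scores[f"{assay}_score"], errors="coerce")
        t = config.thresholds[assay]
        if config.mode == "printed_rounded":
            vals = round_half_away(s.to_numpy(dtype=float), 2)
            call = vals >= t - 1e-12
        else:
            call = s.to_numpy(dtype=float) > t
        call = pd.Series(call, index=scores["sample_id"].to_numpy(), dtype="object")
        call[s.isna().to_numpy()] = np.nan
        out[assay] = call
    return pd.DataFrame(out)


def combine(calls: pd.DataFrame, assays) -> pd.Series:
    """Any-positive (logical OR) combination of the chosen assays.

    Missing member calls are treated as negative.
    """
    assays = list(assays)
    if not assays:
        raise ValueError("at least one assay must be selected")
    sub = calls[assays].eq(True)  # NaN (missing call) compares False
    return sub.any(axis=1)


def sens_spec(calls: pd.Series, is_case: pd.Series, level: float = 0.95) -> dict:
    """Sensitivity/specificity (percent) with Wilson CIs for one call set."""
    calls = calls.astype(bool)
    is_case = is_case.astype(bool)
    tp = int((calls & is_case).sum())
    n_case = int(is_case.sum())
    fp = int((calls & ~is_case).sum())
    n_ctrl = int((~is_case).sum())
    res = {"tp": tp, "n_case": n_case, "fp": fp, "n_ctrl": n_ctrl}
    if n_case:
        res["sensitivity"] = 100.0 * tp / n_case
        res["sens_ci"] = wilson_ci(tp, n_case, level)
    if n_ctrl:
        res["specificity"] = 100.0 * (n_ctrl - fp) / n_ctrl
        res["spec_ci"] = wilson_ci(n_ctrl - fp, n_ctrl, level)
    return res


def subgroup_partition(cohort: CohortTable) -> pd.Series:
    """Mutually exclusive case subgroups in priority order.

    ``hgd`` -- high-grade dysplasia, any size; ``ge2cm`` -- remaining
    cases with size >= 2.0 cm; ``ge1lt2cm`` -- remaining cases with
    1.0 <= size < 2.0 cm.  Raises if a case fits no group.
    """
    cases = cohort.cases.set_index("sample_id")
    out = pd.Series(index=cases.index, dtype="object")
    hgd = cases["dysplasia"] == "high"
    out[hgd] = "hgd"
    size = cases["size_cm"]
    ge2 = ~hgd & (size >= 2.0)
    out[ge2] = "ge2cm"
    ge1lt2 = ~hgd & ~ge2 & (size >= 1.0) & (size < 2.0)
    out[ge1lt2] = "ge1lt2cm"
    if out.isna().any():
        bad = list(out.index[out.isna()])
        raise ValueError(f"cases not assignable to any subgroup: {bad}")
    return out


def subgroup_report(
    scores: pd.DataFrame,
    cohort: CohortTable,
    config: EvalConfig | None = None,
) -> pd.DataFrame:
    """Sensitivity/specificity of every assay combination, overall and by
    adenoma subgroup (the full performance matrix).

    Returns a long-format frame with one row per (methodology, column)
    where ``column`` is ``all`` or a subgroup, carrying detected counts,
    sensitivity with Wilson CI, and the shared specificity with CI.
    """
    config = config or EvalConfig()
    calls = classify(scores, config)
    groups = scores.set_index("sample_id")["group"]
    is_case = groups == "case"
    part = subgroup_partition(cohort)
    rows = []
    for combo in COMBINATIONS:
        name = "+".join(combo)
        call = combine(calls, list(combo))
        overall = sens_spec(call, is_case, config.level)
        cols = {"all": is_case[is_case].index}
        for g in SUBGROUPS:
            cols[g] = part.index[part == g]
        for colname, ids in cols.items():
            tp = int(call.loc[ids].sum())
            n = len(ids)
            lo, hi = wilson_ci(tp, n, config.level)
            rows.append(
                {
                    "methodology": name,
                    "column": colname,
                    "n": n,
                    "detected": tp,
                    "sensitivity": 100.0 * tp / n,
                    "sens_lo": lo,
                    "sens_hi": hi,
                    "fp": overall["fp"],
                    "n_ctrl": overall["n_ctrl"],
                    "specificity": overall.get("specificity", np.nan),
                    "spec_lo": overall.get("spec_ci", (np.nan, np.nan))[0],
                    "spec_hi": overall.get("spec_ci", (np.nan, np.nan))[1],
                }
            )
    return pd.DataFrame(rows)


def literature_comparator(group_sizes, sensitivities) -> tuple[list[int], float]:
    """Expected detections when literature subgroup sensitivities are
    applied to this study's subgroup sizes.

    ``sensitivities`` are percentages; per-subgroup expected counts are
    rounded to the nearest integer and the overall sensitivity is the
    summed count over the summed size, in percent.
    """
    group_sizes = list(group_sizes)
    sens = [float(s) for s in sensitivities]
    if len(group_sizes) != len(sens):
        raise ValueError("group sizes and sensitivities differ in length")
    if any(not 0.0 <= s <= 100.0 for s in sens):
        raise ValueError("sensitivities must be in [0, 100] percent")
    counts = [int(round_half_away(n * s / 100.0, 0)) for n, s in zip(group_sizes, sens)]
    total = sum(group_sizes)
    overall = 100.0 * sum(counts) / total if total else 0.0
    return counts, overall


def comparator_report(cohort: CohortTable) -> pd.DataFrame:
    """Expected FIT / stool-DNA performance on this cohort's subgroup mix."""
    part = subgroup_partition(cohort)
    sizes = [int((part == g).sum()) for g in SUBGROUPS]
    rows = []
    for name, spec in LITERATURE_COMPARATORS.items():
        counts, overall = literature_comparator(sizes, spec["sens"])
        row = {
            "methodology": name,
            "specificity": spec["specificity"],
            "detected": sum(counts),
            "n": sum(sizes),
            "sensitivity": overall,
        }
        for g, n, c in zip(SUBGROUPS, sizes, counts):
            row[f"{g}_detected"] = c
            row[f"{g}_sensitivity"] = 100.0 * c / n if n else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def reproducibility(scores_a, scores_b, threshold: float | None = None) -> dict:
    """Agreement between independently re-assayed duplicate aliquots.

    Pearson correlation is computed on log-scale scores floored at 0.01,
    the resolution at which scores are reported (two decimals); without
    the floor, a single near-zero score pair dominates the correlation
    through unbounded log leverage.  If a positivity ``threshold`` is
    given, concordant positive/negative pair counts are also reported.
    """
    a = np.asarray(list(scores_a), dtype=float)
    b = np.asarray(list(scores_b), dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need >= 3 aligned score pairs")
    la, lb = np.log(np.maximum(a, 1e-2)), np.log(np.maximum(b, 1e-2))
    if np.allclose(la, la[0]) or np.allclose(lb, lb[0]):
        raise ValueError("zero variance in one replicate arm")
    r, p = stats.pearsonr(la, lb)
    out = {"r": float(r), "p_value": float(p), "n": int(a.size)}
    if threshold is not None:
        pa, pb = a > threshold, b > threshold
        out["concordant_positive"] = int((pa & pb).sum())
        out["concordant_negative"] = int((~pa & ~pb).sum())
        out["discordant"] = int((pa != pb).sum())
    return out
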