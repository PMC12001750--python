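"""Fragmentation-signature classifier for cfDNA amplicon count matrices.

The classifier turns a samples x amplicons read-count matrix into a score
in [0, 1] in four stages:

1. **Amplicon filtering** -- amplicons whose depth-normalized counts
   differ across sequencing batches (Kruskal-Wallis, Benjamini-Hochberg
   corrected) or whose typical abundance falls below a floor are removed.
2. **Signature extraction** -- counts are normalized within each
   chromosome arm (each sample's arm profile sums to 1) and factorized by
   non-negative matrix factorization, one factorization per arm.  The
   resulting signatures are distributions over amplicons (non-negative,
   summing to 1); each sample is represented by its non-negative
   least-squares exposures to the signatures, concatenated over arms.
   The shared number of signatures per arm is chosen by stratified
   cross-validation: the smallest rank whose sensitivity at the target
   specificity is within a small tolerance of the best over the grid.
3. **Fragmentation-consistent feature selection** -- tumor-derived cfDNA
   is more fragmented, so informative signatures should either
   concentrate mass on short-insert amplicons and be over-used in cancer,
   or concentrate on long-insert amplicons and be under-used.  A
   signature is kept when its insert-length centroid and the direction of
   its case/control exposure shift agree, at a one-sided rank-test FDR.
4. **Scoring** -- a Gaussian-kernel SVM on the standardized selected
   exposures, with a sigmoid (Platt) map fitted on out-of-fold margins so
   the score lies in [0, 1], and a positivity threshold placed at the
   control quantile for the target specificity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.decomposition import NMF
from sklearn.linear_model import LogisticRegression
from sklearn.metrics.pairwise import rbf_kernel
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests

from .evaluation import calibrate_threshold
from .io import AmpliconPanel, CountMatrix

__all__ = [
    "FilterReport",
    "SignatureModel",
    "SvmScorer",
    "SignalModel",
    "filter_amplicons",
    "normalize_by_arm",
    "extract_signatures",
    "exposures",
    "select_fragmentation_features",
    "choose_dimension",
    "fit_svm_scorer",
    "fit_signal_pipeline",
    "score_signal",
]


# ---------------------------------------------------------------------------
# stage 1: batch-effect filtering
# ---------------------------------------------------------------------------


@dataclass
class FilterReport:
    """Outcome of batch-effect amplicon filtering."""

    kept: list
    dropped: list
    stats: pd.DataFrame  # amplicon_id, statistic, q_value, median_norm, reason

    def __post_init__(self) -> None:
        if set(self.kept) & set(self.dropped):
            raise ValueError("kept and dropped amplicon sets overlap")


def filter_amplicons(
    cm: CountMatrix,
    q_max: float = 0.05,
    floor_frac: float = 0.1,
) -> FilterReport:
    """Drop amplicons that are batch-sensitive or too shallow.

    Counts are depth-normalized per sample, then each amplicon is tested
    for a batch effect with a Kruskal-Wallis test across batches and the
    p-values are BH-corrected; amplicons at q < ``q_max`` are dropped.
    Amplicons whose median normalized count is below ``floor_frac`` times
    the median over amplicons (including all-zero amplicons) are dropped
    regardless.  Run this on training controls only.
    """
    batches = cm.batch
    levels = batches.unique()
    if len(levels) < 2:
        raise ValueError(
            "amplicon filtering needs >= 2 batches; with a single batch, "
            "skip filtering explicitly"
        )
    sizes = batches.value_counts()
    if (sizes < 3).any():
        small = list(sizes.index[sizes < 3])
        raise ValueError(f"each batch needs >= 3 control samples; too small: {small}")
    norm = cm.counts.div(cm.counts.sum(axis=1).replace(0, np.nan), axis=0).fillna(0.0)
    groups = [norm.loc[batches == b].to_numpy() for b in levels]
    n_amp = norm.shape[1]
    pvals = np.ones(n_amp)
    statv = np.zeros(n_amp)
    for j in range(n_amp):
        cols = [g[:, j] for g in groups]
        flat = np.concatenate(cols)
        if np.allclose(flat, flat[0]):
            continue  # constant across all samples: no batch signal
        statv[j], pvals[j] = stats.kruskal(*cols)
    qvals = multipletests(pvals, method="fdr_bh")[1]
    med = norm.median(axis=0).to_numpy()
    floor = floor_frac * np.median(med)
    reason = np.full(n_amp, "", dtype=object)
    drop_batch = qvals < q_max
    drop_floor = med < floor
    reason[drop_batch] = "batch_effect"
    reason[drop_floor] = np.where(
        reason[drop_floor] == "", "low_count", "batch_effect+low_count"
    )
    dropped_mask = drop_batch | drop_floor
    ids = np.asarray(cm.amplicon_ids, dtype=object)
    report = pd.DataFrame(
        {
            "amplicon_id": ids,
            "statistic": statv,
            "q_value": qvals,
            "median_norm": med,
            "reason": reason,
        }
    )
    return FilterReport(
        kept=list(ids[~dropped_mask]),
        dropped=list(ids[dropped_mask]),
        stats=report,
    )


# ---------------------------------------------------------------------------
# stage 2: per-arm normalization and signature extraction
# ---------------------------------------------------------------------------


def normalize_by_arm(
    counts: pd.DataFrame | CountMatrix,
    panel: AmpliconPanel,
    amplicons: list | None = None,
) -> dict[str, pd.DataFrame]:
    """Arm-wise count normalization: each sample's entries within an arm
    sum to 1.

    Returns ``{arm: samples x amplicons_in_arm frame}`` in panel arm
    order.  Per-sample sequencing depth cancels, so the output is
    invariant to scaling a sample's counts.
    """
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    if amplicons is not None:
        counts = counts[[a for a in amplicons if a in counts.columns]]
    arm_of = panel.arm_of()
    unknown = set(counts.columns) - set(arm_of.index)
    if unknown:
        raise ValueError(f"amplicons without arm assignment: {sorted(unknown)[:5]}")
    out: dict[str, pd.DataFrame] = {}
    for arm in panel.arms:
        cols = [a for a in counts.columns if arm_of[a] == arm]
        if not cols:
            continue
        block = counts[cols].astype(float)
        totals = block.sum(axis=1)
        if (totals == 0).any():
            sample = totals.index[totals == 0][0]
            raise ValueError(f"arm total is zero for sample {sample!r} on arm {arm!r}")
        out[arm] = block.div(totals, axis=0)
    return out


@dataclass
class SignatureModel:
    """Per-arm non-negative signature dictionaries.

    ``w[arm]`` is an amplicons x k frame whose columns are fragmentation
    signatures: non-negative distributions over the arm's amplicons.
    """

    w: dict[str, pd.DataFrame]
    k: int
    arm_order: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for arm, w in self.w.items():
            arr = w.to_numpy()
            if (arr < 0).any():
                raise ValueError(f"negative signature weight on arm {arm}")
            sums = arr.sum(axis=0)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError(f"signature columns on arm {arm} must sum to 1")

    @property
    def feature_names(self) -> list[str]:
        return [f"{arm}:s{j}" for arm in self.arm_order for j in range(self.w[arm].shape[1])]


def extract_signatures(
    arm_mats: dict[str, pd.DataFrame],
    k: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> SignatureModel:
    """Factorize each arm's normalized count matrix as V ~ E W^T.

    Frobenius-loss NMF with a deterministic non-negative-SVD
    initialization; the amplicon-side factor is column-normalized so each
    signature is a probability distribution over the arm's amplicons.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    w: dict[str, pd.DataFrame] = {}
    for arm, mat in arm_mats.items():
        n, p = mat.shape
        if k > min(n, p):
            raise ValueError(
                f"k={k} exceeds min(samples, amplicons)={min(n, p)} on arm {arm}"
            )
        model = NMF(
            n_components=k,
            init="nndsvda",
            solver="cd",
            max_iter=max_iter,
            tol=tol,
            random_state=seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(mat.to_numpy())
        comp = model.components_.T  # amplicons x k
        sums = comp.sum(axis=0)
        sums[sums == 0] = 1.0
        comp = comp / sums
        w[arm] = pd.DataFrame(comp, index=mat.columns, columns=[f"s{j}" for j in range(k)])
    return SignatureModel(
        w=w,
        k=k,
        arm_order=list(arm_mats.keys()),
        meta={"max_iter": max_iter, "tol": tol, "seed": seed, "loss": "frobenius"},
    )


def exposures(model: SignatureModel, arm_mats: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Non-negative least-squares exposures of samples to the signatures.

    Each sample's normalized per-arm profile is projected onto the arm's
    signature dictionary by NNLS; exposure vectors are concatenated over
    arms in the model's fixed arm order.
    """
    missing = [a for a in model.arm_order if a not in arm_mats]
    if missing:
        raise ValueError(f"arm profiles missing for arms: {missing}")
    sample_index = arm_mats[model.arm_order[0]].index
    blocks = []
    for arm in model.arm_order:
        w = model.w[arm]
        mat = arm_mats[arm]
        if list(mat.columns) != list(w.index):
            mat = mat.reindex(columns=w.index)
            if mat.isna().any().any():
                raise ValueError(f"panel mismatch on arm {arm}: missing amplicons")
        a = w.to_numpy()
        vs = mat.to_numpy()
        if np.any(vs.sum(axis=1) == 0):
            sample = mat.index[vs.sum(axis=1) == 0][0]
            raise ValueError(f"all-zero profile for sample {sample!r} on arm {arm}")
        expo = np.empty((vs.shape[0], a.shape[1]))
        for i in range(vs.shape[0]):
            expo[i], _ = optimize.nnls(a, vs[i])
        blocks.append(
            pd.DataFrame(
                expo,
                index=mat.index,
                columns=[f"{arm}:{c}" for c in w.columns],
            )
        )
    out = pd.concat(blocks, axis=1)
    return out.loc[sample_index]


# ---------------------------------------------------------------------------
# stage 3: fragmentation-consistent feature selection
# ---------------------------------------------------------------------------


def signature_length_centroids(model: SignatureModel, panel: AmpliconPanel) -> pd.Series:
    """Expected insert length of each signature (mass-weighted)."""
    lengths = panel.insert_lengths()
    vals = {}
    for arm in model.arm_order:
        w = model.w[arm]
        l = lengths.reindex(w.index).to_numpy(dtype=float)
        for c in w.columns:
            vals[f"{arm}:{c}"] = float(w[c].to_numpy() @ l)
    return pd.Series(vals)


def select_fragmentation_features(
    model: SignatureModel,
    panel: AmpliconPanel,
    expo: pd.DataFrame,
    labels,
    q_max: float = 0.1,
) -> list[int]:
    """Indices of signatures consistent with elevated tumor fragmentation.

    A signature qualifies when (a) its length centroid is below the panel
    median insert length and its exposures are one-sided rank-test higher
    in cases, or (b) centroid above the median and exposures lower in
    cases; selection at BH q < ``q_max``.  May return an empty list.
    """
    labels = np.asarray(labels).astype(bool)
    if len(labels) != expo.shape[0]:
        raise ValueError("labels and exposures are misaligned")
    centroids = signature_length_centroids(model, panel)
    used = [a for arm in model.arm_order for a in model.w[arm].index]
    median_len = float(panel.insert_lengths().reindex(used).median())
    pvals, directions = [], []
    for name in expo.columns:
        x = expo[name].to_numpy()
        short = centroids[name] < median_len
        alternative = "greater" if short else "less"
        case_vals, ctrl_vals = x[labels], x[~labels]
        if np.allclose(x, x[0]):
            p = 1.0
        else:
            p = stats.mannwhitneyu(case_vals, ctrl_vals, alternative=alternative).pvalue
        pvals.append(p)
        directions.append("short_up" if short else "long_down")
    qvals = multipletests(pvals, method="fdr_bh")[1]
    return [i for i in range(len(qvals)) if qvals[i] < q_max]


# ---------------------------------------------------------------------------
# stage 4: SVM scoring
# ---------------------------------------------------------------------------


@dataclass
class SvmScorer:
    """A Gaussian-kernel SVM margin plus a sigmoid score map.

    Stores only what is needed to score: support vectors, dual
    coefficients, intercept, kernel width, and the Platt coefficients
    fitted on out-of-fold margins.  ``score`` maps to (0, 1).
    """

    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    gamma: float
    platt_a: float
    platt_b: float

    def decision(self, x: np.ndarray) -> np.ndarray:
        k = rbf_kernel(np.atleast_2d(x), self.support_vectors, gamma=self.gamma)
        return k @ self.dual_coef.ravel() + self.intercept

    def score(self, x: np.ndarray) -> np.ndarray:
        margin = self.decision(x)
        return 1.0 / (1.0 + np.exp(-(self.platt_a * margin + self.platt_b)))

    def to_jsonable(self) -> dict:
        return {
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.ravel().tolist(),
            "intercept": float(self.intercept),
            "gamma": float(self.gamma),
            "platt_a": float(self.platt_a),
            "platt_b": float(self.platt_b),
        }

    @classmethod
    def from_jsonable(cls, d: dict) -> "SvmScorer":
        return cls(
            support_vectors=np.asarray(d["support_vectors"], dtype=float),
            dual_coef=np.asarray(d["dual_coef"], dtype=float),
            intercept=float(d["intercept"]),
            gamma=float(d["gamma"]),
            platt_a=float(d["platt_a"]),
            platt_b=float(d["platt_b"]),
        )


def fit_svm_scorer(
    x: np.ndarray,
    labels,
    gamma: float | str = "scale",
    c: float = 1.0,
    folds: int = 5,
    seed: int = 0,
) -> tuple[SvmScorer, np.ndarray]:
    """Fit the RBF SVM and its Platt sigmoid on out-of-fold margins.

    Returns the scorer and the out-of-fold calibrated scores (used for
    threshold calibration so training-set optimism does not leak into the
    specificity quantile).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required to train the classifier")
    counts = np.bincount(y)
    if counts.min() < 5:
        raise ValueError("need >= 5 samples per class")
    folds = min(folds, counts.min())
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    oof_margin = np.empty(len(y))
    for train_idx, test_idx in skf.split(x, y):
        svc = SVC(kernel="rbf", gamma=gamma, C=c, random_state=seed)
        svc.fit(x[train_idx], y[train_idx])
        oof_margin[test_idx] = svc.decision_function(x[test_idx])
    lr = LogisticRegression(C=1e6, solver="lbfgs")
    lr.fit(oof_margin.reshape(-1, 1), y)
    platt_a = float(lr.coef_[0, 0])
    platt_b = float(lr.intercept_[0])
    svc = SVC(kernel="rbf", gamma=gamma, C=c, random_state=seed)
    svc.fit(x, y)
    scorer = SvmScorer(
        support_vectors=svc.support_vectors_.copy(),
        dual_coef=svc.dual_coef_.copy(),
        intercept=float(svc.intercept_[0]),
        gamma=float(svc._gamma),
        platt_a=platt_a,
        platt_b=platt_b,
    )
    oof_scores = 1.0 / (1.0 + np.exp(-(platt_a * oof_margin + platt_b)))
    return scorer, oof_scores


@dataclass
class SignalModel:
    """Trained fragmentation classifier: filter, signatures, selection,
    standardization, SVM and positivity threshold."""

    kept_amplicons: list
    signatures: SignatureModel
    selected: list[int]
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    svm: SvmScorer
    threshold: float
    filter_report: FilterReport | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")
        n_feat = len(self.signatures.feature_names)
        if any(i < 0 or i >= n_feat for i in self.selected):
            raise ValueError("selected feature index out of range")

    def to_jsonable(self) -> dict:
        return {
            "kept_amplicons": list(self.kept_amplicons),
            "k": self.signatures.k,
            "arm_order": self.signatures.arm_order,
            "w": {
                arm: {
                    "amplicons": list(w.index),
                    "values": w.to_numpy().tolist(),
                }
                for arm, w in self.signatures.w.items()
            },
            "selected": list(map(int, self.selected)),
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_scale": self.scaler_scale.tolist(),
            "svm": self.svm.to_jsonable(),
            "threshold": float(self.threshold),
        }

    @classmethod
    def from_jsonable(cls, d: dict) -> "SignalModel":
        w = {
            arm: pd.DataFrame(
                np.asarray(block["values"], dtype=float),
                index=block["amplicons"],
                columns=[f"s{j}" for j in range(d["k"])],
            )
            for arm, block in d["w"].items()
        }
        sigs = SignatureModel(w=w, k=d["k"], arm_order=list(d["arm_order"]))
        return cls(
            kept_amplicons=list(d["kept_amplicons"]),
            signatures=sigs,
            selected=list(d["selected"]),
            scaler_mean=np.asarray(d["scaler_mean"], dtype=float),
            scaler_scale=np.asarray(d["scaler_scale"], dtype=float),
            svm=SvmScorer.from_jsonable(d["svm"]),
            threshold=float(d["threshold"]),
        )


def _standardize_fit(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = x.mean(axis=0)
    scale = x.std(axis=0)
    scale[scale == 0] = 1.0
    return mean, scale


def fit_signal_pipeline(
    cm: CountMatrix,
    panel: AmpliconPanel,
    labels,
    k: int,
    gamma: float | str = "scale",
    c: float = 1.0,
    specificity: float = 0.995,
    folds: int = 5,
    seed: int = 0,
    q_max_filter: float = 0.05,
    q_max_select: float = 0.1,
    skip_filter: bool = False,
) -> SignalModel:
    """Train the full fragmentation classifier on a labelled cohort.

    Batch filtering uses the training controls only.  If feature
    selection returns nothing, all extracted signatures are used (with a
    warning) so downstream scoring remains defined.
    """
    labels = np.asarray(labels).astype(bool)
    report = None
    if skip_filter or cm.batch.nunique() < 2:
        kept = cm.amplicon_ids
    else:
        ctrl_ids = [s for s, is_case in zip(cm.sample_ids, labels) if not is_case]
        report = filter_amplicons(cm.subset_samples(ctrl_ids), q_max=q_max_filter)
        kept = report.kept
    arm_mats = normalize_by_arm(cm, panel, amplicons=kept)
    sigs = extract_signatures(arm_mats, k=k, seed=seed)
    expo = exposures(sigs, arm_mats)
    selected = select_fragmentation_features(sigs, panel, expo, labels, q_max=q_max_select)
    if not selected:
        warnings.warn("no fragmentation-consistent signature selected; using all")
        selected = list(range(expo.shape[1]))
    x = expo.to_numpy()[:, selected]
    mean, scale = _standardize_fit(x)
    xs = (x - mean) / scale
    svm, oof_scores = fit_svm_scorer(xs, labels, gamma=gamma, c=c, folds=folds, seed=seed)
    threshold = calibrate_threshold(oof_scores[~labels], specificity)
    return SignalModel(
        kept_amplicons=list(kept),
        signatures=sigs,
        selected=selected,
        scaler_mean=mean,
        scaler_scale=scale,
        svm=svm,
        threshold=threshold,
        filter_report=report,
    )


def score_signal(model: SignalModel, cm: CountMatrix, panel: AmpliconPanel) -> pd.Series:
    """Score samples with a trained fragmentation classifier."""
    missing = set(model.kept_amplicons) - set(cm.amplicon_ids)
    if missing:
        raise ValueError(f"count matrix missing model amplicons: {sorted(missing)[:5]}")
    arm_mats = normalize_by_arm(cm, panel, amplicons=model.kept_amplicons)
    expo = exposures(model.signatures, arm_mats)
    x = expo.to_numpy()[:, model.selected]
    xs = (x - model.scaler_mean) / model.scaler_scale
    return pd.Series(model.svm.score(xs), index=expo.index, name="signal_score")


# ---------------------------------------------------------------------------
# cross-validated choice of the signature count
# ---------------------------------------------------------------------------


def choose_dimension(
    cm: CountMatrix,
    panel: AmpliconPanel,
    labels,
    k_grid,
    folds: int = 5,
    specificity: float = 0.995,
    eps: float = 0.01,
    seed: int = 0,
) -> int:
    """Smallest signature count whose cross-validated sensitivity at the
    target specificity is within ``eps`` of the best over ``k_grid``.

    Out-of-fold scores are pooled across stratified folds; the threshold
    is the pooled-control quantile at the target specificity.  Run on
    pre-filtered counts (filtering is a training-control operation and is
    not repeated inside each fold).
    """
    k_grid = list(k_grid)
    if not k_grid:
        raise ValueError("empty k grid")
    if len(k_grid) == 1:
        return k_grid[0]
    labels = np.asarray(labels).astype(bool)
    n_ctrl = int((~labels).sum())
    if specificity < 1.0 and n_ctrl * (1.0 - specificity) < 1.0 / folds:
        # with so few controls the per-grid quantile is meaningless
        if n_ctrl < folds:
            raise ValueError("too few controls to estimate the specificity quantile")
    sens = {}
    ids = np.asarray(cm.sample_ids, dtype=object)
    for k in k_grid:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        oof = np.empty(len(labels))
        for train_idx, test_idx in skf.split(ids, labels.astype(int)):
            sub = cm.subset_samples(list(ids[train_idx]))
            model = fit_signal_pipeline(
                sub, panel, labels[train_idx], k=k, specificity=specificity,
                folds=min(folds, 3), seed=seed, skip_filter=True,
            )
            test = cm.subset_samples(list(ids[test_idx]))
            oof[test_idx] = score_signal(model, test, panel).to_numpy()
        t = calibrate_threshold(oof[~labels], specificity)
        sens[k] = float((oof[labels] > t).mean())
    best = max(sens.values())
    for k in sorted(k_grid):
        if sens[k] >= best - eps:
            return k
    return sorted(k_grid)[0]
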