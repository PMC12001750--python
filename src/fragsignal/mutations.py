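"""Partitioned multi-well mutation detection with an empirical noise null.

cfDNA is split across up to 95 wells (<= 300 genome equivalents each) and
each well is amplified and sequenced independently; partitioning
concentrates the few mutant templates into a handful of wells and raises
the signal-to-noise ratio for rare mutations.  For each tissue-identified
("target") mutation the mutant-allele fraction (MAF) is computed per
qualifying well and pooled across wells.  The background noise of the
assay is modelled empirically from two sources: MAFs of variants observed
in the patient's plasma amplicons that are *not* present in the adenoma
tissue, and MAFs of all variants in a matched no-cancer control run of
the same amplicons.

Each target mutation is scored as the negative log of the add-one
empirical tail probability of its pooled MAF under the noise pool; the
per-sample aggregate is the sum of mutation scores (a Fisher-style
combination).  A Monte-Carlo null re-draws pooled MAFs from the noise
model at the sample's own read depths and mutation count; the sample is
called circulating-mutation positive when the aggregate's p-value falls
below alpha (default 0.01).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import WellTable

__all__ = [
    "MafSummary",
    "NoiseModel",
    "MutationCall",
    "compute_mafs",
    "fit_background",
    "tail_probability",
    "score_mutation",
    "aggregate_pvalue",
    "call_sample",
]

MIN_WELL_DEPTH = 100


@dataclass
class MafSummary:
    """Per-well and pooled MAFs for each mutation after depth filtering."""

    per_well: pd.DataFrame   # sample_id, mutation_id, well_index, mutant, total, maf
    pooled: pd.DataFrame     # sample_id, mutation_id, mutant_sum, total_sum, pooled_maf, n_wells
    excluded_wells: pd.DataFrame


def compute_mafs(wells: WellTable, min_depth: int = MIN_WELL_DEPTH) -> MafSummary:
    """Per-well MAFs (wells below ``min_depth`` total reads are excluded
    and logged) and the depth-weighted pooled MAF per mutation.

    Raises if a mutation retains no qualifying well.
    """
    t = wells.table
    ok = t["total_reads"] >= min_depth
    excluded = t[~ok].copy()
    kept = t[ok].copy()
    lost = set(map(tuple, t[["sample_id", "mutation_id"]].drop_duplicates().itertuples(index=False))) - set(
        map(tuple, kept[["sample_id", "mutation_id"]].drop_duplicates().itertuples(index=False))
    )
    if lost:
        raise ValueError(f"no qualifying wells (depth >= {min_depth}) for: {sorted(lost)[:5]}")
    kept["maf"] = kept["mutant_reads"] / kept["total_reads"]
    pooled = (
        kept.groupby(["sample_id", "mutation_id"], sort=False)
        .agg(
            mutant_sum=("mutant_reads", "sum"),
            total_sum=("total_reads", "sum"),
            n_wells=("well_index", "size"),
            is_target=("is_target", "first"),
        )
        .reset_index()
    )
    pooled["pooled_maf"] = pooled["mutant_sum"] / pooled["total_sum"]
    return MafSummary(per_well=kept, pooled=pooled, excluded_wells=excluded)


@dataclass
class NoiseModel:
    """Empirical background-noise distribution of the assay.

    ``pool`` holds the well-level background MAFs (sorted) used for tail
    probabilities; ``variant_rates`` holds one pooled MAF per background
    variant, the fallback resampling distribution for the Monte-Carlo
    null.  ``matched_controls`` maps each variant measured in the
    no-cancer control run to its pooled (mutant, total) counts there:
    because the control run covers the patient's own target amplicons,
    each target mutation has a variant-matched background measurement
    that shares its position-specific error rate.  A beta distribution
    fitted by the method of moments (after adding the pseudo-count) is
    kept for reference.
    """

    pool: np.ndarray
    variant_rates: np.ndarray
    pseudo: float
    beta_params: tuple[float, float] | None = None
    matched_controls: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pool = np.sort(np.asarray(self.pool, dtype=float))
        self.variant_rates = np.asarray(self.variant_rates, dtype=float)
        if ((self.pool < 0) | (self.pool > 1)).any():
            raise ValueError("pooled MAFs must lie in [0, 1]")

    @property
    def pool_size(self) -> int:
        return int(self.pool.size)


def fit_background(
    sample_nontargets: WellTable,
    control_run: WellTable | None = None,
    min_pool: int = 50,
    min_depth: int = MIN_WELL_DEPTH,
) -> NoiseModel:
    """Fit the noise model from non-target plasma variants and an
    optional no-cancer control run over the same amplicons."""
    frames = [sample_nontargets.table]
    if control_run is not None:
        frames.append(control_run.table)
    combined = WellTable(pd.concat(frames, ignore_index=True).assign(
        sample_id=lambda d: d["sample_id"].astype(str) + "::" + np.where(
            np.arange(len(d)) < len(frames[0]), "plasma", "control"
        )
    ))
    summary = compute_mafs(combined, min_depth=min_depth)
    pool = summary.per_well["maf"].to_numpy()
    if pool.size < min_pool:
        raise ValueError(
            f"background pool of {pool.size} well-level MAFs is below the "
            f"minimum of {min_pool}; empirical noise modelling is unreliable"
        )
    rates = summary.pooled["pooled_maf"].to_numpy()
    matched: dict = {}
    if control_run is not None:
        ctrl_summary = compute_mafs(control_run, min_depth=min_depth)
        for row in ctrl_summary.pooled.itertuples(index=False):
            matched[row.mutation_id] = (int(row.mutant_sum), int(row.total_sum))
    mean_depth = float(summary.per_well["total_reads"].mean())
    pseudo = 0.5 / mean_depth
    adj = pool + pseudo
    m, v = adj.mean(), adj.var()
    beta_params = None
    if v > 0:
        common = m * (1 - m) / v - 1.0
        if common > 0:
            beta_params = (m * common, (1 - m) * common)
    return NoiseModel(
        pool=pool,
        variant_rates=rates,
        pseudo=pseudo,
        beta_params=beta_params,
        matched_controls=matched,
        meta={"mean_depth": mean_depth, "n_variants": int(rates.size)},
    )


def tail_probability(noise: NoiseModel, maf) -> np.ndarray:
    """Add-one empirical upper-tail probability of a MAF under the pool:
    ``(1 + #{pool >= maf}) / (pool_size + 1)`` -- never zero."""
    maf = np.atleast_1d(np.asarray(maf, dtype=float))
    n = noise.pool_size
    below = np.searchsorted(noise.pool, maf, side="left")
    return (1.0 + (n - below)) / (n + 1.0)


def score_mutation(observed_maf, noise: NoiseModel) -> np.ndarray:
    """Mutation score: ``-log`` of the pooled MAF's noise tail probability."""
    return -np.log(tail_probability(noise, observed_maf))


@dataclass
class MutationCall:
    """Per-sample decision of the multi-well mutation statistic."""

    per_mutation: pd.DataFrame  # mutation_id, pooled_maf, n_wells, positive_wells, score
    aggregate_score: float
    p_value: float
    alpha: float
    positive: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")
        if self.positive != (self.p_value < self.alpha):
            raise ValueError("positive flag inconsistent with p-value and alpha")

    def to_jsonable(self) -> dict:
        return {
            "per_mutation": self.per_mutation.to_dict(orient="records"),
            "aggregate_score": float(self.aggregate_score),
            "p_value": float(self.p_value),
            "alpha": float(self.alpha),
            "positive": bool(self.positive),
        }


def aggregate_pvalue(
    targets: WellTable,
    noise: NoiseModel,
    n_null: int = 100_000,
    seed: int = 0,
    alpha: float = 0.01,
    min_depth: int = MIN_WELL_DEPTH,
) -> MutationCall:
    """Aggregate score and Monte-Carlo p-value for one sample's target
    mutations.

    The null assumes every target MAF is background noise: for each
    mutation a background rate is drawn from the noise model and a
    pooled mutant count is drawn binomially at the mutation's observed
    total depth; ``p = (1 + #{null >= observed}) / (n_null + 1)``.

    Background error rates are strongly position-specific, so when the
    noise model carries a variant-matched control-run measurement for a
    mutation, the null rate is drawn from the Jeffreys-posterior beta of
    that measurement (sharing the mutation's own error rate and its
    estimation uncertainty).  Mutations without a matched measurement
    fall back to resampling the pooled background variant rates, which
    is vulnerable to the finite pool's tail and should be avoided when a
    control run is available.
    """
    t = targets.table
    if t.empty:
        raise ValueError("no target mutations to score")
    if t["sample_id"].nunique() > 1:
        raise ValueError("aggregate_pvalue scores one sample at a time")
    if n_null < 1000:
        warnings.warn(f"n_null={n_null} gives a coarse p-value; use >= 1000")
    summary = compute_mafs(targets, min_depth=min_depth)
    pooled = summary.pooled
    scores = score_mutation(pooled["pooled_maf"].to_numpy(), noise)
    # a well is counted positive when its MAF clears the pool's 95th percentile
    well_cut = float(np.quantile(noise.pool, 0.95)) if noise.pool_size else 0.0
    pos_wells = (
        summary.per_well.assign(pos=summary.per_well["maf"] > well_cut)
        .groupby("mutation_id", sort=False)["pos"]
        .sum()
        .reindex(pooled["mutation_id"])
        .to_numpy()
    )
    aggregate = float(scores.sum())

    rng = np.random.default_rng(seed)
    null_agg = np.zeros(n_null)
    for row in pooled.itertuples(index=False):
        d = int(row.total_sum)
        ctrl = noise.matched_controls.get(row.mutation_id)
        if ctrl is not None:
            xc, dc = ctrl
            rates = rng.beta(xc + 0.5, dc - xc + 0.5, size=n_null)
        else:
            rates = rng.choice(noise.variant_rates, size=n_null, replace=True)
        mutants = rng.binomial(d, rates)
        null_agg += score_mutation(mutants / d, noise)
    p = (1.0 + float((null_agg >= aggregate - 1e-12).sum())) / (n_null + 1.0)

    per_mut = pd.DataFrame(
        {
            "mutation_id": pooled["mutation_id"],
            "pooled_maf": pooled["pooled_maf"],
            "n_wells": pooled["n_wells"],
            "positive_wells": pos_wells.astype(int),
            "score": scores,
        }
    )
    return MutationCall(
        per_mutation=per_mut,
        aggregate_score=aggregate,
        p_value=p,
        alpha=alpha,
        positive=bool(p < alpha),
    )


def call_sample(
    wells: WellTable,
    control_run: WellTable | None = None,
    n_null: int = 100_000,
    seed: int = 0,
    alpha: float = 0.01,
    min_depth: int = MIN_WELL_DEPTH,
    min_pool: int = 50,
) -> MutationCall:
    """End-to-end call for one sample's well table: split targets from
    background variants, fit the noise model, score and decide."""
    noise = fit_background(
        wells.non_targets(), control_run, min_pool=min_pool, min_depth=min_depth
    )
    return aggregate_pvalue(
        wells.targets(), noise, n_null=n_null, seed=seed, alpha=alpha, min_depth=min_depth
    )
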