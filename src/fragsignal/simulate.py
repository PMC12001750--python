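"""Synthetic cohorts with the statistical structure the assays assume.

The generator emulates, at desk scale, the data the assays consume:

* an amplicon panel spread over chromosome arms with per-amplicon
  expected insert lengths (uniform 80-160 bp);
* control count profiles: negative-binomial counts (over-dispersed, as
  amplicon assays are) around log-normal baseline amplicon propensities,
  with per-batch multiplicative effects;
* tumor-bearing samples: a latent tumor fraction ``t`` mixes in a
  tumor-derived component whose amplicon propensities are tilted toward
  short inserts (``exp(-beta * (L - L_min))`` -- tumor cfDNA is more
  fragmented, and a repeated-element assay observes fragment length
  through the amplifiability of short-insert loci), plus arm-level
  multipliers ``1 +/- t/2`` on a random set of altered arms (aneuploidy);
* plasma proteins: log-normal baselines with case elevations on a subset
  of the 17 analytes;
* the partitioned mutation assay: mutant templates binomially allocated
  over 95 wells of <= 300 genome equivalents, sequenced with per-variant
  error rates, alongside background (non-target) variants and a matched
  no-cancer control run.

Every latent parameter is recorded in a truth table; a replicate mode
re-draws the technical noise while holding each sample's latent state
fixed, emulating independently re-processed plasma aliquots.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import AmpliconPanel, CohortTable, CountMatrix, PROTEIN_ANALYTES, ProteinTable, WellTable

__all__ = ["SimConfig", "SimCohort", "gen_panel", "gen_cohort", "gen_proteins", "gen_wells"]


@dataclass
class SimConfig:
    """Generator settings.  Defaults are the package's study conditions."""

    # panel
    n_arms: int = 10
    amplicons_per_arm: int = 900
    insert_min: int = 80
    insert_max: int = 160
    # cohort sizes
    n_controls: int = 320
    n_cancers: int = 160
    n_cases: int = 0
    # sequencing depth (per amplicon) and over-dispersion
    depth_mean: float = 200.0
    nb_dispersion: float = 0.1
    # batches
    n_batches: int = 2
    batch_sd: float = 0.05
    # tumor biology
    beta_frag: float = 0.16           # per-bp short-insert tilt of tumor cfDNA
    host_tilt_sd: float = 0.012       # per-subject fragmentation state (per bp)
    tumor_fraction_range: tuple = (0.01, 0.2)       # cancers, log-uniform
    case_tumor_fraction_range: tuple = (0.002, 0.05)  # adenomas, log-uniform
    aneuploid_arms_range: tuple = (1, 3)  # <= 30% of the scaled 10-arm panel
    baseline_sigma: float = 0.5
    # proteins
    protein_n_elevated: int = 6
    protein_effect_log10: float = 0.5
    protein_sigma_log10: float = 0.25
    # multi-well assay
    n_wells: int = 95
    genome_equivalents: int = 300
    well_depth_mean: float = 2000.0
    error_rate_median: float = 1e-4
    error_rate_sigma_log10: float = 0.35
    n_nontarget_variants: int = 30    # background variants per target amplicon
    control_depth_factor: float = 4.0  # the single reference run is sequenced deeper
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_arms, self.amplicons_per_arm, self.n_batches, self.n_wells) < 1:
            raise ValueError("counts in the configuration must be positive")
        if not 0 < self.insert_min <= self.insert_max:
            raise ValueError("invalid insert length range")
        if self.depth_mean <= 0 or self.well_depth_mean <= 0:
            raise ValueError("depths must be positive")
        for lo, hi in (self.tumor_fraction_range, self.case_tumor_fraction_range):
            if not 0 < lo <= hi <= 1:
                raise ValueError("tumor fraction ranges must lie in (0, 1]")


@dataclass
class SimCohort:
    panel: AmpliconPanel
    counts: CountMatrix
    cohort: CohortTable
    truth: pd.DataFrame
    replicate: CountMatrix | None = None

    @property
    def labels(self) -> np.ndarray:
        """Boolean tumor-bearing indicator aligned with the count rows."""
        g = self.cohort.table.set_index("sample_id")["group"]
        return (g.loc[self.counts.sample_ids] != "control").to_numpy()


def gen_panel(config: SimConfig, rng: np.random.Generator) -> AmpliconPanel:
    """Synthetic amplicon panel: ``n_arms`` arms (p/q of consecutive
    autosomes) with ``amplicons_per_arm`` amplicons each."""
    arms = []
    chrom = 1
    while len(arms) < config.n_arms:
        arms.append(f"{chrom}p")
        if len(arms) < config.n_arms:
            arms.append(f"{chrom}q")
        chrom += 1
    rows = []
    for arm in arms:
        inserts = rng.integers(config.insert_min, config.insert_max + 1, size=config.amplicons_per_arm)
        starts = np.sort(rng.integers(1, 120_000_000, size=config.amplicons_per_arm))
        for j in range(config.amplicons_per_arm):
            rows.append(
                {
                    "amplicon_id": f"{arm}_a{j:04d}",
                    "chrom": arm[:-1],
                    "arm": arm,
                    "start": int(starts[j]),
                    "expected_insert_length": int(inserts[j]),
                }
            )
    return AmpliconPanel(pd.DataFrame(rows))


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = m + dispersion * m^2 (gamma-Poisson)."""
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    lam = mean * rng.gamma(shape=r, scale=1.0 / r, size=mean.shape)
    return rng.poisson(lam)


def _tumor_propensity(
    p0: np.ndarray, inserts: np.ndarray, beta: float, arm_of: np.ndarray
) -> np.ndarray:
    """Short-insert tilt of the tumor component, arm-balanced.

    The tilt re-weights amplicons *within* each arm while preserving the
    arm's total propensity: fragment-length preference is compositional,
    whereas arm dosage is governed by copy number (modelled separately
    via arm multipliers).
    """
    q = p0 * np.exp(-beta * (inserts - inserts.min()))
    for arm in np.unique(arm_of):
        mask = arm_of == arm
        arm_total = q[mask].sum()
        if arm_total > 0:
            q[mask] *= p0[mask].sum() / arm_total
    return q / q.sum()


def _loguniform(rng: np.random.Generator, lo: float, hi: float, size: int) -> np.ndarray:
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


def gen_cohort(config: SimConfig, seed: int | None = None, replicates: bool = False) -> SimCohort:
    """Generate a labelled cohort of amplicon count profiles.

    Controls are euploid draws from the baseline propensities; cancers
    and adenoma cases carry a latent tumor fraction that (a) tilts the
    amplicon mixture toward short inserts and (b) multiplies counts on a
    random altered-arm set by ``1 +/- t/2``.  With ``replicates=True`` a
    second count matrix is drawn from the same latent states.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    panel = gen_panel(config, rng)
    inserts = panel.table["expected_insert_length"].to_numpy(dtype=float)
    arm_of = panel.table["arm"].to_numpy()
    arms = panel.arms
    n_amp = len(inserts)

    p0 = rng.lognormal(0.0, config.baseline_sigma, size=n_amp)
    p0 /= p0.sum()
    q_tumor = _tumor_propensity(p0, inserts, config.beta_frag, arm_of)
    batch_mults = rng.lognormal(0.0, config.batch_sd, size=(config.n_batches, n_amp))

    groups = (
        ["control"] * config.n_controls
        + ["cancer"] * config.n_cancers
        + ["case"] * config.n_cases
    )
    n = len(groups)
    sample_ids = [f"S{i:05d}" for i in range(n)]
    batches = rng.integers(0, config.n_batches, size=n)

    tf = np.zeros(n)
    is_tumor = np.array([g != "control" for g in groups])
    n_cancer = config.n_cancers
    tf[config.n_controls : config.n_controls + n_cancer] = _loguniform(
        rng, *config.tumor_fraction_range, size=n_cancer
    )
    tf[config.n_controls + n_cancer :] = _loguniform(
        rng, *config.case_tumor_fraction_range, size=config.n_cases
    )
    lo_arms, hi_arms = config.aneuploid_arms_range
    altered: list[list[str]] = []
    direction: list[str] = []
    for i in range(n):
        if is_tumor[i]:
            k = int(rng.integers(lo_arms, hi_arms + 1))
            altered.append(list(rng.choice(arms, size=min(k, len(arms)), replace=False)))
            direction.append("gain" if rng.random() < 0.5 else "loss")
        else:
            altered.append([])
            direction.append("")

    # latent per-subject fragmentation state, shared between replicate
    # aliquots of the same subject (inter-individual cfDNA variation)
    host_tilt = rng.normal(0.0, config.host_tilt_sd, size=n)

    def draw_matrix(noise_rng: np.random.Generator, batch_idx: np.ndarray) -> np.ndarray:
        counts = np.empty((n, n_amp), dtype=np.int64)
        for i in range(n):
            t = tf[i]
            base = (
                _tumor_propensity(p0, inserts, host_tilt[i], arm_of)
                if host_tilt[i] != 0.0
                else p0
            )
            prop = (1.0 - t) * base + t * q_tumor if t > 0 else base.copy()
            if altered[i]:
                mult = 1.0 + t / 2.0 if direction[i] == "gain" else 1.0 - t / 2.0
                mask = np.isin(arm_of, altered[i])
                prop = prop * np.where(mask, mult, 1.0)
                prop = prop / prop.sum()
            mean = config.depth_mean * n_amp * prop * batch_mults[batch_idx[i]]
            counts[i] = _nb_draw(noise_rng, mean, config.nb_dispersion)
        return counts

    counts = draw_matrix(rng, batches)
    cm = CountMatrix(
        pd.DataFrame(counts, index=sample_ids, columns=panel.amplicon_ids),
        pd.Series([f"batch{b}" for b in batches], index=sample_ids),
    )

    meta = {"sample_id": sample_ids, "group": groups}
    cohort_df = pd.DataFrame(meta)
    if config.n_cases:
        is_case = cohort_df["group"] == "case"
        n_cases = int(is_case.sum())
        sizes = np.round(np.exp(rng.uniform(np.log(1.0), np.log(6.0), n_cases)), 1)
        hist = rng.choice(
            ["tubular", "tubulovillous", "villous", "serrated"],
            size=n_cases,
            p=[0.6, 0.225, 0.05, 0.125],
        )
        dys = np.where(rng.random(n_cases) < 0.2, "high", "low")
        cohort_df.loc[is_case, "size_cm"] = sizes
        cohort_df.loc[is_case, "histology"] = hist
        cohort_df.loc[is_case, "dysplasia"] = dys
    cohort = CohortTable(cohort_df)

    truth = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": groups,
            "tumor_fraction": tf,
            "altered_arms": [";".join(a) for a in altered],
            "direction": direction,
            "batch": [f"batch{b}" for b in batches],
        }
    )

    rep_cm = None
    if replicates:
        rep_batches = rng.integers(0, config.n_batches, size=n)
        rep_counts = draw_matrix(rng, rep_batches)
        rep_cm = CountMatrix(
            pd.DataFrame(rep_counts, index=sample_ids, columns=panel.amplicon_ids),
            pd.Series([f"batch{b}" for b in rep_batches], index=sample_ids),
        )
    return SimCohort(panel=panel, counts=cm, cohort=cohort, truth=truth, replicate=rep_cm)


def gen_proteins(config: SimConfig, labels, seed: int | None = None) -> ProteinTable:
    """Plasma concentrations for the 17 analytes: log-normal baselines,
    with tumor-bearing samples elevated on a fixed analyte subset."""
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels).astype(bool)
    n = len(labels)
    mu = rng.uniform(1.0, 3.0, size=len(PROTEIN_ANALYTES))  # log10 baseline
    elevated = rng.choice(
        len(PROTEIN_ANALYTES), size=min(config.protein_n_elevated, 17), replace=False
    )
    logs = rng.normal(mu, config.protein_sigma_log10, size=(n, len(PROTEIN_ANALYTES)))
    severity = rng.uniform(0.5, 1.5, size=n)
    for j in elevated:
        logs[labels, j] += config.protein_effect_log10 * severity[labels]
    conc = np.power(10.0, logs)
    df = pd.DataFrame(conc, columns=PROTEIN_ANALYTES)
    df.insert(0, "sample_id", [f"S{i:05d}" for i in range(n)])
    return ProteinTable(df)


def gen_wells(
    config: SimConfig,
    true_mafs: dict[str, float],
    seed: int | None = None,
    sample_id: str = "S00000",
) -> tuple[WellTable, WellTable]:
    """Well-level read counts for one sample of the partitioned assay.

    ``true_mafs`` maps target mutation ids to their circulating MAFs
    (0 = mutation absent from plasma).  Mutant templates per well are
    ``Binomial(GE, maf)``; each well's total reads are negative-binomial
    around the well depth; observed mutant reads mix the template
    fraction with a per-variant sequencing error rate.  Background
    (non-target) variants arise from error only.  Returns the sample's
    well table and a matched no-cancer control run over the same
    variants (sharing the per-variant error rates, as position-specific
    assay noise does).
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    if any(not 0.0 <= m < 1.0 for m in true_mafs.values()):
        raise ValueError("true MAFs must lie in [0, 1)")
    targets = list(true_mafs)
    n_bg = config.n_nontarget_variants * max(len(targets), 1)
    variants = targets + [f"bg_{i:04d}" for i in range(n_bg)]
    n_var, w = len(variants), config.n_wells
    ge = config.genome_equivalents

    err = config.error_rate_median * np.power(
        10.0, rng.normal(0.0, config.error_rate_sigma_log10, size=n_var)
    )

    def run(mafs: np.ndarray, run_rng: np.random.Generator, depth: float) -> pd.DataFrame:
        templates = run_rng.binomial(ge, mafs[:, None], size=(n_var, w))
        totals = np.maximum(
            _nb_draw(run_rng, np.full((n_var, w), depth), config.nb_dispersion),
            1,
        )
        frac = templates / ge
        p_read = frac + (1.0 - frac) * err[:, None]
        mutants = run_rng.binomial(totals, p_read)
        return pd.DataFrame(
            {
                "mutation_id": np.repeat(variants, w),
                "well_index": np.tile(np.arange(1, w + 1), n_var),
                "mutant_reads": mutants.ravel(),
                "total_reads": totals.ravel(),
                "is_target": np.repeat([v in true_mafs for v in variants], w),
            }
        )

    maf_vec = np.array([true_mafs.get(v, 0.0) for v in variants])
    plasma = run(maf_vec, rng, config.well_depth_mean).assign(sample_id=sample_id)
    control = run(
        np.zeros(n_var), rng, config.well_depth_mean * config.control_depth_factor
    ).assign(sample_id="control_run")
    cols = ["sample_id", "mutation_id", "well_index", "mutant_reads", "total_reads", "is_target"]
    return WellTable(plasma[cols]), WellTable(control[cols])
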