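"""Data model and I/O for amplicon panels, count matrices, and assay tables.

The package operates on five tabular inputs:

* an **amplicon panel** (``panel.tsv``) annotating each amplicon with its
  chromosome, chromosome arm and expected insert length;
* a samples x amplicons **count matrix** (``counts.tsv``) of integer read
  counts with a per-sample batch label;
* a **cohort table** (``cohort.csv``) with case/control labels and, for
  cases, adenoma size, histology, dysplasia grade and colonic location;
* a **protein table** (``proteins.csv``) with plasma concentrations of the
  17 cancer-associated analytes;
* a **well table** (``wells.tsv``) with per-well mutant/total read counts
  from the partitioned (95-well) mutation assay.

All files are plain UTF-8 text; ``.`` or an empty field denotes a missing
value.  Genomic coordinates are 1-based inclusive and used only for
bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "PROTEIN_ANALYTES",
    "AmpliconPanel",
    "CountMatrix",
    "CohortTable",
    "ProteinTable",
    "WellTable",
    "read_panel",
    "read_counts",
    "write_counts",
    "write_panel",
    "read_cohort",
    "read_proteins",
    "read_wells",
    "write_wells",
    "load_study_cohort",
    "load_study_scores",
]

#: The 17 plasma analytes used by the protein score, in canonical order.
PROTEIN_ANALYTES = [
    "myeloperoxidase",
    "shbg",           # sex hormone-binding globulin
    "gdf15",          # growth differentiation factor 15
    "nse",            # neuron-specific enolase
    "opg",            # osteoprotegerin
    "dkk1",           # Dickkopf-1
    "afp",            # alpha-fetoprotein
    "ca125",
    "ca15_3",
    "ca19_9",
    "cea",
    "hgf",            # hepatocyte growth factor
    "opn",            # osteopontin
    "cyfra21_1",      # cytokeratin 19 fragment
    "il8",
    "fgf2",
    "timp1",
]

GROUPS = {"case", "control", "cancer", "non_cancer"}
DYSPLASIA_LEVELS = {"low", "high", "missing"}
HISTOLOGIES = {"tubular", "tubulovillous", "villous", "serrated"}
LOCATIONS = {
    "cecum",
    "ascending_colon",
    "hepatic_flexure",
    "transverse_colon",
    "descending_colon",
    "sigmoid_colon",
    "rectum",
}

#: Acrocentric short arms carry no usable loci and are excluded by default.
ACROCENTRIC_SHORT_ARMS = {"13p", "14p", "15p", "21p", "22p"}

_MISSING_TOKENS = {"", ".", "na", "nan", "not available", "none"}


class FragsignalIOError(ValueError):
    """Raised when an input file violates the documented contract."""


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and np.isnan(value):
        return True
    return str(value).strip().lower() in _MISSING_TOKENS


def _norm_enum(value, mapping: dict, what: str, allow_missing: bool = False):
    if _is_missing(value):
        if allow_missing:
            return np.nan
        raise FragsignalIOError(f"missing value for required field {what!r}")
    key = str(value).strip().lower().replace(" ", "_").replace("/", "_")
    if key in mapping:
        return mapping[key]
    raise FragsignalIOError(f"unknown {what} value: {value!r}")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class AmpliconPanel:
    """Annotation of the amplicon universe.

    ``table`` has columns ``amplicon_id, chrom, arm, start,
    expected_insert_length`` with unique amplicon ids, positive insert
    lengths, and exactly one arm per amplicon.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["amplicon_id", "chrom", "arm", "start", "expected_insert_length"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise FragsignalIOError(f"panel is missing columns: {missing}")
        t = self.table.reset_index(drop=True).copy()
        if t["amplicon_id"].duplicated().any():
            dup = t.loc[t["amplicon_id"].duplicated(), "amplicon_id"].iloc[0]
            raise FragsignalIOError(f"duplicate amplicon_id in panel: {dup!r}")
        t["expected_insert_length"] = t["expected_insert_length"].astype(int)
        if (t["expected_insert_length"] <= 0).any():
            raise FragsignalIOError("expected_insert_length must be > 0")
        t["start"] = t["start"].astype(int)
        if t["arm"].isna().any():
            raise FragsignalIOError("every amplicon must map to exactly one arm")
        self.table = t

    @property
    def amplicon_ids(self) -> list[str]:
        return list(self.table["amplicon_id"])

    @property
    def arms(self) -> list[str]:
        """Arms in order of first appearance."""
        return list(dict.fromkeys(self.table["arm"]))

    def arm_of(self) -> pd.Series:
        return self.table.set_index("amplicon_id")["arm"]

    def insert_lengths(self) -> pd.Series:
        return self.table.set_index("amplicon_id")["expected_insert_length"]


@dataclass
class CountMatrix:
    """Integer read counts, samples as rows and amplicons as columns.

    ``counts`` is indexed by sample id; ``batch`` is a per-sample label
    aligned with the count index.
    """

    counts: pd.DataFrame
    batch: pd.Series

    def __post_init__(self) -> None:
        counts = self.counts.copy()
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            rounded = np.rint(arr)
            if not np.allclose(arr, rounded, atol=0, rtol=0):
                raise FragsignalIOError("counts must be integers")
            counts = counts.astype(np.int64)
        if (counts.to_numpy() < 0).any():
            raise FragsignalIOError("counts must be non-negative")
        batch = pd.Series(self.batch).astype(str)
        batch.index = pd.Index(self.batch.index if hasattr(self.batch, "index") else counts.index)
        if not counts.index.equals(batch.index):
            batch = batch.reindex(counts.index)
            if batch.isna().any():
                raise FragsignalIOError("batch labels do not cover all samples")
        if counts.index.duplicated().any():
            raise FragsignalIOError("duplicate sample_id in count matrix")
        counts.index.name = "sample_id"
        batch.index.name = "sample_id"
        self.counts = counts
        self.batch = batch

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def amplicon_ids(self) -> list[str]:
        return list(self.counts.columns)

    def subset_samples(self, sample_ids: Iterable[str]) -> "CountMatrix":
        ids = list(sample_ids)
        return CountMatrix(self.counts.loc[ids], self.batch.loc[ids])

    def validate_against(self, panel: AmpliconPanel) -> None:
        extra = set(self.counts.columns) - set(panel.amplicon_ids)
        if extra:
            raise FragsignalIOError(
                f"amplicons absent from panel: {sorted(extra)[:5]}"
            )


@dataclass
class CohortTable:
    """Per-sample labels and, for cases, adenoma attributes."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table.reset_index(drop=True).copy()
        if "sample_id" not in t.columns or "group" not in t.columns:
            raise FragsignalIOError("cohort requires sample_id and group columns")
        if t["sample_id"].duplicated().any():
            dup = t.loc[t["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise FragsignalIOError(f"duplicate sample_id in cohort: {dup!r}")
        group_map = {g: g for g in GROUPS}
        t["group"] = [_norm_enum(v, group_map, "group") for v in t["group"]]
        dys_map = {
            "low": "low",
            "high": "high",
            "high_grade_severe": "high",
            "high_grade": "high",
        }
        hist_map = {h: h for h in HISTOLOGIES}
        hist_map.update({"villous_adenoma": "villous", "serrated_adenoma": "serrated"})
        loc_map = {l: l for l in LOCATIONS}
        for col, mapping in [("dysplasia", dys_map), ("histology", hist_map), ("location", loc_map)]:
            if col in t.columns:
                t[col] = [_norm_enum(v, mapping, col, allow_missing=True) for v in t[col]]
        if "size_cm" in t.columns:
            t["size_cm"] = pd.to_numeric(
                t["size_cm"].map(lambda v: np.nan if _is_missing(v) else v)
            )
            if (t["size_cm"].dropna() <= 0).any():
                raise FragsignalIOError("size_cm must be positive")
        is_case = t["group"] == "case"
        for col in ("size_cm", "histology"):
            if col in t.columns:
                if t.loc[is_case, col].isna().any():
                    raise FragsignalIOError(f"{col} required for every case")
                if t.loc[~is_case, col].notna().any():
                    raise FragsignalIOError(f"{col} must be absent for non-cases")
        if "dysplasia" in t.columns:
            t.loc[is_case & t["dysplasia"].isna(), "dysplasia"] = "missing"
        self.table = t

    @property
    def cases(self) -> pd.DataFrame:
        return self.table[self.table["group"] == "case"]

    @property
    def controls(self) -> pd.DataFrame:
        return self.table[self.table["group"] == "control"]


@dataclass
class ProteinTable:
    """Plasma concentrations of the 17 analytes, one row per sample."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table.reset_index(drop=True).copy()
        if "sample_id" not in t.columns:
            raise FragsignalIOError("protein table requires a sample_id column")
        missing = [a for a in PROTEIN_ANALYTES if a not in t.columns]
        if missing:
            raise FragsignalIOError(f"missing analyte columns: {missing}")
        extra = set(t.columns) - set(PROTEIN_ANALYTES) - {"sample_id"}
        if extra:
            raise FragsignalIOError(f"unexpected columns in protein table: {sorted(extra)}")
        if t["sample_id"].duplicated().any():
            raise FragsignalIOError("duplicate sample_id in protein table")
        vals = t[PROTEIN_ANALYTES].astype(float)
        if (vals.to_numpy() < 0).any():
            raise FragsignalIOError("protein concentrations must be >= 0")
        self.table = pd.concat([t[["sample_id"]], vals], axis=1)

    def matrix(self) -> pd.DataFrame:
        """Concentrations in canonical analyte order, indexed by sample."""
        return self.table.set_index("sample_id")[PROTEIN_ANALYTES]


@dataclass
class WellTable:
    """Per-well mutant/total read counts for the partitioned mutation assay.

    ``is_target`` marks mutations identified in the patient's adenoma
    tissue; other observed variants within the same amplicons feed the
    background-noise model.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table.reset_index(drop=True).copy()
        required = ["sample_id", "mutation_id", "well_index", "mutant_reads", "total_reads", "is_target"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise FragsignalIOError(f"well table missing columns: {missing}")
        for col in ("well_index", "mutant_reads", "total_reads"):
            t[col] = t[col].astype(int)
        if (t["mutant_reads"] < 0).any() or (t["total_reads"] < 0).any():
            raise FragsignalIOError("read counts must be non-negative")
        if (t["mutant_reads"] > t["total_reads"]).any():
            raise FragsignalIOError("mutant_reads cannot exceed total_reads")
        if isinstance(t["is_target"].iloc[0] if len(t) else True, str):
            t["is_target"] = t["is_target"].str.strip().str.lower().map(
                {"true": True, "false": False, "1": True, "0": False}
            )
        t["is_target"] = t["is_target"].astype(bool)
        if t.duplicated(["sample_id", "mutation_id", "well_index"]).any():
            raise FragsignalIOError("well_index must be unique per (sample, mutation)")
        self.table = t

    def targets(self) -> "WellTable":
        return WellTable(self.table[self.table["is_target"]])

    def non_targets(self) -> "WellTable":
        return WellTable(self.table[~self.table["is_target"]])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_panel(path) -> AmpliconPanel:
    """Read a tab-separated amplicon annotation table."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return AmpliconPanel(pd.read_csv(path, sep="\t", dtype={"amplicon_id": str, "chrom": str, "arm": str}))


def read_counts(path, panel_path) -> tuple[CountMatrix, AmpliconPanel]:
    """Read a counts TSV plus its companion panel and cross-validate them.

    The counts file has one row per sample, a ``sample_id`` column, a
    ``batch`` column, and one integer column per amplicon.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    panel = read_panel(panel_path)
    raw = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "batch": str})
    for col in ("sample_id", "batch"):
        if col not in raw.columns:
            raise FragsignalIOError(f"counts file requires a {col!r} column")
    counts = raw.drop(columns=["batch"]).set_index("sample_id")
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise FragsignalIOError("non-numeric count value encountered")
    if not np.allclose(arr, np.rint(arr), atol=0, rtol=0):
        raise FragsignalIOError("non-integer count value encountered")
    cm = CountMatrix(counts.astype(np.int64), raw.set_index("sample_id")["batch"])
    cm.validate_against(panel)
    return cm, panel


def write_counts(cm: CountMatrix, path) -> None:
    out = cm.counts.copy()
    out.insert(0, "batch", cm.batch)
    out.to_csv(path, sep="\t", index=True, index_label="sample_id")


def write_panel(panel: AmpliconPanel, path) -> None:
    panel.table.to_csv(path, sep="\t", index=False)


def read_cohort(path) -> CohortTable:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return CohortTable(pd.read_csv(path, dtype={"sample_id": str}))


def read_proteins(path) -> ProteinTable:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return ProteinTable(pd.read_csv(path, dtype={"sample_id": str}))


def read_wells(path) -> WellTable:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return WellTable(pd.read_csv(path, sep="\t", dtype={"sample_id": str, "mutation_id": str}))


def write_wells(wt: WellTable, path) -> None:
    wt.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# packaged study fixtures
# ---------------------------------------------------------------------------


def _data_path(name: str) -> Path:
    return Path(__file__).parent / "data" / name


def load_study_cohort() -> CohortTable:
    """The 40 advanced-adenoma cases of the study, with per-case scores
    dropped (cohort metadata only)."""
    df = pd.read_csv(_data_path("aa_cases_published.csv"), dtype={"sample_id": str})
    meta = df.drop(columns=["signal_score", "gas_score", "protein17_score"])
    return CohortTable(meta)


def load_study_scores(include_controls: bool = True) -> pd.DataFrame:
    """Per-sample scores and cohort metadata for the 72-subject study set.

    The 40 case rows are the published per-case scores; the 32 control
    rows are a synthetic stand-in (control-level scores were not published)
    constrained to the control positivity the study reports: none exceed
    the fragmentation or protein thresholds and exactly two exceed the
    aneuploidy threshold.
    """
    cases = pd.read_csv(_data_path("aa_cases_published.csv"), dtype={"sample_id": str})
    if not include_controls:
        return cases
    controls = pd.read_csv(_data_path("controls_scores_synthetic.csv"), dtype={"sample_id": str})
    return pd.concat([cases, controls], ignore_index=True)
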