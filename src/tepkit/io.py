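"""Data model and on-disk formats for TMS-evoked potential (TEP) arrays and cohort tables.

A TEP file is a single text file: a one-line JSON header (prefixed ``#TEP1``)
carrying the metadata, followed by a whitespace-delimited numeric matrix with
one row per sample and one column per channel/vertex.  The cohort table is a
flat CSV, one row per subject, with repeated per-timepoint fields joined by
``;`` inside one cell.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TARGETS = ("DLPFC", "IPL")
SPACES = ("sensor", "source_roi")
GENDERS = ("female", "male")
TARGETING_METHODS = ("anatomical", "functional")

#: epoch must cover at least this interval (ms) for baseline + response windows
REQUIRED_SPAN_MS = (-900.0, 400.0)

TEP_MAGIC = "#TEP1"

COHORT_COLUMNS = [
    "subject_id",
    "phq_pre",
    "phq_pandemic",
    "phq2_pre",
    "gad2_pre",
    "phq2_pandemic",
    "gad2_pandemic",
    "pss14",
    "age",
    "gender",
    "education_years",
    "months_since_tms",
    "targeting_method",
    "completed_targets",
]


class TEPFormatError(ValueError):
    """Malformed TEP file or metadata inconsistent with the matrix."""


class CohortValidationError(ValueError):
    """Cohort table violates a documented invariant."""


@dataclass
class TEPTimeSeries:
    """One subject x one target evoked response (trial average).

    data is samples x series, in microvolt (sensor space) or unit current
    density (source space).  Sample ``i`` sits at ``t0_ms + i / fs_hz * 1000``
    ms relative to the TMS pulse at t = 0.
    """

    subject_id: str
    target: str
    data: np.ndarray
    t0_ms: float
    fs_hz: float
    space: str
    series_ids: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.series_ids = [str(s) for s in self.series_ids]
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        if self.target not in TARGETS:
            raise TEPFormatError(f"unknown target {self.target!r}")
        if self.space not in SPACES:
            raise TEPFormatError(f"unknown space {self.space!r}")
        if not self.fs_hz > 0:
            raise TEPFormatError(f"fs_hz must be positive, got {self.fs_hz}")
        if self.data.ndim != 2:
            raise TEPFormatError(f"data must be 2-D, got shape {self.data.shape}")
        if len(self.series_ids) != self.data.shape[1]:
            raise TEPFormatError(
                f"series_ids length {len(self.series_ids)} does not match "
                f"n_series {self.data.shape[1]}"
            )
        if len(set(self.series_ids)) != len(self.series_ids):
            raise TEPFormatError("series_ids contains duplicates")
        if not np.all(np.isfinite(self.data)):
            raise TEPFormatError("data contains non-finite values")
        t_end = self.times[-1] if self.n_samples else self.t0_ms
        lo, hi = REQUIRED_SPAN_MS
        if self.t0_ms > lo or t_end < hi:
            raise TEPFormatError(
                f"epoch [{self.t0_ms}, {t_end}] ms does not cover the required "
                f"[{lo}, {hi}] ms span"
            )

    # -- geometry --------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_series(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Time axis in ms relative to the pulse."""
        return self.t0_ms + np.arange(self.n_samples) / self.fs_hz * 1000.0

    def window_indices(self, start_ms: float, end_ms: float) -> np.ndarray:
        """Indices of samples inside the closed window [start_ms, end_ms]."""
        return window_indices(self.times, start_ms, end_ms)

    def series_index(self, series_id: str) -> int:
        try:
            return self.series_ids.index(str(series_id))
        except ValueError:
            raise KeyError(f"series {series_id!r} not in TEP") from None


def window_indices(times: np.ndarray, start_ms: float, end_ms: float) -> np.ndarray:
    """Sample indices of a closed time window, endpoint-inclusive.

    A tolerance of 1e-9 ms absorbs floating-point drift of the time axis so
    that nominal endpoints (e.g. 400 ms at 1 kHz) are always included.
    """
    if start_ms > end_ms:
        raise ValueError(f"window start {start_ms} > end {end_ms}")
    if start_ms < times[0] - 1e-9 or end_ms > times[-1] + 1e-9:
        raise ValueError(
            f"window [{start_ms}, {end_ms}] ms outside series span "
            f"[{times[0]}, {times[-1]}] ms"
        )
    mask = (times >= start_ms - 1e-9) & (times <= end_ms + 1e-9)
    return np.nonzero(mask)[0]


@dataclass
class ROIDefinition:
    """Region of interest: the source-space vertices around a stimulation target."""

    target: str
    vertex_ids: list[str]

    def __post_init__(self) -> None:
        self.vertex_ids = [str(v) for v in self.vertex_ids]
        if self.target not in TARGETS:
            raise ValueError(f"unknown target {self.target!r}")
        if not self.vertex_ids:
            raise ValueError("ROI must contain at least one vertex")

    def check_against(self, tep: TEPTimeSeries) -> None:
        missing = set(self.vertex_ids) - set(tep.series_ids)
        if missing:
            raise KeyError(f"ROI vertices missing from TEP: {sorted(missing)[:5]}...")


@dataclass
class ReactivityScore:
    """Scalar predictors for one subject x target.

    local_auc is in z*ms (z-scored rectified ROI average), global_auc in
    microvolt*ms (GMFA), baseline_activity in rectified-amplitude*ms.  The
    z-scored local series can dip below its baseline mean, so local_auc may
    be any real number.
    """

    subject_id: str
    target: str
    local_auc: float
    global_auc: float
    baseline_activity: float

    def __post_init__(self) -> None:
        for name in ("local_auc", "global_auc", "baseline_activity"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} is not finite for {self.subject_id}")


# ---------------------------------------------------------------------------
# TEP file round-trip
# ---------------------------------------------------------------------------

def write_tep(tep: TEPTimeSeries, path: str | os.PathLike, *, overwrite: bool = False) -> None:
    """Write a TEP file (JSON header line + delimited matrix)."""
    path = os.fspath(path)
    if os.path.exists(path) and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    header = {
        "subject_id": tep.subject_id,
        "target": tep.target,
        "t0_ms": tep.t0_ms,
        "fs_hz": tep.fs_hz,
        "space": tep.space,
        "series_ids": tep.series_ids,
    }
    with open(path, "w") as fh:
        fh.write(TEP_MAGIC + " " + json.dumps(header, sort_keys=True) + "\n")
        np.savetxt(fh, tep.data, fmt="%.10g", delimiter="\t")


def read_tep(path: str | os.PathLike) -> TEPTimeSeries:
    """Read and validate a TEP file written by :func:`write_tep`."""
    path = os.fspath(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith(TEP_MAGIC + " "):
            raise TEPFormatError(f"{path}: missing {TEP_MAGIC} header line")
        try:
            header = json.loads(first[len(TEP_MAGIC) + 1 :])
        except json.JSONDecodeError as exc:
            raise TEPFormatError(f"{path}: unparseable JSON header: {exc}") from exc
        for key in ("subject_id", "target", "t0_ms", "fs_hz", "space", "series_ids"):
            if key not in header:
                raise TEPFormatError(f"{path}: header missing field {key!r}")
        try:
            data = np.loadtxt(fh, ndmin=2)
        except ValueError as exc:
            raise TEPFormatError(f"{path}: unreadable data matrix: {exc}") from exc
    try:
        return TEPTimeSeries(
            subject_id=header["subject_id"],
            target=header["target"],
            data=data,
            t0_ms=float(header["t0_ms"]),
            fs_hz=float(header["fs_hz"]),
            space=header["space"],
            series_ids=header["series_ids"],
        )
    except TEPFormatError as exc:
        raise TEPFormatError(f"{path}: {exc}") from exc


def tep_filename(subject_id: str, target: str, space: str) -> str:
    return f"{subject_id}_{target}_{space}.tep"


# ---------------------------------------------------------------------------
# Cohort table
# ---------------------------------------------------------------------------

@dataclass
class CohortTable:
    """Per-subject questionnaire, demographic and acquisition metadata.

    Wraps a DataFrame with one row per subject.  ``phq_pandemic`` (and the
    optional subscale columns) hold Python lists of 1-3 integer timepoint
    scores; ``completed_targets`` holds a list drawn from {"DLPFC", "IPL"}.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)
        validate_cohort(self.df)

    def __len__(self) -> int:
        return len(self.df)

    def row(self, subject_id: str) -> pd.Series:
        hit = self.df[self.df["subject_id"] == subject_id]
        if hit.empty:
            raise KeyError(f"subject {subject_id!r} not in cohort")
        return hit.iloc[0]

    @property
    def subject_ids(self) -> list[str]:
        return list(self.df["subject_id"])


def _check_phq_total(value, subject_id: str, col: str) -> None:
    if not (isinstance(value, (int, np.integer)) and 0 <= value <= 12):
        raise CohortValidationError(
            f"subject {subject_id}: {col}={value!r} outside the PHQ-4 range 0-12"
        )


def _check_subscale(value, subject_id: str, col: str) -> None:
    if not (isinstance(value, (int, np.integer)) and 0 <= value <= 6):
        raise CohortValidationError(
            f"subject {subject_id}: {col}={value!r} outside the subscale range 0-6"
        )


def validate_cohort(df: pd.DataFrame) -> None:
    required = {"subject_id", "phq_pre", "phq_pandemic", "pss14", "age", "gender",
                "education_years", "months_since_tms", "targeting_method",
                "completed_targets"}
    missing = required - set(df.columns)
    if missing:
        raise CohortValidationError(f"cohort missing columns {sorted(missing)}")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise CohortValidationError(f"duplicate subject ids {dupes}")
    has_subscales = {"phq2_pandemic", "gad2_pandemic"} <= set(df.columns)
    for _, r in df.iterrows():
        sid = r["subject_id"]
        _check_phq_total(r["phq_pre"], sid, "phq_pre")
        pan = r["phq_pandemic"]
        if not isinstance(pan, (list, tuple)) or not 1 <= len(pan) <= 3:
            raise CohortValidationError(
                f"subject {sid}: phq_pandemic must hold 1-3 scores, got {pan!r}"
            )
        for v in pan:
            _check_phq_total(v, sid, "phq_pandemic")
        if not (isinstance(r["pss14"], (int, np.integer)) and 0 <= r["pss14"] <= 56):
            raise CohortValidationError(
                f"subject {sid}: pss14={r['pss14']!r} outside the PSS-14 range 0-56"
            )
        if r["gender"] not in GENDERS:
            raise CohortValidationError(f"subject {sid}: unknown gender {r['gender']!r}")
        if r["targeting_method"] not in TARGETING_METHODS:
            raise CohortValidationError(
                f"subject {sid}: unknown targeting_method {r['targeting_method']!r}"
            )
        for t in r["completed_targets"]:
            if t not in TARGETS:
                raise CohortValidationError(
                    f"subject {sid}: unknown completed target {t!r}"
                )
        if has_subscales:
            p2, g2 = r["phq2_pandemic"], r["gad2_pandemic"]
            if len(p2) != len(pan) or len(g2) != len(pan):
                raise CohortValidationError(
                    f"subject {sid}: subscale timepoint counts differ from phq_pandemic"
                )
            for a, b, tot in zip(p2, g2, pan):
                _check_subscale(a, sid, "phq2_pandemic")
                _check_subscale(b, sid, "gad2_pandemic")
                if a + b != tot:
                    raise CohortValidationError(
                        f"subject {sid}: phq2+gad2 = {a + b} != total {tot}"
                    )
        if has_subscales and {"phq2_pre", "gad2_pre"} <= set(df.columns):
            _check_subscale(r["phq2_pre"], sid, "phq2_pre")
            _check_subscale(r["gad2_pre"], sid, "gad2_pre")
            if r["phq2_pre"] + r["gad2_pre"] != r["phq_pre"]:
                raise CohortValidationError(
                    f"subject {sid}: pre-pandemic phq2+gad2 != phq_pre"
                )


def _join(values) -> str:
    return ";".join(str(v) for v in values)


def _split_ints(cell: str) -> list[int]:
    if cell == "" or pd.isna(cell):
        return []
    return [int(x) for x in str(cell).split(";")]


def write_cohort(table: CohortTable, path: str | os.PathLike, *, overwrite: bool = False) -> None:
    path = os.fspath(path)
    if os.path.exists(path) and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    df = table.df.copy()
    for col in ("phq_pandemic", "phq2_pandemic", "gad2_pandemic", "completed_targets"):
        if col in df.columns:
            df[col] = df[col].map(_join)
    df.to_csv(path, index=False)


def read_cohort(path: str | os.PathLike) -> CohortTable:
    """Read a cohort CSV; unknown columns are preserved but ignored."""
    df = pd.read_csv(os.fspath(path), dtype={"subject_id": str}, keep_default_na=False)
    for col in ("phq_pandemic", "phq2_pandemic", "gad2_pandemic"):
        if col in df.columns:
            df[col] = df[col].map(_split_ints)
    if "completed_targets" in df.columns:
        df["completed_targets"] = df["completed_targets"].map(
            lambda c: [t for t in str(c).split(";") if t]
        )
    for col in ("phq_pre", "pss14", "phq2_pre", "gad2_pre"):
        if col in df.columns:
            df[col] = df[col].astype(int)
    return CohortTable(df)
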