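"""Region atlas, cohort table and time-series I/O.

Every node-level quantity in the pipeline is indexed by the AAL-90
parcellation: the 90 cerebral regions of the Anatomical Automatic
Labeling template, 45 per hemisphere, odd 1-based indices left and even
right.  The atlas metadata (index, abbreviation such as ``TPOmid.L``,
full anatomical name, hemisphere, lobe) ships as a package data file and
fixes the node order of every matrix and vector the package produces.

A reduced synthetic atlas of arbitrary size is available for fast
experimentation; it follows the same odd/even hemisphere convention.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import numpy as np
import pandas as pd

VALID_LOBES = frozenset(
    {"frontal", "parietal", "occipital", "temporal", "insula", "limbic", "subcortex"}
)
SCORE_NAMES = ("MMSE", "MoCA", "MES", "CDR", "BNT", "UPSIT")

#: Valid (inclusive) ranges used for validation and synthetic-score clipping.
SCORE_RANGES: dict[str, tuple[float, float]] = {
    "MMSE": (0.0, 30.0),
    "MoCA": (0.0, 30.0),
    "MES": (0.0, 100.0),
    "CDR": (0.0, 3.0),
    "BNT": (0.0, 30.0),
    "UPSIT": (0.0, 40.0),
}


class ValidationError(ValueError):
    """Raised when an input file or record violates the data contract."""


class ConfigurationError(ValueError):
    """Raised when configuration or packaged metadata is malformed."""


@dataclass(frozen=True)
class Region:
    index: int  # 1-based atlas index
    abbrev: str  # e.g. "TPOmid.L"
    name: str
    hemisphere: str  # "L" or "R"
    lobe: str


@dataclass(frozen=True)
class RegionAtlas:
    """Ordered region list; node k of every matrix is ``regions[k]``."""

    regions: tuple[Region, ...]

    def __post_init__(self) -> None:
        n = len(self.regions)
        idx = [r.index for r in self.regions]
        if idx != list(range(1, n + 1)):
            raise ConfigurationError("atlas indices must be 1..N in order")
        abbrevs = [r.abbrev for r in self.regions]
        if len(set(abbrevs)) != n:
            raise ConfigurationError("atlas abbreviations must be unique")
        for r in self.regions:
            if r.hemisphere not in ("L", "R"):
                raise ConfigurationError(f"bad hemisphere for {r.abbrev}")
            if (r.index % 2 == 1) != (r.hemisphere == "L"):
                raise ConfigurationError(
                    f"region {r.abbrev}: odd indices must be left-hemisphere"
                )

    def __len__(self) -> int:
        return len(self.regions)

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def abbrevs(self) -> tuple[str, ...]:
        return tuple(r.abbrev for r in self.regions)

    def index_of(self, abbrev: str) -> int:
        """0-based position of an abbreviation (bijective lookup)."""
        try:
            return self.abbrevs.index(abbrev)
        except ValueError:
            raise KeyError(abbrev) from None

    def by_abbrev(self, abbrev: str) -> Region:
        return self.regions[self.index_of(abbrev)]


def load_atlas() -> RegionAtlas:
    """Load the packaged AAL-90 cerebral atlas (90 regions, fixed order)."""
    ref = resources.files("neurograph.data").joinpath("aal90.csv")
    with ref.open("r", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        try:
            regions = tuple(
                Region(
                    index=int(row["index"]),
                    abbrev=row["abbrev"],
                    name=row["name"],
                    hemisphere=row["hemisphere"],
                    lobe=row["lobe"],
                )
                for row in reader
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigurationError(f"malformed atlas metadata: {exc}") from exc
    if len(regions) != 90:
        raise ConfigurationError(f"expected 90 atlas regions, found {len(regions)}")
    bad = {r.lobe for r in regions} - VALID_LOBES
    if bad:
        raise ConfigurationError(f"unknown lobes in atlas metadata: {sorted(bad)}")
    return RegionAtlas(regions)


def synthetic_atlas(n_regions: int) -> RegionAtlas:
    """Reduced atlas of ``n_regions`` synthetic regions (even count).

    Region pairs SYN01.L/SYN01.R, SYN02.L/... with lobes assigned
    round-robin; used by the fast demo / calibration modes.
    """
    if n_regions == 90:
        return load_atlas()
    if n_regions < 2 or n_regions % 2:
        raise ConfigurationError("synthetic atlas size must be a positive even number")
    lobes = sorted(VALID_LOBES)
    regions = []
    for pair in range(n_regions // 2):
        lobe = lobes[pair % len(lobes)]
        for hemi, off in (("L", 1), ("R", 2)):
            regions.append(
                Region(
                    index=2 * pair + off,
                    abbrev=f"SYN{pair + 1:02d}.{hemi}",
                    name=f"Synthetic region {pair + 1}",
                    hemisphere=hemi,
                    lobe=lobe,
                )
            )
    return RegionAtlas(tuple(regions))


@dataclass
class SubjectRecord:
    subject_id: str
    group: str  # "AD" or "NC"
    age: float
    sex: str  # "M" or "F"
    education: float
    scores: dict[str, float] = field(default_factory=dict)  # missing keys = missing

    def __post_init__(self) -> None:
        if self.group not in ("AD", "NC"):
            raise ValidationError(
                f"subject {self.subject_id!r}: unknown group {self.group!r}"
            )
        if self.sex not in ("M", "F"):
            raise ValidationError(f"subject {self.subject_id!r}: sex must be M or F")
        for name, value in self.scores.items():
            lo, hi = SCORE_RANGES.get(name, (-np.inf, np.inf))
            if not np.isfinite(value):
                raise ValidationError(
                    f"subject {self.subject_id!r}: non-finite {name} score"
                )
            if not lo <= value <= hi:
                raise ValidationError(
                    f"subject {self.subject_id!r}: {name}={value} outside [{lo}, {hi}]"
                )


@dataclass
class CohortTable:
    records: list[SubjectRecord]

    def __post_init__(self) -> None:
        ids = [r.subject_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate subject ids: {dupes}")
        if self.n_ad == 0 or self.n_nc == 0:
            raise ValidationError("both AD and NC groups must be non-empty")

    @property
    def n_ad(self) -> int:
        return sum(r.group == "AD" for r in self.records)

    @property
    def n_nc(self) -> int:
        return sum(r.group == "NC" for r in self.records)

    def group(self, label: str) -> list[SubjectRecord]:
        return [r for r in self.records if r.group == label]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "subject_id": r.subject_id,
                "group": r.group,
                "age": r.age,
                "sex": r.sex,
                "education": r.education,
            }
            for s in SCORE_NAMES:
                row[s] = r.scores.get(s, np.nan)
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class TimeSeriesMatrix:
    """One subject's T x N region-by-time signal (rows = time points)."""

    subject_id: str
    data: np.ndarray
    tr_seconds: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError(f"{self.subject_id}: time series must be 2-D")
        if self.data.shape[0] < 3:
            raise ValidationError(f"{self.subject_id}: need at least 3 time points")
        if not np.isfinite(self.data).all():
            raise ValidationError(f"{self.subject_id}: non-finite values in time series")
        if self.tr_seconds <= 0:
            raise ValidationError(f"{self.subject_id}: TR must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]


def read_cohort(path) -> CohortTable:
    """Read a cohort CSV (subject_id, group, age, sex, education, scores).

    Empty score cells are preserved as missing, never coerced to zero.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    required = ["subject_id", "group", "age", "sex", "education"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"cohort file missing columns: {missing}")
    score_cols = [c for c in df.columns if c in SCORE_NAMES]
    records = []
    for pos, row in df.iterrows():
        scores = {}
        for c in score_cols:
            cell = row[c]
            if pd.isna(cell):
                continue
            try:
                scores[c] = float(cell)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"row {pos + 1} (subject {row['subject_id']!r}): "
                    f"non-numeric {c} score {cell!r}"
                ) from None
        try:
            records.append(
                SubjectRecord(
                    subject_id=str(row["subject_id"]),
                    group=str(row["group"]),
                    age=float(row["age"]),
                    sex=str(row["sex"]),
                    education=float(row["education"]),
                    scores=scores,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"row {pos + 1}: {exc}") from None
    return CohortTable(records)


def write_cohort(cohort: CohortTable, path) -> None:
    cohort.to_frame().to_csv(path, index=False, float_format="%.10g")


def read_timeseries(path, atlas: RegionAtlas, *, subject_id: str | None = None,
                    tr_seconds: float = 2.0) -> TimeSeriesMatrix:
    """Read a T x N region time-series table (TSV default, comma accepted).

    An optional header row of atlas abbreviations is validated and, if it
    is a permutation of the atlas order, the columns are reordered to the
    canonical order.
    """
    path = str(path)
    sep = "," if path.endswith(".csv") else r"\s+"
    head = pd.read_csv(path, sep=sep, nrows=1, header=None)
    has_header = head.iloc[0].astype(str).str.fullmatch(r"[-+0-9.eE]+").sum() == 0
    df = pd.read_csv(path, sep=sep, header=0 if has_header else None)
    if df.shape[1] != atlas.n_regions:
        raise ValidationError(
            f"{path}: expected {atlas.n_regions} region columns, found {df.shape[1]}"
        )
    if has_header:
        cols = [str(c) for c in df.columns]
        if sorted(cols) != sorted(atlas.abbrevs):
            raise ValidationError(f"{path}: header does not match atlas abbreviations")
        df = df[list(atlas.abbrevs)]
    values = df.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        bad = np.argwhere(~np.isfinite(values))[0]
        raise ValidationError(f"{path}: non-finite value at row {bad[0]}, col {bad[1]}")
    if subject_id is None:
        import os

        subject_id = os.path.splitext(os.path.basename(path))[0]
    return TimeSeriesMatrix(subject_id=subject_id, data=values, tr_seconds=tr_seconds)


def write_timeseries(ts: TimeSeriesMatrix, path, atlas: RegionAtlas | None = None) -> None:
    """Write a time series as TSV with an abbreviation header (17 sig. digits)."""
    header = "\t".join(atlas.abbrevs) + "\n" if atlas is not None else ""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header)
        np.savetxt(fh, ts.data, fmt="%.17g", delimiter="\t")
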