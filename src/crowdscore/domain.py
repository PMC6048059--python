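"""Shared data types, proportion-bin schemes and CSV interchange.

The whole pipeline speaks two dialects: lightweight dataclasses for
record-level semantics and validation, and pandas DataFrames (one row per
record, same column names as the CSV files) for bulk computation.
Converters between the two live here.

Classification records obey the conditional-questioning rules of the
scoring task: the proportion bin is present iff cancer was indicated, and
the intensity is present iff the proportion bin is greater than zero.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BinScheme",
    "SCHEMES",
    "get_scheme",
    "bin_midpoint",
    "Classification",
    "CoreScore",
    "ExpertScore",
    "CorrectedScore",
    "PatientRecord",
    "AgreementResult",
    "ValidationError",
    "validate_classification",
    "read_classifications",
    "write_classifications",
    "read_classifications_frame",
    "write_classifications_frame",
    "classifications_to_frame",
    "frame_to_classifications",
    "CLASSIFICATION_COLUMNS",
    "PROPORTION_BOUNDS",
    "INTENSITY_BOUNDS",
]

#: Valid range of a (possibly corrected) proportion score, in percent.
PROPORTION_BOUNDS = (0.0, 100.0)
#: Valid range of a (possibly corrected) mean intensity score.
INTENSITY_BOUNDS = (0.0, 3.0)

CLASSIFICATION_COLUMNS = [
    "core_id",
    "segment_index",
    "cancer_present",
    "proportion_bin",
    "intensity",
]


class ValidationError(ValueError):
    """Raised when a record violates a domain invariant."""


@dataclass(frozen=True)
class BinScheme:
    """One of the three proportion-bin category schemes.

    ``bounds`` holds the printed (lower, upper) percentage label of each of
    the six bins; bin 0 is the zero bin ``(0, 0)``.  For censoring a
    continuous value into a bin, bins are treated as the half-open
    partition ``{0}, (0, u1], (u1, u2], ...`` of [0, 100].
    """

    scheme_id: int
    bounds: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.bounds) != 6:
            raise ValueError("a bin scheme has exactly six bins")
        if self.bounds[0] != (0.0, 0.0) and self.bounds[0] != (0, 0):
            raise ValueError("bin 0 must be the zero bin")
        uppers = [b[1] for b in self.bounds]
        if sorted(uppers) != uppers or uppers[-1] != 100:
            raise ValueError("bin upper edges must increase to 100")

    @property
    def n_bins(self) -> int:
        return len(self.bounds)

    @property
    def upper_edges(self) -> np.ndarray:
        """Upper edge of each bin (the partition edges used for censoring)."""
        return np.asarray([b[1] for b in self.bounds], dtype=float)

    @property
    def midpoints(self) -> np.ndarray:
        """Numeric value assigned to each bin: 0 for the zero bin, else the
        arithmetic midpoint of the printed bounds."""
        return np.asarray([(lo + hi) / 2.0 for lo, hi in self.bounds])

    def midpoint(self, bin_index: int) -> float:
        if not 0 <= int(bin_index) <= 5:
            raise ValueError(f"bin index out of range: {bin_index}")
        return float(self.midpoints[int(bin_index)])

    def censor(self, values) -> np.ndarray:
        """Map continuous proportions in [0, 100] to bin indices 0-5.

        Exactly 0 falls in the zero bin; a positive value v falls in the
        bin whose half-open interval (lower, upper] contains it.
        """
        v = np.asarray(values, dtype=float)
        if np.any((v < 0) | (v > 100)):
            raise ValueError("proportion values must lie in [0, 100]")
        bins = 1 + np.searchsorted(self.upper_edges[1:], v, side="left")
        bins = np.where(v == 0, 0, bins)
        return bins.astype(int) if bins.ndim else int(bins)


SCHEMES: dict[int, BinScheme] = {
    1: BinScheme(1, ((0, 0), (1, 25), (25, 50), (50, 75), (75, 95), (95, 100))),
    2: BinScheme(2, ((0, 0), (1, 10), (10, 25), (25, 50), (50, 75), (75, 100))),
    3: BinScheme(3, ((0, 0), (1, 10), (10, 25), (25, 65), (65, 95), (95, 100))),
}


def get_scheme(scheme: int | BinScheme) -> BinScheme:
    """Resolve a scheme id (1, 2 or 3) or pass a BinScheme through."""
    if isinstance(scheme, BinScheme):
        return scheme
    try:
        return SCHEMES[int(scheme)]
    except (KeyError, TypeError, ValueError):
        raise ValueError(f"unknown bin scheme: {scheme!r}") from None


def bin_midpoint(bin_index: int, scheme: int | BinScheme) -> float:
    """Numeric value of a proportion bin: 0 for bin 0, else the midpoint
    of the printed bin bounds (e.g. bin 1 of scheme 1, labelled 1-25%,
    maps to 13)."""
    return get_scheme(scheme).midpoint(bin_index)


@dataclass(frozen=True)
class Classification:
    """A single citizen response to one core segment."""

    core_id: str
    segment_index: int
    cancer_present: bool
    proportion_bin: int | None = None
    intensity: int | None = None

    def __post_init__(self) -> None:
        validate_classification(self)


def validate_classification(c: "Classification") -> None:
    """Enforce the conditional-questioning invariants.

    Raises :class:`ValidationError` on any violation.
    """
    if not 0 <= int(c.segment_index) <= 35:
        raise ValidationError(f"segment_index out of range: {c.segment_index}")
    if c.cancer_present:
        if c.proportion_bin is None:
            raise ValidationError("proportion_bin required when cancer_present")
        if not 0 <= int(c.proportion_bin) <= 5:
            raise ValidationError(f"proportion_bin out of range: {c.proportion_bin}")
        if int(c.proportion_bin) == 0:
            if c.intensity is not None:
                raise ValidationError(
                    "intensity must be absent when proportion_bin is 0"
                )
        else:
            if c.intensity is None:
                raise ValidationError(
                    "intensity required when proportion_bin > 0"
                )
            if not 1 <= int(c.intensity) <= 3:
                raise ValidationError(f"intensity out of range: {c.intensity}")
    else:
        if c.proportion_bin is not None:
            raise ValidationError("proportion_bin must be absent without cancer")
        if c.intensity is not None:
            raise ValidationError("intensity must be absent without cancer")


@dataclass
class CoreScore:
    """Aggregated numeric score for one core."""

    core_id: str
    marker_id: str
    proportion: float
    intensity: float
    n_responses: int
    n_cancer_responses: int
    n_intensity_responses: int
    all_no_cancer: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.proportion <= 100:
            raise ValidationError(f"proportion out of bounds: {self.proportion}")
        if not 0 <= self.intensity <= 3:
            raise ValidationError(f"intensity out of bounds: {self.intensity}")
        if not (
            self.n_intensity_responses
            <= self.n_cancer_responses
            <= self.n_responses
        ):
            raise ValidationError("response counts must be nested")


@dataclass
class ExpertScore:
    """Gold-standard per-core score."""

    core_id: str
    marker_id: str
    proportion: float
    intensity: float

    def __post_init__(self) -> None:
        if not 0 <= self.proportion <= 100:
            raise ValidationError(f"proportion out of bounds: {self.proportion}")
        if not 0 <= self.intensity <= 3:
            raise ValidationError(f"intensity out of bounds: {self.intensity}")


@dataclass
class CorrectedScore:
    """Bias-corrected per-core score with the derived H-score."""

    core_id: str
    marker_id: str
    proportion_corrected: float
    intensity_corrected: float
    h_score: float
    clipped_proportion: bool = False
    clipped_intensity: bool = False
    was_cv: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.h_score <= 300:
            raise ValidationError(f"h_score out of bounds: {self.h_score}")


COHORTS = ("cystectomy", "rt_1995_1999", "rt_2002_2005")


@dataclass
class PatientRecord:
    """One patient outcome row."""

    patient_id: str
    cohort: str
    time_months: float
    event: bool
    age: float
    t_stage: int
    n_stage: int
    grade: int
    sex: str
    hydronephrosis: bool

    def __post_init__(self) -> None:
        if self.time_months <= 0:
            raise ValidationError("survival time must be positive")
        if self.cohort not in COHORTS:
            raise ValidationError(f"unknown cohort: {self.cohort}")


@dataclass
class AgreementResult:
    """An agreement statistic with a percentile-bootstrap CI."""

    metric: str
    estimate: float
    ci_low: float
    ci_high: float
    n_pairs: int
    n_bootstrap: int

    def __post_init__(self) -> None:
        if not -1 - 1e-12 <= self.estimate <= 1 + 1e-12:
            raise ValidationError(f"estimate out of [-1, 1]: {self.estimate}")
        if not self.ci_low - 1e-12 <= self.estimate <= self.ci_high + 1e-12:
            raise ValidationError("estimate outside its own CI")


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

_TRUE = {"true", "1", "t", "yes"}
_FALSE = {"false", "0", "f", "no"}


def _parse_bool(text: str, row_no: int) -> bool:
    t = text.strip().lower()
    if t in _TRUE:
        return True
    if t in _FALSE:
        return False
    raise ValidationError(f"row {row_no}: cannot parse boolean {text!r}")


def _parse_optional_int(text: str) -> int | None:
    t = text.strip()
    return None if t == "" else int(t)


def read_classifications(path) -> list[Classification]:
    """Read classifications.csv into validated records.

    Invalid rows are rejected with their (1-based, header-inclusive) row
    numbers collected into a single :class:`ValidationError`.
    """
    records: list[Classification] = []
    problems: list[str] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != CLASSIFICATION_COLUMNS:
            raise ValidationError(
                f"malformed classification CSV header: {header!r}"
            )
        for row_no, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            if len(row) != 5:
                problems.append(f"row {row_no}: expected 5 fields, got {len(row)}")
                continue
            try:
                rec = Classification(
                    core_id=row[0].strip(),
                    segment_index=int(row[1]),
                    cancer_present=_parse_bool(row[2], row_no),
                    proportion_bin=_parse_optional_int(row[3]),
                    intensity=_parse_optional_int(row[4]),
                )
            except (ValidationError, ValueError) as exc:
                problems.append(f"row {row_no}: {exc}")
                continue
            records.append(rec)
    if problems:
        raise ValidationError(
            "invalid classification rows:\n  " + "\n  ".join(problems)
        )
    return records


def write_classifications(records: Iterable[Classification], path) -> None:
    """Write records to CSV (header, UTF-8, empty field for absent values)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CLASSIFICATION_COLUMNS)
        for c in records:
            writer.writerow(
                [
                    c.core_id,
                    c.segment_index,
                    "true" if c.cancer_present else "false",
                    "" if c.proportion_bin is None else int(c.proportion_bin),
                    "" if c.intensity is None else int(c.intensity),
                ]
            )


def classifications_to_frame(records: Sequence[Classification]) -> pd.DataFrame:
    """Convert records to the canonical DataFrame layout."""
    return pd.DataFrame(
        {
            "core_id": [c.core_id for c in records],
            "segment_index": np.array(
                [c.segment_index for c in records], dtype=int
            ),
            "cancer_present": np.array(
                [c.cancer_present for c in records], dtype=bool
            ),
            "proportion_bin": pd.array(
                [c.proportion_bin for c in records], dtype="Int64"
            ),
            "intensity": pd.array(
                [c.intensity for c in records], dtype="Int64"
            ),
        }
    )


def frame_to_classifications(frame: pd.DataFrame) -> list[Classification]:
    """Convert a classification DataFrame back to validated records."""
    out = []
    for row in frame.itertuples(index=False):
        out.append(
            Classification(
                core_id=str(row.core_id),
                segment_index=int(row.segment_index),
                cancer_present=bool(row.cancer_present),
                proportion_bin=(
                    None if pd.isna(row.proportion_bin) else int(row.proportion_bin)
                ),
                intensity=None if pd.isna(row.intensity) else int(row.intensity),
            )
        )
    return out


def validate_frame(frame: pd.DataFrame) -> None:
    """Validate every row of a classification DataFrame (vectorised)."""
    seg_bad = (frame["segment_index"] < 0) | (frame["segment_index"] > 35)
    cancer = frame["cancer_present"].astype(bool)
    has_bin = frame["proportion_bin"].notna()
    has_int = frame["intensity"].notna()
    bin_vals = frame["proportion_bin"].fillna(0).astype(int)
    int_vals = frame["intensity"].fillna(1).astype(int)
    bad = (
        seg_bad
        | (cancer & ~has_bin)
        | (~cancer & (has_bin | has_int))
        | (cancer & has_bin & (bin_vals < 0))
        | (cancer & has_bin & (bin_vals > 5))
        | (cancer & has_bin & (bin_vals == 0) & has_int)
        | (cancer & has_bin & (bin_vals > 0) & ~has_int)
        | (has_int & ((int_vals < 1) | (int_vals > 3)))
    )
    if bad.any():
        rows = list(frame.index[bad][:20])
        raise ValidationError(f"invalid classification rows at index {rows}")


def read_classifications_frame(path) -> pd.DataFrame:
    """Read classifications.csv straight into the DataFrame layout."""
    frame = pd.read_csv(
        path,
        dtype={"core_id": str},
        converters={"cancer_present": lambda s: s.strip().lower() in _TRUE},
    )
    frame["proportion_bin"] = pd.array(frame["proportion_bin"], dtype="Int64")
    frame["intensity"] = pd.array(frame["intensity"], dtype="Int64")
    validate_frame(frame)
    return frame


def write_classifications_frame(frame: pd.DataFrame, path) -> None:
    out = frame.copy()
    out["cancer_present"] = np.where(
        out["cancer_present"].astype(bool), "true", "false"
    )
    out.to_csv(path, index=False)
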