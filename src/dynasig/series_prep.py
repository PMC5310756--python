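"""Series containers, table I/O, and the standardize/difference pipeline.

Every analysis in this package operates on annual scalar time series that
have been (1) optionally trimmed to a year range, (2) standardized to zero
mean and unit sample standard deviation, and (3) first-differenced.
Standardization puts series of very different magnitudes (landings in
tonnes, larvae per square metre, model biomass) on a common scale;
differencing removes first-order autocorrelation and trend so that forecast
skill reflects dynamics rather than persistence.

The transform order is fixed: trim, then standardize, then difference.
The differenced output is deliberately *not* re-standardized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateSeriesError,
    FormatError,
    GapError,
    LengthError,
    ProvenanceError,
)

#: Recognised series categories: two observed-data classes, two
#: model-output classes, and three synthetic stand-in classes.
CATEGORIES = frozenset(
    {
        "landings",
        "survey",
        "assessment",
        "atlantis",
        "synthetic_nonlinear",
        "synthetic_linear",
        "synthetic_smoothed",
    }
)

#: Minimum post-trim raw length accepted by :func:`prepare`.  Shorter
#: series cannot support embedding-dimension selection up to the default
#: maximum with leave-one-out cross-validation.
MIN_USABLE_LENGTH = 10

CSV_COLUMNS = ("series_id", "category", "year", "value")


@dataclass(frozen=True)
class RawSeries:
    """An annual scalar time series with identity and category."""

    id: str
    category: str
    years: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=np.int64)
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "values", values)
        if self.category not in CATEGORIES:
            raise FormatError(
                f"unknown category {self.category!r}; expected one of "
                f"{sorted(CATEGORIES)}"
            )
        if years.ndim != 1 or values.ndim != 1 or len(years) != len(values):
            raise FormatError("years and values must be 1-d and equally long")
        if len(years) < 1:
            raise LengthError("a series needs at least one observation")
        steps = np.diff(years)
        if np.any(steps <= 0):
            raise FormatError(f"series {self.id!r}: years must strictly increase")
        if np.any(steps != 1):
            raise GapError(
                f"series {self.id!r}: gap in years (steps {sorted(set(steps))}); "
                "interpolation is not performed"
            )

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class PreparedSeries:
    """A standardized, first-differenced series ready for embedding.

    ``values`` holds the differenced series (one observation shorter than
    the standardized input).  ``provenance`` records the transforms applied:
    trim bounds, the standardization mean and sd, and the transform chain.
    """

    id: str
    category: str
    values: np.ndarray
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=np.float64)
        )

    @property
    def n(self) -> int:
        return len(self.values)

    def __len__(self) -> int:
        return len(self.values)


def standardize(values: Sequence[float]) -> np.ndarray:
    """Center and scale to unit *sample* (n-1) standard deviation.

    Raises
    ------
    LengthError
        If fewer than two observations are supplied.
    DegenerateSeriesError
        If the series is constant (zero variance).
    """
    x = np.asarray(values, dtype=np.float64)
    if len(x) < 2:
        raise LengthError("standardize needs at least two observations")
    sd = float(np.std(x, ddof=1))
    if sd == 0.0 or not np.isfinite(sd):
        raise DegenerateSeriesError("constant series cannot be standardized")
    return (x - float(np.mean(x))) / sd


def first_difference(values: Sequence[float]) -> np.ndarray:
    """Return ``x[t+1] - x[t]``; output is one element shorter."""
    x = np.asarray(values, dtype=np.float64)
    if len(x) < 2:
        raise LengthError("first_difference needs at least two observations")
    return np.diff(x)


def _resolve_trim(trim) -> tuple[int | None, int | None]:
    if trim is None:
        return (None, None)
    if isinstance(trim, (int, np.integer)):
        return (int(trim), None)
    start, end = trim
    return (None if start is None else int(start), None if end is None else int(end))


def prepare(
    raw: RawSeries,
    trim=None,
    min_length: int = MIN_USABLE_LENGTH,
) -> PreparedSeries:
    """Trim, standardize, and first-difference a raw series.

    Parameters
    ----------
    raw
        The input series.  Passing an already-prepared series raises
        :class:`~dynasig.errors.ProvenanceError`: re-standardizing a
        differenced series is not the same transform and the pipeline
        forbids it.
    trim
        ``None`` (keep all years), a single start year, or a
        ``(start_year, end_year)`` pair (inclusive; either side ``None``).
        Trimming to a fully developed period is a per-series judgment and
        is therefore configuration, not inference.
    min_length
        Minimum acceptable post-trim raw length.
    """
    if isinstance(raw, PreparedSeries):
        raise ProvenanceError(
            "prepare() takes a RawSeries; preparing twice is forbidden"
        )
    start, end = _resolve_trim(trim)
    mask = np.ones(len(raw), dtype=bool)
    if start is not None:
        mask &= raw.years >= start
    if end is not None:
        mask &= raw.years <= end
    years = raw.years[mask]
    values = raw.values[mask]
    if len(values) < max(min_length, 2):
        raise LengthError(
            f"series {raw.id!r}: {len(values)} observations after trimming; "
            f"need at least {min_length}"
        )
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1))
    std = standardize(values)
    diffed = first_difference(std)
    provenance = {
        "trim": (start, end),
        "first_year": int(years[0]),
        "last_year": int(years[-1]),
        "mean": mean,
        "sd": sd,
        "transforms": ("trim", "standardize", "first_difference"),
    }
    return PreparedSeries(
        id=raw.id, category=raw.category, values=diffed, provenance=provenance
    )


def trim_standardize(
    raw: RawSeries,
    trim=None,
    min_length: int = MIN_USABLE_LENGTH,
) -> np.ndarray:
    """The pre-differencing stage of :func:`prepare`.

    Exposed separately because the observation-noise experiment injects
    noise on the standardized scale *before* differencing.
    """
    if isinstance(raw, PreparedSeries):
        raise ProvenanceError("trim_standardize() takes a RawSeries")
    start, end = _resolve_trim(trim)
    mask = np.ones(len(raw), dtype=bool)
    if start is not None:
        mask &= raw.years >= start
    if end is not None:
        mask &= raw.years <= end
    values = raw.values[mask]
    if len(values) < max(min_length, 2):
        raise LengthError(
            f"series {raw.id!r}: {len(values)} observations after trimming; "
            f"need at least {min_length}"
        )
    return standardize(values)


def read_series_table(path) -> list[RawSeries]:
    """Read a long-format CSV (``series_id,category,year,value``).

    Rows are sorted by year within each series.  Duplicate
    ``(series_id, year)`` pairs, non-numeric values, unknown categories,
    inconsistent per-series categories, and gaps in years are all errors;
    nothing is silently repaired.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"missing columns: {sorted(missing)}")
    try:
        df["year"] = df["year"].astype(np.int64)
        df["value"] = pd.to_numeric(df["value"], errors="raise").astype(np.float64)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"non-numeric year or value: {exc}") from exc
    if df.duplicated(subset=["series_id", "year"]).any():
        dup = df[df.duplicated(subset=["series_id", "year"], keep=False)]
        raise FormatError(
            "duplicate (series_id, year) rows: "
            + ", ".join(
                f"{r.series_id}/{r.year}" for r in dup.head(5).itertuples()
            )
        )
    out: list[RawSeries] = []
    for sid, grp in df.groupby("series_id", sort=True):
        grp = grp.sort_values("year")
        cats = grp["category"].unique()
        if len(cats) != 1:
            raise FormatError(
                f"series {sid!r} has multiple categories: {list(cats)}"
            )
        out.append(
            RawSeries(
                id=str(sid),
                category=str(cats[0]),
                years=grp["year"].to_numpy(),
                values=grp["value"].to_numpy(),
            )
        )
    return out


def write_series_table(series: Iterable[RawSeries], path) -> None:
    """Write series to long-format CSV, full float precision."""
    frames = [
        pd.DataFrame(
            {
                "series_id": s.id,
                "category": s.category,
                "year": s.years,
                "value": s.values,
            }
        )
        for s in series
    ]
    if not frames:
        df = pd.DataFrame(columns=CSV_COLUMNS)
    else:
        df = pd.concat(frames, ignore_index=True)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)  # default float repr round-trips exactly
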