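"""Monitoring-table I/O and the negation convention.

Reference conditions are low quantiles of concentration *minima*, while
threshold-exceedance machinery is formulated for maxima.  The standard
device is to sign-flip ("negate") every series before modelling and flip
fitted quantiles back at the end.  This module holds the in-memory
containers for monthly monitoring series, the CSV reader, the negation
helpers, and JSON report I/O.

Input CSV dialect: UTF-8, header ``site,date,variable,value``; dates are
``YYYY-MM`` or ``YYYY-MM-DD`` (day of month is ignored; series are stored
at month resolution).
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConvergenceError, EmptyDatasetError, FormatError

logger = logging.getLogger(__name__)

ORIGINAL = "original"
NEGATED = "negated"

REQUIRED_COLUMNS = ("site", "date", "variable", "value")


@dataclass(eq=False)
class ObservationSeries:
    """One site's time-ordered monthly values for one variable.

    Parameters
    ----------
    site_id : str
    variable : str
        Free-form variable name, e.g. ``"TN"``.
    months : pandas.PeriodIndex
        Monthly periods, strictly increasing.  Gaps are allowed; they
        split the series into separate Markov segments (a transition term
        is only formed between consecutive months).
    values : ndarray of float
        Concentrations.  On the original scale values must be finite and
        >= 0 (zeros are retained as ordinary observations; there is no
        detection-limit handling).
    scale : {"original", "negated"}
    """

    site_id: str
    variable: str
    months: pd.PeriodIndex
    values: np.ndarray
    scale: str = ORIGINAL

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not isinstance(self.months, pd.PeriodIndex):
            self.months = pd.PeriodIndex(self.months, freq="M")
        if self.months.freqstr not in ("M", "ME"):
            self.months = self.months.asfreq("M")
        if len(self.values) != len(self.months):
            raise FormatError(
                f"site {self.site_id!r}: {len(self.values)} values for "
                f"{len(self.months)} months"
            )
        if len(self.values) < 2:
            raise FormatError(
                f"site {self.site_id!r}: series has fewer than 2 observations"
            )
        diffs = np.diff(self.months.asi8)
        if np.any(diffs <= 0):
            raise FormatError(
                f"site {self.site_id!r}: months not strictly increasing "
                "(duplicate or unordered dates)"
            )
        if not np.all(np.isfinite(self.values)):
            raise FormatError(f"site {self.site_id!r}: non-finite values")
        if self.scale == ORIGINAL and np.any(self.values < 0):
            raise FormatError(
                f"site {self.site_id!r}: negative concentrations on the "
                "original scale"
            )
        if self.scale not in (ORIGINAL, NEGATED):
            raise ValueError(f"unknown scale {self.scale!r}")

    @property
    def n(self) -> int:
        return len(self.values)

    def negate(self) -> "ObservationSeries":
        """Sign-flip the values; negation is an involution."""
        out = ObservationSeries.__new__(ObservationSeries)
        out.site_id = self.site_id
        out.variable = self.variable
        out.months = self.months
        out.values = -self.values
        out.scale = NEGATED if self.scale == ORIGINAL else ORIGINAL
        return out

    def segments(self) -> list[np.ndarray]:
        """Contiguous monthly runs of values (gap-split Markov segments)."""
        diffs = np.diff(self.months.asi8)
        cut = np.flatnonzero(diffs > 1) + 1
        return np.split(self.values, cut)

    def __eq__(self, other):
        if not isinstance(other, ObservationSeries):
            return NotImplemented
        return (
            self.site_id == other.site_id
            and self.variable == other.variable
            and self.scale == other.scale
            and self.months.equals(other.months)
            and np.array_equal(self.values, other.values)
        )


@dataclass(eq=False)
class Dataset:
    """All sites' series for one variable.

    Series at different sites are treated as independent Markov chains
    (observations of different sites at the same time are independent).
    """

    variable: str
    series: list[ObservationSeries]

    def __post_init__(self):
        if not self.series:
            raise EmptyDatasetError(f"no series for variable {self.variable!r}")
        for s in self.series:
            if s.variable != self.variable:
                raise FormatError(
                    f"series variable {s.variable!r} != dataset {self.variable!r}"
                )
        ids = [s.site_id for s in self.series]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate site_ids in dataset")
        scales = {s.scale for s in self.series}
        if len(scales) != 1:
            raise FormatError("mixed scales in dataset")

    @property
    def scale(self) -> str:
        return self.series[0].scale

    @property
    def site_ids(self) -> list[str]:
        return [s.site_id for s in self.series]

    @property
    def n_obs(self) -> int:
        return sum(s.n for s in self.series)

    def __len__(self) -> int:
        return len(self.series)

    def __iter__(self):
        return iter(self.series)

    def __getitem__(self, i) -> ObservationSeries:
        return self.series[i]

    def get(self, site_id: str) -> ObservationSeries:
        for s in self.series:
            if s.site_id == site_id:
                return s
        raise KeyError(site_id)

    def negate(self) -> "Dataset":
        return Dataset(self.variable, [s.negate() for s in self.series])

    def all_values(self) -> np.ndarray:
        return np.concatenate([s.values for s in self.series])

    def all_segments(self) -> list[np.ndarray]:
        """Gap-split segments pooled over sites, each an independent chain."""
        out: list[np.ndarray] = []
        for s in self.series:
            out.extend(s.segments())
        return out

    def to_frame(self) -> pd.DataFrame:
        frames = [
            pd.DataFrame(
                {
                    "site": s.site_id,
                    "date": s.months.astype(str),
                    "variable": s.variable,
                    "value": s.values,
                }
            )
            for s in self.series
        ]
        return pd.concat(frames, ignore_index=True)

    def __eq__(self, other):
        if not isinstance(other, Dataset):
            return NotImplemented
        return self.variable == other.variable and self.series == other.series


def negate(ds: Dataset) -> Dataset:
    """Sign-flip every value in the dataset (module-level alias)."""
    return ds.negate()


def read_observations(path, variable: str) -> Dataset:
    """Read a long-format monitoring CSV and return one variable's Dataset.

    Rows for other variables are ignored.  Row order is irrelevant: any
    permutation of the input yields the same Dataset.

    Raises
    ------
    FormatError
        Missing required column, non-numeric value (row numbers listed),
        unparseable date, duplicate site-month, negative concentration,
        or a site series shorter than 2 observations.
    EmptyDatasetError
        No rows for the requested variable.
    """
    path = Path(path)
    df = pd.read_csv(
        path, dtype={"site": str, "variable": str}, float_precision="round_trip"
    )
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing required column(s) {missing}")

    sub = df[df["variable"] == variable]
    if sub.empty:
        raise EmptyDatasetError(f"{path.name}: no rows for variable {variable!r}")

    values = pd.to_numeric(sub["value"], errors="coerce")
    bad = sub.index[values.isna() & sub["value"].notna()] + 2  # header + 1-based
    bad = sorted(set(bad) | set(sub.index[sub["value"].isna()] + 2))
    if bad:
        raise FormatError(f"{path.name}: non-numeric value at line(s) {bad}")

    dates = pd.to_datetime(sub["date"], errors="coerce", format="mixed")
    badd = list(sub.index[dates.isna()] + 2)
    if badd:
        raise FormatError(f"{path.name}: unparseable date at line(s) {badd}")

    tidy = pd.DataFrame(
        {
            "site": sub["site"].astype(str),
            "month": dates.dt.to_period("M"),
            "value": values.astype(float),
        }
    ).sort_values(["site", "month"], kind="mergesort")

    series = []
    for site_id, grp in tidy.groupby("site", sort=True):
        if grp["month"].duplicated().any():
            dup = grp.loc[grp["month"].duplicated(), "month"].iloc[0]
            raise FormatError(
                f"{path.name}: duplicate observation for site {site_id!r} "
                f"month {dup}"
            )
        series.append(
            ObservationSeries(
                site_id=str(site_id),
                variable=variable,
                months=pd.PeriodIndex(grp["month"]),
                values=grp["value"].to_numpy(),
            )
        )
    logger.info(
        "read %d rows for variable %r from %s (%d sites)",
        len(tidy),
        variable,
        path.name,
        len(series),
    )
    return Dataset(variable, series)


def write_observations(ds: Dataset, path) -> None:
    """Write a Dataset in the same CSV dialect ``read_observations`` reads."""
    ds.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# fitted-model reports


def write_report(fit, quantile, path, extra: dict | None = None) -> None:
    """Serialize a converged fit plus its quantile estimate to JSON.

    ``fit`` is a ``MarkovPOTResults`` (or anything exposing ``to_dict`` and
    ``converged``); ``quantile`` is a ``QuantileEstimate`` or None.  The
    report is round-trippable through :func:`read_report` (byte-identical
    modulo the ``created`` timestamp).
    """
    if not getattr(fit, "converged", False):
        raise ConvergenceError("refusing to write a report for an unconverged fit")
    report = {"fit": fit.to_dict()}
    if quantile is not None:
        report["quantile"] = dataclasses.asdict(quantile)
    if extra:
        report.update(extra)
    report["created"] = datetime.datetime.now(datetime.timezone.utc).isoformat()
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def read_report(path) -> dict:
    try:
        return json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"malformed report {path}: {exc}") from exc
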