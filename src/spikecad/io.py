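"""Loading, validation and binning of multivariate spike-time data.

A recording is a set of units, each carrying a sorted list of spike times in
seconds over a common recording span.  All downstream statistics operate on
equal-width bin counts derived from these times; binning uses half-open bins
``[left, right)`` and drops a trailing partial bin so that every unit shares
the same series length ``T``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SpikeDataset",
    "CountSeries",
    "read_spike_dataset",
    "bin_dataset",
    "subtract_floor",
]


@dataclass
class SpikeDataset:
    """Multivariate spike-time data over a common recording span.

    Parameters
    ----------
    units : dict
        Mapping of unit identifier to a sorted 1-D array of spike times
        (seconds).
    span : tuple of float
        ``(t_start, t_end)`` common to all units.
    """

    units: dict[Hashable, np.ndarray]
    span: tuple[float, float]

    def __post_init__(self) -> None:
        t0, t1 = self.span
        if not t1 > t0:
            raise ValueError(f"empty recording span {self.span}")
        clean: dict[Hashable, np.ndarray] = {}
        for uid, times in self.units.items():
            arr = np.asarray(times, dtype=float)
            if arr.ndim != 1:
                raise ValueError(f"unit {uid!r}: spike times must be 1-D")
            if arr.size and (arr.min() < t0 or arr.max() > t1):
                raise ValueError(f"unit {uid!r}: spike times outside span {self.span}")
            if not np.all(np.diff(arr) >= 0):
                arr = np.sort(arr)
            clean[uid] = arr
        self.units = clean

    @property
    def unit_ids(self) -> list[Hashable]:
        return list(self.units.keys())

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def duration(self) -> float:
        return self.span[1] - self.span[0]

    def n_spikes(self, unit_id: Hashable | None = None) -> int:
        if unit_id is not None:
            return int(self.units[unit_id].size)
        return int(sum(v.size for v in self.units.values()))

    def mean_rates(self) -> dict[Hashable, float]:
        """Per-unit mean firing rate in Hz."""
        dur = self.duration
        return {uid: times.size / dur for uid, times in self.units.items()}

    def exclude_low_rate(self, min_rate: float = 0.2) -> "SpikeDataset":
        """Drop units firing below ``min_rate`` Hz (preprocessing option)."""
        keep = {u: t for u, t in self.units.items()
                if t.size / self.duration >= min_rate}
        return SpikeDataset(units=keep, span=self.span)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns ``unit_id``, ``time_s``."""
        rows = [(uid, t) for uid, times in self.units.items() for t in times]
        return pd.DataFrame(rows, columns=["unit_id", "time_s"])


@dataclass
class CountSeries:
    """Spike counts of one unit at a fixed bin width.

    ``counts[t]`` is the number of spikes in bin ``t`` (0-based here,
    half-open bins of width ``bin_width``).  ``max_count`` is the largest
    count observed, the number of binary layers the series decomposes into.
    """

    unit_id: Hashable
    bin_width: float
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1:
            raise ValueError("counts must be a 1-D sequence")
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("negative spike count")

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)

    @property
    def max_count(self) -> int:
        return int(self.counts.max(initial=0))


def read_spike_dataset(
    path: str | Path,
    format: str | None = None,
    span: tuple[float, float] | None = None,
) -> SpikeDataset:
    """Read a two-column (unit_id, time_s) spike table.

    The delimiter is inferred from the file extension (``.tsv`` -> tab,
    otherwise comma) unless ``format`` is given as ``"csv"`` or ``"tsv"``.
    An optional header row is detected and skipped.  Duplicate identical rows
    are retained as two spikes (a warning is logged).  The span defaults to
    ``[0, last spike time]``.
    """
    path = Path(path)
    if format is None:
        format = "tsv" if path.suffix.lower() in (".tsv", ".tab") else "csv"
    if format not in ("csv", "tsv"):
        raise ValueError(f"unknown format {format!r}")
    sep = "\t" if format == "tsv" else ","

    try:
        df = pd.read_csv(path, sep=sep, header=None, comment="#",
                         names=["unit_id", "time_s"], skip_blank_lines=True,
                         dtype={"unit_id": str})
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty spike table") from None
    if df.empty:
        raise ValueError(f"{path}: empty spike table")

    # tolerate a single header row such as "unit_id,time_s"
    first = df.iloc[0]["time_s"]
    try:
        float(first)
    except (TypeError, ValueError):
        df = df.iloc[1:].reset_index(drop=True)
        if df.empty:
            raise ValueError(f"{path}: no spike rows after header")

    times = pd.to_numeric(df["time_s"], errors="coerce")
    if times.isna().any():
        line = int(times.index[times.isna()][0]) + 1
        raise ValueError(f"{path}: non-numeric spike time at data row {line}")
    df["time_s"] = times.astype(float)

    if df.duplicated().any():
        ndup = int(df.duplicated().sum())
        logger.warning("%s: %d duplicate (unit, time) rows retained as extra spikes",
                       path, ndup)

    units = {uid: np.sort(g["time_s"].to_numpy())
             for uid, g in df.groupby("unit_id", sort=True)}
    if span is None:
        span = (0.0, float(df["time_s"].max()))
        if span[1] <= span[0]:
            span = (0.0, span[1] + 1.0)  # degenerate single-instant file
    return SpikeDataset(units=units, span=span)


def bin_dataset(dataset: SpikeDataset, delta: float) -> list[CountSeries]:
    """Bin every unit at width ``delta`` (seconds).

    Bin ``i`` covers ``[t_start + i*delta, t_start + (i+1)*delta)``; the
    trailing partial bin is dropped so all units share
    ``T = floor(span/delta)`` bins.
    """
    if delta <= 0:
        raise ValueError(f"bin width must be positive, got {delta}")
    t0, t1 = dataset.span
    T = int(np.floor((t1 - t0) / delta + 1e-9))
    if T < 1:
        raise ValueError(f"bin width {delta} exceeds recording span")
    out = []
    for uid, times in dataset.units.items():
        idx = np.floor((times - t0) / delta).astype(np.int64)
        idx = idx[(idx >= 0) & (idx < T)]
        counts = np.bincount(idx, minlength=T)
        out.append(CountSeries(unit_id=uid, bin_width=delta, counts=counts))
    return out


def subtract_floor(series: CountSeries) -> CountSeries:
    """Remove the non-informative floor count: subtract the series minimum.

    At coarse bin widths counts may never fall below some baseline; those
    baseline spikes carry no information about coupled dynamics, so they are
    removed before statistical testing.  A no-op when the minimum is zero.
    Idempotent.
    """
    m = int(series.counts.min()) if series.counts.size else 0
    if m == 0:
        return series
    return CountSeries(unit_id=series.unit_id, bin_width=series.bin_width,
                       counts=series.counts - m)


def dataset_from_frame(df: pd.DataFrame,
                       span: tuple[float, float] | None = None) -> SpikeDataset:
    """Build a :class:`SpikeDataset` from a long-format table.

    Accepts columns named ``unit_id``/``time_s`` (or the first two columns).
    """
    cols = list(df.columns)
    ucol = "unit_id" if "unit_id" in cols else cols[0]
    tcol = "time_s" if "time_s" in cols else cols[1]
    units = {uid: np.sort(g[tcol].to_numpy(dtype=float))
             for uid, g in df.groupby(ucol, sort=True)}
    if span is None:
        tmax = float(df[tcol].max()) if len(df) else 1.0
        span = (0.0, tmax if tmax > 0 else 1.0)
    return SpikeDataset(units=units, span=span)


def write_spike_dataset(dataset: SpikeDataset, path: str | Path) -> None:
    """Write the dataset as a two-column CSV (unit_id, time_s)."""
    dataset.to_frame().to_csv(path, index=False)
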