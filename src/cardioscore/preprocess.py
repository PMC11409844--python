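"""RR-interval series cleaning and per-performance normalization.

The wearable ECG sensor emits a beat-to-beat (RR) interval series per
musician and performance.  Before modeling, ectopic (premature) beats
are removed with a running-median filter — a premature beat shows up as
an interval far shorter than its neighbourhood, followed by a
compensatory pause — and the surviving normal-beat series is normalized
per performance so that musicians with different baseline heart rates
become comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

#: Default running-median window (number of surrounding beats).
DEFAULT_ECTOPIC_WINDOW = 5
#: Default relative deviation from the running median that flags a beat.
DEFAULT_ECTOPIC_THRESHOLD = 0.2


@dataclass
class RRSeries:
    """Beat-to-beat intervals for one musician in one performance.

    ``times`` are R-peak wall-clock times in seconds; ``rr_ms`` is the
    interval starting at that R-peak, in milliseconds.
    """

    performance_id: int
    musician_id: str
    times: np.ndarray
    rr_ms: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.rr_ms = np.asarray(self.rr_ms, dtype=float)
        if self.times.shape != self.rr_ms.shape or self.times.ndim != 1:
            raise ValueError("times and rr_ms must be 1-D arrays of equal length")
        if self.times.size == 0:
            raise ValueError("empty RR series")
        if np.any(self.rr_ms <= 0):
            raise ValueError("RR intervals must be positive")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("R-peak times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    def check_continuity(self, rel_tol: float = 0.05) -> bool:
        """True when successive R-peak gaps agree with the intervals.

        Holds for raw device output; intentionally *not* enforced after
        cleaning, which drops beats while preserving timestamps.
        """
        gaps_ms = np.diff(self.times) * 1000.0
        return bool(np.all(np.abs(gaps_ms - self.rr_ms[:-1]) <= rel_tol * self.rr_ms[:-1]))


@dataclass
class RemovalReport:
    """Audit record of beats removed by the ectopic filter."""

    removed_indices: np.ndarray
    removed_times: np.ndarray
    removed_rr_ms: np.ndarray
    window: int
    rel_threshold: float

    @property
    def n_removed(self) -> int:
        return int(self.removed_indices.size)


@dataclass
class NormalizedSignal:
    """A normalized vector plus the affine parameters that produced it."""

    values: np.ndarray
    method: str
    params: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def _running_median_neighbors(rr: np.ndarray, window: int) -> np.ndarray:
    """Median of up to ``window`` beats surrounding (excluding) each beat."""
    n = rr.size
    half = max(1, window // 2)
    med = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        neighbors = np.concatenate([rr[lo:i], rr[i + 1 : hi]])
        med[i] = np.median(neighbors)
    return med


def remove_ectopic(
    series: RRSeries,
    rel_threshold: float = DEFAULT_ECTOPIC_THRESHOLD,
    window: int = DEFAULT_ECTOPIC_WINDOW,
) -> tuple[RRSeries, RemovalReport]:
    """Drop beats deviating from the local running median.

    A beat is removed when its interval differs from the median of the
    surrounding ``window`` beats by more than ``rel_threshold`` of that
    median.  Medians are computed on the *original* series in a single
    pass; removed beats are dropped (not interpolated) and the remaining
    timestamps are untouched — the later score-time resampling bridges
    the gaps.
    """
    if not 0.0 < rel_threshold < 1.0:
        raise ValueError("rel_threshold must lie in (0, 1)")
    if len(series) < window + 1:
        raise ValueError(f"need at least {window + 1} beats for window={window}")
    med = _running_median_neighbors(series.rr_ms, window)
    bad = np.abs(series.rr_ms - med) > rel_threshold * med
    report = RemovalReport(
        removed_indices=np.flatnonzero(bad),
        removed_times=series.times[bad],
        removed_rr_ms=series.rr_ms[bad],
        window=window,
        rel_threshold=rel_threshold,
    )
    cleaned = RRSeries(
        performance_id=series.performance_id,
        musician_id=series.musician_id,
        times=series.times[~bad],
        rr_ms=series.rr_ms[~bad],
    )
    return cleaned, report


def normalize(values: np.ndarray, method: str = "minmax") -> NormalizedSignal:
    """Normalize a vector to [0, 1] (``minmax``) or to mean 0 / SD 1 (``zscore``).

    Degenerate input (zero range or zero SD) raises rather than silently
    returning zeros; a flat RR series indicates an upstream problem.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise ValueError("need a 1-D vector with at least two values")
    if method == "minmax":
        lo, hi = float(values.min()), float(values.max())
        if hi - lo <= 0:
            raise ValueError("degenerate input: zero range for min-max normalization")
        return NormalizedSignal((values - lo) / (hi - lo), "minmax", {"min": lo, "max": hi})
    if method == "zscore":
        mean = float(values.mean())
        sd = float(values.std(ddof=1))
        if sd <= 0:
            raise ValueError("degenerate input: zero SD for z-score normalization")
        return NormalizedSignal((values - mean) / sd, "zscore", {"mean": mean, "sd": sd})
    raise ValueError(f"unknown normalization method {method!r}")


def read_rr_csv(path: str | Path) -> list[RRSeries]:
    """Read RR series from a CSV with columns performance_id, musician, t_s, rr_ms."""
    frame = pd.read_csv(path)
    required = {"performance_id", "musician", "t_s", "rr_ms"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"RR CSV {path} missing columns: {sorted(missing)}")
    out = []
    for (perf, musician), sub in frame.groupby(["performance_id", "musician"], sort=True):
        sub = sub.sort_values("t_s")
        out.append(
            RRSeries(
                performance_id=int(perf),
                musician_id=str(musician),
                times=sub["t_s"].to_numpy(),
                rr_ms=sub["rr_ms"].to_numpy(),
            )
        )
    return out


def write_rr_csv(
    path: str | Path,
    series: list[RRSeries],
    reports: dict[tuple[int, str], RemovalReport] | None = None,
) -> None:
    """Write RR series in the ingest schema plus a ``removed`` audit flag."""
    rows: list[dict[str, Any]] = []
    for s in series:
        removed_times: set[float] = set()
        if reports is not None:
            rep = reports.get((s.performance_id, s.musician_id))
            if rep is not None:
                removed_times = set(np.round(rep.removed_times, 9))
        for t, rr in zip(s.times, s.rr_ms):
            rows.append(
                {
                    "performance_id": s.performance_id,
                    "musician": s.musician_id,
                    "t_s": t,
                    "rr_ms": rr,
                    "removed": int(round(t, 9) in removed_times),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
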