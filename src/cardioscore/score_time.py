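"""Score-time lattice and wall-clock <-> score-time mapping.

Performances of the same piece differ in duration, so signals measured
in seconds (RR intervals, loudness) are re-expressed on a common
*score-time* axis: the half-beat (eighth-note) lattice of the piece.
For the Schubert trio movement studied here the lattice has L = 848
half-beat samples in 2/4 meter, i.e. 4 half-beats per bar and 212 bars.

A :class:`BeatTimeMap` gives, for one performance, the wall-clock time
of every half-beat (manually annotated beat onsets).  Continuous-time
signals are moved onto the lattice by linear interpolation at those
beat times.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .signals import FeatureSignal

#: Half-beats per bar in 2/4 meter with an eighth-note pulse.
DEFAULT_BEATS_PER_BAR = 4

#: Half-beat lattice length of the Schubert movement (212 bars x 4).
SCHUBERT_N_SAMPLES = 848


@dataclass(frozen=True)
class ScoreTimeGrid:
    """The piece's half-beat lattice, 1-indexed samples ``1..n_samples``."""

    n_samples: int
    beats_per_bar: int = DEFAULT_BEATS_PER_BAR

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("grid must have at least one sample")
        if self.beats_per_bar <= 0:
            raise ValueError("beats_per_bar must be positive")
        if self.n_samples % self.beats_per_bar != 0:
            raise ValueError(
                f"n_samples={self.n_samples} is not a whole number of bars "
                f"({self.beats_per_bar} half-beats per bar)"
            )

    @property
    def n_bars(self) -> int:
        return self.n_samples // self.beats_per_bar

    @property
    def sample_indices(self) -> np.ndarray:
        """1-indexed half-beat positions ``1..L``."""
        return np.arange(1, self.n_samples + 1)


@dataclass
class BeatTimeMap:
    """Wall-clock time (seconds) of each half-beat for one performance."""

    performance_id: int
    beat_times: np.ndarray

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        if self.beat_times.ndim != 1 or self.beat_times.size < 2:
            raise ValueError("beat_times must be a 1-D array with >= 2 entries")
        if np.any(self.beat_times < 0):
            raise ValueError("beat times must be nonnegative")
        if np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat times must be strictly increasing")

    def __len__(self) -> int:
        return self.beat_times.size


def bar_to_beat(bar: int, grid: ScoreTimeGrid) -> int:
    """Half-beat index of bar ``bar``.

    The convention ``beat = bar * beats_per_bar`` reproduces the piece's
    printed (bar, half-beat) landmarks, e.g. bar 67 -> half-beat 268.
    Equivalently, bar ``n`` occupies half-beats ``(n-1)*b + 1 .. n*b``.
    """
    if not 1 <= bar <= grid.n_bars:
        raise ValueError(f"bar {bar} outside 1..{grid.n_bars}")
    return bar * grid.beats_per_bar


def bar_span_to_samples(start_bar: int, end_bar: int, grid: ScoreTimeGrid) -> tuple[int, int]:
    """Inclusive 1-indexed half-beat range covered by bars ``start..end``."""
    if start_bar > end_bar:
        raise ValueError("start_bar must not exceed end_bar")
    if not (1 <= start_bar and end_bar <= grid.n_bars):
        raise ValueError(f"bars {start_bar}-{end_bar} outside 1..{grid.n_bars}")
    first = (start_bar - 1) * grid.beats_per_bar + 1
    last = end_bar * grid.beats_per_bar
    return first, last


def resample_to_score_time(
    times: np.ndarray,
    values: np.ndarray,
    beat_map: BeatTimeMap,
    name: str = "signal",
    units: str = "unitless",
) -> FeatureSignal:
    """Linearly interpolate a wall-clock signal at the annotated beat times.

    Beat times outside the sampled span take the nearest endpoint value
    (clamped, not extrapolated), so sparse coverage at the edges cannot
    produce wild values.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.ndim != 1 or times.shape != values.shape:
        raise ValueError("times and values must be 1-D arrays of equal length")
    if times.size < 2:
        raise ValueError("need at least two samples to resample")
    if np.any(np.diff(times) < 0):
        raise ValueError("sample times must be monotone non-decreasing")
    out = np.interp(beat_map.beat_times, times, values)
    return FeatureSignal(
        name,
        out,
        units,
        meta={
            "performance_id": beat_map.performance_id,
            "n_input_samples": int(times.size),
            "resampled": True,
        },
    )


def read_beat_instants(path: str | Path) -> np.ndarray:
    """Read a beat-onset annotation file (Sonic Visualiser "instants" export).

    One onset time in seconds per line; an optional trailing label column
    (comma-, tab- or space-separated) is ignored.
    """
    times: list[float] = []
    with open(path, newline="") as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            for sep in (",", "\t"):
                line = line.replace(sep, " ")
            times.append(float(line.split()[0]))
    if not times:
        raise ValueError(f"no beat instants found in {path}")
    return np.asarray(times, dtype=float)


def write_beat_instants(path: str | Path, beat_times: np.ndarray) -> None:
    """Write beat onsets in the same one-time-per-line dialect."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        for t in np.asarray(beat_times, dtype=float):
            writer.writerow([f"{t:.6f}"])
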