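"""Music-feature predictors: tempo, loudness and note density.

Tempo is derived from the annotated beat times; loudness from the
ensemble audio through an RMS -> dB -> sone-like mapping (a deliberately
simple stand-in for a full psychoacoustic loudness model — the
statistical layer normalizes the signal, so only its shape matters) and
low-pass smoothed with a zero-phase Butterworth filter; note density is
counted from each musician's part in the score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .score_time import BeatTimeMap, ScoreTimeGrid, resample_to_score_time
from .signals import FeatureSignal

#: Butterworth defaults for loudness smoothing (fraction of Nyquist).
LOUDNESS_FILTER_ORDER = 3
LOUDNESS_FILTER_WN = 0.125

#: Note-density window, in half-beats (one bar in 2/4 meter).
DEFAULT_DENSITY_WINDOW = 4.0


@dataclass
class ScoreNotes:
    """One musician's part as a note list.

    ``onsets`` are 1-indexed half-beat positions, ``durations`` are in
    half-beats, ``pitches`` are MIDI numbers.
    """

    musician_id: str
    onsets: np.ndarray
    durations: np.ndarray
    pitches: np.ndarray

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.durations = np.asarray(self.durations, dtype=float)
        self.pitches = np.asarray(self.pitches, dtype=float)
        if not (self.onsets.shape == self.durations.shape == self.pitches.shape):
            raise ValueError("onsets, durations, pitches must have equal length")
        if self.onsets.size and np.any(self.durations <= 0):
            raise ValueError("note durations must be positive")

    def __len__(self) -> int:
        return self.onsets.size


def tempo_from_beats(beat_map: BeatTimeMap, pulse: str = "quarter") -> FeatureSignal:
    """Per-sample tempo in BPM from the half-beat annotation times.

    The local inter-half-beat interval is estimated by central
    differences (one-sided at the endpoints).  With ``pulse="quarter"``
    the tempo of the notated quarter-note pulse is reported,
    ``60 / (2 * dt_eighth)``; ``pulse="eighth"`` reports the raw
    half-beat rate.
    """
    t = beat_map.beat_times
    dt = np.empty_like(t)
    dt[1:-1] = (t[2:] - t[:-2]) / 2.0
    dt[0] = t[1] - t[0]
    dt[-1] = t[-1] - t[-2]
    if pulse == "quarter":
        bpm = 60.0 / (2.0 * dt)
    elif pulse == "eighth":
        bpm = 60.0 / dt
    else:
        raise ValueError(f"unknown pulse {pulse!r}")
    return FeatureSignal(
        "tempo", bpm, "BPM", {"performance_id": beat_map.performance_id, "pulse": pulse}
    )


def loudness_from_audio(
    waveform: np.ndarray,
    sample_rate: float,
    beat_map: BeatTimeMap,
    frame_s: float = 0.05,
    hop_s: float = 0.025,
    level_offset_db: float = 100.0,
) -> FeatureSignal:
    """Sone-like loudness from a mono waveform, resampled to score time.

    Frame RMS energy is converted to a dB level (``20*log10(rms) +
    level_offset_db``) and then to a sone-like scale ``2**((level-40)/10)``,
    so a perceived doubling corresponds to ~10 dB.  The result is flagged
    ``approximate`` in metadata: it is an energy-based surrogate, not a
    Bark-band psychoacoustic model.
    """
    waveform = np.asarray(waveform, dtype=float)
    if waveform.ndim == 2:  # downmix
        waveform = waveform.mean(axis=1)
    if waveform.ndim != 1 or waveform.size == 0:
        raise ValueError("waveform must be a non-empty 1-D (or stereo 2-D) array")
    if not np.any(waveform != 0):
        raise ValueError("silent audio: all samples are zero")
    frame_n = max(1, int(round(frame_s * sample_rate)))
    hop_n = max(1, int(round(hop_s * sample_rate)))
    starts = np.arange(0, max(1, waveform.size - frame_n + 1), hop_n)
    rms = np.array(
        [np.sqrt(np.mean(waveform[s : s + frame_n] ** 2)) for s in starts]
    )
    rms = np.maximum(rms, 1e-10)
    level_db = 20.0 * np.log10(rms) + level_offset_db
    sones = 2.0 ** ((level_db - 40.0) / 10.0)
    frame_times = (starts + frame_n / 2.0) / sample_rate
    if frame_times.size < 2:
        raise ValueError("audio too short for the chosen frame/hop sizes")
    out = resample_to_score_time(frame_times, sones, beat_map, "loudness", "sone-like")
    out.meta.update(
        approximate=True,
        frame_s=frame_s,
        hop_s=hop_s,
        level_offset_db=level_offset_db,
    )
    return out


def loudness_from_samples(
    times: np.ndarray, values: np.ndarray, beat_map: BeatTimeMap
) -> FeatureSignal:
    """Precomputed-loudness path: resample externally computed loudness
    samples (e.g. from a dedicated psychoacoustic tool) to the grid."""
    out = resample_to_score_time(times, values, beat_map, "loudness", "sone-like")
    out.meta["precomputed"] = True
    return out


def smooth_loudness(
    signal: FeatureSignal | np.ndarray,
    order: int = LOUDNESS_FILTER_ORDER,
    wn: float = LOUDNESS_FILTER_WN,
) -> FeatureSignal | np.ndarray:
    """Zero-phase low-pass Butterworth smoothing (DC gain exactly 1).

    ``wn`` is a fraction of the Nyquist rate of the half-beat grid.
    Forward-backward application avoids introducing lag between the
    loudness predictor and the RR response; the effective attenuation is
    the squared magnitude response.
    """
    values = signal.values if isinstance(signal, FeatureSignal) else np.asarray(signal, float)
    padlen = 3 * (order + 1)
    if values.size <= padlen:
        raise ValueError(f"signal too short for zero-phase filtering (need > {padlen})")
    b, a = sps.butter(order, wn, btype="low")
    smoothed = sps.filtfilt(b, a, values)
    if isinstance(signal, FeatureSignal):
        return signal.with_values(smoothed, filter={"order": order, "wn": wn, "zero_phase": True})
    return smoothed


def note_density(
    notes: ScoreNotes,
    grid: ScoreTimeGrid,
    window_beats: float = DEFAULT_DENSITY_WINDOW,
) -> FeatureSignal:
    """Note onsets per half-beat in a centered window around each sample.

    The window is the half-open interval ``[i - w/2, i + w/2)`` clipped
    to the grid; the count is divided by the clipped window length, so a
    uniformly dense part keeps constant density at the edges.
    """
    if window_beats <= 0:
        raise ValueError("window_beats must be positive")
    L = grid.n_samples
    if len(notes) == 0:
        warnings.warn(f"empty note list for {notes.musician_id}; density is all zero")
        return FeatureSignal("note_density", np.zeros(L), "notes_per_halfbeat",
                             {"musician_id": notes.musician_id, "window_beats": window_beats})
    if np.any(notes.onsets < 1) or np.any(notes.onsets > L):
        raise ValueError("note onsets outside the score-time grid")
    onsets = np.sort(notes.onsets)
    idx = np.arange(1, L + 1, dtype=float)
    lo = np.maximum(1.0, idx - window_beats / 2.0)
    hi = np.minimum(L + 1.0, idx + window_beats / 2.0)
    counts = np.searchsorted(onsets, hi, side="left") - np.searchsorted(onsets, lo, side="left")
    dens = counts / (hi - lo)
    return FeatureSignal(
        "note_density",
        dens,
        "notes_per_halfbeat",
        {"musician_id": notes.musician_id, "window_beats": window_beats},
    )


def read_notes_csv(path: str | Path) -> dict[str, ScoreNotes]:
    """Read score note lists: columns musician, onset_beat, duration_beats, midi_pitch."""
    frame = pd.read_csv(path)
    required = {"musician", "onset_beat", "duration_beats", "midi_pitch"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"notes CSV {path} missing columns: {sorted(missing)}")
    out = {}
    for musician, sub in frame.groupby("musician", sort=True):
        out[str(musician)] = ScoreNotes(
            musician_id=str(musician),
            onsets=sub["onset_beat"].to_numpy(),
            durations=sub["duration_beats"].to_numpy(),
            pitches=sub["midi_pitch"].to_numpy(),
        )
    return out


def write_notes_csv(path: str | Path, notes: dict[str, ScoreNotes]) -> None:
    rows = []
    for musician, part in sorted(notes.items()):
        for o, d, p in zip(part.onsets, part.durations, part.pitches):
            rows.append({"musician": musician, "onset_beat": o,
                         "duration_beats": d, "midi_pitch": p})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_feature_samples(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a precomputed-feature CSV with columns ``t_s, value``."""
    frame = pd.read_csv(path)
    if not {"t_s", "value"} <= set(frame.columns):
        raise ValueError(f"feature CSV {path} must have columns t_s, value")
    frame = frame.sort_values("t_s")
    return frame["t_s"].to_numpy(), frame["value"].to_numpy()
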