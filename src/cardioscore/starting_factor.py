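"""Starting factor: the role-dependent power-law onset response.

At the start of playing, RR intervals drop sharply — an initial
sympathetic activation unrelated to any specific musical feature.  This
is modeled as a piecewise power law over the first 80 half-beat samples
(20 bars):

    f(t) = t ** (b1 * m(t) + b2 * a(t))   for t in 1..t_end,
    f(t) = 0                              for t > t_end,

where m(t) / a(t) indicate whether the musician plays melody /
(significant) accompaniment at score-time t, and b1, b2 are exponents
fitted to the opening melody player's and the accompanist's first
``t_end`` score-time RR values.  A musician who is silent during the
opening (m = a = 0) gets a rectangular factor, t**0 = 1.

The power law starts at t = 1: t = 0 would diverge for negative
exponents, so the lattice's first sample anchors the curve at 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .interpretation_map import InterpretationMap, term_binary
from .score_time import ScoreTimeGrid
from .signals import FeatureSignal

#: Default exponents: opening-melody role (cello) and accompaniment role
#: (piano), means of per-performance power-law fits.
B_MELODY_DEFAULT = -0.2364
B_ACCOMP_DEFAULT = -0.0871

#: Score-time extent of the onset response (80 half-beats = 20 bars),
#: tailored to this piece's calm opening.
T_END_DEFAULT = 80


@dataclass
class StartingFactorParams:
    """Exponents, extent and role indicators for one musician."""

    b_melody: float = B_MELODY_DEFAULT
    b_accomp: float = B_ACCOMP_DEFAULT
    t_end: int = T_END_DEFAULT
    melody_indicator: np.ndarray | None = None
    accomp_indicator: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.b_melody) or not np.isfinite(self.b_accomp):
            raise ValueError("exponents must be finite")
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")
        for name in ("melody_indicator", "accomp_indicator"):
            ind = getattr(self, name)
            if ind is not None:
                ind = np.asarray(ind, dtype=float)
                if not np.all(np.isin(ind, (0.0, 1.0))):
                    raise ValueError(f"{name} must be binary")
                setattr(self, name, ind)


def roles_from_map(
    imap: InterpretationMap, grid: ScoreTimeGrid, t_end: int = T_END_DEFAULT
) -> tuple[np.ndarray, np.ndarray]:
    """Role indicators m(t), a(t) over the opening, from the musician's map.

    Melody pools melodic interest/interaction; accompaniment pools plain
    and significant accompaniment.  Both are zeroed beyond ``t_end``.
    """
    m = term_binary(imap, "melody", grid)
    a = np.maximum(
        term_binary(imap, "accompaniment", grid),
        term_binary(imap, "significant_accompaniment", grid),
    )
    m[t_end:] = 0.0
    a[t_end:] = 0.0
    return m, a


def build_starting_factor(
    params: StartingFactorParams, grid: ScoreTimeGrid
) -> FeatureSignal:
    """Evaluate the piecewise power law on the grid.

    Indicators default to all-zero (the silent-opening case), giving the
    rectangular factor 1 on samples 1..t_end and 0 after.
    """
    L = grid.n_samples
    if params.t_end > L:
        raise ValueError("t_end exceeds grid length")
    t = np.arange(1, L + 1, dtype=float)
    m = params.melody_indicator
    a = params.accomp_indicator
    m = np.zeros(L) if m is None else np.resize(np.asarray(m, float), L)
    a = np.zeros(L) if a is None else np.resize(np.asarray(a, float), L)
    exponent = params.b_melody * m + params.b_accomp * a
    values = np.where(t <= params.t_end, t**exponent, 0.0)
    return FeatureSignal(
        "starting_factor",
        values,
        "unitless",
        {"b_melody": params.b_melody, "b_accomp": params.b_accomp, "t_end": params.t_end},
    )


def _fit_single_exponent(values: np.ndarray, scale: str) -> float:
    t = np.arange(1, values.size + 1, dtype=float)
    if scale == "raw":
        res = least_squares(
            lambda b: t ** b[0] - values, x0=[0.0], xtol=1e-14, ftol=1e-14, gtol=1e-14
        )
        return float(res.x[0])
    if scale == "loglog":
        # t^b is linear in log-log: log y = b log t (no intercept).
        logt = np.log(t)
        return float(np.dot(logt, np.log(values)) / np.dot(logt, logt))
    raise ValueError(f"unknown fitting scale {scale!r}")


def fit_exponent(
    rr_scoretime: list[np.ndarray] | np.ndarray,
    t_end: int = T_END_DEFAULT,
    scale: str = "raw",
) -> tuple[float, list[float]]:
    """Least-squares fit of ``t**b`` to each performance's opening RR values.

    Parameters
    ----------
    rr_scoretime:
        One positive length->=``t_end`` vector per performance (values
        beyond ``t_end`` are ignored).  Normalized RR in score time.
    scale:
        ``"raw"`` (default): nonlinear least squares on the raw scale,
        robust to near-zero values under the log map.  ``"loglog"``:
        closed-form regression of log y on log t.

    Returns
    -------
    (mean exponent over performances, per-performance exponents).
    """
    if isinstance(rr_scoretime, np.ndarray) and rr_scoretime.ndim == 1:
        rr_scoretime = [rr_scoretime]
    if t_end < 10:
        raise ValueError("need t_end >= 10 samples for a stable exponent fit")
    exponents: list[float] = []
    for series in rr_scoretime:
        series = np.asarray(series, dtype=float)[:t_end]
        if series.size < t_end:
            raise ValueError(f"series shorter than t_end={t_end}")
        if np.any(series <= 0):
            raise ValueError("power-law fit requires positive values")
        exponents.append(_fit_single_exponent(series, scale))
    return float(np.mean(exponents)), exponents
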