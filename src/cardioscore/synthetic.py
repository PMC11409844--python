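"""Synthetic trio-performance generator for end-to-end testing.

No public recordings of the study setting exist, so this module
fabricates the full fixture tree — score note lists, Interpretation
Maps, per-performance beat times and loudness curves, and RR interval
series — with the statistical structure the analysis assumes: the
normalized score-time response is exactly

    y = X beta + u_performance + eps,

with X built *by the real pipeline modules* from the generated
fixtures, per-performance random intercepts u ~ N(0, sigma_u^2) and iid
Gaussian noise.  The response is then mapped back to a
millisecond-scale beat-to-beat series on the jittered beat times, so
the measured-data path (ectopic cleaning, score-time resampling,
normalization) is exercised end to end.  Defaults emulate the study
conditions: 9 performances of an 848-half-beat piece played by a
violinist, cellist and pianist, with the reference Model-Set-3
coefficient columns as ground truth and noise calibrated so the fixed
effects explain about half of the response variance.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from . import pipeline as pl
from . import preprocess as prep
from .features import ScoreNotes, write_notes_csv
from .interpretation_map import (
    Annotation,
    InterpretationMap,
    MODEL_TERM_CATEGORIES,
    write_annotations_csv,
)
from .lme import INTERCEPT, ModelSpec, StackedDesign, fit_lmm
from .score_time import BeatTimeMap, ScoreTimeGrid, write_beat_instants

ROLES = ("violinist", "cellist", "pianist")

#: Ground-truth Model-Set-3 coefficient columns (normalized-RR scale).
#: Terms eliminated as non-significant in the reference fits carry 0.0.
TRUE_BETA: dict[str, dict[str, float]] = {
    "violinist": {
        INTERCEPT: 0.653, "loudness": -0.495, "tempo": -0.214,
        "note_density": -0.004, "melody": -0.093, "dialogue": -0.083,
        "significant_accompaniment": -0.052, "accompaniment": 0.0,
        "climax": -0.330, "moment_of_concern": 0.166, "starting_factor": 0.300,
    },
    "cellist": {
        INTERCEPT: 0.868, "loudness": -0.246, "tempo": -0.143,
        "note_density": -0.008, "melody": -0.195, "dialogue": -0.138,
        "significant_accompaniment": -0.030, "accompaniment": 0.0,
        "climax": -0.712, "moment_of_concern": -0.506, "starting_factor": -0.156,
    },
    "pianist": {
        INTERCEPT: 0.511, "loudness": -0.431, "tempo": 0.094,
        "note_density": -0.0004, "melody": -0.038, "dialogue": -0.228,
        "significant_accompaniment": -0.027, "accompaniment": -0.093,
        "climax": -0.495, "moment_of_concern": -0.151, "starting_factor": 0.327,
    },
}

OPENING_BARS = 20  # calm opening: cello melody over piano accompaniment


@dataclass(kw_only=True)
class SyntheticConfig:
    """Generator settings; defaults are the emulated study conditions."""

    seed: int
    n_bars: int = 212
    beats_per_bar: int = 4
    n_performances: int = 9
    musicians: tuple[str, ...] = ROLES
    true_beta: dict[str, dict[str, float]] = field(
        default_factory=lambda: copy.deepcopy(TRUE_BETA)
    )
    random_intercept_sd: float = 0.02
    #: None -> calibrated per musician to the SD of the fixed-effect
    #: signal, putting the fixed effects at ~50% of response variance.
    noise_sd: float | None = None
    b_melody: float = -0.2364
    b_accomp: float = -0.0871
    t_end: int = 80
    base_bpm: float = 88.0  # quarter-note pulse
    tempo_sd: float = 0.04
    jitter_sd: float = 0.01
    rr_base_ms: float = 700.0
    rr_span_ms: float = 200.0
    n_ectopic: int = 0
    ar1_noise: float = 0.0  # beyond the model's own assumptions; stress tests only

    def __post_init__(self) -> None:
        if self.n_bars < 30:
            raise ValueError("need at least 30 bars for the section structure")
        if self.random_intercept_sd < 0 or (self.noise_sd is not None and self.noise_sd < 0):
            raise ValueError("SDs must be nonnegative")
        for musician in self.musicians:
            if musician not in self.true_beta:
                raise ValueError(f"no true beta for musician {musician!r}")

    @property
    def grid(self) -> ScoreTimeGrid:
        return ScoreTimeGrid(self.n_bars * self.beats_per_bar, self.beats_per_bar)

    def design_params(self) -> pl.DesignParams:
        return pl.DesignParams(
            b_melody=self.b_melody, b_accomp=self.b_accomp, t_end=self.t_end
        )


@dataclass
class SyntheticFixtures:
    """Score, maps, beat times and loudness for one simulated rehearsal set."""

    config: SyntheticConfig
    grid: ScoreTimeGrid
    maps: dict[str, InterpretationMap]
    notes: dict[str, ScoreNotes]
    beat_maps: dict[int, BeatTimeMap]
    loudness: dict[int, tuple[np.ndarray, np.ndarray]]
    section_bounds: list[tuple[int, int]]
    climax_sections: list[int]


def _smooth_unit_noise(rng: np.random.Generator, n: int, sigma: float) -> np.ndarray:
    """Gaussian-filtered white noise rescaled to unit SD."""
    x = gaussian_filter1d(rng.normal(0.0, 1.0, n), sigma, mode="nearest")
    sd = x.std()
    return x / sd if sd > 0 else x


def _generate_sections(config: SyntheticConfig, rng: np.random.Generator):
    bounds = [(1, OPENING_BARS)]
    start = OPENING_BARS + 1
    while start <= config.n_bars:
        length = int(rng.integers(4, 13))
        end = min(config.n_bars, start + length - 1)
        bounds.append((start, end))
        start = end + 1
    # two climax sections, roughly a third and three quarters in
    targets = [0.30 * config.n_bars, 0.72 * config.n_bars]
    climax = []
    for target in targets:
        centers = [abs((a + b) / 2 - target) for a, b in bounds]
        idx = int(np.argmin(centers))
        if idx == 0:
            idx = 1
        if idx not in climax:
            climax.append(idx)
    return bounds, climax


def _generate_maps(
    config: SyntheticConfig,
    rng: np.random.Generator,
    bounds: list[tuple[int, int]],
    climax_sections: list[int],
) -> dict[str, InterpretationMap]:
    maps = {m: InterpretationMap(m) for m in config.musicians}
    # opening: cello leads the melody, piano accompanies, violin is silent
    role_of = dict(zip(ROLES, config.musicians))
    maps[role_of["cellist"]].annotations.append(Annotation("melody", 1, OPENING_BARS))
    maps[role_of["pianist"]].annotations.append(
        Annotation("accompaniment", 1, OPENING_BARS)
    )
    lead_cycle = list(config.musicians)
    for s, (a, b) in enumerate(bounds[1:], start=1):
        if rng.random() < 0.15 and len(config.musicians) >= 2:
            pair = rng.choice(len(config.musicians), size=2, replace=False)
            for i, m in enumerate(config.musicians):
                if i in pair:
                    maps[m].annotations.append(Annotation("dialogue", a, b))
                elif rng.random() < 0.7:
                    maps[m].annotations.append(Annotation("accompaniment", a, b))
        else:
            lead = lead_cycle[s % len(lead_cycle)]
            for m in config.musicians:
                if m == lead:
                    if rng.random() < 0.9:
                        cat = "melody" if rng.random() < 0.8 else "melodic_interaction"
                        maps[m].annotations.append(Annotation(cat, a, b))
                else:
                    u = rng.random()
                    if u < 0.25:
                        maps[m].annotations.append(
                            Annotation("significant_accompaniment", a, b)
                        )
                    elif u < 0.75:
                        maps[m].annotations.append(Annotation("accompaniment", a, b))
        if s in climax_sections:
            for m in config.musicians:
                maps[m].annotations.append(Annotation("climax", a, b))
    # moments of concern: short risky passages, one or two per musician
    for m in config.musicians:
        for _ in range(int(rng.integers(1, 3))):
            start = int(rng.integers(OPENING_BARS + 2, config.n_bars - 4))
            maps[m].annotations.append(
                Annotation("moment_of_concern", start, start + int(rng.integers(1, 4)))
            )
        if rng.random() < 0.5:
            start = int(rng.integers(OPENING_BARS + 2, config.n_bars - 2))
            maps[m].annotations.append(Annotation("return_repose", start, start + 1))
    # every model term needs at least one span per musician, otherwise the
    # musician's design would carry a constant (all-zero) column
    for m in config.musicians:
        have = {a.category for a in maps[m].annotations}
        for term, cats in MODEL_TERM_CATEGORIES.items():
            if not have & set(cats):
                start = int(rng.integers(OPENING_BARS + 2, config.n_bars - 3))
                maps[m].annotations.append(Annotation(cats[0], start, start + 2))
    _ensure_distinct_terms(config, rng, maps)
    return maps


def _ensure_distinct_terms(
    config: SyntheticConfig, rng: np.random.Generator, maps: dict[str, InterpretationMap]
) -> None:
    """Perturb annotations until the term indicator columns are
    linearly independent (jointly with the intercept).

    On short pieces one category's spans can coincide with another's, or
    with a union of others (e.g. a climax section that exactly tiles a
    melody plus an accompaniment span); the kernel encoding is linear,
    so any such dependence makes the design rank-deficient.  Shifting a
    span boundary by one bar breaks the dependence.
    """
    from .interpretation_map import term_binary

    grid = config.grid
    terms = list(MODEL_TERM_CATEGORIES)
    for m in config.musicians:
        for _ in range(100):
            M = np.column_stack(
                [np.ones(grid.n_samples)]
                + [term_binary(maps[m], t, grid) for t in terms]
            )
            _, s, vt = np.linalg.svd(M, full_matrices=False)
            if s[-1] > 1e-8 * s[0]:
                break
            # perturb the term loading heaviest on the null direction
            null = vt[-1]
            order = np.argsort(-np.abs(null[1:]))
            perturbed = False
            for j in order:
                cats = set(MODEL_TERM_CATEGORIES[terms[j]])
                anns = maps[m].annotations
                for idx, ann in enumerate(anns):
                    if ann.category in cats and ann.start_bar > OPENING_BARS:
                        if ann.end_bar < config.n_bars:
                            anns[idx] = Annotation(
                                ann.category, ann.start_bar, ann.end_bar + 1
                            )
                        else:
                            anns[idx] = Annotation(
                                ann.category, ann.start_bar - 1, ann.end_bar
                            )
                        perturbed = True
                        break
                if perturbed:
                    break
            if not perturbed:
                break


def _bar_activity(imap: InterpretationMap, bar: int) -> str:
    for ann in imap.annotations:
        if ann.start_bar <= bar <= ann.end_bar and ann.category in (
            "melody", "melodic_interaction", "dialogue",
            "significant_accompaniment", "accompaniment",
        ):
            return ann.category
    return "rest"


def _generate_notes(
    config: SyntheticConfig, rng: np.random.Generator, maps: dict[str, InterpretationMap]
) -> dict[str, ScoreNotes]:
    counts = {
        "melody": (2, 5), "melodic_interaction": (2, 5), "dialogue": (2, 4),
        "significant_accompaniment": (2, 5), "accompaniment": (1, 4), "rest": (0, 3),
    }
    notes: dict[str, ScoreNotes] = {}
    for m in config.musicians:
        onsets, durs, pitches = [], [], []
        for bar in range(1, config.n_bars + 1):
            activity = _bar_activity(maps[m], bar)
            if m == config.musicians[0] and bar <= OPENING_BARS:
                continue  # the violin tacets through the opening
            lo, hi = counts[activity]
            if m == config.musicians[-1] and activity == "accompaniment":
                lo, hi = 3, 7  # keyboard chords
            n_notes = int(rng.integers(lo, hi + 1))
            for _ in range(n_notes):
                pos = int(rng.integers(0, config.beats_per_bar))
                onsets.append((bar - 1) * config.beats_per_bar + 1 + pos)
                durs.append(float(rng.choice([0.5, 1.0, 2.0])))
                pitches.append(int(rng.integers(36, 96)))
        notes[m] = ScoreNotes(m, np.array(onsets, float), np.array(durs), np.array(pitches))
    return notes


def _loudness_latent(
    config: SyntheticConfig,
    bounds: list[tuple[int, int]],
    climax_sections: list[int],
    rng: np.random.Generator,
) -> np.ndarray:
    L = config.grid.n_samples
    bpb = config.beats_per_bar
    levels = []
    for s, _ in enumerate(bounds):
        if s in climax_sections:
            levels.append(1.0)
        elif s == 0:
            levels.append(0.3)
        else:
            levels.append(float(rng.choice([0.25, 0.4, 0.55, 0.7, 0.85])))
    latent = np.empty(L)
    for (a, b), lev in zip(bounds, levels):
        latent[(a - 1) * bpb : b * bpb] = lev
    # crescendos: ramp over the four bars before each climax
    for s in climax_sections:
        start = (bounds[s][0] - 1) * bpb
        ramp = min(4 * bpb, start)
        if ramp > 0:
            latent[start - ramp : start] = np.linspace(
                latent[start - ramp], 1.0, ramp, endpoint=False
            )
    return gaussian_filter1d(latent, 3.0, mode="nearest")


def generate_fixtures(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> SyntheticFixtures:
    """Generate score, maps, beat times and loudness for all performances.

    Deterministic given the config seed: the same config yields
    byte-identical fixture files.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    grid = config.grid
    L = grid.n_samples
    bounds, climax_sections = _generate_sections(config, rng)
    maps = _generate_maps(config, rng, bounds, climax_sections)
    notes = _generate_notes(config, rng, maps)
    latent = _loudness_latent(config, bounds, climax_sections, rng)
    eighth_s = 60.0 / (2.0 * config.base_bpm)
    beat_maps: dict[int, BeatTimeMap] = {}
    loudness: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for perf in range(1, config.n_performances + 1):
        scale = float(np.exp(rng.normal(0.0, 0.02)))
        curve = np.exp(config.tempo_sd * _smooth_unit_noise(rng, L, 15.0))
        jitter = np.exp(rng.normal(0.0, config.jitter_sd, L))
        durations = eighth_s * scale * curve * jitter
        times = 0.5 + np.concatenate([[0.0], np.cumsum(durations[:-1])])
        beat_maps[perf] = BeatTimeMap(perf, times)
        gain = float(np.exp(rng.normal(0.0, 0.05)))
        dev = np.exp(0.08 * _smooth_unit_noise(rng, L, 12.0))
        sones = 2.0 + 6.0 * latent * gain * dev
        loudness[perf] = (times.copy(), sones)
    return SyntheticFixtures(
        config, grid, maps, notes, beat_maps, loudness, bounds, climax_sections
    )


def build_design(fixtures: SyntheticFixtures, musician: str) -> StackedDesign:
    """Predictor design for one musician, via the public pipeline API."""
    cfg = fixtures.config
    return pl.build_musician_design(
        fixtures.grid,
        fixtures.beat_maps,
        fixtures.loudness,
        fixtures.notes[musician],
        fixtures.maps[musician],
        cfg.design_params(),
    )


def calibrate_noise_sd(design: StackedDesign, beta: dict[str, float]) -> float:
    """Noise SD equal to the SD of the fixed-effect signal.

    With iid noise of this size the fixed effects account for about half
    of the response variance, the regime of the reference fits.
    """
    xb = design.X() @ _beta_vector(design, beta)
    return float(np.std(xb))


def _beta_vector(design: StackedDesign, beta: dict[str, float]) -> np.ndarray:
    return np.array([beta[INTERCEPT]] + [beta[t] for t in design.terms])


def generate_rr(
    config: SyntheticConfig,
    fixtures: SyntheticFixtures,
    design: StackedDesign,
    musician: str,
    rng: np.random.Generator,
) -> tuple[dict[int, prep.RRSeries], dict]:
    """Simulate RR series whose normalized score-time response is X beta + u + eps.

    The grid-level response is mapped to milliseconds by a fixed affine
    back-map and emitted as a beat-to-beat series: each R-peak advances
    the clock by the local interval read off the wall-clock
    interpolation of the target.  Optional ectopic beats replace an
    interval by half its value and push the remainder onto the next beat
    (premature beat + compensatory pause).
    """
    beta = config.true_beta[musician]
    xb = design.X() @ _beta_vector(design, beta)
    sigma_eps = config.noise_sd if config.noise_sd is not None else float(np.std(xb))
    groups = design.groups()
    series: dict[int, prep.RRSeries] = {}
    truth: dict = {
        "musician": musician,
        "beta": dict(beta),
        "sigma_eps": sigma_eps,
        "sigma_u": config.random_intercept_sd,
        "rr_base_ms": config.rr_base_ms,
        "rr_span_ms": config.rr_span_ms,
        "u": {},
        "ectopic_indices": {},
        "y_grid": {},
    }
    for perf in sorted(fixtures.beat_maps):
        mask = groups == perf
        u_p = float(rng.normal(0.0, config.random_intercept_sd))
        eps = rng.normal(0.0, sigma_eps, int(mask.sum()))
        if config.ar1_noise:
            phi = config.ar1_noise
            for i in range(1, eps.size):
                eps[i] = phi * eps[i - 1] + np.sqrt(1 - phi**2) * eps[i]
        y = xb[mask] + u_p + eps
        rr_target = config.rr_base_ms + config.rr_span_ms * y
        if rr_target.min() < 150.0:
            raise ValueError(
                "back-mapped RR would be implausibly short; adjust rr_base_ms/rr_span_ms"
            )
        bt = fixtures.beat_maps[perf].beat_times
        t = bt[0] - 0.8
        peaks, intervals = [], []
        while t < bt[-1] + 0.8:
            rr = float(np.interp(t, bt, rr_target))
            peaks.append(t)
            intervals.append(rr)
            t += rr / 1000.0
        rr_arr = np.asarray(intervals)
        t0 = peaks[0]
        ect_idx: list[int] = []
        if config.n_ectopic > 0:
            ect_idx = sorted(
                rng.choice(np.arange(3, rr_arr.size - 3), config.n_ectopic, replace=False)
            )
            for j in ect_idx:
                delta = 0.5 * rr_arr[j]
                rr_arr[j] -= delta
                rr_arr[j + 1] += delta
        times = t0 + np.concatenate([[0.0], np.cumsum(rr_arr[:-1])]) / 1000.0
        series[perf] = prep.RRSeries(perf, musician, times, rr_arr)
        truth["u"][perf] = u_p
        truth["ectopic_indices"][perf] = [int(j) for j in ect_idx]
        truth["y_grid"][perf] = y
    return series, truth


def simulate_dataset(
    config: SyntheticConfig,
) -> tuple[SyntheticFixtures, dict[str, dict[int, prep.RRSeries]], dict[str, dict]]:
    """Fixtures plus RR series and truth records for every musician."""
    rng = np.random.default_rng(config.seed)
    fixtures = generate_fixtures(config, rng)
    rr: dict[str, dict[int, prep.RRSeries]] = {}
    truths: dict[str, dict] = {}
    for musician in config.musicians:
        design = build_design(fixtures, musician)
        rr[musician], truths[musician] = generate_rr(config, fixtures, design, musician, rng)
    return fixtures, rr, truths


def write_fixture_tree(
    out_dir: str | Path,
    fixtures: SyntheticFixtures,
    rr: dict[str, dict[int, prep.RRSeries]],
    truths: dict[str, dict],
) -> Path:
    """Write the full fixture tree in the pipeline's ingest formats."""
    out = Path(out_dir)
    for sub in ("beats", "loudness"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    write_notes_csv(out / "notes.csv", fixtures.notes)
    write_annotations_csv(out / "annotations.csv", fixtures.maps)
    for perf, bm in fixtures.beat_maps.items():
        write_beat_instants(out / "beats" / f"beats_p{perf}.csv", bm.beat_times)
        lt, lv = fixtures.loudness[perf]
        pd.DataFrame({"t_s": lt, "value": lv}).to_csv(
            out / "loudness" / f"loudness_p{perf}.csv", index=False
        )
    all_series = [s for per_m in rr.values() for s in per_m.values()]
    prep.write_rr_csv(out / "rr.csv", all_series)
    slim = {
        m: {k: v for k, v in t.items() if k != "y_grid"} for m, t in truths.items()
    }
    (out / "truth.json").write_text(json.dumps(slim, indent=2, default=float))
    return out


# ---------------------------------------------------------------------------
# parameter-recovery experiments


def run_recovery_replicate(
    musician: str,
    config: SyntheticConfig,
    rng: np.random.Generator,
    stepwise: bool = False,
) -> dict:
    """One generate -> pipeline -> fit cycle; coefficient estimates on the
    generator's response scale.

    The pipeline min-max normalizes each performance by its own realized
    range, so fitted coefficients would live on a per-run,
    per-performance scale.  Before fitting, each performance's
    normalized response is converted back to the generator's
    normalized-RR units by inverting the recorded normalization
    parameters and the generator's fixed millisecond back-map — unit
    bookkeeping from run metadata and generator constants, independent
    of the true coefficient values.
    """
    fixtures = generate_fixtures(config, rng)
    design = build_design(fixtures, musician)
    series, truth = generate_rr(config, fixtures, design, musician, rng)
    design, proc_meta = pl.attach_response(
        design, series, fixtures.beat_maps, config.design_params()
    )
    frame = design.frame.copy()
    for perf, meta in proc_meta.items():
        p = meta["norm_params"]
        mask = frame["performance"] == perf
        rr_ms = frame.loc[mask, "rr_norm"] * (p["max"] - p["min"]) + p["min"]
        frame.loc[mask, "rr_norm"] = (rr_ms - config.rr_base_ms) / config.rr_span_ms
    design = StackedDesign(frame, design.terms)
    spec = ModelSpec.for_set(3)
    if stepwise:
        from .lme import backward_stepwise_aic

        spec, fit, _ = backward_stepwise_aic(design, spec)
    else:
        fit = fit_lmm(design, spec)
    estimates = {t: fit.beta[t] for t in spec.fixed_terms}
    estimates[INTERCEPT] = fit.beta[INTERCEPT]
    return {
        "estimates": estimates,
        "fit": fit,
        "design": design,
        "truth": truth,
        "proc_meta": proc_meta,
    }


def recovery_experiment(
    musician: str,
    n_replicates: int,
    seed: int,
    config: SyntheticConfig | None = None,
) -> pd.DataFrame:
    """Repeated recovery replicates; one row of scale-corrected estimates each."""
    base = config if config is not None else SyntheticConfig(seed=seed)
    children = np.random.SeedSequence(seed).spawn(n_replicates)
    rows = []
    for child in children:
        rep = run_recovery_replicate(
            musician, replace(base, seed=seed), np.random.default_rng(child)
        )
        rows.append(rep["estimates"])
    return pd.DataFrame(rows)
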