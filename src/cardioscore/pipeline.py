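"""End-to-end orchestration: ingest -> preprocess -> features -> design -> fit.

The same design-construction code serves two callers: the analysis of
measured recordings (via :func:`run_pipeline`) and the synthetic-data
generator, which builds its generative design through these public
functions so that any design bug breaks the recovery tests by
construction.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import features as feat
from . import interpretation_map as imod
from . import preprocess as prep
from . import score_time as st
from .lme import (
    INTERCEPT,
    FitResult,
    ModelSpec,
    StackedDesign,
    backward_stepwise_aic,
    bootstrap_inference,
    cohens_f2,
    compute_vif,
    correlation_matrix,
    fit_lmm,
)
from .starting_factor import StartingFactorParams, build_starting_factor, roles_from_map

log = logging.getLogger("cardioscore")

#: Interpretation-Map model terms in design order.
MAP_TERMS = tuple(imod.MODEL_TERM_CATEGORIES)


@dataclass
class DesignParams:
    """Knobs of the design-construction stage (defaults are the study's)."""

    normalization: str = "minmax"
    filter_order: int = feat.LOUDNESS_FILTER_ORDER
    filter_wn: float = feat.LOUDNESS_FILTER_WN
    density_window: float = feat.DEFAULT_DENSITY_WINDOW
    kernel_offset: int = imod.KERNEL_CENTER_OFFSET
    kernel_sd: float = imod.KERNEL_SD
    b_melody: float = -0.2364
    b_accomp: float = -0.0871
    t_end: int = 80
    tempo_pulse: str = "quarter"


def build_musician_design(
    grid: st.ScoreTimeGrid,
    beat_maps: dict[int, st.BeatTimeMap],
    loudness_samples: dict[int, tuple[np.ndarray, np.ndarray]],
    notes: feat.ScoreNotes,
    imap: imod.InterpretationMap,
    params: DesignParams | None = None,
) -> StackedDesign:
    """Stack the per-performance predictor signals for one musician.

    Loudness and tempo are computed and normalized per performance;
    note density, the kernel-encoded annotation terms and the starting
    factor come from the score/map and are shared across performances.
    The response column is absent (all-NaN) until attached.
    """
    params = params or DesignParams()
    dens = feat.note_density(notes, grid, params.density_window)
    kernels = {
        term: imod.binary_to_kernel(
            imod.term_binary(imap, term, grid),
            params.kernel_offset,
            params.kernel_sd,
            category=term,
        )
        for term in MAP_TERMS
    }
    m, a = roles_from_map(imap, grid, params.t_end)
    sf = build_starting_factor(
        StartingFactorParams(params.b_melody, params.b_accomp, params.t_end, m, a), grid
    )
    frames = []
    for perf in sorted(beat_maps):
        bm = beat_maps[perf]
        if len(bm) != grid.n_samples:
            raise ValueError(
                f"performance {perf}: beat map length {len(bm)} != grid {grid.n_samples}"
            )
        tempo = feat.tempo_from_beats(bm, params.tempo_pulse)
        lt, lv = loudness_samples[perf]
        loud = feat.loudness_from_samples(lt, lv, bm)
        loud_s = feat.smooth_loudness(loud, params.filter_order, params.filter_wn)
        frames.append(
            pd.DataFrame(
                {
                    "performance": perf,
                    "sample": grid.sample_indices,
                    "loudness": prep.normalize(loud_s.values, params.normalization).values,
                    "tempo": prep.normalize(tempo.values, params.normalization).values,
                    "note_density": dens.values,
                    **{t: kernels[t].values for t in MAP_TERMS},
                    "starting_factor": sf.values,
                    "rr_norm": np.nan,
                }
            )
        )
    frame = pd.concat(frames, ignore_index=True)
    terms = ("loudness", "tempo", "note_density", *MAP_TERMS, "starting_factor")
    return StackedDesign(frame, terms)


def process_rr(
    series: prep.RRSeries,
    beat_map: st.BeatTimeMap,
    ectopic_threshold: float = prep.DEFAULT_ECTOPIC_THRESHOLD,
    ectopic_window: int = prep.DEFAULT_ECTOPIC_WINDOW,
    normalization: str = "minmax",
) -> tuple[prep.NormalizedSignal, prep.RemovalReport]:
    """Clean one RR series, move it to score time, normalize it."""
    cleaned, report = prep.remove_ectopic(series, ectopic_threshold, ectopic_window)
    resampled = st.resample_to_score_time(
        cleaned.times, cleaned.rr_ms, beat_map, "rr", "ms"
    )
    return prep.normalize(resampled.values, normalization), report


def attach_response(
    design: StackedDesign,
    rr_series: dict[int, prep.RRSeries],
    beat_maps: dict[int, st.BeatTimeMap],
    params: DesignParams | None = None,
    ectopic_threshold: float = prep.DEFAULT_ECTOPIC_THRESHOLD,
    ectopic_window: int = prep.DEFAULT_ECTOPIC_WINDOW,
) -> tuple[StackedDesign, dict[int, dict]]:
    """Fill the response column from measured RR series.

    Returns the design plus per-performance processing metadata
    (normalization parameters, removal counts) needed for audits and
    for mapping coefficient estimates back to physical units.
    """
    params = params or DesignParams()
    meta: dict[int, dict] = {}
    frame = design.frame.copy()
    for perf, series in rr_series.items():
        norm, report = process_rr(
            series, beat_maps[perf], ectopic_threshold, ectopic_window, params.normalization
        )
        mask = frame["performance"] == perf
        if mask.sum() != norm.values.size:
            raise ValueError(f"performance {perf}: response length mismatch")
        frame.loc[mask, "rr_norm"] = norm.values
        meta[perf] = {"norm_params": norm.params, "n_removed": report.n_removed,
                      "method": norm.method}
    return StackedDesign(frame, design.terms, design.response, design.group_col), meta


# ---------------------------------------------------------------------------
# full run orchestration


@dataclass
class RunConfig:
    """File-driven pipeline configuration (YAML-loadable)."""

    rr_csv: str
    beats_dir: str
    notes_csv: str
    annotations_csv: str
    loudness_dir: str
    out_dir: str
    expected_samples: int = st.SCHUBERT_N_SAMPLES
    model_sets: tuple[int, ...] = (1, 2, 3)
    n_boot: int = 1000
    seed: int = 0
    stepwise: bool = True
    design: DesignParams = field(default_factory=DesignParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        design = DesignParams(**raw.pop("design", {}))
        cfg = cls(design=design, **raw)
        for set_id in cfg.model_sets:
            if set_id not in (1, 2, 3):
                raise ValueError(f"unknown model set id {set_id}")
        for p in (cfg.rr_csv, cfg.beats_dir, cfg.notes_csv, cfg.annotations_csv,
                  cfg.loudness_dir):
            if not Path(p).exists():
                raise FileNotFoundError(p)
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _fit_result_record(fit: FitResult, design: StackedDesign) -> dict:
    rec = {
        "set_id": fit.spec.set_id,
        "terms": list(fit.spec.fixed_terms),
        "dropped_terms": list(fit.dropped_terms),
        "beta": fit.beta,
        "sigma_u2": fit.sigma_u2,
        "sigma2": fit.sigma2,
        "llf": fit.llf,
        "aic": fit.aic,
        "r2_marginal": fit.r2_marginal,
        "r2_conditional": fit.r2_conditional,
        "vif": fit.vif,
        "f2": fit.f2,
        "inference": {
            t: {"beta": ti.beta, "ci_low": ti.ci_low, "ci_high": ti.ci_high,
                "p": ti.p_value}
            for t, ti in fit.inference.items()
        },
    }
    return rec


def fit_model_set(
    design: StackedDesign,
    set_id: int,
    n_boot: int = 1000,
    seed: int = 0,
    stepwise: bool = True,
) -> FitResult:
    """Stepwise-reduce (optional), bootstrap, and attach diagnostics."""
    spec = ModelSpec.for_set(set_id)
    spec = ModelSpec(set_id, tuple(t for t in spec.fixed_terms if t in design.terms))
    if stepwise:
        spec, fit, dropped = backward_stepwise_aic(design, spec)
    else:
        fit = fit_lmm(design, spec)
        dropped = ()
    if spec.fixed_terms:
        inference, info = bootstrap_inference(design, spec, n_boot, seed)
        fit.inference = inference
        fit.meta["bootstrap"] = {"n_boot": info["n_boot"], "retries": info["retries"],
                                 "seed": seed}
    if len(spec.fixed_terms) >= 2:
        fit.vif = compute_vif(design, spec.fixed_terms)
    fit.f2 = {t: cohens_f2(design, spec, t, fit) for t in spec.fixed_terms}
    fit.dropped_terms = dropped
    return fit


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write a Table-1-shaped results bundle.

    Produces per musician x model set: coefficients with bootstrap CIs
    and p-values, R^2 (marginal and conditional), AIC, VIF, Cohen's f^2
    and the stepwise-dropped ("non-sign.") terms, plus the predictor
    correlation matrix; everything stamped with the config hash and seed.
    """
    t0 = time.time()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage = "ingest"
    try:
        rr_all = prep.read_rr_csv(config.rr_csv)
        notes = feat.read_notes_csv(config.notes_csv)
        maps = imod.read_annotations_csv(config.annotations_csv)
        beat_maps: dict[int, st.BeatTimeMap] = {}
        for path in sorted(Path(config.beats_dir).glob("beats_p*.csv")):
            perf = int(path.stem.split("_p")[-1])
            beat_maps[perf] = st.BeatTimeMap(perf, st.read_beat_instants(path))
        loudness: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        for path in sorted(Path(config.loudness_dir).glob("loudness_p*.csv")):
            perf = int(path.stem.split("_p")[-1])
            loudness[perf] = feat.read_feature_samples(path)
        if not beat_maps:
            raise FileNotFoundError(f"no beats_p*.csv in {config.beats_dir}")
        n_samples = len(next(iter(beat_maps.values())))
        if n_samples != config.expected_samples:
            raise ValueError(
                f"beat annotation length {n_samples} != expected "
                f"{config.expected_samples}"
            )
        grid = st.ScoreTimeGrid(n_samples)

        results: dict = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "normalization": config.design.normalization,
            "musicians": {},
        }
        for musician in sorted(notes):
            stage = f"design[{musician}]"
            log.info("building design for %s", musician)
            design = build_musician_design(
                grid, beat_maps, loudness, notes[musician], maps[musician], config.design
            )
            series = {s.performance_id: s for s in rr_all
                      if s.musician_id == musician}
            stage = f"preprocess[{musician}]"
            design, proc_meta = attach_response(design, series, beat_maps, config.design)
            stage = f"fit[{musician}]"
            mus_res: dict = {"preprocess": {str(k): v for k, v in proc_meta.items()}}
            r_mat, p_mat, flagged = correlation_matrix(design)
            mus_res["correlations"] = {
                "r": r_mat.round(6).to_dict(),
                "flagged_pairs": flagged,
            }
            for set_id in config.model_sets:
                fit = fit_model_set(design, set_id, config.n_boot, config.seed,
                                    config.stepwise)
                mus_res[f"model_set_{set_id}"] = _fit_result_record(fit, design)
            results["musicians"][musician] = mus_res
    except Exception:
        manifest = {"failed_stage": stage, "elapsed_s": time.time() - t0}
        (out_dir / "partial_manifest.json").write_text(json.dumps(manifest, indent=2))
        log.exception("pipeline failed at stage %s", stage)
        raise
    results["elapsed_s"] = time.time() - t0
    (out_dir / "results.json").write_text(json.dumps(results, indent=2, default=float))
    _results_to_csv(results, out_dir / "results.csv")
    log.info("pipeline finished in %.1f s", results["elapsed_s"])
    return results


def _results_to_csv(results: dict, path: Path) -> None:
    rows = []
    for musician, mus in results["musicians"].items():
        for key, rec in mus.items():
            if not key.startswith("model_set_"):
                continue
            terms = [INTERCEPT] + rec["terms"] + rec["dropped_terms"]
            for term in terms:
                inf = rec["inference"].get(term, {})
                rows.append(
                    {
                        "musician": musician,
                        "model_set": rec["set_id"],
                        "term": term,
                        "beta": rec["beta"].get(term),
                        "ci_low": inf.get("ci_low"),
                        "ci_high": inf.get("ci_high"),
                        "p": inf.get("p"),
                        "f2": rec["f2"].get(term),
                        "vif": rec["vif"].get(term),
                        "dropped": term in rec["dropped_terms"],
                        "r2_marginal": rec["r2_marginal"],
                        "r2_conditional": rec["r2_conditional"],
                        "aic": rec["aic"],
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def report(results: dict, out_dir: str | Path) -> Path:
    """Human-readable summary plus basic predictor/response plots.

    Missing fields are listed rather than fatal: a partial bundle still
    yields a partial report.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lines: list[str] = []
    problems: list[str] = []
    musicians = results.get("musicians", {})
    if not musicians:
        problems.append("no musician results present")
    for musician, mus in sorted(musicians.items()):
        lines.append(f"== {musician} ==")
        for key in sorted(k for k in mus if k.startswith("model_set_")):
            rec = mus[key]
            lines.append(
                f"  Model set {rec['set_id']}: R2(marginal)={rec['r2_marginal']:.3f} "
                f"R2(conditional)={rec['r2_conditional']:.3f} AIC={rec['aic']:.0f}"
            )
            for term in [INTERCEPT] + rec["terms"]:
                inf = rec["inference"].get(term, {})
                ci = (f" [{inf['ci_low']:+.3f}, {inf['ci_high']:+.3f}] p={inf['p']:.4f}"
                      if inf else "")
                f2 = rec["f2"].get(term)
                vif = rec["vif"].get(term)
                extra = "".join(
                    s for s in (
                        f" f2={f2:.3f}" if f2 is not None else "",
                        f" VIF={vif:.2f}" if vif is not None else "",
                    )
                )
                lines.append(f"    {term:<26s} {rec['beta'][term]:+.4f}{ci}{extra}")
            for term in rec["dropped_terms"]:
                lines.append(f"    {term:<26s} non-sign.")
    if problems:
        lines.append("WARNINGS: " + "; ".join(problems))
    summary = out_dir / "summary.txt"
    summary.write_text("\n".join(lines) + "\n")

    for musician, mus in sorted(musicians.items()):
        sets = [k for k in mus if k.startswith("model_set_")]
        if not sets:
            continue
        fig, ax = plt.subplots(figsize=(7, 3))
        for key in sorted(sets):
            rec = mus[key]
            betas = [rec["beta"][t] for t in rec["terms"]]
            ax.plot(rec["terms"], betas, marker="o", label=f"set {rec['set_id']}")
        ax.axhline(0, color="k", lw=0.5)
        ax.set_ylabel("coefficient")
        ax.set_title(musician)
        ax.tick_params(axis="x", rotation=45)
        ax.legend()
        fig.tight_layout()
        fig.savefig(out_dir / f"coefficients_{musician}.png", dpi=100)
        plt.close(fig)
    return summary
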