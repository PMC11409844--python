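import numpy as np
import pytest

from cardioscore.interpretation_map import MODEL_TERM_CATEGORIES, term_binary
from cardioscore.lme import INTERCEPT, ModelSpec, StackedDesign, fit_lmm
from cardioscore.pipeline import attach_response, process_rr
from cardioscore.synthetic import (
    SyntheticConfig,
    build_design,
    generate_fixtures,
    generate_rr,
    run_recovery_replicate,
    simulate_dataset,
    write_fixture_tree,
)


class TestFixtureGeneration:
    def test_deterministic_given_seed(self, tmp_path):
        cfg = SyntheticConfig(seed=42, n_bars=40, n_performances=2)
        a = generate_fixtures(cfg)
        b = generate_fixtures(cfg)
        assert a.maps == b.maps
        for p in a.beat_maps:
            assert np.array_equal(a.beat_maps[p].beat_times, b.beat_maps[p].beat_times)
            assert np.array_equal(a.loudness[p][1], b.loudness[p][1])
        # byte-identical fixture trees
        fx, rr, truths = simulate_dataset(cfg)
        fx2, rr2, truths2 = simulate_dataset(cfg)
        d1 = write_fixture_tree(tmp_path / "a", fx, rr, truths)
        d2 = write_fixture_tree(tmp_path / "b", fx2, rr2, truths2)
        for f1 in sorted(d1.rglob("*.csv")) + [d1 / "truth.json"]:
            f2 = d2 / f1.relative_to(d1)
            assert f1.read_bytes() == f2.read_bytes(), f1.name

    def test_default_grid_is_848(self):
        assert SyntheticConfig(seed=1).grid.n_samples == 848

    def test_maps_cover_every_model_term(self, small_fixtures):
        grid = small_fixtures.grid
        for m, imap in small_fixtures.maps.items():
            for term in MODEL_TERM_CATEGORIES:
                vec = term_binary(imap, term, grid)
                assert vec.any(), f"{m} lacks {term}"

    def test_beat_times_strictly_increasing(self, small_fixtures):
        for bm in small_fixtures.beat_maps.values():
            assert np.all(np.diff(bm.beat_times) > 0)
            assert len(bm) == small_fixtures.grid.n_samples

    def test_opening_roles(self, small_fixtures):
        """The cellist leads the opening melody over piano accompaniment;
        the violinist is silent for the first 20 bars."""
        grid = small_fixtures.grid
        viol, cello, piano = small_fixtures.config.musicians
        assert term_binary(small_fixtures.maps[cello], "melody", grid)[:80].all()
        acc = np.maximum(
            term_binary(small_fixtures.maps[piano], "accompaniment", grid),
            term_binary(small_fixtures.maps[piano], "significant_accompaniment", grid),
        )
        assert acc[:80].all()
        for term in MODEL_TERM_CATEGORIES:
            assert not term_binary(small_fixtures.maps[viol], term, grid)[:79].any()
        assert len(small_fixtures.notes[viol]) > 0
        assert small_fixtures.notes[viol].onsets.min() > 80

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SyntheticConfig(seed=1, n_bars=10)
        with pytest.raises(ValueError):
            SyntheticConfig(seed=1, random_intercept_sd=-0.1)
        with pytest.raises(ValueError):
            SyntheticConfig(seed=1, musicians=("violist",))


class TestGenerateRR:
    def test_exact_limit_recovers_beta(self, small_config, small_fixtures):
        """With zero noise and zero random-intercept variance the fitted
        coefficients equal the generating ones to numerical precision
        (response attached at the grid level, no beat-sampling channel)."""
        import dataclasses

        cfg = dataclasses.replace(small_config, noise_sd=0.0, random_intercept_sd=0.0)
        design = build_design(small_fixtures, "cellist")
        _, truth = generate_rr(cfg, small_fixtures, design, "cellist",
                               np.random.default_rng(0))
        frame = design.frame.copy()
        for perf, y in truth["y_grid"].items():
            frame.loc[frame["performance"] == perf, "rr_norm"] = y
        filled = StackedDesign(frame, design.terms)
        fit = fit_lmm(filled, ModelSpec.for_set(3))
        for term, b_true in truth["beta"].items():
            est = fit.beta[INTERCEPT] if term == INTERCEPT else fit.beta[term]
            assert abs(est - b_true) < 1e-6, term

    def test_channel_round_trip_within_interpolation_tolerance(
        self, small_config, small_fixtures
    ):
        """Noiseless back-mapped RR series, cleaned and resampled,
        reproduce the grid-level response up to beat-sampling
        interpolation error (the R-peak clock samples the response more
        coarsely than the half-beat grid)."""
        import dataclasses

        cfg = dataclasses.replace(small_config, noise_sd=0.0, random_intercept_sd=0.0)
        design = build_design(small_fixtures, "cellist")
        series, truth = generate_rr(
            cfg, small_fixtures, design, "cellist", np.random.default_rng(1)
        )
        for perf, s in series.items():
            assert s.check_continuity()
            norm, _ = process_rr(s, small_fixtures.beat_maps[perf])
            y = np.asarray(truth["y_grid"][perf])
            y_norm = (y - y.min()) / np.ptp(y)
            assert np.corrcoef(norm.values, y_norm)[0, 1] > 0.995
            assert np.max(np.abs(norm.values - y_norm)) < 0.06

    def test_rr_values_physiological(self, small_config, small_fixtures):
        design = build_design(small_fixtures, "pianist")
        series, _ = generate_rr(
            small_config, small_fixtures, design, "pianist", np.random.default_rng(2)
        )
        for s in series.values():
            assert 200 < s.rr_ms.min() and s.rr_ms.max() < 2000

    def test_ectopic_injection_and_removal_round_trip(self, small_fixtures):
        """Injected premature beats (half interval + compensatory pause)
        are caught by the running-median filter, restoring nearly the
        clean-channel fidelity."""
        import dataclasses

        cfg_clean = dataclasses.replace(small_fixtures.config, seed=77)
        cfg_ect = dataclasses.replace(cfg_clean, n_ectopic=6)
        design = build_design(small_fixtures, "cellist")
        clean, truth_c = generate_rr(cfg_clean, small_fixtures, design, "cellist",
                                     np.random.default_rng(7))
        ect, truth_e = generate_rr(cfg_ect, small_fixtures, design, "cellist",
                                   np.random.default_rng(7))
        perf = 1
        y = np.asarray(truth_c["y_grid"][perf])
        bm = small_fixtures.beat_maps[perf]
        fid_clean = np.corrcoef(process_rr(clean[perf], bm)[0].values, y)[0, 1]
        norm_ect, report = process_rr(ect[perf], bm)
        fid_ect = np.corrcoef(norm_ect.values, y)[0, 1]
        assert report.n_removed >= 1
        assert fid_ect >= 0.95 * fid_clean

    def test_noise_calibration_targets_half_variance(self, small_config, small_fixtures):
        """Auto noise SD equals the fixed-effect signal SD, putting the
        marginal R^2 of the refit near one half."""
        rep = run_recovery_replicate("violinist", small_config, np.random.default_rng(9))
        assert 0.35 < rep["fit"].r2_marginal < 0.75


class TestRecovery:
    def test_full_pipeline_recovery_small_scale(self, small_config):
        """Mean recovered coefficients approach the generating ones even
        at the shrunk problem size."""
        from cardioscore.synthetic import recovery_experiment

        df = recovery_experiment("cellist", 8, seed=31, config=small_config)
        truth = small_config.true_beta["cellist"]
        for term in ("climax", "moment_of_concern", "loudness"):
            assert abs(df[term].mean() - truth[term]) < 0.1, term

    def test_design_built_through_pipeline_modules(self, small_fixtures):
        design = build_design(small_fixtures, "violinist")
        assert design.terms == (
            "loudness", "tempo", "note_density", "melody", "dialogue",
            "significant_accompaniment", "accompaniment", "climax",
            "moment_of_concern", "starting_factor",
        )
        n = small_fixtures.grid.n_samples * small_fixtures.config.n_performances
        assert design.n_rows == n
        # loudness/tempo normalized per performance
        for perf, sub in design.frame.groupby("performance"):
            assert abs(sub["loudness"].min()) < 1e-12
            assert abs(sub["loudness"].max() - 1.0) < 1e-12
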