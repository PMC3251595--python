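"""Simulator: population structure, rendering, time-course models,
dataset emission and end-to-end recovery realism."""

import math

import numpy as np
import pytest

from arqiv.pipeline import process_sessions, quality_report
from arqiv.plate_io import ValidationError, read_layout, read_regional_export
from arqiv.simulate import (
    FLAT,
    AblationRegen,
    DoseResponse,
    Induction,
    Ros,
    SimulationConfig,
    ablation_scenario,
    dose_response_scenario,
    emit_dataset,
    make_population,
    render_scan,
    sb_regime_config,
    simulate_timecourse,
)


def cfg(**kw):
    kw.setdefault("seed", 99)
    return SimulationConfig(**kw)


class TestPopulation:
    def test_sigma_zero_degenerate(self, rng):
        subjects = make_population(cfg(sigma_log=0.0), rng)
        expr = {s.expression_rfu for s in subjects if s.group != "NEGATIVE_CONTROL"}
        assert expr == {cfg().expression_median_rfu}

    def test_default_spread_spans_order_of_magnitude(self):
        config = cfg(n_per_group=1000)
        subjects = make_population(config, config.rng())
        expr = np.array(
            [s.expression_rfu for s in subjects if s.group == "TRANSGENIC_CONTROL"]
        )
        lo, hi = np.percentile(expr, [2.5, 97.5])
        closed_form = math.exp(2 * 1.96 * config.sigma_log)  # ~10.5 at default
        assert closed_form >= 10.0
        assert hi / lo == pytest.approx(closed_form, rel=0.2)

    def test_same_seed_identical(self):
        config = cfg()
        a = make_population(config, config.rng())
        b = make_population(config, config.rng())
        assert [s.expression_rfu for s in a] == [s.expression_rfu for s in b]

    def test_negatives_have_zero_expression(self, rng):
        subjects = make_population(cfg(), rng)
        assert all(
            s.expression_rfu == 0.0
            for s in subjects
            if s.group == "NEGATIVE_CONTROL"
        )

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValidationError):
            cfg(sigma_log=-1.0)
        with pytest.raises(ValidationError):
            cfg(n_signal_regions=5, pattern_n=2)


class TestRenderScan:
    def _subject(self, expr=1000.0):
        pop = make_population(
            cfg(sigma_log=0.0, expression_median_rfu=expr),
            np.random.default_rng(0),
        )
        return next(s for s in pop if s.group == "TRANSGENIC_CONTROL")

    def test_noise_free_regional_single_region(self, rng):
        config = cfg(
            replicate_cv=0.0, autofluor_sd_rfu=0.0, autofluor_mean_rfu=5.0,
            sigma_log=0.0, expression_median_rfu=1000.0,
        )
        grid = render_scan(self._subject(), 0.0, config, rng)
        values = sorted(grid.values)
        assert values[:3] == [5.0, 5.0, 5.0]
        assert values[3] == pytest.approx(1005.0)

    def test_global_spreads_over_all_regions(self, rng):
        config = cfg(
            spatial_profile="GLOBAL", replicate_cv=0.0, autofluor_sd_rfu=0.0,
            autofluor_mean_rfu=0.0, sigma_log=0.0, expression_median_rfu=1000.0,
        )
        grid = render_scan(self._subject(), 0.0, config, rng)
        assert grid.values == pytest.approx([250.0] * 4)

    def test_expected_total_signal_arithmetic(self, rng):
        """At cv=0 the DIRECT TS expectation is true signal plus
        n_signal_regions x autofluorescence mean."""
        config = cfg(
            replicate_cv=0.0, autofluor_sd_rfu=0.0, autofluor_mean_rfu=30.0,
            sigma_log=0.0, expression_median_rfu=2000.0,
        )
        grid = render_scan(self._subject(expr=2000.0), 0.0, config, rng)
        assert max(grid.values) == pytest.approx(2000.0 + 30.0)

    def test_replicate_cv_recovered(self):
        """Monte-Carlo: empirical cv of rendered TS matches configured cv."""
        config = cfg(
            replicate_cv=0.05, autofluor_mean_rfu=0.0, autofluor_sd_rfu=0.0,
            sigma_log=0.0, expression_median_rfu=10_000.0,
        )
        r = config.rng()
        subject = self._subject(expr=10_000.0)
        totals = [
            sum(render_scan(subject, 0.0, config, r).values) for _ in range(10_000)
        ]
        cv = np.std(totals, ddof=1) / np.mean(totals)
        assert cv == pytest.approx(0.05, rel=0.1)


class TestTimecourseModels:
    times = np.linspace(0.0, 240.0, 41)

    def test_flat_model(self):
        assert simulate_timecourse(FLAT, [0.0, 1.0]).tolist() == [1.0, 1.0]

    def test_dose_zero_identity(self):
        m = DoseResponse(dose=0.0, ic50=10.0)
        assert simulate_timecourse(m, self.times).tolist() == [1.0] * len(self.times)

    @pytest.mark.parametrize("hill", [0.5, 1.0, 3.0])
    def test_hill_midpoint(self, hill):
        m = DoseResponse(dose=10.0, ic50=10.0, hill=hill, onset_hpf=0.0)
        assert m.plateau == pytest.approx(0.5)
        # long after onset the trajectory sits at the plateau
        assert m.fraction(1e6) == pytest.approx(0.5)

    def test_ablation_bounds_and_recovery_monotone(self):
        m = AblationRegen(treat_start_hpf=0.0, floor_fraction=0.1, recovery_rate_per_h=0.02)
        f = simulate_timecourse(m, self.times)
        assert np.all(f > 0.0999) and np.all(f <= 1.0)
        after = f[self.times >= 24.0]
        assert np.all(np.diff(after) >= 0)  # nondecreasing after washout

    def test_ablation_trough_near_floor(self):
        m = AblationRegen(treat_start_hpf=120.0, floor_fraction=0.1)
        assert m.fraction(144.0) == pytest.approx(0.1, abs=1e-3)

    def test_induction_onset_and_amplitude(self):
        m = Induction(onset_h=10.0, amplitude=3.0, rise_rate_per_h=0.5)
        assert m.fraction(10.0) == 1.0
        assert m.fraction(1e6) == pytest.approx(3.0)

    def test_ros_multiplicative_effects(self):
        m = Ros(stressor_effects=(2.5, 1.2), scavenger_multiplier=0.4,
                scavenger_cotreated=True)
        assert m.fraction(1.0) == pytest.approx(2.5 * 1.2 * 0.4)

    def test_negative_rates_rejected(self):
        with pytest.raises(ValidationError):
            AblationRegen(treat_start_hpf=0.0, recovery_rate_per_h=-0.1)
        with pytest.raises(ValidationError):
            simulate_timecourse(FLAT, [1.0, 1.0])


class TestEmitDataset:
    def test_cardinality(self, tmp_path):
        ds = ablation_scenario(seed=3, n_per_group=8, timepoints=(0.0, 24.0, 48.0))
        paths = emit_dataset(ds, tmp_path)
        sessions = read_regional_export(paths["export"])
        assert len(sessions) == 3
        # 8 negative + 8 control + 8 treated subjects, 3 replicates each
        assert len(sessions[0].grids) == 24 * 3

    def test_readback_matches_truth_noise_free(self, tmp_path):
        ds = ablation_scenario(
            seed=3, n_per_group=4, n_negative=2,
            replicate_cv=0.0, session_sd_log=0.0, shared_drift_sd_log=0.0,
            autofluor_mean_rfu=0.0, autofluor_sd_rfu=0.0,
            timepoints=(120.0, 144.0),
        )
        paths = emit_dataset(ds, tmp_path)
        sessions = read_regional_export(paths["export"])
        by_subject = {s.subject_id: s.expression_rfu for s in ds.subjects}
        baseline = min(sessions, key=lambda s: s.timepoint_hpf)
        for g in baseline.grids:
            assert sum(g.values) == pytest.approx(by_subject[g.subject_id], rel=1e-12)

    def test_byte_identical_under_same_seed(self, tmp_path):
        a = emit_dataset(ablation_scenario(seed=11, n_per_group=4), tmp_path / "a")
        b = emit_dataset(ablation_scenario(seed=11, n_per_group=4), tmp_path / "b")
        c = emit_dataset(ablation_scenario(seed=12, n_per_group=4), tmp_path / "c")
        for key in a:
            assert a[key].read_bytes() == b[key].read_bytes()
        assert a["export"].read_bytes() != c["export"].read_bytes()

    def test_layout_readable(self, tmp_path):
        ds = ablation_scenario(seed=3, n_per_group=4)
        paths = emit_dataset(ds, tmp_path)
        layout = read_layout(paths["layout_P1"])
        assert layout.wells_in_group("NEGATIVE_CONTROL")


class TestQualityRealism:
    """Per-individual Z' tracks the S:B regime: excellent for bright global
    reporters, collapsing once per-region signal nears the detection limit."""

    def _mean_zprime(self, sb):
        config = sb_regime_config(
            seed=42, sb_ratio=sb, spatial_profile="GLOBAL", n_per_group=24
        )
        ds_groups = [
            ("NEGATIVE_CONTROL", None, config.n_negative, FLAT),
            ("TRANSGENIC_CONTROL", None, config.n_per_group, FLAT),
        ]
        from arqiv.simulate import _build_dataset

        ds = _build_dataset(config, ds_groups, timepoints=(0.0,))
        reports = quality_report(ds.sessions, ds.layouts)
        return reports[config.channel].zprime_per_individual.mean

    def test_high_sb_excellent_and_degrades_toward_detection_limit(self):
        z_high = self._mean_zprime(100.0)
        z_mid = self._mean_zprime(5.0)
        z_low = self._mean_zprime(2.0)
        assert z_high > 0.5
        assert z_low < z_mid < z_high
        assert z_low < 0.0
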