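"""Generator behavior: dose linearity, mosaicism, reproducibility."""

import dataclasses

import numpy as np
import pytest
from scipy import stats as sps

from nsepscreen.samples import samples_to_frame
from nsepscreen.synth import (
    GeneratorConfig,
    generate_cell_sample,
    generate_replication_series,
    generate_screen,
)


def expected_delta(cfg: GeneratorConfig, effect: float, editing: float = 1.0) -> float:
    """Closed-form E[exposed mean - sham mean] at unit plate scale."""
    base = cfg.slope_per_pulse * cfg.pulses
    return (1.0 - cfg.outlier_rate) * base * (1.0 + editing * (effect - 1.0))


class TestCellSample:
    def test_zero_dose_exposed_and_sham_are_the_same_law(self):
        cfg = GeneratorConfig(pulses=0, cells_per_sample=4000, seed=7)
        exposed = generate_cell_sample(cfg, "KO001", "exposed", rng=1)
        sham = generate_cell_sample(cfg, "KO001", "sham", rng=2)
        stat = sps.ks_2samp(exposed.yp, sham.yp)
        assert stat.pvalue > 0.01

    def test_dose_response_is_linear_through_origin(self):
        means = []
        pulse_counts = [10, 20, 30, 40, 50]
        for pulses in pulse_counts:
            cfg = GeneratorConfig(
                pulses=pulses, cells_per_sample=20000, outlier_rate=0.0, seed=3
            )
            exp = generate_cell_sample(cfg, "KO001", "exposed", rng=pulses)
            sham = generate_cell_sample(cfg, "KO001", "sham", rng=pulses + 1)
            means.append(exp.yp.mean() - sham.yp.mean())
        res = sps.linregress(pulse_counts, means)
        cfg0 = GeneratorConfig()
        assert res.slope == pytest.approx(cfg0.slope_per_pulse, rel=0.05)
        # line passes through the origin within the fit uncertainty
        assert abs(res.intercept) < 3 * res.intercept_stderr + 2.0

    def test_effect_multiplies_mean_uptake_increment(self):
        cfg = GeneratorConfig(
            effect_map={"KOX": 1.4},
            cells_per_sample=10000,
            outlier_rate=0.0,
            seed=5,
        )
        exp = generate_cell_sample(cfg, "KOX", "exposed", rng=1)
        sham = generate_cell_sample(cfg, "KOX", "sham", rng=2)
        observed = exp.yp.mean() - sham.yp.mean()
        expected = expected_delta(cfg, 1.4)
        # SE of the MC mean is ~ sd/sqrt(n); allow 4 of those
        se = exp.yp.std() / np.sqrt(exp.n_cells)
        assert observed == pytest.approx(expected, abs=4 * se)

    def test_partial_editing_dilutes_the_effect(self):
        cfg = GeneratorConfig(
            effect_map={"KOX": 1.8},
            editing_fraction={"KOX": 0.5},
            cells_per_sample=40000,
            outlier_rate=0.0,
            seed=9,
        )
        exp = generate_cell_sample(cfg, "KOX", "exposed", rng=1)
        sham = generate_cell_sample(cfg, "KOX", "sham", rng=2)
        observed = exp.yp.mean() - sham.yp.mean()
        assert observed == pytest.approx(expected_delta(cfg, 1.8, 0.5), rel=0.05)

    def test_unknown_variant_and_bad_condition_raise(self):
        cfg = GeneratorConfig()
        with pytest.raises(KeyError):
            generate_cell_sample(cfg, "NOPE", "exposed")
        with pytest.raises(ValueError):
            generate_cell_sample(cfg, "KO001", "zapped")

    def test_divergence_above_linear_limit_inflates_mean_and_scatter(self):
        linear = GeneratorConfig(pulses=50, cells_per_sample=20000,
                                 outlier_rate=0.0, seed=4)
        heavy = GeneratorConfig(pulses=75, cells_per_sample=20000,
                                outlier_rate=0.0, seed=4)
        y50 = generate_cell_sample(linear, "KO001", "exposed", rng=1).yp
        y75 = generate_cell_sample(heavy, "KO001", "exposed", rng=1).yp
        # the mean leaves the extrapolated line and the spread blows up
        assert y75.mean() > 1.2 * y50.mean() * (75 / 50)
        assert y75.std() > 1.5 * y50.std() * (75 / 50)


class TestScreen:
    def test_sample_count(self, small_cfg):
        samples, _ = generate_screen(small_cfg)
        n_scr = small_cfg.n_scr_per_plate
        assert len(samples) == 2 * (6 + n_scr) * 3

    def test_same_seed_reproduces_byte_for_byte(self, small_cfg):
        a, _ = generate_screen(small_cfg)
        b, _ = generate_screen(dataclasses.replace(small_cfg))
        ta = samples_to_frame(a).to_csv(index=False)
        tb = samples_to_frame(b).to_csv(index=False)
        assert ta == tb

    def test_ground_truth_covers_every_variant_once(self, small_cfg):
        samples, truth = generate_screen(small_cfg)
        generated = {s.variant for s in samples}
        assert set(truth.effects) == generated
        assert set(truth.plate_of) == generated
        assert all(truth.effects[v] == 1.0 for v in truth.scr_ids)

    def test_plate_partitioning_adds_scr_to_every_plate(self):
        cfg = GeneratorConfig(
            n_variants=30, plate_size=15, n_scr_per_plate=2,
            n_experiments=2, cells_per_sample=50, seed=1,
        )
        _, truth = generate_screen(cfg)
        plates = set(truth.plate_of.values())
        assert plates == {"P1", "P2"}
        for p in plates:
            scr_here = [v for v in truth.scr_ids if truth.plate_of[v] == p]
            assert len(scr_here) == 2


class TestReplicationSeries:
    def test_full_attenuation_reverts_all_knockouts_to_control(self):
        cfg = GeneratorConfig(
            effect_map={"KOA": 1.5, "KOB": 0.7},
            cells_per_sample=20000,
            outlier_rate=0.0,
            n_experiments=2,
            seed=21,
        )
        samples, truth = generate_replication_series(cfg, attenuation=1.0)
        assert all(truth.editing[v] == 0.0 for v in cfg.effect_map)
        by_key = {(s.variant, s.condition, s.experiment): s for s in samples}
        d_ko = (by_key[("KOA", "exposed", "E1")].yp.mean()
                - by_key[("KOA", "sham", "E1")].yp.mean())
        scr = next(v for v in truth.scr_ids)
        d_scr = (by_key[(scr, "exposed", "E1")].yp.mean()
                 - by_key[(scr, "sham", "E1")].yp.mean())
        scale = truth.plate_scales[("E1", "P1")]
        assert d_ko == pytest.approx(d_scr, rel=0.15)
        assert d_ko / scale == pytest.approx(expected_delta(cfg, 1.0), rel=0.1)

    def test_half_attenuation_halves_the_excess(self):
        cfg = GeneratorConfig(
            effect_map={"KOA": 1.4},
            cells_per_sample=60000,
            outlier_rate=0.0,
            plate_scale_sd=0.0,
            n_experiments=2,
            seed=22,
        )
        samples, truth = generate_replication_series(cfg, attenuation=0.5)
        assert truth.editing["KOA"] == 0.5
        by_key = {(s.variant, s.condition, s.experiment): s for s in samples}
        d = (by_key[("KOA", "exposed", "E1")].yp.mean()
             - by_key[("KOA", "sham", "E1")].yp.mean())
        # excess over null shrinks from +40% to +20%
        assert d == pytest.approx(expected_delta(cfg, 1.4, 0.5), rel=0.05)

    def test_attenuation_bounds(self, small_cfg):
        with pytest.raises(ValueError):
            generate_replication_series(small_cfg, attenuation=1.5)
        with pytest.raises(ValueError):
            generate_replication_series(small_cfg, attenuation=-0.1)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "fields",
        [
            {"n_experiments": 0},
            {"cells_per_sample": 0},
            {"pulses": -1},
            {"sham_cv": -0.5},
            {"outlier_rate": 1.5},
            {"effect_map": {"SCR-P1-1": 1.3}},
            {"editing_fraction": {"KO001": 1.2}},
        ],
    )
    def test_invalid_configs_raise(self, fields):
        with pytest.raises(ValueError):
            GeneratorConfig(**fields)


class TestOutlierRobustness:
    def test_median_metric_is_robust_to_dead_cell_outliers(self):
        """Raising the outlier rate leaves median ΔF alone but inflates the
        scatter of mean ΔF — the rationale for running both metrics."""
        base = dict(cells_per_sample=2000, plate_scale_sd=0.0)
        med = {0.0: [], 0.02: []}
        mean = {0.0: [], 0.02: []}
        for rate in (0.0, 0.02):
            cfg = GeneratorConfig(outlier_rate=rate, seed=31, **base)
            for rep in range(40):
                e = generate_cell_sample(cfg, "KO001", "exposed", rng=2 * rep)
                s = generate_cell_sample(cfg, "KO001", "sham", rng=2 * rep + 1)
                med[rate].append(np.median(e.yp) - np.median(s.yp))
                mean[rate].append(e.yp.mean() - s.yp.mean())
        med_shift = abs(np.mean(med[0.02]) - np.mean(med[0.0]))
        med_se = np.std(med[0.0]) / np.sqrt(40) + np.std(med[0.02]) / np.sqrt(40)
        assert med_shift < 3 * med_se + 1.0
        assert np.std(mean[0.02]) > 2.0 * np.std(mean[0.0])
        assert np.std(med[0.02]) < 1.5 * np.std(med[0.0])
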