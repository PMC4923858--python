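"""Force-curve parsing, baseline, rupture detection, histogram, probability."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import smolbind as sb
from smolbind.afm import (
    ForceHistogramModel,
    binding_probability,
    compare_forces,
    correct_baseline,
    detect_ruptures,
    fit_force_histogram,
    read_force_curves,
    write_force_curve,
)
from smolbind.simulate import (
    ForceConfig,
    ForceCurve,
    simulate_force_curve,
    simulate_force_curves,
)


def make_curve(retract_force=None, n=400, contact_slope=60.0):
    """Hand-built curve over separations -10..100 nm with contact repulsion."""
    sep = np.linspace(-10.0, 100.0, n)
    contact = np.where(sep < 0, -contact_slope * sep, 0.0)
    retract = contact + (retract_force if retract_force is not None else 0.0)
    return ForceCurve(
        approach_separation=sep[::-1].copy(), approach_force=contact[::-1].copy(),
        retract_separation=sep.copy(), retract_force=retract,
        spring_constant=0.06, loading_rate=1e4, curve_id="manual",
    )


class TestDialect:
    def test_minimal_file_round_trip(self, tmp_path, clean_force_config):
        curve, _ = simulate_force_curve(True, clean_force_config)
        path = tmp_path / "c1.txt"
        write_force_curve(path, curve)
        back, = read_force_curves(path)
        assert np.allclose(back.retract_force, curve.retract_force, atol=1e-9)
        assert np.allclose(back.approach_separation, curve.approach_separation)
        assert back.spring_constant == curve.spring_constant
        assert back.loading_rate == curve.loading_rate

    def test_unit_conversion_60_pn(self, tmp_path):
        path = tmp_path / "c.txt"
        path.write_text(
            "#id unit\n#spring_constant_N_per_m 0.06\n"
            "#loading_rate_pN_per_s 10000\n"
            "#segment approach\n5.0\t1.0\n4.0\t1.0\n"
            "#segment retract\n4.0\t1.0\n5.0\t1.0\n"
        )
        curve, = read_force_curves(path)
        assert curve.approach_force[0] == pytest.approx(60.0)

    def test_missing_spring_constant_header(self, tmp_path):
        path = tmp_path / "c.txt"
        path.write_text("#id x\n#segment approach\n1.0\t0.0\n#segment retract\n1.0\t0.0\n")
        with pytest.raises(sb.ParseError, match="spring_constant"):
            read_force_curves(path)
        # but an explicit override makes the file readable
        curve, = read_force_curves(path, spring_constant=0.06)
        assert curve.spring_constant == 0.06

    def test_non_monotone_separation(self, tmp_path):
        path = tmp_path / "c.txt"
        path.write_text(
            "#id x\n#spring_constant_N_per_m 0.06\n#segment approach\n"
            "1.0\t0.0\n3.0\t0.0\n2.0\t0.0\n#segment retract\n1.0\t0.0\n2.0\t0.0\n"
        )
        with pytest.raises(sb.ParseError, match="monotone"):
            read_force_curves(path)

    def test_unknown_segment_tag(self, tmp_path):
        path = tmp_path / "c.txt"
        path.write_text("#id x\n#spring_constant_N_per_m 0.06\n#segment sideways\n")
        with pytest.raises(sb.ParseError, match="segment"):
            read_force_curves(path)

    def test_malformed_rows_logged_and_skipped(self, tmp_path, caplog):
        path = tmp_path / "c.txt"
        path.write_text(
            "#id x\n#spring_constant_N_per_m 0.06\n#segment approach\n"
            "2.0\t0.0\nnot-a-number\n1.0\t0.0\n#segment retract\n1.0\t0.0\n2.0\t0.0\n"
        )
        with caplog.at_level("WARNING"):
            curve, = read_force_curves(path)
        assert curve.approach_separation.size == 2
        assert any("malformed" in r.message for r in caplog.records)

    def test_batch_round_trip(self, tmp_path):
        cfg = ForceConfig(seed=40, n_curves=100, points_per_segment=60)
        curves, _ = simulate_force_curves(cfg, "ctl")
        for c in curves:
            write_force_curve(tmp_path / f"{c.curve_id}.txt", c)
        back = read_force_curves(tmp_path)
        assert len(back) == 100
        by_id = {c.curve_id: c for c in curves}
        for b in back:
            orig = by_id[b.curve_id]
            assert np.allclose(b.retract_force, orig.retract_force, atol=1e-9)


class TestBaseline:
    def test_linear_tilt_removed(self):
        curve = make_curve()
        tilted = replace(
            curve,
            approach_force=curve.approach_force + 7.0 + 0.3 * curve.approach_separation,
            retract_force=curve.retract_force + 7.0 + 0.3 * curve.retract_separation,
        )
        corr = correct_baseline(tilted)
        far = corr.retract_separation > 50
        assert np.max(np.abs(corr.retract_force[far])) < 1e-6

    def test_contact_point_matches_ground_truth(self, clean_force_config):
        cfg = clean_force_config.model_copy(
            update={"baseline_offset_sd": 3.0, "baseline_slope_sd": 0.02}
        )
        curve, _ = simulate_force_curve(False, cfg)
        corr = correct_baseline(curve)
        ds = np.diff(np.sort(curve.retract_separation))[0]
        assert abs(corr.contact_nm - 0.0) <= ds + 1e-9

    def test_idempotent_on_flat_curve(self):
        curve = make_curve()
        once = correct_baseline(curve)
        twice = correct_baseline(once)
        assert np.allclose(once.retract_force, twice.retract_force, atol=1e-9)
        assert np.allclose(once.approach_force, twice.approach_force, atol=1e-9)

    def test_short_retract_raises(self):
        curve = make_curve(n=40)
        with pytest.raises(sb.InputError):
            correct_baseline(curve)


class TestRuptureDetection:
    def test_requires_corrected_curve(self):
        with pytest.raises(sb.StateError):
            detect_ruptures(make_curve())

    def test_flat_noiseless_retract_no_events(self):
        corr = correct_baseline(make_curve())
        assert detect_ruptures(corr) == []

    def test_constructed_sawtooth_at_25_nm(self):
        sep = np.linspace(-10.0, 100.0, 441)  # 0.25 nm spacing, 25 on grid
        retract = np.where(sep < 0, -60.0 * sep, 0.0)
        ramp = (sep > 25.0 - 49.5 / 3.0) & (sep <= 25.0)
        retract[ramp] -= 3.0 * (sep[ramp] - (25.0 - 49.5 / 3.0))
        curve = ForceCurve(
            approach_separation=sep[::-1].copy(),
            approach_force=np.where(sep < 0, -60.0 * sep, 0.0)[::-1],
            retract_separation=sep, retract_force=retract,
            spring_constant=0.06, loading_rate=1e4,
        )
        events = detect_ruptures(correct_baseline(curve))
        assert len(events) == 1
        evt = events[0]
        assert evt.specific
        assert evt.force == pytest.approx(49.5, abs=0.5)
        assert evt.separation == pytest.approx(25.0, abs=0.5)

    def test_nonspecific_adhesion_flagged_not_specific(self, clean_force_config):
        cfg = clean_force_config.model_copy(
            update={"p_nonspecific": 1.0, "noise_sd": 1.0}
        )
        curve, _ = simulate_force_curve(False, cfg)
        events = detect_ruptures(correct_baseline(curve))
        assert len(events) >= 1
        assert not any(e.specific for e in events)
        assert all(e.distance_from_contact < 10.0 for e in events)

    def test_sensitivity_and_false_rate(self):
        cfg = ForceConfig(seed=41, n_curves=1000, p_specific=0.2)
        curves, truth = simulate_force_curves(cfg)
        tp = fp = 0
        for curve, has in zip(curves, truth.has_specific):
            events = detect_ruptures(correct_baseline(curve))
            found = any(e.specific for e in events)
            if has and found:
                tp += 1
            if not has and found:
                fp += 1
        n_true = int(truth.has_specific.sum())
        assert tp / n_true >= 0.95
        assert fp / (1000 - n_true) <= 0.02

    def test_translation_and_scale_covariance(self, clean_force_config):
        cfg = clean_force_config.model_copy(update={"noise_sd": 2.0})
        curve, _ = simulate_force_curve(True, cfg)
        corr = correct_baseline(curve)
        events = detect_ruptures(corr)
        shifted = replace(
            corr,
            approach_separation=corr.approach_separation + 37.0,
            retract_separation=corr.retract_separation + 37.0,
            contact_nm=corr.contact_nm + 37.0,
        )
        ev_shift = detect_ruptures(shifted)
        assert [e.force for e in ev_shift] == [e.force for e in events]
        assert [e.separation for e in ev_shift] == pytest.approx(
            [e.separation + 37.0 for e in events]
        )
        scaled = replace(
            corr,
            approach_force=corr.approach_force * 2.5,
            retract_force=corr.retract_force * 2.5,
        )
        ev_scaled = detect_ruptures(scaled)
        assert [e.force for e in ev_scaled] == pytest.approx(
            [2.5 * e.force for e in events]
        )


class TestForceHistogram:
    def test_gaussian_sample_peak_recovered(self):
        rng = np.random.default_rng(50)
        forces = rng.normal(49.5, 10.0, 10_000)
        fit = fit_force_histogram(forces)
        assert fit.peak == pytest.approx(49.5, abs=0.5)
        assert fit.good_fit

    def test_peak_close_to_median_for_symmetric_sample(self):
        rng = np.random.default_rng(51)
        forces = rng.normal(60.0, 12.0, 5000)
        fit = fit_force_histogram(forces)
        assert abs(fit.peak - np.median(forces)) <= 2 * fit.bin_width

    def test_identical_forces_degenerate(self):
        with pytest.raises(sb.FitError):
            fit_force_histogram([50.0] * 100)

    def test_too_few_forces(self):
        with pytest.raises(sb.InputError):
            fit_force_histogram(np.arange(10.0))

    def test_bimodal_flags_poor_fit(self):
        rng = np.random.default_rng(52)
        forces = np.concatenate(
            [rng.normal(30, 4, 3000), rng.normal(80, 4, 3000)]
        )
        fit = ForceHistogramModel(forces).fit()
        assert not fit.good_fit
        assert fit.goodness < 0.8


class TestBindingProbability:
    def test_no_events_zero_percent(self):
        bp = binding_probability({"e1": [False] * 60})
        assert bp.probability == 0.0
        assert bp.single_molecule_regime

    def test_all_events_100_percent(self):
        bp = binding_probability({"e1": [True] * 60, "e2": [True] * 60})
        assert bp.probability == 100.0
        assert not bp.single_molecule_regime

    def test_mean_and_sem_across_experiments(self):
        flags = {
            "e1": [True] * 20 + [False] * 80,
            "e2": [True] * 25 + [False] * 75,
            "e3": [True] * 30 + [False] * 70,
        }
        bp = binding_probability(flags)
        assert bp.probability == pytest.approx(25.0)
        assert bp.sem == pytest.approx(5.0 / np.sqrt(3))
        assert bp.n_with_event == 75 and bp.n_total == 300
        assert bp.single_molecule_regime

    def test_min_curve_count_enforced(self):
        with pytest.raises(sb.InputError):
            binding_probability({"e1": [True] * 10})

    def test_empty_input(self):
        with pytest.raises(sb.InputError):
            binding_probability({})


class TestCompareForces:
    def test_wraps_exact_mannwhitney(self):
        res = compare_forces([1.0, 2.0], [3.0, 4.0], alternative="less")
        assert res.pvalue == pytest.approx(1 / 6)

    def test_small_samples_rejected(self):
        with pytest.raises(sb.InputError):
            compare_forces([1.0], [2.0, 3.0])
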