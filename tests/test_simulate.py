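"""Generator correctness: constructions, determinism, marginal statistics."""

import numpy as np
import pytest

import smolbind as sb
from smolbind.simulate import (
    BindingSimConfig,
    ForceConfig,
    MovieConfig,
    TWOFOLD_SERIES_UM,
    simulate_binding_series,
    simulate_force_curve,
    simulate_force_curves,
    simulate_photobleach_trace,
    simulate_tirfm_movie,
    write_movie_tiff,
    read_movie_tiff,
)
from smolbind._util import spawn_rng

from _oracles import binomial_interval


# ----------------------------------------------------------------- traces

class TestPhotobleachTraces:
    def test_noiseless_single_step_construction(self, noiseless_movie_config):
        trace, bf = simulate_photobleach_trace(
            1, noiseless_movie_config, bleach_frames=[100]
        )
        u = noiseless_movie_config.unit_intensity
        assert np.all(trace.values[:100] == u)
        assert np.all(trace.values[100:] == 0.0)
        assert list(bf) == [100]

    def test_noiseless_two_fluorophores_levels(self, noiseless_movie_config):
        trace, _ = simulate_photobleach_trace(
            2, noiseless_movie_config, bleach_frames=[80, 150]
        )
        u = noiseless_movie_config.unit_intensity
        levels = np.unique(trace.values)
        assert set(levels) == {0.0, u, 2 * u}
        drops = np.nonzero(np.diff(trace.values) < 0)[0]
        assert list(drops + 1) == [80, 150]

    def test_mean_first_level_matches_two_units(self, movie_config):
        """Monte-Carlo: first-segment mean of dimer traces ~ 2 * unit."""
        rng = spawn_rng(movie_config.seed, 0)
        first_means, per_trace_var = [], []
        for _ in range(10_000):
            trace, bf = simulate_photobleach_trace(2, movie_config, rng)
            first = int(bf[0])
            if first >= 5:
                seg = trace.values[:first]
                first_means.append(seg.mean())
                per_trace_var.append(seg.var(ddof=1) / seg.size)
        first_means = np.asarray(first_means)
        se = first_means.std(ddof=1) / np.sqrt(first_means.size)
        expected = 2 * movie_config.unit_intensity
        assert abs(first_means.mean() - expected) < 3 * se

    def test_noiseless_traces_piecewise_constant_non_increasing(
        self, noiseless_movie_config
    ):
        rng = spawn_rng(99, 0)
        for _ in range(50):
            trace, bf = simulate_photobleach_trace(3, noiseless_movie_config, rng)
            levels = trace.values
            # level changes only at ground-truth bleach frames
            change = np.nonzero(np.diff(levels) != 0)[0] + 1
            assert set(change) <= set(int(b) for b in bf)
            assert np.all(np.diff(levels) <= 0)

    def test_determinism(self, movie_config):
        t1, b1 = simulate_photobleach_trace(2, movie_config)
        t2, b2 = simulate_photobleach_trace(2, movie_config)
        assert np.array_equal(t1.values, t2.values)
        assert np.array_equal(b1, b2)

    def test_invalid_fluorophore_count(self, movie_config):
        with pytest.raises(sb.ConfigError):
            simulate_photobleach_trace(4, movie_config)

    def test_fraction_validation(self):
        with pytest.raises(Exception):
            MovieConfig(seed=1, fraction_monomer=0.5, fraction_dimer=0.4,
                        fraction_trimer=0.2)


# ----------------------------------------------------------------- movies

class TestTirfmMovies:
    def test_background_only_stack(self):
        cfg = MovieConfig(seed=5, n_spots=0, image_size=(48, 48), n_frames=40)
        stack, truth = simulate_tirfm_movie(cfg)
        n = stack.size
        se = np.sqrt(cfg.background_level + cfg.read_noise_sd**2) / np.sqrt(n)
        assert abs(stack.mean() - cfg.background_level) < 3 * se
        assert truth.counts.size == 0

    def test_single_monomer_noiseless_reproduces_trace(self):
        cfg = MovieConfig(seed=6, n_spots=1, image_size=(48, 48), n_frames=60,
                          fraction_monomer=1.0, fraction_dimer=0.0,
                          fraction_trimer=0.0, shot_noise=False)
        stack, truth = simulate_tirfm_movie(cfg)
        r, c = (int(round(v)) for v in truth.centers[0])
        region = stack[:, r - 2: r + 3, c - 2: c + 3].sum(axis=(1, 2))
        signal = region - 25.0 * cfg.background_level
        bf = truth.bleach_frames[0]
        expected_on = np.arange(cfg.n_frames) < bf[0]
        # trace shape recovered exactly up to the constant 5x5 PSF capture
        on_vals = signal[expected_on]
        off_vals = signal[~expected_on]
        if on_vals.size:
            assert np.allclose(on_vals, on_vals[0], atol=1e-9)
            capture = on_vals[0] / cfg.unit_intensity
            assert 0.5 < capture <= 1.0
        assert np.allclose(off_vals, 0.0, atol=1e-9)

    def test_dimer_count_within_binomial_interval(self):
        cfg = MovieConfig(seed=7, n_spots=200, image_size=(220, 220), n_frames=20,
                          fraction_monomer=0.6, fraction_dimer=0.4,
                          fraction_trimer=0.0, shot_noise=False)
        _, truth = simulate_tirfm_movie(cfg)
        lo, hi = binomial_interval(200, 0.4, level=0.99)
        assert lo <= np.sum(truth.counts == 2) <= hi

    def test_min_pairwise_separation(self):
        cfg = MovieConfig(seed=8, n_spots=60, image_size=(128, 128), n_frames=20)
        _, truth = simulate_tirfm_movie(cfg)
        c = truth.centers
        d = np.sqrt(((c[:, None, :] - c[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 4 * cfg.psf_sigma

    def test_infeasible_placement_raises(self):
        cfg = MovieConfig(seed=9, n_spots=500, image_size=(32, 32), n_frames=20)
        with pytest.raises(sb.PlacementError):
            simulate_tirfm_movie(cfg)

    def test_tiff_round_trip(self, tmp_path):
        cfg = MovieConfig(seed=10, n_spots=3, image_size=(48, 48), n_frames=25)
        stack, _ = simulate_tirfm_movie(cfg)
        path = tmp_path / "movie.tif"
        write_movie_tiff(path, stack)
        back = read_movie_tiff(path)
        assert back.shape == stack.shape
        assert back.dtype == np.uint16
        assert np.array_equal(back, np.clip(np.round(stack), 0, 65535))

    def test_ground_truth_consistent_with_noiseless_render(self):
        cfg = MovieConfig(seed=11, n_spots=4, image_size=(64, 64), n_frames=50,
                          shot_noise=False)
        stack, truth = simulate_tirfm_movie(cfg)
        for center, bf in zip(truth.centers, truth.bleach_frames):
            r, c = (int(round(v)) for v in center)
            region = stack[:, r - 2: r + 3, c - 2: c + 3].sum(axis=(1, 2))
            jumps = set((np.nonzero(np.abs(np.diff(region)) > 1e-6)[0] + 1).tolist())
            assert jumps == {int(b) for b in bf if b < cfg.n_frames}


# ----------------------------------------------------------------- forces

class TestForceCurves:
    def test_flat_retract_without_events(self, clean_force_config):
        curve, f = simulate_force_curve(False, clean_force_config)
        assert f is None
        mask = curve.retract_separation > 0
        assert np.allclose(curve.retract_force[mask], 0.0, atol=1e-9)

    def test_constructed_rupture_magnitude(self, clean_force_config):
        cfg = clean_force_config.model_copy(
            update={"specific_force_mean": 49.5, "specific_force_sd": 0.0}
        )
        curve, f = simulate_force_curve(True, cfg)
        assert f == pytest.approx(49.5)
        drops = np.diff(curve.retract_force)
        assert drops.max() == pytest.approx(49.5, abs=cfg.tether_stiffness
                                            * np.diff(curve.retract_separation)[0])

    def test_event_fraction_binomial(self):
        cfg = ForceConfig(seed=20, n_curves=1000, p_specific=0.2,
                          points_per_segment=60)
        _, truth = simulate_force_curves(cfg)
        lo, hi = binomial_interval(1000, 0.2, level=0.99)
        assert lo <= truth.has_specific.sum() <= hi

    def test_determinism(self):
        cfg = ForceConfig(seed=21, n_curves=5, points_per_segment=80)
        c1, t1 = simulate_force_curves(cfg)
        c2, t2 = simulate_force_curves(cfg)
        for a, b in zip(c1, c2):
            assert np.array_equal(a.retract_force, b.retract_force)
        assert t1.equals(t2)


# ---------------------------------------------------------------- binding

class TestBindingSeries:
    def test_half_saturation_identity(self):
        cfg = BindingSimConfig(seed=1, true_KD=15.9, Rmax=100.0,
                               concentrations=[15.9, 1.0, 2.0, 4.0])
        series = simulate_binding_series(cfg)
        assert series.responses[0] == pytest.approx(50.0)

    def test_competition_midpoint(self):
        cfg = BindingSimConfig(seed=1, mode="competition", true_logIC50=-4.16,
                               concentrations=[10**-4.16, 1e-6, 1e-5, 1e-3])
        series = simulate_binding_series(cfg)
        assert series.responses[0] == pytest.approx(50.0)

    def test_top_dose_closed_form(self):
        """R(62.5; KD=15.9, Rmax=100) = 100*62.5/78.4 = 79.719..."""
        cfg = BindingSimConfig(seed=1, true_KD=15.9, Rmax=100.0)
        series = simulate_binding_series(cfg)
        top = series.responses[np.argmax(series.concentrations)]
        assert top == pytest.approx(100.0 * 62.5 / 78.4, abs=1e-9)

    def test_default_series_is_twofold_dilution(self):
        c = np.asarray(TWOFOLD_SERIES_UM)
        assert c.max() == pytest.approx(62.5)
        assert c.min() == pytest.approx(1.953125)
        assert np.allclose(c[1:] / c[:-1], 2.0)

    def test_noise_and_determinism(self):
        cfg = BindingSimConfig(seed=2, noise_sd=2.0)
        s1 = simulate_binding_series(cfg)
        s2 = simulate_binding_series(cfg)
        assert np.array_equal(s1.responses, s2.responses)
        clean = simulate_binding_series(cfg.model_copy(update={"noise_sd": 0.0}))
        assert not np.allclose(s1.responses, clean.responses)
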