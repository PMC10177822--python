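"""Profile extraction and steepest-slope estimation against analytic truth."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from ctiq import phantom, profiles
from ctiq.errors import ConfigError, DegenerateProfileError, SamplingError

from conftest import aligned_spec, centered_border


def make_profile(positions, values):
    return profiles.Profile(np.asarray(positions, float),
                            np.asarray(values, float))


def template_profile(step=0.1, half=4.5, hu_high=50.0, hu_low=-100.0,
                     slope=-150.0):
    m = int(round(half / step))
    pos = (np.arange(2 * m + 1) - m) * step
    return make_profile(pos, phantom.edge_template(pos, hu_high, hu_low, slope))


class TestExtractProfiles:
    def test_station_geometry_vertical_border(self, noiseless_phantom):
        spec, image, _ = noiseless_phantom
        border = centered_border(spec, length_mm=9.0)
        profs = profiles.extract_profiles(image, border)
        assert len(profs) == 10
        ys = [p.station_mm[1] for p in profs]
        assert np.allclose(np.diff(ys), 1.0)  # stations 1 mm apart
        xs = {p.station_mm[0] for p in profs}
        assert len(xs) == 1  # border is vertical, stations share x

    def test_noiseless_profiles_match_template_exactly(self, noiseless_phantom):
        spec, image, _ = noiseless_phantom
        profs = profiles.extract_profiles(image, centered_border(spec))
        for p in profs:
            expected = phantom.edge_template(p.positions, 50, -100, -150)
            assert np.max(np.abs(p.values - expected)) < 1e-9
            assert p.positions[0] == pytest.approx(-4.5)
            assert p.positions[-1] == pytest.approx(4.5)

    def test_rotated_profiles_match_template_away_from_kinks(self):
        spec = aligned_spec(width_mm=40.0, height_mm=40.0, edge_angle_deg=30.0)
        image, truth = phantom.generate_edge_phantom(spec)
        profs = profiles.extract_profiles(image, centered_border(spec))
        s = spec.pixel_spacing_mm
        w = truth.transition_width_mm
        for p in profs:
            expected = phantom.edge_template(p.positions, 50, -100, -150)
            err = np.abs(p.values - expected)
            # bilinear is exact on plateau/ramp cells; only cells straddling
            # the two kink lines deviate, bounded by |slope| * spacing / 2
            kink_dist = np.minimum(np.abs(p.positions + w / 2),
                                   np.abs(p.positions - w / 2))
            far = kink_dist > 1.5 * s * math.sqrt(2)
            assert err[far].max() < 1e-9
            assert err.max() <= abs(spec.edge_slope_hu_per_mm) * s / 2

    def test_sample_outside_raster_names_station(self, noiseless_phantom):
        spec, image, _ = noiseless_phantom
        cx, cy = image.center_mm
        # border hugs the left margin; horizontal profiles leave the raster
        border = profiles.BorderSpec((1.0, cy - 4.5), (1.0, cy + 4.5))
        with pytest.raises(SamplingError, match="station 0"):
            profiles.extract_profiles(image, border)

    def test_single_station_is_midpoint(self, noiseless_phantom):
        spec, image, _ = noiseless_phantom
        border = centered_border(spec, n_profiles=1)
        (p,) = profiles.extract_profiles(image, border)
        assert p.station_mm == pytest.approx(image.center_mm)


class TestBaselines:
    def test_exact_on_noiseless_template(self):
        upper, lower = profiles.estimate_baselines(template_profile())
        assert upper == pytest.approx(50.0, abs=1e-12)
        assert lower == pytest.approx(-100.0, abs=1e-12)

    def test_constant_profile_flagged(self):
        pos = np.linspace(-4.5, 4.5, 91)
        with pytest.raises(DegenerateProfileError):
            profiles.estimate_baselines(make_profile(pos, np.full(91, 42.0)))

    def test_too_few_plateau_samples_rejected(self):
        pos = np.linspace(-4.5, 4.5, 15)
        vals = phantom.edge_template(pos, 50, -100, -150)
        with pytest.raises(ConfigError):
            profiles.estimate_baselines(make_profile(pos, vals),
                                        plateau_fraction=0.1)

    def test_noisy_baselines_within_standard_error(self, rng):
        # 91 samples per side at 0.1 mm, fraction 0.25 -> plateau mean of 22
        errs_u, errs_l = [], []
        for _ in range(50):
            p = template_profile(step=0.1, half=9.1 / 2)
            noisy = make_profile(p.positions,
                                 p.values + rng.normal(0, 5, p.values.shape))
            u, l = profiles.estimate_baselines(noisy)
            errs_u.append(u - 50.0)
            errs_l.append(l + 100.0)
        bound = 3 * 5 / np.sqrt(22)
        assert np.percentile(np.abs(errs_u), 95) < bound
        assert np.percentile(np.abs(errs_l), 95) < bound


class TestSteepestSlope:
    def test_exact_on_linear_ramp(self):
        a = profiles.steepest_slope(template_profile(step=0.1))
        assert a.steepest_slope_hu_per_mm == pytest.approx(-150.0, abs=1e-6)
        assert a.distance_mm == pytest.approx(-0.2)
        assert not a.no_transition
        assert a.upper_baseline_hu > a.lower_baseline_hu

    def test_constant_profile_flagged_no_transition(self):
        pos = np.linspace(-4.5, 4.5, 91)
        a = profiles.steepest_slope(make_profile(pos, np.full(91, 42.0)))
        assert a.no_transition
        assert a.steepest_slope_hu_per_mm == 0.0
        assert a.distance_mm == 0.0

    def test_nonuniform_sampling_rejected(self):
        pos = np.array([-1.0, -0.5, 0.0, 0.3, 1.0])
        with pytest.raises(ConfigError):
            profiles.steepest_slope(make_profile(pos, np.zeros(5)))

    def test_tie_broken_toward_border(self):
        # two separated ramps of equal steepness; the window nearest 0 wins
        pos = np.linspace(-4.5, 4.5, 91)
        vals = (phantom.edge_template(pos + 3.0, 50, 0, -50)
                + phantom.edge_template(pos - 1.0, 0, -50, -50))
        a = profiles.steepest_slope(make_profile(pos, vals))
        assert abs(a.slope_window_center_mm - 1.0) < 0.6

    def test_noisy_slope_median_bias_below_15pct(self):
        truth = -150.0
        medians = []
        for seed in range(200):
            spec = phantom.PhantomSpec(width_mm=24, height_mm=24,
                                       pixel_spacing_mm=0.25,
                                       noise_sd_hu=5.0, seed=seed)
            image, _ = phantom.generate_edge_phantom(spec)
            profs = profiles.extract_profiles(image, centered_border(spec))
            s = profiles.summarize(profiles.analyze_profiles(profs))
            medians.append(s.median_slope_hu_per_mm)
        bias = (np.median(medians) - truth) / truth
        assert 0 <= bias < 0.15  # 3-point windows bias steeper, bounded


class TestSummarize:
    def test_identical_analyses_are_idempotent(self):
        a = profiles.ProfileAnalysis(50.0, -100.0, -150.0, 0.0, -0.2)
        s = profiles.summarize([a] * 10)
        assert s.median_slope_hu_per_mm == -150.0
        assert s.median_upper_hu == 50.0
        assert s.median_distance_mm == -0.2

    def test_even_count_median_is_central_mean(self):
        analyses = [profiles.ProfileAnalysis(50.0, -100.0, float(-k), 0.0, -0.2)
                    for k in range(1, 11)]
        assert profiles.summarize(analyses).median_slope_hu_per_mm == -5.5

    def test_empty_list_rejected(self):
        with pytest.raises(ConfigError):
            profiles.summarize([])

    @settings(deadline=None, max_examples=25)
    @given(perm=hst.permutations(list(range(10))))
    def test_permutation_invariance(self, perm):
        analyses = [profiles.ProfileAnalysis(50.0 + k, -100.0 - k,
                                             -100.0 - 7 * k, 0.0, -0.2)
                    for k in range(10)]
        base = profiles.summarize(analyses)
        shuffled = profiles.summarize([analyses[i] for i in perm])
        assert shuffled == base


class TestSlopeRecovery:
    @pytest.mark.parametrize("slope", [-50.0, -100.0, -168.4, -300.0])
    @pytest.mark.parametrize("spacing", [0.234, 0.469])
    def test_noiseless_recovery_within_2pct_up_to_resolution_limit(
            self, slope, spacing):
        # the 3-point difference at step spacing/2 cannot report magnitudes
        # beyond contrast / (2 * spacing); resolved slopes recover exactly
        spec = phantom.PhantomSpec(width_mm=26, height_mm=26,
                                   pixel_spacing_mm=spacing,
                                   edge_slope_hu_per_mm=slope, noise_sd_hu=0.0)
        image, _ = phantom.generate_edge_phantom(spec)
        profs = profiles.extract_profiles(image, centered_border(spec))
        s = profiles.summarize(profiles.analyze_profiles(profs))
        contrast = spec.hu_high - spec.hu_low
        expected = -min(abs(slope), contrast / (2 * spacing))
        assert abs(s.median_slope_hu_per_mm - expected) <= 0.02 * abs(expected)

    def test_steeper_truth_never_estimated_shallower(self):
        # equal noise: resolution ordering must be preserved
        for seed in range(20):
            ests = {}
            for slope, spacing in [(-168.4, 0.234), (-94.5, 0.469)]:
                spec = phantom.PhantomSpec(width_mm=24, height_mm=24,
                                           pixel_spacing_mm=spacing,
                                           edge_slope_hu_per_mm=slope,
                                           noise_sd_hu=5.0, seed=seed)
                image, _ = phantom.generate_edge_phantom(spec)
                profs = profiles.extract_profiles(image, centered_border(spec))
                s = profiles.summarize(profiles.analyze_profiles(profs))
                ests[slope] = s.median_slope_hu_per_mm
            assert abs(ests[-168.4]) > abs(ests[-94.5])
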