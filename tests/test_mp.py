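"""Mass-photometry analysis: calibration, histogramming, mixture fits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from capsidkit import (build_histogram, detect_antibody_binding, ep_ratio,
                       fit_mass_calibration, fit_species_mixture,
                       noise_threshold, simulate_mp_events, unbinding_fraction)
from capsidkit.mp import MixtureComponent, SpeciesMixtureFit


def _mix(areas, means=None, sds=None):
    means = means or {"EP": 3.73e6, "FP": 4.51e6, "OP": 5.3e6}
    sds = sds or {}
    comps = [MixtureComponent(k, means.get(k, 4e6), sds.get(k, 1.5e5), v)
             for k, v in areas.items()]
    return SpeciesMixtureFit(comps, 5e4, 0.0, sum(areas.values()))


class TestCalibration:
    def test_two_point_line_is_exact(self):
        cal = fit_mass_calibration([("BSA", 66_000, 1.0), ("thyro", 660_000, 10.0)])
        assert cal.to_mass(1.0) == pytest.approx(66_000)
        assert cal.to_mass(10.0) == pytest.approx(660_000)

    def test_noiseless_line_recovered(self):
        slope, icpt = 6.5e4, 1.0e3
        stds = [(f"s{i}", slope * c + icpt, c) for i, c in enumerate([1.0, 5.0, 9.0])]
        cal = fit_mass_calibration(stds)
        assert cal.slope == pytest.approx(slope, rel=1e-12)
        assert cal.intercept == pytest.approx(icpt, rel=1e-9)

    def test_residuals_match_ols_oracle(self):
        contrast = np.array([1.0, 2.0, 3.0])
        mass = np.array([70_000.0, 128_000.0, 195_000.0])
        cal = fit_mass_calibration([("a", mass[0], 1.0), ("b", mass[1], 2.0),
                                    ("c", mass[2], 3.0)])
        # closed-form OLS oracle
        X = np.vstack([contrast, np.ones(3)]).T
        beta, *_ = np.linalg.lstsq(X, mass, rcond=None)
        assert np.allclose(cal.residuals, mass - X @ beta)

    def test_duplicate_contrasts_rejected(self):
        with pytest.raises(ValueError):
            fit_mass_calibration([("a", 1e5, 1.0), ("b", 2e5, 1.0)])


class TestHistogram:
    def test_all_events_in_one_bin(self):
        edges, counts = build_histogram([2.51e6] * 10, 5e4, (2e6, 3e6))
        assert counts.sum() == 10
        assert counts.max() == 10

    def test_edge_event_goes_to_upper_bin(self):
        edges, counts = build_histogram([2.05e6], 5e4, (2e6, 3e6))
        i = np.nonzero(counts)[0][0]
        assert edges[i] == pytest.approx(2.05e6)

    def test_conservation_of_in_range_events(self):
        rng = np.random.default_rng(0)
        m = rng.uniform(1.5e6, 7.5e6, 1000)
        edges, counts = build_histogram(m, 5e4, (2e6, 7e6))
        assert counts.sum() == np.count_nonzero((m >= 2e6) & (m < edges[-1]))

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            build_histogram([1.0], 5e4, (3e6, 2e6))


class TestMixtureFit:
    def test_three_component_recovery_over_seeds(self):
        comps = [("EP", 3.73e6, 1.5e5, 0.2), ("FP", 4.51e6, 1.5e5, 0.6),
                 ("OP", 5.30e6, 1.5e5, 0.2)]
        truth = {"EP": (3.73e6, 0.2), "FP": (4.51e6, 0.6), "OP": (5.30e6, 0.2)}
        for seed in range(20):
            ev = simulate_mp_events(comps, 5000, 0.0, seed=seed)
            hist = build_histogram(ev["mass_da"])
            fit = fit_species_mixture(hist, [("EP", 3.73e6), ("FP", 4.51e6),
                                             ("OP", 5.30e6)])
            total = sum(c.area for c in fit.components)
            for c in fit.components:
                mean, w = truth[c.label]
                assert c.mean == pytest.approx(mean, rel=0.02)
                assert c.area / total == pytest.approx(w, abs=0.03)

    def test_single_component_area_conserves_counts(self):
        ev = simulate_mp_events([("FP", 4.51e6, 1.5e5, 1.0)], 5000, 0.0, seed=1)
        fit = fit_species_mixture(build_histogram(ev["mass_da"]), [("FP", 4.51e6)])
        assert fit.components[0].area == pytest.approx(5000, rel=0.01)

    def test_degenerate_components_merged_with_warning(self):
        ev = simulate_mp_events([("FP", 4.51e6, 1.5e5, 1.0)], 3000, 0.0, seed=2)
        hist = build_histogram(ev["mass_da"])
        with pytest.warns(UserWarning, match="collapsed"):
            fit = fit_species_mixture(hist, [("A", 4.50e6), ("B", 4.52e6)])
        assert len(fit.components) == 1

    def test_empty_histogram_rejected(self):
        edges = np.arange(2e6, 3e6, 5e4)
        with pytest.raises(ValueError):
            fit_species_mixture((edges, np.zeros(len(edges) - 1)), [("FP", 2.5e6)])


class TestEPRatio:
    def test_zero_ep_area(self):
        r = ep_ratio(_mix({"EP": 0.0, "FP": 100.0}))
        assert r.ep_ratio == 0.0 and not r.significant

    def test_arithmetic_and_significance(self):
        r = ep_ratio(_mix({"EP": 30.0, "FP": 60.0, "OP": 10.0}))
        assert r.ep_ratio == pytest.approx(0.30)
        assert r.significant
        r2 = ep_ratio(_mix({"EP": 10.0, "FP": 90.0}))
        assert r2.ep_ratio == pytest.approx(0.10)
        assert not r2.significant

    def test_missing_fp_component(self):
        with pytest.raises(KeyError):
            ep_ratio(_mix({"EP": 10.0}))

    @given(scale=st.floats(0.01, 100.0))
    @settings(derandomize=True, max_examples=30)
    def test_invariant_under_area_rescaling(self, scale):
        base = ep_ratio(_mix({"EP": 30.0, "FP": 60.0, "OP": 10.0}))
        scaled = ep_ratio(_mix({"EP": 30.0 * scale, "FP": 60.0 * scale,
                                "OP": 10.0 * scale}))
        assert scaled.ep_ratio == pytest.approx(base.ep_ratio, rel=1e-12)


class TestNoiseThreshold:
    def test_control_sample_constant(self):
        assert noise_threshold(0.077, 0.023) == pytest.approx(0.146)

    def test_degenerate_cases(self):
        assert noise_threshold(0.1, 0.0) == 0.1
        assert noise_threshold(0.1, 0.05, k=0) == 0.1


class TestUnbinding:
    def test_counts_match_brute_force(self):
        rng = np.random.default_rng(0)
        m = rng.normal(0, 1, 500)
        assert unbinding_fraction(m) == sum(1 for x in m if x < 0) / len(m)

    def test_all_positive_and_zero_tie(self):
        assert unbinding_fraction([1.0, 2.0, 0.0]) == 0.0

    def test_simple_fraction(self):
        assert unbinding_fraction([-1, -2, -3, 1, 2, 3, 4, 5, 6, 7]) == pytest.approx(0.3)


class TestAntibodyShift:
    def test_identical_fits_not_bound(self):
        mix = _mix({"FP": 3000.0})
        bound, shift, _ = detect_antibody_binding(mix, mix)
        assert shift == 0.0 and not bound

    def test_synthetic_positive_shift_detected(self):
        pre = simulate_mp_events([("FP", 4.51e6, 1.5e5, 1.0)], 3000, 0.0, seed=4)
        post = simulate_mp_events([("FP", 5.41e6, 1.5e5, 1.0)], 3000, 0.0, seed=5)
        fit_pre = fit_species_mixture(build_histogram(pre["mass_da"]), [("FP", 4.51e6)])
        fit_post = fit_species_mixture(build_histogram(post["mass_da"]), [("FP", 5.41e6)])
        bound, shift, thresh = detect_antibody_binding(fit_pre, fit_post)
        assert bound
        assert shift == pytest.approx(0.9e6, rel=0.05)

    def test_shift_below_threshold_not_bound(self):
        pre = _mix({"FP": 3000.0}, means={"FP": 4.51e6})
        post = _mix({"FP": 3000.0}, means={"FP": 4.511e6})
        bound, shift, thresh = detect_antibody_binding(pre, post, min_shift=5e4)
        assert shift == pytest.approx(1e3) and not bound
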