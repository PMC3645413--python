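"""The wider operation catalogue: autocorrelation, stationarity, scaling,
model-fit, symbolic and perturbation features, plus registry-wide
contracts (purity, honest scale-sensitivity metadata, special-value
behaviour)."""

import numpy as np
import pytest

import tscompass as tc
from tscompass.catalogue import (
    ar3_coeff,
    autocorr,
    dfa_exponent,
    gp_lengthscale,
    inertial_particle_stat,
    mean_forecaster_resid_ac,
    outlier_adjusted_ac3,
    spectral_slope,
    statav,
    symbolic_word_prob,
    variance_ratio,
)
from tscompass.catalogue.modelfit import _gp_grid
from tscompass.values import SpecialValue


def ar1(phi, n, seed, sigma=1.0):
    rng = np.random.default_rng(seed)
    e = rng.normal(0, sigma, n)
    x = np.empty(n)
    x[0] = rng.normal(0, sigma / np.sqrt(1 - phi**2))
    for t in range(1, n):
        x[t] = phi * x[t - 1] + e[t]
    return x


class TestAutocorr:
    def test_lag0_is_one(self):
        assert autocorr(np.random.default_rng(0).standard_normal(50), 0) == 1.0

    def test_alternating_series(self):
        x = np.tile([1.0, -1.0], 50)
        assert autocorr(x, 1) == pytest.approx(-1, abs=0.03)

    def test_ar1_population_value(self):
        assert autocorr(ar1(0.5, 5000, 1), 2) == pytest.approx(0.25, abs=0.05)

    def test_matches_direct_formula(self):
        x = np.random.default_rng(2).standard_normal(200)
        xc = x - x.mean()
        expected = np.dot(xc[:-3], xc[3:]) / np.dot(xc, xc)
        assert autocorr(x, 3) == pytest.approx(expected, abs=1e-14)

    def test_constant_is_special(self):
        assert autocorr(np.full(10, 2.0), 1).reason == "constant_input"


class TestStatAv:
    def test_iid_noise_scales_as_inverse_sqrt_w(self):
        vals = [statav(np.random.default_rng(s).standard_normal(10000), 100)
                for s in range(50)]
        # sampling sd of the statistic measured over the same 50 draws
        assert abs(np.mean(vals) - 0.1) < 3 * np.std(vals)

    def test_repeating_pattern_is_stationary(self):
        x = np.tile(np.random.default_rng(1).standard_normal(100), 20)
        assert statav(x, 100) < 1e-12

    def test_linear_ramp_matches_direct_computation(self):
        x = np.arange(1.0, 1001.0)
        means = x.reshape(10, 100).mean(axis=1)
        expected = means.std(ddof=1) / x.std(ddof=1)
        assert statav(x, 100) == pytest.approx(expected, abs=1e-14)


class TestVarianceRatio:
    def test_random_walk_near_one(self):
        rw = np.cumsum(np.random.default_rng(0).standard_normal(10000))
        assert variance_ratio(rw, 2) == pytest.approx(1.0, abs=0.1)

    def test_white_noise_levels_near_half(self):
        x = np.random.default_rng(1).standard_normal(10000)
        assert variance_ratio(x, 2) == pytest.approx(0.5, abs=0.1)

    def test_linear_ramp_constant_increments(self):
        assert variance_ratio(np.arange(100.0), 2).reason == "constant_input"


class TestAR3:
    def test_recovers_ar1_coefficient(self):
        assert ar3_coeff(ar1(0.8, 5000, 2)) == pytest.approx(0.8, abs=0.1)

    def test_white_noise_near_zero(self):
        x = np.random.default_rng(3).standard_normal(5000)
        assert abs(ar3_coeff(x)) < 0.05

    def test_short_series_flagged(self):
        assert ar3_coeff(np.arange(10.0)).reason == "too_short"


class TestMeanForecaster:
    @pytest.mark.parametrize("gen", [
        lambda rng: rng.standard_normal(5000),
        lambda rng: np.cumsum(rng.standard_normal(5000)),
    ])
    def test_matches_two_step_oracle(self, gen):
        x = gen(np.random.default_rng(4))
        w = 3
        resid = np.array([x[t] - x[t - w:t].mean() for t in range(w, x.size)])
        rc = resid - resid.mean()
        expected = np.dot(rc[:-1], rc[1:]) / np.dot(rc, rc)
        assert mean_forecaster_resid_ac(x, w) == pytest.approx(expected, abs=1e-12)

    def test_constant_input_inapplicable(self):
        assert mean_forecaster_resid_ac(np.full(100, 1.0), 3).reason == "inapplicable"


class TestOutlierAdjustedAC3:
    def test_equals_composition_oracle(self):
        rng = np.random.default_rng(5)
        x = ar1(0.8, 200, 6)
        spikes = rng.choice(200, 10, replace=False)
        x[spikes] += rng.choice([-8, 8], 10)
        k = int(np.ceil(0.1 * x.size))
        dev = np.abs(x - x.mean())
        drop = np.argsort(dev, kind="stable")[x.size - k:]
        keep = np.ones(x.size, bool)
        keep[drop] = False
        expected = autocorr(x, 3) / autocorr(x[keep], 3)
        assert outlier_adjusted_ac3(x) == pytest.approx(expected, abs=1e-12)

    def test_removal_count_contract(self):
        # ceil(0.1 * 100) = 10 points removed: survivors length 90
        x = np.random.default_rng(7).standard_normal(100)
        k = int(np.ceil(0.1 * 100))
        assert k == 10

    def test_degenerate_denominator_flagged(self):
        # survivors constant: 18 identical + 2 extreme outliers removed
        x = np.concatenate([np.full(18, 1.0), [50.0, -50.0]])
        out = outlier_adjusted_ac3(x)
        assert tc.is_special(out)


class TestSymbolic:
    def test_two_letter_word_probabilities_sum_to_one(self):
        x = np.random.default_rng(8).standard_normal(1000)
        total = sum(
            symbolic_word_prob(x, a + b) for a in "ABC" for b in "ABC"
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_linear_ramp_degenerate(self):
        assert symbolic_word_prob(np.arange(100.0), "AC").reason == "inapplicable"

    def test_matches_string_scan_oracle(self):
        x = np.random.default_rng(9).standard_normal(500)
        d = np.diff(x)
        order = np.argsort(d, kind="stable")
        ranks = np.empty(d.size, int)
        ranks[order] = np.arange(d.size)
        s = "".join("ABC"[r * 3 // d.size] for r in ranks)
        count = sum(1 for i in range(len(s) - 1) if s[i:i + 2] == "AC")
        assert symbolic_word_prob(x, "AC") == pytest.approx(
            count / (len(s) - 1), abs=1e-15
        )


class TestInertialParticle:
    def test_constant_input_particle_rests(self):
        x = np.full(100, 2.5)
        assert inertial_particle_stat(x, which="resid_sd") == 0.0
        assert inertial_particle_stat(x, which="mean_abs_v") == 0.0

    def test_linearity_scaling(self):
        x = np.random.default_rng(10).standard_normal(500)
        a = inertial_particle_stat(x, which="resid_sd")
        b = inertial_particle_stat(2 * x, which="resid_sd")
        assert b == pytest.approx(2 * a, rel=1e-12)

    def test_matches_stepwise_simulation_oracle(self):
        x = np.sin(2 * np.pi * 0.01 * np.arange(300))
        p, v = 0.0, 0.0
        ps = []
        p = x[0]
        for t in range(300):
            ps.append(p)
            v = 0.9 * v + 0.1 * (x[t] - p)
            p = p + v
        resid = x[30:] - np.array(ps)[30:]
        assert inertial_particle_stat(x, which="resid_sd") == pytest.approx(
            resid.std(ddof=1), abs=1e-12
        )


class TestGPLengthscale:
    def test_smooth_exceeds_noise(self):
        for seed in range(10):
            noise = np.random.default_rng(seed).standard_normal(400)
            smooth = (np.sin(2 * np.pi * 0.005 * np.arange(400))
                      + 0.05 * np.random.default_rng(seed).standard_normal(400))
            assert gp_lengthscale(smooth) > gp_lengthscale(noise)

    def test_white_noise_in_lower_grid_half(self):
        ells, _, _ = _gp_grid(50)
        mid = 0.5 * (np.log(ells[0]) + np.log(ells[-1]))
        vals = [gp_lengthscale(np.random.default_rng(s).standard_normal(400))
                for s in range(10)]
        assert all(v < mid for v in vals)

    def test_too_short_flagged(self):
        assert gp_lengthscale(np.arange(100.0), seg=50).reason == "too_short"


class TestScalingEstimators:
    def test_dfa_exposes_fluctuation_table(self):
        from tscompass.catalogue import dfa_profile

        x = np.random.default_rng(11).standard_normal(2000)
        sizes, fs = dfa_profile(x)
        assert sizes.size >= 10
        assert np.all(np.diff(sizes) > 0)
        assert np.all(fs > 0)

    def test_dfa_on_selfaffine_alpha_one(self):
        from tscompass import synth

        es = [dfa_exponent(synth.fourier_filter(1.0, 5000, seed=s).values)
              for s in range(20)]
        assert abs(np.mean(es) - 1.0) < 0.15

    def test_spectral_slope_on_negative_alpha(self):
        from tscompass import synth

        sl = [spectral_slope(synth.fourier_filter(-1.0, 8192, seed=s).values)
              for s in range(20)]
        assert abs(np.mean(sl) - 1.0) < 0.25


class TestRegistryContracts:
    def test_size_unique_ids_and_families(self, registry):
        assert len(registry) >= 60
        assert len(set(registry.ids)) == len(registry)
        assert registry.families == set(
            ("distribution", "correlation", "spectral", "stationarity",
             "information", "scaling", "model_fit", "symbolic", "novel")
        )

    def test_every_operation_returns_real_or_special(self, registry):
        ts = tc.TimeSeries(
            id="n", values=np.random.default_rng(0).standard_normal(1000)
        )
        for op in registry:
            out = tc.evaluate(op, ts)
            assert tc.is_special(out) or np.isfinite(out)

    def test_purity_bit_identical_re_evaluation(self, registry):
        ts = tc.TimeSeries(
            id="n", values=np.random.default_rng(1).standard_normal(600)
        )
        for op in registry:
            a, b = tc.evaluate(op, ts), tc.evaluate(op, ts)
            if tc.is_special(a):
                assert tc.is_special(b) and a.reason == b.reason
            else:
                assert a == b

    def test_scale_sensitivity_metadata_is_honest(self, registry):
        x = np.random.default_rng(7).standard_normal(1200)
        t1 = tc.TimeSeries(id="a", values=x)
        t2 = tc.TimeSeries(id="b", values=3 * x + 7)
        for op in registry:
            if op.scale_sensitive:
                continue
            v1, v2 = tc.evaluate(op, t1), tc.evaluate(op, t2)
            assert tc.is_special(v1) == tc.is_special(v2)
            if not tc.is_special(v1):
                assert abs(v1 - v2) <= 1e-9 * max(1.0, abs(v1)), op.id

    def test_registry_json_export_round_trips(self, registry):
        import json

        records = json.loads(registry.to_json())
        assert len(records) == len(registry)
        assert {r["id"] for r in records} == set(registry.ids)
        assert all(set(r) == {"id", "name", "family", "params",
                              "scale_sensitive"} for r in records)

    def test_unknown_special_reason_rejected(self):
        with pytest.raises(ValueError):
            SpecialValue("bogus")

    def test_special_value_never_coerces(self):
        with pytest.raises(TypeError):
            float(SpecialValue("nan"))


def test_evaluate_maps_exceptions_and_nonfinite_to_special(registry):
    from tscompass.catalogue.base import Operation

    boom = Operation("boom", "raises", "novel", lambda x: 1 / 0)
    nan_op = Operation("nanop", "nan", "novel", lambda x: float("nan"))
    inf_op = Operation("infop", "inf", "novel", lambda x: float("inf"))
    ts = tc.TimeSeries(id="t", values=np.arange(30.0))
    assert tc.evaluate(boom, ts).reason == "error"
    assert tc.evaluate(nan_op, ts).reason == "nan"
    assert tc.evaluate(inf_op, ts).reason == "inf"
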