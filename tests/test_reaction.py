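"""Glycine-dimerization kinetics: rhs, integration, rate fitting, grid."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from thermotrap.reaction import (
    REFERENCE_RATES,
    RateConstants,
    build_reaction_grid,
    fit_k4,
    fit_rates,
    integrate_batch,
    reaction_rhs,
    reaction_yield,
)
from thermotrap.synthetic import synth_reaction_data

HOURS = 3600.0


def trace_product_oracle(g0, t0, t):
    """Closed-form perturbation limit for trace concentrations.

    At conversions << 1 the activated species reaches quasi-steady state
    [GlyAct] = k1 [G][T]/k2 within ~1/k2, the dimer forms at rate
    k3 [GlyAct][G] from TMP decaying at k4, and decays itself at k5:
    GG(t) = R (exp(-k4 t) - exp(-k5 t)) / (k5 - k4), R = k1 k3 G^2 T0 / k2.
    """
    r = REFERENCE_RATES
    R = r.k1 * r.k3 * g0**2 * t0 / r.k2
    return R * (np.exp(-r.k4 * t) - np.exp(-r.k5 * t)) / (r.k5 - r.k4)


class TestRhs:
    def test_zero_state_zero_derivatives(self):
        assert np.allclose(reaction_rhs(np.zeros(4), REFERENCE_RATES), 0.0)

    @given(
        st.lists(st.floats(0.0, 1.0), min_size=4, max_size=4),
        st.lists(st.floats(1e-9, 1e-2), min_size=5, max_size=5),
    )
    @settings(max_examples=50, deadline=None)
    def test_glycine_units_conserved_algebraically(self, state, ks):
        rates = RateConstants(*ks)
        d = reaction_rhs(np.array(state), rates)
        # d/dt ([Gly] + [GlyAct] + 2 [GlyGly]) = 0 for any state and rates
        # (to floating-point cancellation of the individual terms)
        scale = np.abs(d).max() + 1e-30
        assert abs(d[0] + d[1] + 2 * d[2]) <= 1e-12 * scale + 1e-25

    def test_tmp_only_decays_first_order(self):
        d = reaction_rhs(np.array([0.0, 0.0, 0.0, 2e-4]), REFERENCE_RATES)
        assert np.allclose(d[:3], 0.0)
        assert d[3] == pytest.approx(-REFERENCE_RATES.k4 * 2e-4)


class TestIntegration:
    def test_zero_rates_keep_state_constant(self):
        rates = RateConstants(0, 0, 0, 0, 0)
        out = integrate_batch({"Gly": 0.1, "TMP": 0.01}, rates, duration=100 * HOURS)
        assert np.allclose(out["Gly"], 0.1)
        assert np.allclose(out["TMP"], 0.01)

    def test_tmp_half_life_about_23_days(self):
        t_half = np.log(2) / REFERENCE_RATES.k4
        assert t_half / 86400 == pytest.approx(22.9, abs=0.2)
        out = integrate_batch(
            {"TMP": 2e-4}, REFERENCE_RATES, duration=t_half, t_eval=[t_half]
        )
        assert out["TMP"].iloc[-1] == pytest.approx(1e-4, rel=1e-4)

    def test_glycine_units_conserved_numerically(self):
        out = integrate_batch(
            {"Gly": 0.1, "TMP": 0.1}, REFERENCE_RATES, duration=120 * HOURS
        )
        units = out["Gly"] + out["GlyAct"] + 2 * out["GlyGly"]
        assert np.allclose(units / units.iloc[0], 1.0, atol=1e-8)

    def test_trace_concentration_perturbation_oracle(self):
        # 1 uM + 1 uM for 120 h: integrator vs closed form within 5 %,
        # landing at the sub-femtomolar scale
        t = 120 * HOURS
        out = integrate_batch({"Gly": 1e-6, "TMP": 1e-6}, REFERENCE_RATES, duration=t)
        gg = out["GlyGly"].iloc[-1]
        assert gg == pytest.approx(trace_product_oracle(1e-6, 1e-6, t), rel=0.05)
        assert 1e-16 < gg < 1e-15

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            integrate_batch({"Gly": -1.0}, REFERENCE_RATES, duration=10.0)
        with pytest.raises(ValueError):
            integrate_batch({"Gly": 1.0}, REFERENCE_RATES, duration=0.0)


class TestYield:
    def test_values(self):
        assert reaction_yield(0.0, 1.0) == 0.0
        assert reaction_yield(5.0, 90.0) == pytest.approx(0.10)
        assert reaction_yield(5e-6, 90e-6) == pytest.approx(0.10)  # scale-free

    def test_undefined_for_double_zero(self):
        with pytest.raises(ValueError):
            reaction_yield(0.0, 0.0)


class TestFitK4:
    times = np.linspace(0, 120 * HOURS, 13)

    def test_noiseless_recovery(self):
        c = 2e-4 * np.exp(-REFERENCE_RATES.k4 * self.times)
        fit = fit_k4(self.times, c)
        assert fit["k4"] == pytest.approx(REFERENCE_RATES.k4, rel=0.01)
        assert not fit["at_boundary"]

    def test_constant_series_fits_zero(self):
        fit = fit_k4(self.times, np.full_like(self.times, 2e-4))
        # half-life centuries: zero on every physical scale of this system
        assert fit["k4"] == pytest.approx(0.0, abs=1e-9)
        assert fit["at_boundary"]

    def test_multiplicative_noise_bias_below_two_percent(self):
        # 200 trials in antithetic pairs (z, -z): cancels the Monte-Carlo
        # sampling error of the bias estimate itself
        rng = np.random.default_rng(5)
        got = []
        clean = 2e-4 * np.exp(-REFERENCE_RATES.k4 * self.times)
        for _ in range(100):
            z = 0.05 * rng.standard_normal(self.times.size)
            got.append(fit_k4(self.times, clean * np.exp(z))["k4"])
            got.append(fit_k4(self.times, clean * np.exp(-z))["k4"])
        assert np.mean(got) == pytest.approx(REFERENCE_RATES.k4, rel=0.02)
        assert np.std(got) > 0


class TestFitRates:
    @pytest.fixture(scope="class")
    def noiseless_fit(self):
        tit, ts = synth_reaction_data(REFERENCE_RATES, noise_sigma=0.0, n_replicates=1)
        data = pd.concat([tit, ts])
        return fit_rates(data, k4=REFERENCE_RATES.k4, seed=0)

    def test_noiseless_recovery_within_five_percent(self, noiseless_fit):
        for name in ("k1", "k2", "k3", "k5"):
            assert getattr(noiseless_fit, name) == pytest.approx(
                getattr(REFERENCE_RATES, name), rel=0.05
            ), name

    def test_zero_product_data_flags_boundary(self):
        tit, _ = synth_reaction_data(REFERENCE_RATES, noise_sigma=0.0, n_replicates=1)
        tit["glygly_M"] = 0.0
        with pytest.warns(UserWarning, match="unidentifiable"):
            fit = fit_rates(tit, k4=REFERENCE_RATES.k4, seed=0, n_starts=2)
        # the fitted scheme must predict negligible product at the design
        check = integrate_batch(
            {"Gly": 0.1, "TMP": 0.158}, fit, duration=16 * HOURS
        )["GlyGly"].iloc[-1]
        assert check < 1e-9

    def test_noise_propagates_to_k2_spread(self, noiseless_fit):
        # ~10 % data noise should leave k2 determined to roughly +-10 %
        x0 = noiseless_fit.as_array()[[0, 1, 2, 4]]
        vals = []
        for trial in range(10):
            tit, ts = synth_reaction_data(
                REFERENCE_RATES, noise_sigma=0.10, seed=100 + trial, n_replicates=1
            )
            fit = fit_rates(
                pd.concat([tit, ts]), k4=REFERENCE_RATES.k4, seed=trial,
                n_starts=1, x0=x0,
            )
            vals.append(fit.k2)
        spread = np.std(np.log(vals))
        assert 0.02 < spread < 0.35


class TestReactionGrid:
    def test_dilute_corner_has_negligible_yield(self, reaction_grid):
        gg = reaction_grid.glygly[0, 0, -1]
        g = reaction_grid.gly[0, 0, -1]
        assert reaction_yield(gg, g) < 1e-9

    def test_yield_monotone_in_tmp_at_fixed_gly(self, reaction_grid):
        i = np.searchsorted(reaction_grid.log10_gly, -2.0)  # 10 mM glycine
        gg = reaction_grid.glygly[i, :, -1]
        g = reaction_grid.gly[i, :, -1]
        y = reaction_yield(gg, g)
        assert np.all(np.diff(y) > -1e-12)

    def test_interpolated_product_matches_direct_integration(self, reaction_grid):
        f_gg, _ = reaction_grid.final_interpolators()
        lg, lt = -3.3, -2.6  # off-grid point
        interp = 10.0 ** float(f_gg([[lg, lt]])[0])
        direct = integrate_batch(
            {"Gly": 10**lg, "TMP": 10**lt}, REFERENCE_RATES,
            duration=float(reaction_grid.times_s[-1]),
            t_eval=[reaction_grid.times_s[-1]],
        )["GlyGly"].iloc[-1]
        assert interp == pytest.approx(direct, rel=0.10)

    def test_no_failures_recorded(self, reaction_grid):
        assert reaction_grid.failures == []

    def test_save_load_roundtrip(self, reaction_grid, tmp_path):
        reaction_grid.save(tmp_path / "grid")
        back = reaction_grid.load(tmp_path / "grid")
        assert np.array_equal(back.glygly, reaction_grid.glygly)
        assert back.rates.k4 == reaction_grid.rates.k4
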