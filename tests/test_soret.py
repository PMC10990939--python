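"""Fraction normalization, enrichment statistics, Soret fitting, and the
systematic/random replicate-error decomposition."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from thermotrap.soret import (
    estimates_frame,
    fit_soret,
    normalize_fractions,
    pairwise_enrichment,
    pool_enrichment,
    replicate_error_split,
    simulate_fraction_means,
)
from thermotrap.synthetic import SyntheticSpec, synth_fraction_table
from thermotrap.physics import Solute
from tests.conftest import SOLVER_KW


def table_from(values: dict, delta_T=15.0) -> pd.DataFrame:
    """values: species -> {replicate -> fraction list (top-first)}"""
    rows = []
    for sp, reps in values.items():
        for k, fr in reps.items():
            for j, v in enumerate(fr, start=1):
                rows.append(
                    dict(species=sp, replicate=k, fraction_index=j, value=v,
                         delta_T_K=delta_T)
                )
    return pd.DataFrame(rows)


class TestNormalization:
    def test_uniform_values_normalize_to_one(self):
        t = table_from({"A": {1: [2.0, 2.0, 2.0, 2.0]}})
        out = normalize_fractions(t)
        assert np.allclose(out["value"], 1.0)

    def test_arithmetic(self):
        t = table_from({"A": {1: [4.0, 2.0, 1.0, 1.0]}})
        out = normalize_fractions(t).sort_values("fraction_index")
        assert np.allclose(out["value"], [2.0, 1.0, 0.5, 0.5])

    def test_calibration_invariance(self):
        t1 = table_from({"A": {1: [4.0, 2.0, 1.0, 1.0], 2: [3.0, 2.0, 2.0, 1.0]}})
        t2 = t1.copy()
        t2["value"] *= 37.3  # arbitrary per-species calibration factor
        assert np.allclose(
            normalize_fractions(t1)["value"], normalize_fractions(t2)["value"]
        )

    @given(
        st.lists(st.floats(0.01, 100.0), min_size=4, max_size=4),
    )
    @settings(max_examples=25, deadline=None)
    def test_idempotent(self, fractions):
        t = table_from({"A": {1: fractions}})
        once = normalize_fractions(t)["value"].to_numpy()
        twice = normalize_fractions(normalize_fractions(t))["value"].to_numpy()
        assert np.allclose(once, twice, rtol=1e-12)

    def test_all_zero_species_rejected_by_name(self):
        t = table_from({"A": {1: [0.0, 0.0, 0.0, 0.0]}, "B": {1: [1, 2, 3, 4]}})
        with pytest.raises(ValueError, match="A"):
            normalize_fractions(t)


class TestPairwiseEnrichment:
    def test_self_enrichment_is_zero(self):
        t = table_from({"A": {1: [2, 1, 1, 4], 2: [1, 1, 2, 4]}})
        mean, sd = pairwise_enrichment(t, fraction=4)
        assert mean.loc["A", "A"] == 0.0

    def test_constant_replicate_ratios(self):
        # per-replicate bottom ratios all equal 2 -> enrichment 100 %, sd 0
        t = table_from(
            {
                "A": {k: [1.0, 1.0, 1.0, 2.0] for k in (1, 2, 3)},
                "B": {k: [1.2, 1.2, 1.2, 1.0] for k in (1, 2, 3)},
            }
        )
        mean, sd = pairwise_enrichment(t, fraction=4)
        # normalization rescales each species; ratio of normalized bottoms
        expected = (2.0 / 1.25) / (1.0 / 1.15)
        assert mean.loc["A", "B"] == pytest.approx(expected - 1.0, rel=1e-12)
        assert sd.loc["A", "B"] == pytest.approx(0.0, abs=1e-12)

    def test_constructed_aminoazole_like_fixture(self):
        # synthetic fixture built so the bottom enrichment of the stronger
        # species over the weaker is 32 % +- 3.6 % (s.d. over 3 repeats)
        # symmetric triple {r-a, r, r+a} has sample s.d. exactly a
        ratios = np.array([1.32 - 0.036, 1.32, 1.32 + 0.036])
        t = table_from(
            {
                # pre-normalized per replicate (mean 1), bottom value = ratio
                "2AI": {
                    k: [(4 - r) / 3, (4 - r) / 3, (4 - r) / 3, float(r)]
                    for k, r in zip((1, 2, 3), ratios)
                },
                "2AO": {k: [1.0, 1.0, 1.0, 1.0] for k in (1, 2, 3)},
            }
        )
        mean, sd = pairwise_enrichment(t, fraction=4)
        assert mean.loc["2AI", "2AO"] == pytest.approx(0.32, abs=1e-9)
        assert sd.loc["2AI", "2AO"] == pytest.approx(0.036, rel=1e-9)

    def test_averaging_order_mean_of_ratios_not_ratio_of_means(self):
        # replicate ratios 2 and 1/2: mean-of-ratios gives +0.25, the
        # ratio-of-averages would give 0 — the pipeline must return +0.25
        t = table_from(
            {
                "A": {1: [1, 1, 1, 2.0], 2: [1, 1, 1, 1.0]},
                "B": {1: [1, 1, 1, 1.0], 2: [1, 1, 1, 2.0]},
            }
        )
        norm_ratio = lambda num, den: (num / (3 + num) * 4) / (den / (3 + den) * 4)
        r1 = norm_ratio(2.0, 1.0)
        r2 = norm_ratio(1.0, 2.0)
        mean, _ = pairwise_enrichment(t, fraction=4)
        assert mean.loc["A", "B"] == pytest.approx((r1 + r2) / 2 - 1, rel=1e-12)
        assert mean.loc["A", "B"] != pytest.approx(0.0, abs=1e-3)

    @given(
        st.lists(st.floats(0.2, 5.0), min_size=2, max_size=5),
    )
    @settings(max_examples=30, deadline=None)
    def test_jensen_inequality_of_reciprocal_directions(self, ratios):
        # (1 + enrich(A,B)) * (1 + enrich(B,A)) >= 1, equality iff constant
        t = table_from(
            {
                "A": {k: [1, 1, 1, float(r)] for k, r in enumerate(ratios, 1)},
                "B": {k: [1, 1, 1, 1.0] for k in range(1, len(ratios) + 1)},
            }
        )
        mean, _ = pairwise_enrichment(t, fraction=4)
        prod = (1 + mean.loc["A", "B"]) * (1 + mean.loc["B", "A"])
        assert prod >= 1.0 - 1e-9

    def test_zero_denominator_rejected(self):
        t = table_from({"A": {1: [1, 1, 1, 1]}, "B": {1: [1, 1, 1, 0.0]}})
        with pytest.raises(ValueError, match="zero"):
            pairwise_enrichment(t, fraction=4)


class TestPoolEnrichment:
    def test_two_species_arithmetic(self):
        t = table_from({"A": {1: [1, 1, 1, 2.0]}, "B": {1: [1, 1, 1, 1.0]}})
        norm = normalize_fractions(t)
        vals = pool_enrichment(t, fraction=4)
        a = 2.0 / 1.25
        b = 1.0 / 1.0
        pool = (a + b) / 2
        assert vals["A"] == pytest.approx(a / pool - 1, rel=1e-12)
        assert vals["B"] == pytest.approx(b / pool - 1, rel=1e-12)

    def test_single_species_equals_pool(self):
        t = table_from({"A": {1: [1, 1, 1, 3.0]}})
        vals = pool_enrichment(t, fraction=4)
        assert vals["A"] == pytest.approx(0.0, abs=1e-12)

    def test_literal_difference_variant_differs(self):
        t = table_from({"A": {1: [1, 1, 1, 2.0]}, "B": {1: [1, 1, 1, 1.0]}})
        ratio_form = pool_enrichment(t, fraction=4)
        diff_form = pool_enrichment(t, fraction=4, literal_difference=True)
        assert not np.allclose(ratio_form.to_numpy(), diff_form.to_numpy())


class TestSoretFit:
    def test_uniform_fractions_fit_zero(self):
        t = table_from({"A": {1: [1.0, 1.0, 1.0, 1.0]}})
        est = fit_soret(t, D=1.4e-9, **SOLVER_KW)
        assert abs(est[0].S_T) < 1e-4

    def test_noiseless_roundtrip_recovers_generating_value(self):
        true = 3e-3
        spec = SyntheticSpec(
            solutes=(Solute("X", D=1.4e-9, S_T=true),),
            delta_T_K=15.0, jitter_K=0.0, n_replicates=1, noise_sigma=0.0, seed=4,
        )
        t = synth_fraction_table(spec, **SOLVER_KW)
        est = fit_soret(t, D=1.4e-9, **SOLVER_KW)
        assert est[0].S_T == pytest.approx(true, rel=0.02)

    def test_fit_insensitive_to_assumed_diffusivity(self):
        spec = SyntheticSpec(
            solutes=(Solute("X", D=1.4e-9, S_T=5.1e-3),),
            delta_T_K=15.0, jitter_K=0.0, n_replicates=1, noise_sigma=0.0, seed=4,
        )
        t = synth_fraction_table(spec, **SOLVER_KW)
        lo = fit_soret(t, D=0.7e-9, **SOLVER_KW)[0].S_T
        hi = fit_soret(t, D=2.1e-9, **SOLVER_KW)[0].S_T
        assert abs(lo / 5.1e-3 - 1) < 0.10
        assert abs(hi / 5.1e-3 - 1) < 0.10

    def test_estimates_frame_schema(self):
        t = table_from({"A": {1: [1.0, 1.0, 1.0, 1.0]}})
        df = estimates_frame(fit_soret(t, D=1.4e-9, **SOLVER_KW))
        assert list(df.columns) == [
            "species", "S_T_per_K", "sigma_random", "sigma_systematic", "n_replicates",
        ]


class TestReplicateErrorSplit:
    def test_identical_replicates(self):
        df = pd.DataFrame({"r1": [1e-3, 5e-3, 8e-3], "r2": [1e-3, 5e-3, 8e-3]})
        out = replicate_error_split(df)
        assert out["sigma_systematic"] == pytest.approx(0.0, abs=1e-12)
        assert out["sigma_random"] == pytest.approx(0.0, abs=1e-12)

    def test_pure_multiplicative_offset(self):
        a = np.array([1e-3, 5e-3, 8e-3])
        df = pd.DataFrame({"r1": a, "r2": 1.1 * a})
        out = replicate_error_split(df)
        assert out["sigma_systematic"] == pytest.approx(0.10, rel=1e-9)
        assert out["sigma_random"] == pytest.approx(0.0, abs=1e-12)

    def test_recovers_injected_gaussian_noise(self):
        rng = np.random.default_rng(7)
        sigma = 3e-4
        base = np.linspace(1e-3, 8e-3, 12)
        got = []
        for _ in range(200):
            df = pd.DataFrame(
                {
                    "r1": base + rng.normal(0, sigma, base.size),
                    "r2": base + rng.normal(0, sigma, base.size),
                    "r3": base + rng.normal(0, sigma, base.size),
                }
            )
            got.append(replicate_error_split(df)["sigma_random"])
        assert np.mean(got) == pytest.approx(sigma, rel=0.1)

    def test_requires_two_species(self):
        with pytest.raises(ValueError, match="2 species"):
            replicate_error_split(pd.DataFrame({"r1": [1e-3], "r2": [1e-3]}))
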