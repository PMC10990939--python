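"""Crack-network generation, flow solving, propagation and statistics."""

import numpy as np
import pytest

from thermotrap.network import (
    ensemble,
    generate_topology,
    max_enrichment,
    median_of_top,
    propagate,
    purity,
    solve_flow_rates,
)
from thermotrap.synthetic import fixture_solutes

NL = 1e-12  # 1 nl/s in m^3/s


def two_species():
    return [s for s in fixture_solutes("amino_acids") if s.name in ("G", "I")]


class TestTopology:
    def test_single_chamber_network(self):
        topo = generate_topology(1, 1, NL, seed=0)
        outs = topo.outflows(0, 0)
        assert 1 <= len(outs) <= 2
        assert all(c.m_to is None for c in outs)

    def test_connectivity_rules(self):
        topo = generate_topology(8, 12, NL, seed=5)
        for c in topo.channels:
            if c.m_to is not None:
                assert abs(c.m_to - c.m_from) <= 1
                assert 0 <= c.m_to < 8
        for n in range(12):
            for m in range(8):
                assert 1 <= len(topo.outflows(m, n)) <= 2
                targets = [c.m_to for c in topo.outflows(m, n) if c.m_to is not None]
                assert len(set(targets)) == len(targets)  # distinct targets
                if n > 0:
                    assert len(topo.inflows(m, n)) >= 1

    def test_seed_determinism(self):
        a = generate_topology(6, 6, NL, seed=42).signature()
        b = generate_topology(6, 6, NL, seed=42).signature()
        c = generate_topology(6, 6, NL, seed=43).signature()
        assert a == b
        assert a != c


class TestFlows:
    def test_single_chain_carries_inlet_rate(self):
        # a 1-row network has only single-outflow chambers: every channel
        # carries exactly the inlet rate
        topo = generate_topology(1, 6, NL, seed=1)
        flows = solve_flow_rates(topo)
        assert np.allclose(flows.Q_total, NL, rtol=1e-12)
        for c in topo.channels:
            assert c.rate == pytest.approx(NL, rel=1e-12)

    def test_global_solvent_balance_exact(self):
        topo = generate_topology(9, 7, NL, seed=2)
        flows = solve_flow_rates(topo)
        out = sum(c.rate for c in topo.channels if c.m_to is None)
        assert out == pytest.approx(9 * NL, rel=1e-12)
        # per-column balance too
        assert np.allclose(flows.Q_total.sum(axis=0), 9 * NL, rtol=1e-12)

    def test_flow_rates_mostly_between_point1_and_10_nl(self):
        fracs = []
        for seed in range(30):
            topo = generate_topology(20, 20, NL, seed=seed)
            q = solve_flow_rates(topo).Q_total.ravel() / NL
            fracs.append(np.mean((q >= 0.1) & (q <= 10.0)))
        assert np.mean(fracs) >= 0.80


class TestPropagation:
    def test_zero_gradient_is_identity(self, coarse_table):
        topo = generate_topology(6, 6, NL, seed=3)
        flows = solve_flow_rates(topo)
        st = propagate(topo, flows, two_species(), 0.0, coarse_table, clamp=True)
        assert np.allclose(st.c_bot, 1.0, atol=1e-5)
        assert max_enrichment(st, "G", "I") == pytest.approx(1.0, abs=1e-5)

    def test_per_chamber_gradient_jitter(self, coarse_table):
        # robustness option: a mild per-chamber dT scatter perturbs the
        # enrichment statistic only moderately
        topo = generate_topology(8, 8, NL, seed=6)
        flows = solve_flow_rates(topo)
        rng = np.random.default_rng(6)
        dT_map = 6.0 + rng.uniform(-1.0, 1.0, size=(8, 8))
        uniform = propagate(topo, flows, two_species(), 6.0, coarse_table, clamp=True)
        jitter = propagate(topo, flows, two_species(), dT_map, coarse_table, clamp=True)
        r_u = max_enrichment(uniform, "I", "G")
        r_j = max_enrichment(jitter, "I", "G")
        assert 0.5 < r_j / r_u < 2.0

    def test_solute_conservation_through_network(self, coarse_table):
        topo = generate_topology(10, 10, NL, seed=4)
        flows = solve_flow_rates(topo)
        st = propagate(topo, flows, two_species(), 6.0, coarse_table, clamp=True)
        for sp in ("G", "I"):
            influx = 10 * NL
            assert st.boundary_outflux(sp) == pytest.approx(influx, rel=0.02)

    def test_gravity_segregates_strong_species_into_lower_rows(self, coarse_table):
        # the strongly thermophoretic species sinks through bottom-port
        # channels and dominates the lower rows; the weak species remains
        # relatively enriched in the upper rows
        ratios = []
        for seed in range(5):
            topo = generate_topology(12, 12, NL, seed=seed)
            flows = solve_flow_rates(topo)
            st = propagate(topo, flows, two_species(), 6.0, coarse_table, clamp=True)
            iG, iI = st.species.index("G"), st.species.index("I")
            ratios.append(np.log(st.c_bot[iI] / st.c_bot[iG]).mean(axis=1))
        row_mean = np.mean(ratios, axis=0)  # geometric-mean log ratio per row
        assert row_mean[-4:].mean() > row_mean[:4].mean() + np.log(1.2)
        # segregation deepens with row depth
        assert np.corrcoef(np.arange(12), row_mean)[0, 1] > 0.4

    def test_purity_niches_at_reference_settings(self, coarse_table):
        # 20 x 20 chambers, dT = 6 K, 30 systems: some chamber reaches
        # >= 95 % purity of the strong species and some >= 99.9 % of the weak
        states = []
        for seed in range(30):
            topo = generate_topology(20, 20, NL, seed=seed)
            flows = solve_flow_rates(topo)
            states.append(propagate(topo, flows, two_species(), 6.0, coarse_table, clamp=True))
        assert purity(states, "I", "G") >= 0.95
        assert purity(states, "G", "I") >= 0.999


class TestStatistics:
    def test_median_of_top_arithmetic(self):
        # ratios 1..20: the ten largest are 11..20, median 15.5
        assert median_of_top(np.arange(1.0, 21.0)) == 15.5
        assert median_of_top([3.0, 1.0]) == 2.0  # fewer than ten: use all

    def test_self_ratio_is_one(self, coarse_table):
        topo = generate_topology(6, 6, NL, seed=3)
        flows = solve_flow_rates(topo)
        st = propagate(topo, flows, two_species(), 6.0, coarse_table, clamp=True)
        assert max_enrichment(st, "G", "G") == pytest.approx(1.0, rel=1e-12)


class TestEnsemble:
    def test_zero_error_fixed_topologies_is_deterministic(self, coarse_table):
        sols = [s.__class__(s.name, D=s.D, S_T=s.S_T, sigma_random=0.0) for s in two_species()]
        res = ensemble(
            sols, coarse_table, n_rows=6, n_cols=6, delta_T=6.0,
            n_systems=2, n_repeats=3, seed=9, fixed_topologies=True,
            pairs=[("G", "I")],
        )
        assert res.sd("G", "I") == pytest.approx(0.0, abs=1e-12)
        assert res.n_failed == 0

    def test_spread_grows_with_soret_error(self, coarse_table):
        sds = []
        for sig_rel in (0.0, 0.1, 0.3):
            sols = [
                s.__class__(s.name, D=s.D, S_T=s.S_T, sigma_random=sig_rel * s.S_T)
                for s in two_species()
            ]
            res = ensemble(
                sols, coarse_table, n_rows=6, n_cols=6, delta_T=6.0,
                n_systems=3, n_repeats=4, seed=11, fixed_topologies=True,
                pairs=[("G", "I")],
            )
            sds.append(res.sd("G", "I"))
        assert sds[0] == pytest.approx(0.0, abs=1e-12)
        assert sds[1] > 0
        assert sds[2] > sds[1]

    def test_enrichment_grows_with_gradient_and_saturates_reverse(self, coarse_table):
        weak_over_strong, strong_over_weak = [], []
        for dT in (2.0, 6.0, 10.0):
            res = ensemble(
                two_species(), coarse_table, n_rows=10, n_cols=10, delta_T=dT,
                n_systems=5, n_repeats=1, seed=1, resample_soret=False,
                pairs=[("G", "I"), ("I", "G")],
            )
            weak_over_strong.append(res.mean("G", "I"))
            strong_over_weak.append(res.mean("I", "G"))
        assert np.all(np.diff(weak_over_strong) > 0)
        # the strong-over-weak direction saturates/declines at high dT
        assert strong_over_weak[2] < max(strong_over_weak)
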