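"""Stochastic model of interconnected heat-flow chambers ("crack networks").

A network is a grid of chambers (rows ``m``, columns ``n``); geothermal
fluid enters every first-column chamber at a fixed rate and percolates
strictly left-to-right: every channel connects a chamber to one in the
next column whose row differs by at most one, or leaves the system at the
last column.  The generator assigns each chamber one-or-two outflow
channels and guarantees at least one inflow per chamber (several inflows
are possible and their concentrations mix flow-weighted).  Channel flow
rates follow from solvent mass conservation, with randomly drawn split
ratios where a chamber has two outflows.

Each chamber's solute response (outlet split and bottom-region
concentration, per species) is looked up in a precomputed
:class:`~thermotrap.transfer.TransferTable`; concentrations propagate
column by column.  Because the table stores exact solute-split fractions,
solvent conservation is exact at every node and solute conservation is
exact through the interpolation.

A chamber with a single outflow channel is a pass-through for the
transported concentration (conservation leaves no alternative), but its
bottom region is still enriched; the bottom-outflow share used for its
table lookup is 100 % when the channel leaves via the bottom port and the
table's minimum share (a nearly closed bottom) when it leaves via the top.

The headline statistic is the "maximum enrichment" of species A over B:
the median of the ten largest per-chamber bottom-concentration ratios,
pooled over the chambers of all systems of an ensemble.  Ensemble errors
are propagated by redrawing each species' Soret coefficient from a
Gaussian with its random error, regenerating the topologies, and
repeating the run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .physics import Solute
from .transfer import TransferTable, interpolate_transfer

__all__ = [
    "Channel",
    "NetworkTopology",
    "NetworkState",
    "EnsembleResult",
    "generate_topology",
    "solve_flow_rates",
    "propagate",
    "max_enrichment",
    "purity",
    "ensemble",
]

#: bounds for the random two-outflow split ratio (bottom share)
SPLIT_BOUNDS = (0.1, 0.9)


@dataclass
class Channel:
    """A directed connection from chamber (m_from, n) to column n+1.

    ``m_to`` is the target row; ``m_to is None`` marks a boundary outflow
    at the last column.  ``port`` ("top" | "bottom") and ``rate`` (m^3/s)
    are assigned by :func:`solve_flow_rates`.
    """

    m_from: int
    n_from: int
    m_to: int | None
    port: str | None = None
    rate: float | None = None


@dataclass
class NetworkTopology:
    n_rows: int
    n_cols: int
    Q_in_per_inlet: float
    seed: int
    channels: list = field(default_factory=list)

    def outflows(self, m: int, n: int) -> list:
        return [c for c in self.channels if c.m_from == m and c.n_from == n]

    def inflows(self, m: int, n: int) -> list:
        return [c for c in self.channels if c.n_from == n - 1 and c.m_to == m]

    def signature(self) -> tuple:
        """Hashable connectivity fingerprint (for same-seed checks)."""
        return tuple(sorted((c.m_from, c.n_from, -1 if c.m_to is None else c.m_to) for c in self.channels))


def _assign_column(rng, n_rows: int, p_branch: float) -> list[tuple[int, int]]:
    """Edges (source_row, target_row) between two adjacent columns.

    Every target row receives at least one inflow; every source row has
    one or two outflows (never more, never zero, distinct targets).
    """
    allowed = [
        [r for r in (t - 1, t, t + 1) if 0 <= r < n_rows] for t in range(n_rows)
    ]
    for _ in range(200):
        counts = np.zeros(n_rows, dtype=int)
        src_of = np.empty(n_rows, dtype=int)
        # greedy min-count assignment in random order keeps out-degrees <= 2
        for t in rng.permutation(n_rows):
            cands = allowed[t]
            cmin = min(counts[c] for c in cands)
            pick = [c for c in cands if counts[c] == cmin]
            s = int(pick[rng.integers(len(pick))])
            src_of[t] = s
            counts[s] += 1
        if counts.max() <= 2:
            break
    else:  # pragma: no cover - greedy failure is not observed in practice
        raise RuntimeError("could not satisfy out-degree constraints")
    edges = [(int(src_of[t]), t) for t in range(n_rows)]
    # sources without any outflow must get 1-2; sources with one may branch
    targets_of = {s: {t for ss, t in edges if ss == s} for s in range(n_rows)}
    for s in range(n_rows):
        cands = [t for t in (s - 1, s, s + 1) if 0 <= t < n_rows]
        have = targets_of[s]
        if len(have) == 0:
            k = 1 + int(rng.random() < p_branch and len(cands) > 1)
            chosen = rng.choice(len(cands), size=min(k, len(cands)), replace=False)
            for i in np.atleast_1d(chosen):
                edges.append((s, cands[int(i)]))
        elif len(have) == 1 and rng.random() < p_branch:
            extra = [t for t in cands if t not in have]
            if extra:
                edges.append((s, extra[int(rng.integers(len(extra)))]))
    return edges


def generate_topology(
    n_rows: int,
    n_cols: int,
    Q_in_per_inlet: float = 1e-12,
    seed: int = 0,
    p_branch: float = 0.5,
) -> NetworkTopology:
    """Random crack-network connectivity, deterministic given ``seed``."""
    if n_rows < 1 or n_cols < 1:
        raise ValueError("grid dimensions must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x746F706F]))
    channels = []
    for n in range(n_cols - 1):
        for s, t in _assign_column(rng, n_rows, p_branch):
            channels.append(Channel(m_from=s, n_from=n, m_to=t))
    # last column: 1-2 boundary outflows each
    for m in range(n_rows):
        k = 1 + int(rng.random() < p_branch)
        for _ in range(k):
            channels.append(Channel(m_from=m, n_from=n_cols - 1, m_to=None))
    return NetworkTopology(
        n_rows=n_rows,
        n_cols=n_cols,
        Q_in_per_inlet=Q_in_per_inlet,
        seed=seed,
        channels=channels,
    )


@dataclass
class NetworkFlows:
    """Channel rates/ports and per-chamber flow summaries."""

    Q_total: np.ndarray  # (n_rows, n_cols) chamber throughflow, m^3/s
    s_bot: np.ndarray  # (n_rows, n_cols) bottom-outflow share used for lookup
    single_outflow: np.ndarray  # bool mask


def _geometric_port(channel: Channel) -> str | None:
    """Port implied by the channel's row offset, or None if ambiguous.

    The network is a vertical arrangement of tall chambers: a channel that
    feeds the chamber one row BELOW must leave through the bottom outlet, a
    channel to the row ABOVE through the top outlet.  Same-row and boundary
    channels carry no geometric constraint.
    """
    if channel.m_to is None or channel.m_to == channel.m_from:
        return None
    return "bottom" if channel.m_to > channel.m_from else "top"


def solve_flow_rates(
    topology: NetworkTopology,
    seed: int | None = None,
    table_s_min: float = 0.01,
    port_assignment: str = "geometric",
) -> NetworkFlows:
    """Assign channel flow rates and ports by solvent mass conservation.

    Two-outflow chambers split their throughflow with a bottom share drawn
    uniformly from ``SPLIT_BOUNDS``.  Which channel attaches to which port
    follows the geometry by default (``port_assignment="geometric"``): a
    channel descending a row leaves via the bottom outlet, a channel
    ascending a row via the top outlet; only same-row/boundary channels are
    assigned at random.  This preserves the gravity-driven segregation of
    thermophoretically strong (sinking) and weak (staying high) species
    across the network.  ``port_assignment="random"`` ignores the rows.

    Single-outflow chambers route everything through one port; ``s_bot``
    for the chamber-response lookup is then 1.0 (bottom port) or
    ``table_s_min`` (top port, i.e. a nearly closed bottom).
    """
    if port_assignment not in ("geometric", "random"):
        raise ValueError("port_assignment must be 'geometric' or 'random'")
    R, C = topology.n_rows, topology.n_cols
    rng = np.random.default_rng(
        np.random.SeedSequence([topology.seed if seed is None else seed, 0x666C6F77])
    )
    Q = np.zeros((R, C))
    Q[:, 0] = topology.Q_in_per_inlet
    s_bot = np.zeros((R, C))
    single = np.zeros((R, C), dtype=bool)
    for n in range(C):
        for m in range(R):
            outs = topology.outflows(m, n)
            q = Q[m, n]
            if q <= 0:
                raise RuntimeError(f"chamber ({m},{n}) has zero throughflow")
            if len(outs) == 2:
                f = float(rng.uniform(*SPLIT_BOUNDS))
                if port_assignment == "geometric":
                    p0, p1 = _geometric_port(outs[0]), _geometric_port(outs[1])
                    if p0 is None and p1 is None:
                        p0 = "bottom" if rng.random() < 0.5 else "top"
                    if p0 is None:
                        p0 = "top" if p1 == "bottom" else "bottom"
                    elif p1 is None or p1 == p0:
                        p1 = "top" if p0 == "bottom" else "bottom"
                else:
                    p0 = "bottom" if rng.random() < 0.5 else "top"
                    p1 = "top" if p0 == "bottom" else "bottom"
                for ch, p in ((outs[0], p0), (outs[1], p1)):
                    ch.port = p
                    ch.rate = (f if p == "bottom" else 1.0 - f) * q
                s_bot[m, n] = f
            elif len(outs) == 1:
                port = _geometric_port(outs[0]) if port_assignment == "geometric" else None
                if port is None:
                    port = "bottom" if rng.random() < 0.5 else "top"
                outs[0].port = port
                outs[0].rate = q
                s_bot[m, n] = 1.0 if port == "bottom" else table_s_min
                single[m, n] = True
            else:
                raise RuntimeError(f"chamber ({m},{n}) has {len(outs)} outflows")
            if n + 1 < C:
                for c in outs:
                    Q[c.m_to, n + 1] += c.rate
    return NetworkFlows(Q_total=Q, s_bot=s_bot, single_outflow=single)


@dataclass
class NetworkState:
    """Per-chamber concentrations of one propagated system (per species)."""

    topology: NetworkTopology
    flows: NetworkFlows
    species: list
    c_in: np.ndarray  # (n_species, n_rows, n_cols), units of the feed
    c_bot: np.ndarray
    c_out_top: np.ndarray
    c_out_bot: np.ndarray
    feed: np.ndarray  # (n_species,)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        R, C = self.topology.n_rows, self.topology.n_cols
        for i, sp in enumerate(self.species):
            for m in range(R):
                for n in range(C):
                    rows.append(
                        {
                            "species": sp,
                            "m": m,
                            "n": n,
                            "c_in": self.c_in[i, m, n],
                            "c_bot": self.c_bot[i, m, n],
                            "c_out_top": self.c_out_top[i, m, n],
                            "c_out_bot": self.c_out_bot[i, m, n],
                        }
                    )
        return pd.DataFrame(rows)

    def boundary_outflux(self, species: str) -> float:
        """Total solute flux leaving the system (concentration x m^3/s)."""
        i = self.species.index(species)
        total = 0.0
        for c in self.topology.channels:
            if c.m_to is None:
                m, n = c.m_from, c.n_from
                conc = self._channel_concentration(i, m, n, c)
                total += c.rate * conc
        return total

    def _channel_concentration(self, i: int, m: int, n: int, channel: Channel) -> float:
        if self.flows.single_outflow[m, n]:
            return self.c_in[i, m, n]  # conservation: all solute, one channel
        return self.c_out_bot[i, m, n] if channel.port == "bottom" else self.c_out_top[i, m, n]


def propagate(
    topology: NetworkTopology,
    flows: NetworkFlows,
    solutes: list[Solute],
    delta_T,
    table: TransferTable,
    feed: dict | float = 1.0,
    clamp: bool = False,
) -> NetworkState:
    """Column-by-column steady propagation of all species through the grid.

    First-column inlets carry the feed concentration; each chamber's inlet
    concentration is the flow-weighted mix of its feeding channels, and
    its outlet/bottom concentrations follow from the transfer table (the
    response is linear in the inlet concentration).  ``delta_T`` is a
    scalar (uniform network, the default situation) or an (n_rows,
    n_cols) array of per-chamber temperature differences for robustness
    studies.
    """
    R, C = topology.n_rows, topology.n_cols
    delta_T = np.broadcast_to(np.asarray(delta_T, dtype=float), (R, C))
    n_sp = len(solutes)
    feed_vec = np.array(
        [feed[s.name] if isinstance(feed, dict) else float(feed) for s in solutes]
    )
    c_in = np.zeros((n_sp, R, C))
    c_bot = np.zeros((n_sp, R, C))
    c_top_out = np.zeros((n_sp, R, C))
    c_bot_out = np.zeros((n_sp, R, C))
    state = NetworkState(
        topology=topology,
        flows=flows,
        species=[s.name for s in solutes],
        c_in=c_in,
        c_bot=c_bot,
        c_out_top=c_top_out,
        c_out_bot=c_bot_out,
        feed=feed_vec,
    )
    c_in[:, :, 0] = feed_vec[:, None]

    by_source = {}
    for ch in topology.channels:
        by_source.setdefault((ch.m_from, ch.n_from), []).append(ch)

    for n in range(C):
        for i, sol in enumerate(solutes):
            try:
                resp = interpolate_transfer(
                    table,
                    delta_T[:, n],
                    sol.D,
                    sol.S_T,
                    flows.Q_total[:, n],
                    flows.s_bot[:, n],
                    clamp=clamp,
                )
            except Exception as exc:
                raise RuntimeError(
                    f"transfer lookup failed in column {n} for {sol.name}: {exc}"
                ) from exc
            c_bot[i, :, n] = resp.bottom_mean * c_in[i, :, n]
            c_top_out[i, :, n] = resp.c_out_top * c_in[i, :, n]
            c_bot_out[i, :, n] = resp.c_out_bot * c_in[i, :, n]
        if n + 1 < C:
            influx = np.zeros((n_sp, R))
            for m in range(R):
                for ch in by_source.get((m, n), []):
                    conc = np.array(
                        [state._channel_concentration(i, m, n, ch) for i in range(n_sp)]
                    )
                    influx[:, ch.m_to] += ch.rate * conc
            c_in[:, :, n + 1] = influx / flows.Q_total[:, n + 1][None, :]
    return state


def median_of_top(values, n_top: int = 10) -> float:
    """Median of the ``n_top`` largest values (all values if fewer)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty value set")
    top = np.sort(values)[-min(n_top, values.size):]
    return float(np.median(top))


def max_enrichment(
    states: NetworkState | list[NetworkState],
    species_a: str,
    species_b: str,
    n_top: int = 10,
) -> float:
    """Median of the ``n_top`` largest per-chamber bottom ratios A/B.

    Chambers are pooled across the given systems.  Ratios are formed on
    concentrations relative to the respective feeds, so a 1:1 comparison is
    returned even for unequal absolute feeds.  Chambers where B's bottom
    concentration is zero are excluded with a warning; fewer than ``n_top``
    chambers means all are used.
    """
    if isinstance(states, NetworkState):
        states = [states]
    ratios = []
    for st in states:
        ia, ib = st.species.index(species_a), st.species.index(species_b)
        a = st.c_bot[ia].ravel() / st.feed[ia]
        b = st.c_bot[ib].ravel() / st.feed[ib]
        ok = b > 0
        if not ok.all():
            warnings.warn(
                f"excluding {int((~ok).sum())} chambers with zero {species_b} bottom concentration"
            )
        ratios.append(a[ok] / b[ok])
    ratios = np.concatenate(ratios)
    if ratios.size == 0:
        raise ValueError("no valid chambers for enrichment statistic")
    return median_of_top(ratios, n_top)


def purity(states: NetworkState | list[NetworkState], species_a: str, species_b: str) -> float:
    """Largest per-chamber purity c_A/(c_A + c_B) over the pooled chambers
    (concentrations relative to the feeds, i.e. for a 1:1 feed)."""
    if isinstance(states, NetworkState):
        states = [states]
    best = 0.0
    for st in states:
        ia, ib = st.species.index(species_a), st.species.index(species_b)
        a = st.c_bot[ia].ravel() / st.feed[ia]
        b = st.c_bot[ib].ravel() / st.feed[ib]
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(a + b > 0, a / (a + b), 0.0)
        best = max(best, float(p.max()))
    return best


@dataclass
class EnsembleResult:
    """Max-enrichment statistics over repeated resampled ensembles."""

    pairs: dict  # (A, B) -> {"mean", "sd", "values"}
    n_failed: int
    config: dict

    def mean(self, a: str, b: str) -> float:
        return self.pairs[(a, b)]["mean"]

    def sd(self, a: str, b: str) -> float:
        return self.pairs[(a, b)]["sd"]


def ensemble(
    solutes: list[Solute],
    table: TransferTable,
    n_rows: int,
    n_cols: int,
    delta_T: float,
    Q_in_per_inlet: float = 1e-12,
    n_systems: int = 30,
    n_repeats: int = 3,
    seed: int = 0,
    resample_soret: bool = True,
    clamp: bool = True,
    pairs: list | None = None,
    keep_states: bool = False,
    fixed_topologies: bool = False,
) -> EnsembleResult:
    """Monte-Carlo ensemble of crack networks with Soret-error propagation.

    Per repeat, each species' Soret coefficient is redrawn from a Gaussian
    around its mean with its random error (if ``resample_soret``), and
    ``n_systems`` independent topologies are generated and propagated; the
    pooled max-enrichment statistic of each species pair is recorded.  The
    result carries the mean and s.d. over repeats.  Failing systems are
    excluded and counted.
    """
    ss = np.random.SeedSequence([seed, 0x656E7362])
    rep_seeds = ss.spawn(n_repeats)
    names = [s.name for s in solutes]
    if pairs is None:
        pairs = [(a, b) for a in names for b in names if a != b]
    values = {p: [] for p in pairs}
    n_failed = 0
    all_states = []
    for r, rs in enumerate(rep_seeds):
        rng = np.random.default_rng(rs)
        if resample_soret:
            drawn = [
                Solute(
                    s.name,
                    D=s.D,
                    S_T=float(rng.normal(s.S_T, s.sigma_random)),
                    sigma_random=s.sigma_random,
                    sigma_systematic=s.sigma_systematic,
                )
                for s in solutes
            ]
        else:
            drawn = solutes
        states = []
        if fixed_topologies:
            sys_seeds = np.random.default_rng(
                np.random.SeedSequence([seed, 0x746F706F])
            ).integers(0, 2**31 - 1, size=n_systems)
        else:
            sys_seeds = rng.integers(0, 2**31 - 1, size=n_systems)
        for z in range(n_systems):
            try:
                topo = generate_topology(
                    n_rows, n_cols, Q_in_per_inlet, seed=int(sys_seeds[z])
                )
                flows = solve_flow_rates(topo, table_s_min=float(table.axes["s_bot"][0]))
                states.append(propagate(topo, flows, drawn, delta_T, table, clamp=clamp))
            except Exception as exc:
                n_failed += 1
                warnings.warn(f"repeat {r} system {z} failed: {exc}")
        if not states:
            continue
        if keep_states:
            all_states.append(states)
        for p in pairs:
            values[p].append(max_enrichment(states, *p))
    result = EnsembleResult(
        pairs={
            p: {
                "mean": float(np.mean(v)) if v else float("nan"),
                "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
                "values": v,
            }
            for p, v in values.items()
        },
        n_failed=n_failed,
        config={
            "n_rows": n_rows,
            "n_cols": n_cols,
            "delta_T": delta_T,
            "Q_in_per_inlet": Q_in_per_inlet,
            "n_systems": n_systems,
            "n_repeats": n_repeats,
            "seed": seed,
        },
    )
    if keep_states:
        result.states = all_states
    return result
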