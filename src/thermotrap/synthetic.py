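"""Synthetic datasets with the statistical structure the pipeline assumes.

Every input the analysis consumes can be generated here, so all stages are
testable without measurements:

* fraction tables — the forward chamber model run per replicate with a
  small uniform temperature-difference jitter (replicate temperature
  gradients genuinely differ by 1-2 K, which shifts all species of one
  replicate together and is the dominant systematic error), followed by
  multiplicative lognormal measurement noise (detector integrals are
  positive with roughly proportional error);
* reaction datasets — the dimerization ODEs integrated at the standard
  titration + time-series design, with optional lognormal noise and a
  triplicate structure;
* solute presets — named fixture tables spanning the observed Soret range
  1.4e-3 to 7.5e-3 1/K.  Only two values are measured anchors
  (3',5'-cAMP: 5.1e-3 +- 0.9e-3 1/K; TMP: ~7e-3 1/K); all other preset
  values are synthetic stand-ins chosen once to reproduce the qualitative
  ordering of the compound classes, and are labelled as such.

All generators are deterministic functions of their seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .physics import ChamberGeometry, SINGLE_CHAMBER, Solute
from .reaction import (
    RateConstants,
    TITRATION_GLY_LEVELS_M,
    TITRATION_TMP_LEVELS_M,
    integrate_batch,
)
from .soret import D_AMINO_ACID, D_NUCLEOTIDE, FRACTION_COLUMNS, simulate_fraction_means

__all__ = [
    "SyntheticSpec",
    "synth_fraction_table",
    "synth_reaction_data",
    "fixture_solutes",
    "preset_hash",
    "PRESETS",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Conditions for a synthetic fraction-table experiment."""

    solutes: tuple  # of Solute (true S_T and D)
    delta_T_K: float = 15.0
    jitter_K: float = 1.5  # replicate gradients differ by 1-2 K
    n_replicates: int = 3
    noise_sigma: float = 0.03  # multiplicative lognormal sigma
    seed: int = 0

    def __post_init__(self):
        if self.jitter_K < 0 or self.noise_sigma < 0:
            raise ValueError("jitter and noise must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")


def synth_fraction_table(
    spec: SyntheticSpec,
    geometry: ChamberGeometry = SINGLE_CHAMBER,
    duration: float = 18 * 3600.0,
    T_mean: float = 32.5,
    nx: int = 40,
    ny: int = 200,
) -> pd.DataFrame:
    """Triplicate-style fraction table from the forward chamber model.

    Per replicate k the temperature difference is drawn uniformly within
    ``+- jitter/2`` of the nominal value (recorded in ``delta_T_K``... the
    *nominal* value, as an experimenter reading a setpoint would log it —
    the jitter is what the error decomposition is meant to recover); each
    solute is run through the transient solver and the four fraction means
    receive lognormal noise.  The true parameters are stored in
    ``df.attrs["truth"]``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x66726163]))
    rows = []
    truth = {"delta_T_actual_K": {}, "S_T": {}, "D": {}}
    for k in range(1, spec.n_replicates + 1):
        dT_k = spec.delta_T_K + rng.uniform(-0.5, 0.5) * spec.jitter_K
        truth["delta_T_actual_K"][k] = dT_k
        for sol in spec.solutes:
            means = simulate_fraction_means(
                sol.S_T, sol.D, dT_k, geometry, T_mean, duration, nx, ny
            )
            noisy = means * np.exp(spec.noise_sigma * rng.standard_normal(len(means)))
            for j, v in enumerate(noisy, start=1):
                rows.append(
                    {
                        "species": sol.name,
                        "replicate": k,
                        "fraction_index": j,
                        "value": v,
                        "delta_T_K": spec.delta_T_K,
                    }
                )
            truth["S_T"][sol.name] = sol.S_T
            truth["D"][sol.name] = sol.D
    df = pd.DataFrame(rows, columns=FRACTION_COLUMNS)
    df.attrs["truth"] = truth
    return df


def synth_reaction_data(
    rates: RateConstants,
    noise_sigma: float = 0.0,
    seed: int = 0,
    n_replicates: int = 3,
    titration_time_s: float = 16 * 3600.0,
    timeseries_times_s: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic (titration, time-series) product datasets.

    Titration: product concentration after 16 h for 2 glycine levels x 9
    TMP levels; time series: Gly = TMP = 100 mM followed to 120 h.
    Lognormal multiplicative noise of width ``noise_sigma`` per replicate.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x72786E]))
    if timeseries_times_s is None:
        timeseries_times_s = np.array([2, 4, 8, 16, 24, 48, 72, 96, 120]) * 3600.0

    def noisy(x):
        return x * np.exp(noise_sigma * rng.standard_normal())

    tit_rows = []
    for g0 in TITRATION_GLY_LEVELS_M:
        for t0 in TITRATION_TMP_LEVELS_M:
            df = integrate_batch(
                {"Gly": g0, "TMP": t0}, rates, duration=titration_time_s,
                t_eval=[titration_time_s],
            )
            gg = float(df["GlyGly"].iloc[-1])
            for k in range(1, n_replicates + 1):
                tit_rows.append(
                    {
                        "gly_init_M": g0, "tmp_init_M": t0,
                        "time_s": titration_time_s, "glygly_M": noisy(gg),
                        "replicate": k,
                    }
                )
    ts_rows = []
    df = integrate_batch(
        {"Gly": 0.1, "TMP": 0.1}, rates,
        duration=float(np.max(timeseries_times_s)), t_eval=timeseries_times_s,
    )
    for t, gg in zip(df.index.to_numpy(), df["GlyGly"].to_numpy()):
        for k in range(1, n_replicates + 1):
            ts_rows.append(
                {
                    "gly_init_M": 0.1, "tmp_init_M": 0.1,
                    "time_s": float(t), "glygly_M": noisy(float(gg)),
                    "replicate": k,
                }
            )
    return pd.DataFrame(tit_rows), pd.DataFrame(ts_rows)


# ---------------------------------------------------------------------------
# solute presets
#
# provenance "anchor"    : measured value quoted in the field
# provenance "stand-in"  : synthetic value chosen to span the observed
#                          Soret range with the right qualitative ordering
# ---------------------------------------------------------------------------

_SIGMA_REL = 0.15  # stand-in random error as a fraction of S_T
_SIGMA_SYS = 0.10  # stand-in systematic error fraction

def _standin(name, S_T, D):
    return {
        "name": name, "D": D, "S_T": S_T,
        "sigma_random": _SIGMA_REL * S_T, "sigma_systematic": _SIGMA_SYS,
        "provenance": "stand-in",
    }


PRESETS = {
    # proteogenic amino acids: glycine weakest, aliphatics (I, L, V) strongest
    "amino_acids": [
        _standin("G", 1.4e-3, D_AMINO_ACID),
        _standin("S", 1.9e-3, D_AMINO_ACID),
        _standin("N", 2.1e-3, D_AMINO_ACID),
        _standin("Q", 2.3e-3, D_AMINO_ACID),
        _standin("F", 6.3e-3, D_AMINO_ACID),
        _standin("V", 7.0e-3, D_AMINO_ACID),
        _standin("L", 7.2e-3, D_AMINO_ACID),
        _standin("I", 7.5e-3, D_AMINO_ACID),
    ],
    # adenosine and its phosphorylation states: phosphates strengthen S_T,
    # cyclic ones most; the 3',5'-cAMP value is a measured anchor
    "adenine_series": [
        _standin("Ado", 3.2e-3, D_NUCLEOTIDE),
        _standin("5'-AMP", 4.4e-3, D_NUCLEOTIDE),
        {
            "name": "3',5'-cAMP", "D": D_NUCLEOTIDE, "S_T": 5.1e-3,
            "sigma_random": 0.9e-3, "sigma_systematic": _SIGMA_SYS,
            "provenance": "anchor",
        },
        _standin("2',3'-cAMP", 5.3e-3, D_NUCLEOTIDE),
    ],
    # 2-aminoazoles: 2AI accumulates more strongly than 2AO
    "aminoazoles": [
        _standin("2AO", 1.6e-3, D_NUCLEOTIDE),
        _standin("2AT", 2.4e-3, D_NUCLEOTIDE),
        _standin("2AI", 3.0e-3, D_NUCLEOTIDE),
    ],
    # the reaction pair: TMP thermophoretically strong (measured anchor),
    # glycine the weakest compound of the set
    "gly_tmp": [
        _standin("Gly", 1.4e-3, D_AMINO_ACID),
        {
            "name": "TMP", "D": D_NUCLEOTIDE, "S_T": 7.0e-3,
            "sigma_random": _SIGMA_REL * 7.0e-3, "sigma_systematic": _SIGMA_SYS,
            "provenance": "anchor",
        },
    ],
}


def fixture_solutes(preset: str) -> list[Solute]:
    """Named, immutable solute tables (see PRESETS for provenance)."""
    if preset not in PRESETS:
        raise KeyError(f"unknown preset {preset!r}; have {sorted(PRESETS)}")
    return [
        Solute(
            name=e["name"], D=e["D"], S_T=e["S_T"],
            sigma_random=e["sigma_random"], sigma_systematic=e["sigma_systematic"],
        )
        for e in PRESETS[preset]
    ]


def preset_hash(preset: str) -> str:
    """Content hash versioning a preset (changes iff its values change)."""
    payload = json.dumps(PRESETS[preset], sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()
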