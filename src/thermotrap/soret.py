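"""Soret-coefficient inference from fraction-averaged concentration tables.

The measurement a chamber experiment produces is, per species and
replicate, four vertical-fraction concentrations (arbitrary detector
units).  The pipeline here mirrors the analysis chain of such experiments:

1. per-species, per-replicate normalization to mean 1 over the fractions
   (calibration factors and absolute concentrations cancel);
2. pairwise enrichment of species A over B in a fraction — the replicate
   mean of the per-replicate concentration *ratio*, minus 1 (ratios are
   formed before averaging because the temperature difference jitters
   between replicates and shifts all species of one replicate together);
3. enrichment of one species against the pool mean of all species;
4. per-replicate least-squares fits of the Soret coefficient by matching
   the transient (18 h) forward chamber model to the measured fraction
   means;
5. decomposition of replicate scatter into a systematic part (common
   multiplicative shift, from the replicate-vs-replicate regression slope)
   and a random part (residual scatter about that regression).

Fraction tables are plain pandas DataFrames with columns
``species, replicate, fraction_index, value, delta_T_K``
(fraction 1 = top).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .physics import ChamberGeometry, SINGLE_CHAMBER, Solute, ThermalConditions
from .solver import convective_flow_field, fraction_averages, solve_drift_diffusion

__all__ = [
    "FRACTION_COLUMNS",
    "SoretEstimate",
    "normalize_fractions",
    "pairwise_enrichment",
    "pool_enrichment",
    "simulate_fraction_means",
    "fit_soret",
    "replicate_error_split",
]

FRACTION_COLUMNS = ["species", "replicate", "fraction_index", "value", "delta_T_K"]

#: default diffusion coefficients by compound class, m^2/s
D_AMINO_ACID = 800e-12
D_NUCLEOTIDE = 1400e-12

#: search bounds for the Soret coefficient, 1/K
S_T_BOUNDS = (-1e-2, 2e-2)


def _check_table(table: pd.DataFrame) -> None:
    missing = [c for c in FRACTION_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"fraction table missing columns {missing}")
    if (table["value"] < 0).any():
        raise ValueError("fraction table contains negative values")


def normalize_fractions(table: pd.DataFrame) -> pd.DataFrame:
    """Normalize each (species, replicate) to mean 1 over its fractions.

    Idempotent; raises if any (species, replicate) group is all zero.
    """
    _check_table(table)
    out = table.copy()
    means = out.groupby(["species", "replicate"])["value"].transform("mean")
    zero = means <= 0
    if zero.any():
        bad = out.loc[zero, ["species", "replicate"]].drop_duplicates()
        raise ValueError(
            "all-zero fraction values for "
            + ", ".join(f"{r.species}/replicate {r.replicate}" for r in bad.itertuples())
        )
    out["value"] = out["value"] / means
    return out


def _pivot(table: pd.DataFrame) -> pd.DataFrame:
    """(species, replicate) x fraction_index matrix of normalized values."""
    return table.pivot_table(
        index=["species", "replicate"], columns="fraction_index", values="value"
    )


def pairwise_enrichment(table: pd.DataFrame, fraction: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean and s.d. of the enrichment of A over B in one fraction.

    Entry (A, B) is ``mean_k([A]_{j,k} / [B]_{j,k}) - 1`` over replicates k,
    with the ratio formed per replicate before averaging.  Returns
    (mean_matrix, sd_matrix) as species x species DataFrames; the diagonal
    is exactly 0.
    """
    norm = normalize_fractions(table)
    sub = norm[norm["fraction_index"] == fraction]
    if sub.empty:
        raise ValueError(f"no rows for fraction {fraction}")
    wide = sub.pivot_table(index="replicate", columns="species", values="value")
    if wide.isna().any().any():
        raise ValueError("unequal replicate sets across species")
    if (wide <= 0).any().any():
        raise ValueError("zero concentration in denominator replicate")
    species = list(wide.columns)
    vals = wide.to_numpy()  # (K, S)
    ratios = vals[:, :, None] / vals[:, None, :]  # (K, A, B)
    mean = ratios.mean(axis=0) - 1.0
    sd = ratios.std(axis=0, ddof=1) if len(wide) > 1 else np.zeros_like(mean)
    np.fill_diagonal(mean, 0.0)
    np.fill_diagonal(sd, 0.0)
    return (
        pd.DataFrame(mean, index=species, columns=species),
        pd.DataFrame(sd, index=species, columns=species),
    )


def pool_enrichment(
    table: pd.DataFrame, fraction: int, literal_difference: bool = False
) -> pd.Series:
    """Enrichment of each species against the pool mean in one fraction.

    The pool mean is the average of the normalized concentrations of all
    species (per replicate).  By default the replicate mean of the RATIO
    species/pool, minus 1, is returned; ``literal_difference=True`` instead
    averages the difference species - pool (then subtracts 1), reproducing
    the printed formula literally.
    """
    norm = normalize_fractions(table)
    sub = norm[norm["fraction_index"] == fraction]
    wide = sub.pivot_table(index="replicate", columns="species", values="value")
    pool = wide.mean(axis=1)
    if (pool <= 0).any():
        raise ValueError("pool mean is zero in at least one replicate")
    if literal_difference:
        return (wide.sub(pool, axis=0)).mean(axis=0) - 1.0
    return (wide.div(pool, axis=0)).mean(axis=0) - 1.0


def simulate_fraction_means(
    S_T: float,
    D: float,
    delta_T: float,
    geometry: ChamberGeometry = SINGLE_CHAMBER,
    T_mean: float = 32.5,
    duration: float = 18 * 3600.0,
    nx: int = 40,
    ny: int = 200,
) -> np.ndarray:
    """Forward model: normalized fraction means (top-first) after a closed
    transient run of ``duration`` seconds."""
    thermal = ThermalConditions.from_delta(delta_T, T_mean=T_mean)
    solute = Solute("fit", D=D, S_T=float(S_T))
    flow = convective_flow_field(geometry, thermal, nx=nx, ny=ny)
    fld = solve_drift_diffusion(flow, solute, mode="transient", duration=duration)
    return fraction_averages(fld)


@dataclass
class SoretEstimate:
    """Fitted Soret coefficient of one species."""

    species: str
    S_T: float  # replicate mean, 1/K
    sigma_random: float  # s.d. across replicates, 1/K
    sigma_systematic: float  # fraction (filled by replicate_error_split)
    per_replicate: dict = field(default_factory=dict)
    at_boundary: bool = False


def _fit_one(
    measured: np.ndarray,
    D: float,
    delta_T: float,
    geometry: ChamberGeometry,
    T_mean: float,
    duration: float,
    nx: int,
    ny: int,
    n_scan: int = 9,
) -> tuple[float, bool]:
    """Bounded least squares of one replicate's fraction means over S_T.

    A coarse scan over the bounded range (the multi-start stage) brackets
    the optimum; a local bounded least-squares refines it.
    """
    lo, hi = S_T_BOUNDS

    def resid(s):
        sim = simulate_fraction_means(
            float(np.atleast_1d(s)[0]), D, delta_T, geometry, T_mean, duration, nx, ny
        )
        return sim - measured

    # scan: log-spaced magnitudes of both signs plus zero
    pos = np.geomspace(2e-4, hi * 0.9, n_scan // 2 + 1)
    neg = -np.geomspace(2e-4, -lo * 0.9, n_scan // 2)[::-1]
    starts = np.concatenate([neg, [0.0], pos])
    costs = [float(np.sum(resid(s) ** 2)) for s in starts]
    s0 = starts[int(np.argmin(costs))]
    res = least_squares(
        resid, x0=[s0], bounds=([lo], [hi]), xtol=1e-12, ftol=1e-12, diff_step=1e-2
    )
    s_fit = float(res.x[0])
    at_boundary = min(s_fit - lo, hi - s_fit) < 1e-4 * (hi - lo)
    return s_fit, at_boundary


def fit_soret(
    table: pd.DataFrame,
    D: float | dict,
    geometry: ChamberGeometry = SINGLE_CHAMBER,
    T_mean: float = 32.5,
    duration: float = 18 * 3600.0,
    nx: int = 40,
    ny: int = 200,
) -> list[SoretEstimate]:
    """Fit one Soret coefficient per species by matching the forward model.

    Per replicate, the measured normalized fraction means are matched by
    the 18 h transient chamber model at that replicate's recorded
    temperature difference; the species estimate is the mean and s.d. of
    the per-replicate fits.  ``D`` is the assumed diffusion coefficient
    (scalar, or a dict per species); the fit depends only weakly on it.
    """
    norm = normalize_fractions(table)
    estimates = []
    for species, grp in norm.groupby("species", sort=False):
        D_sp = D[species] if isinstance(D, dict) else float(D)
        per_rep = {}
        flagged = False
        for rep, rg in grp.groupby("replicate"):
            rg = rg.sort_values("fraction_index")
            measured = rg["value"].to_numpy()
            delta_T = float(rg["delta_T_K"].iloc[0])
            s_fit, at_b = _fit_one(
                measured, D_sp, delta_T, geometry, T_mean, duration, nx, ny
            )
            per_rep[rep] = s_fit
            flagged = flagged or at_b
        vals = np.array(list(per_rep.values()))
        estimates.append(
            SoretEstimate(
                species=str(species),
                S_T=float(vals.mean()),
                sigma_random=float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                sigma_systematic=0.0,
                per_replicate=per_rep,
                at_boundary=flagged,
            )
        )
    return estimates


def estimates_frame(estimates: list) -> pd.DataFrame:
    """Tabulate fitted estimates (the soret_estimates.csv schema)."""
    return pd.DataFrame(
        {
            "species": [e.species for e in estimates],
            "S_T_per_K": [e.S_T for e in estimates],
            "sigma_random": [e.sigma_random for e in estimates],
            "sigma_systematic": [e.sigma_systematic for e in estimates],
            "n_replicates": [len(e.per_replicate) for e in estimates],
        }
    )


def replicate_error_split(per_replicate: pd.DataFrame) -> dict:
    """Split replicate scatter of fitted S_T values into systematic/random.

    Parameters
    ----------
    per_replicate : DataFrame
        Rows = species, columns = replicates, values = fitted S_T (1/K).
        Needs >= 2 species and >= 2 replicates.

    Returns
    -------
    dict with
        ``sigma_systematic`` — mean over replicate pairs of
        ``max(slope, 1/slope) - 1`` of the through-origin regression of one
        replicate's values on the other's (a common temperature-difference
        offset shifts all species of a replicate together, i.e. appears as
        a slope != 1);
        ``sigma_random`` — pooled s.d. of the regression residuals divided
        by sqrt(2) (both replicates carry the noise), in 1/K.

    Notes
    -----
    Both pair directions give the same result by the symmetric slope form.
    """
    X = per_replicate.to_numpy(dtype=float)
    n_species, n_rep = X.shape
    if n_species < 2:
        raise ValueError("replicate_error_split needs >= 2 species (slope undefined)")
    if n_rep < 2:
        raise ValueError("replicate_error_split needs >= 2 replicates")
    slopes = []
    resid_sq = []
    for a, b in itertools.combinations(range(n_rep), 2):
        xa, xb = X[:, a], X[:, b]
        denom = float(xa @ xa)
        if denom == 0:
            raise ValueError("degenerate replicate with all-zero S_T values")
        slope = float(xb @ xa) / denom
        slopes.append(max(abs(slope), 1.0 / abs(slope)) - 1.0)
        r = xb - slope * xa
        resid_sq.extend((r**2).tolist())
    sigma_sys = float(np.mean(slopes))
    sigma_rand = float(np.sqrt(np.mean(resid_sq) / 2.0))
    return {"sigma_systematic": sigma_sys, "sigma_random": sigma_rand}
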