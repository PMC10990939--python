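"""Precomputed single-chamber responses on a parameter grid.

The network simulator never solves a chamber PDE directly: every chamber's
steady response is looked up in a :class:`TransferTable` computed once over
a grid of boundary conditions (temperature difference, diffusion
coefficient, Soret coefficient, inflow rate, bottom-outflow share) and
interpolated multilinearly, with the flow-rate axis handled in log space.

Stored per cell (all for unit feed concentration):

* ``phi_top`` / ``phi_bot`` — the fractions of the incoming solute flux
  leaving through the top and bottom outlets.  They sum to 1 exactly for
  every cell, and because the sum is linear it is preserved by the
  interpolation, so solute conservation through table lookups is exact by
  construction.  Outlet concentrations are recovered at query time as
  ``c_out_top = phi_top / (1 - s_bot)`` and ``c_out_bot = phi_bot / s_bot``.
* ``bottom_mean`` — the mean concentration of the lowest
  ``bottom_probe_height`` of the chamber (the "reaction volume").
* ``fraction_means`` — equal-height slab means, top-first.

Tables are persisted as a ``.npz`` array container plus a human-readable
JSON metadata sidecar; :func:`build_transfer_table` reuses an existing file
when its axes and settings match.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .physics import ChamberGeometry, NETWORK_CHAMBER, Solute, ThermalConditions
from .solver import SolverError, chamber_response, convective_flow_field, solve_drift_diffusion

__all__ = [
    "TransferTable",
    "TransferResponse",
    "OutOfHullError",
    "DEFAULT_AXES",
    "build_transfer_table",
    "interpolate_transfer",
]

logger = logging.getLogger(__name__)

AXIS_NAMES = ("delta_T", "D", "S_T", "Q_in", "s_bot")

#: the reference parameter sweep (temperatures in K, D in m^2/s, S_T in 1/K,
#: Q_in in m^3/s, bottom-outflow share dimensionless)
DEFAULT_AXES = {
    "delta_T": np.arange(0.0, 13.0),  # 0..12 K
    "D": np.array([800e-12, 1400e-12]),
    "S_T": np.array([1e-3, 4e-3, 8e-3, 12e-3]),
    "Q_in": np.array([0.01, 0.05, 0.1, 0.5, 1.0, 5.0, 10.0]) * 1e-12,  # nl/s -> m^3/s
    "s_bot": np.array([0.01, 0.05, 0.10, 0.20, 0.50, 1.00]),
}


class OutOfHullError(ValueError):
    """A query lies outside the table's axis hull."""


@dataclass
class TransferResponse:
    """Interpolated chamber response for unit feed concentration."""

    phi_top: np.ndarray
    phi_bot: np.ndarray
    bottom_mean: np.ndarray
    fraction_means: np.ndarray
    c_out_top: np.ndarray
    c_out_bot: np.ndarray


@dataclass
class TransferTable:
    axes: dict[str, np.ndarray]
    phi_top: np.ndarray
    phi_bot: np.ndarray
    bottom_mean: np.ndarray
    fraction_means: np.ndarray  # (*grid, n_fractions)
    metadata: dict
    _interp: dict = field(default_factory=dict, repr=False)

    @property
    def shape(self) -> tuple:
        return tuple(len(self.axes[k]) for k in AXIS_NAMES)

    def axis_points(self):
        return [np.asarray(self.axes[k], dtype=float) for k in AXIS_NAMES]

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for k in AXIS_NAMES:
            h.update(np.ascontiguousarray(self.axes[k], dtype=float).tobytes())
        for arr in (self.phi_top, self.phi_bot, self.bottom_mean, self.fraction_means):
            h.update(np.ascontiguousarray(arr, dtype=float).tobytes())
        return h.hexdigest()

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez_compressed(
            path.with_suffix(".npz"),
            phi_top=self.phi_top,
            phi_bot=self.phi_bot,
            bottom_mean=self.bottom_mean,
            fraction_means=self.fraction_means,
            **{f"axis_{k}": self.axes[k] for k in AXIS_NAMES},
        )
        meta = dict(self.metadata)
        meta["content_hash"] = self.content_hash()
        meta["axes"] = {k: np.asarray(self.axes[k]).tolist() for k in AXIS_NAMES}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "TransferTable":
        path = Path(path)
        with np.load(path.with_suffix(".npz")) as z:
            axes = {k: z[f"axis_{k}"] for k in AXIS_NAMES}
            table = cls(
                axes=axes,
                phi_top=z["phi_top"],
                phi_bot=z["phi_bot"],
                bottom_mean=z["bottom_mean"],
                fraction_means=z["fraction_means"],
                metadata=json.loads(path.with_suffix(".json").read_text()),
            )
        return table


def _validate_axes(axes: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    out = {}
    for name in AXIS_NAMES:
        if name not in axes:
            raise ValueError(f"missing axis {name!r}")
        vals = np.asarray(axes[name], dtype=float)
        if vals.ndim != 1 or len(vals) < 1:
            raise ValueError(f"axis {name!r} must be a 1-D array")
        if np.any(np.diff(vals) <= 0):
            raise ValueError(f"axis {name!r} must be strictly increasing")
        out[name] = vals
    if out["Q_in"][0] <= 0:
        raise ValueError("Q_in axis values must be > 0 (log-space interpolation)")
    if out["s_bot"][0] < 0 or out["s_bot"][-1] > 1:
        raise ValueError("s_bot axis must lie in [0, 1]")
    return out


def build_transfer_table(
    geometry: ChamberGeometry = NETWORK_CHAMBER,
    axes: dict[str, np.ndarray] | None = None,
    T_mean: float = 35.0,
    nx: int = 40,
    ny: int = 200,
    path: str | Path | None = None,
    progress: bool = False,
) -> TransferTable:
    """Solve one steady chamber per grid cell and collect the responses.

    If ``path`` is given and a previously saved table there matches the
    requested axes and settings, it is loaded instead of recomputed
    (resumability).  Cells whose steady solve fails are recorded in
    ``metadata['failed_cells']`` and filled with NaN — never silently
    interpolated over (queries touching them produce NaN, and a warning is
    emitted at build time).
    """
    axes = _validate_axes(axes if axes is not None else DEFAULT_AXES)
    settings = {
        "geometry": {
            "height": geometry.height,
            "width": geometry.width,
            "thickness": geometry.thickness,
            "n_fractions": geometry.n_fractions,
            "bottom_probe_height": geometry.bottom_probe_height,
        },
        "T_mean": T_mean,
        "nx": nx,
        "ny": ny,
    }
    if path is not None:
        path = Path(path)
        if path.with_suffix(".npz").exists() and path.with_suffix(".json").exists():
            try:
                cached = TransferTable.load(path)
                same_axes = all(
                    np.array_equal(cached.axes[k], axes[k]) for k in AXIS_NAMES
                )
                if same_axes and cached.metadata.get("settings") == settings:
                    return cached
            except Exception:  # corrupt cache: rebuild
                logger.warning("could not reuse cached transfer table at %s", path)

    shape = tuple(len(axes[k]) for k in AXIS_NAMES)
    phi_top = np.full(shape, np.nan)
    phi_bot = np.full(shape, np.nan)
    bottom_mean = np.full(shape, np.nan)
    fraction_means = np.full(shape + (geometry.n_fractions,), np.nan)
    failed = []

    ranges = [range(len(axes[k])) for k in AXIS_NAMES]
    total = int(np.prod(shape))
    done = 0
    for idx in itertools.product(*ranges):
        i_dT, i_D, i_ST, i_Q, i_s = idx
        dT = axes["delta_T"][i_dT]
        D = axes["D"][i_D]
        ST = axes["S_T"][i_ST]
        Q = axes["Q_in"][i_Q]
        s = axes["s_bot"][i_s]
        thermal = ThermalConditions.from_delta(dT, T_mean=T_mean)
        solute = Solute("cell", D=D, S_T=ST)
        try:
            flow = convective_flow_field(
                geometry, thermal, Q_in=Q, bottom_outflow_fraction=s, nx=nx, ny=ny
            )
            fld = solve_drift_diffusion(flow, solute, mode="steady")
            resp = chamber_response(fld, flow)
            pt = (1.0 - s) * resp.c_out_top
            pb = s * resp.c_out_bot
            # the split must sum to 1 (solute balance); tolerate only solver
            # roundoff and renormalize it away so conservation is exact
            if abs(pt + pb - 1.0) > 1e-3:
                raise SolverError(
                    f"solute flux imbalance {pt + pb - 1.0:.2e} in steady response"
                )
            phi_top[idx] = pt / (pt + pb)
            phi_bot[idx] = pb / (pt + pb)
            bottom_mean[idx] = resp.bottom_mean
            fraction_means[idx] = resp.fraction_means
        except SolverError as exc:
            failed.append({"index": list(idx), "error": str(exc)})
        done += 1
        if progress and done % 200 == 0:
            logger.info("transfer table: %d/%d cells", done, total)
    if failed:
        logger.warning("transfer table: %d/%d cells failed to converge", len(failed), total)

    table = TransferTable(
        axes=axes,
        phi_top=phi_top,
        phi_bot=phi_bot,
        bottom_mean=bottom_mean,
        fraction_means=fraction_means,
        metadata={"settings": settings, "failed_cells": failed, "version": 1},
    )
    if path is not None:
        table.save(path)
    return table


def _transformed_points(table: TransferTable):
    pts = table.axis_points()
    pts[3] = np.log(pts[3])  # Q_in in log space
    return pts


def _get_interpolator(table: TransferTable, name: str) -> RegularGridInterpolator:
    if name not in table._interp:
        values = getattr(table, name)
        table._interp[name] = RegularGridInterpolator(
            _transformed_points(table), values, method="linear", bounds_error=False
        )
    return table._interp[name]


def interpolate_transfer(
    table: TransferTable,
    delta_T,
    D,
    S_T,
    Q_in,
    s_bot,
    clamp: bool = False,
) -> TransferResponse:
    """Multilinear lookup of the chamber response at arbitrary conditions.

    All five arguments broadcast to a common shape.  Queries outside the
    axis hull raise :class:`OutOfHullError` naming the offending axis, or —
    with ``clamp=True`` — are clipped to the hull (the event is logged).
    Queries exactly on grid nodes return the stored values.
    """
    q = np.broadcast_arrays(
        *[np.asarray(v, dtype=float) for v in (delta_T, D, S_T, Q_in, s_bot)]
    )
    shape = q[0].shape
    cols = [c.ravel().copy() for c in q]
    for name, vals, ax in zip(AXIS_NAMES, cols, table.axis_points()):
        lo, hi = ax[0], ax[-1]
        bad = (vals < lo) | (vals > hi)
        if np.any(bad):
            if clamp:
                logger.info(
                    "clamping %d %s queries to [%g, %g]", int(bad.sum()), name, lo, hi
                )
                np.clip(vals, lo, hi, out=vals)
            else:
                off = vals[bad][0]
                raise OutOfHullError(
                    f"axis {name!r}: query {off:g} outside hull [{lo:g}, {hi:g}]"
                )
    pts = np.column_stack(cols)
    pts[:, 3] = np.log(pts[:, 3])

    phi_top = _get_interpolator(table, "phi_top")(pts).reshape(shape)
    phi_bot = _get_interpolator(table, "phi_bot")(pts).reshape(shape)
    bottom = _get_interpolator(table, "bottom_mean")(pts).reshape(shape)
    fracs = _get_interpolator(table, "fraction_means")(pts).reshape(
        shape + (table.fraction_means.shape[-1],)
    )

    s = cols[4].reshape(shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        c_top = np.where(s < 1.0, phi_top / np.maximum(1.0 - s, 1e-300), 0.0)
        c_bot = np.where(s > 0.0, phi_bot / np.maximum(s, 1e-300), 0.0)
    return TransferResponse(
        phi_top=phi_top,
        phi_bot=phi_bot,
        bottom_mean=bottom,
        fraction_means=fracs,
        c_out_top=c_top,
        c_out_bot=c_bot,
    )
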