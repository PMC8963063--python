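"""Transient Pennes bioheat solver on the voxel model.

Integrates

    rho*c dT/dt = div(k grad T) - rho_b*c_b*w_v*(T - T_b) + rho*SAR

with implicit Euler on the model grid.  ``w_v`` is the volumetric perfusion
rate in 1/s, converted from the tabulated mL/kg/min as
``w_v = perfusion * rho_tissue * 1e-6 / 60``.  Conduction uses the same
two-point-flux discretization as the field solver (harmonic face
conductances, exact for layered media); the domain boundary is held at the
baseline temperature, which is weakly influential at the >= 10 mm margin.
Applicator materials conduct but have zero perfusion and carry no SAR
inside conductors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .model import VoxelModel

MM = 1e-3

#: clinical per-region maximum temperature limits (deg C)
DEFAULT_LIMITS = {"all tissue": 47.0, "urethra": 43.5, "bladder": 42.5, "rectum": 41.5}


@dataclass
class ThermalModel:
    """Blood-side and integration parameters for the Pennes solve."""

    blood_density: float = 1050.0       # kg/m^3
    blood_heat_capacity: float = 3617.0  # J/kg/K
    arterial_temperature: float = 37.0   # deg C
    baseline_temperature: float = 37.0   # deg C
    dt: float = 1.0                      # s
    duration: float = 1200.0             # s (20 min heating)

    def __post_init__(self):
        if min(self.blood_density, self.blood_heat_capacity, self.dt) <= 0:
            raise ValueError("thermal parameters must be > 0")
        if self.duration < 0:
            raise ValueError("duration must be >= 0")


@dataclass
class TemperatureVolume:
    """Per-cell temperature (deg C) after ``time`` seconds of heating."""

    T: np.ndarray
    time: float


def _conduction_matrix(model: VoxelModel) -> sp.csr_matrix:
    """Conduction operator K (W/K) plus boundary rows, cells in C order."""
    grid = model.grid
    nx, ny, nz = grid.shape
    n = nx * ny * nz
    k = model.property_map("k")
    dx = grid.steps("x") * MM
    dy = grid.steps("y") * MM
    dz = grid.steps("z") * MM
    r = [
        (dx[:, None, None] / 2.0) / k,
        (dy[None, :, None] / 2.0) / k,
        (dz[None, None, :] / 2.0) / k,
    ]
    areas = [
        (dy[:, None] * dz[None, :]),
        (dx[:, None] * dz[None, :]),
        (dx[:, None] * dy[None, :]),
    ]
    idx = np.arange(n).reshape(nx, ny, nz)
    diag = np.zeros(n)
    rows, cols, vals = [], [], []
    for axis in range(3):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(None, -1)
        sl_hi[axis] = slice(1, None)
        sl_lo, sl_hi = tuple(sl_lo), tuple(sl_hi)
        if axis == 0:
            area = areas[0][None, :, :] * np.ones((nx - 1, 1, 1))
        elif axis == 1:
            area = areas[1][:, None, :] * np.ones((1, ny - 1, 1))
        else:
            area = areas[2][:, :, None] * np.ones((1, 1, nz - 1))
        g = area / (r[axis][sl_lo] + r[axis][sl_hi])
        p = idx[sl_lo].ravel()
        q = idx[sl_hi].ravel()
        gf = g.ravel()
        np.add.at(diag, p, gf)
        np.add.at(diag, q, gf)
        rows += [p, q]
        cols += [q, p]
        vals += [-gf, -gf]
    # baseline Dirichlet at the outer faces via ghost half-cells
    bnd = np.zeros(n)
    for axis in range(3):
        for side in (0, -1):
            sl = [slice(None)] * 3
            sl[axis] = side
            sl = tuple(sl)
            if axis == 0:
                area = areas[0]
            elif axis == 1:
                area = areas[1]
            else:
                area = areas[2]
            g = area / r[axis][sl]
            np.add.at(bnd, idx[sl].ravel(), g.ravel())
    diag += bnd
    K = sp.coo_matrix(
        (np.concatenate(vals + [diag]), (np.concatenate(rows + [np.arange(n)]),
                                         np.concatenate(cols + [np.arange(n)]))),
        shape=(n, n),
    ).tocsr()
    return K, bnd


def solve_pennes(
    model: VoxelModel,
    sar: np.ndarray,
    thermal: ThermalModel | None = None,
    times: list[float] | None = None,
) -> TemperatureVolume | list[TemperatureVolume]:
    """Integrate the bioheat equation from baseline under a fixed SAR source.

    ``sar`` is the per-cell SAR (W/kg).  Returns the temperature volume at
    ``thermal.duration`` (or at each requested time, rounded up to the time
    step).  The implicit-Euler system matrix is factorised once.
    """
    thermal = thermal or ThermalModel()
    grid = model.grid
    n = grid.n_cells
    sar = np.asarray(sar, dtype=float)
    if sar.shape != grid.shape:
        raise ValueError("SAR volume must live on the model grid")

    rho = model.property_map("rho")
    c = model.property_map("c")
    perf = model.property_map("perfusion", fill=0.0)
    vol = grid.cell_volumes_mm3() * 1e-9

    w_v = perf * rho * 1e-6 / 60.0  # 1/s
    sink = thermal.blood_density * thermal.blood_heat_capacity * w_v * vol  # W/K per cell
    heat_cap = rho * c * vol  # J/K per cell

    K, bnd = _conduction_matrix(model)
    S = sp.diags(sink.ravel())
    M = sp.diags(heat_cap.ravel() / thermal.dt)
    A = (M + K + S).tocsc()
    lu = spla.splu(A)

    src = rho * sar * vol  # W per cell
    const = (
        src.ravel()
        + sink.ravel() * thermal.arterial_temperature
        + bnd * thermal.baseline_temperature
    )

    T = np.full(n, thermal.baseline_temperature)
    t = 0.0
    out: list[TemperatureVolume] = []
    targets = sorted(times) if times is not None else [thermal.duration]
    m_diag = heat_cap.ravel() / thermal.dt
    for target in targets:
        while t < target - 1e-9:
            T = lu.solve(m_diag * T + const)
            t += thermal.dt
        out.append(TemperatureVolume(T=T.reshape(grid.shape).copy(), time=t))
    return out if times is not None else out[0]


def constraint_report(
    temperature: TemperatureVolume,
    region_masks: dict[str, np.ndarray],
    limits: dict[str, float] | None = None,
) -> dict:
    """Per-region maximum temperatures against clinical limits.

    ``region_masks`` maps region names to boolean cell masks; the reserved
    name ``"all tissue"`` defaults to the whole volume when absent.
    Unknown regions in ``limits`` raise.
    """
    limits = dict(DEFAULT_LIMITS if limits is None else limits)
    T = temperature.T
    masks = dict(region_masks)
    if "all tissue" not in masks:
        masks["all tissue"] = np.ones(T.shape, dtype=bool)
    for name in limits:
        if name not in masks:
            raise KeyError(f"unknown region {name!r} in constraint limits")
    report: dict = {"time_s": temperature.time, "regions": {}}
    ok = True
    for name, limit in limits.items():
        mask = masks[name]
        if not np.any(mask):
            report["regions"][name] = {"limit_c": limit, "max_c": None, "pass": True}
            continue
        tmax = float(T[mask].max())
        loc = np.unravel_index(int(np.argmax(np.where(mask, T, -np.inf))), T.shape)
        passed = tmax <= limit
        ok &= passed
        report["regions"][name] = {
            "limit_c": limit,
            "max_c": tmax,
            "pass": bool(passed),
            "argmax_cell": [int(v) for v in loc],
        }
    report["pass"] = bool(ok)
    return report
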