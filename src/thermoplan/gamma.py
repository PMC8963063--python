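"""3D gamma-index comparison of SAR volumes.

The gamma index combines a dose-difference (DD, % of a normalisation SAR)
and a distance-to-agreement (DTA, mm) criterion: for every reference voxel
the generalized Gamma function

    Gamma(r_e, r_r) = sqrt( (SAR(r_r) - SAR(r_e))^2 / DD_abs^2
                            + ||r_r - r_e||^2 / DTA^2 )

is minimised over evaluated-field sample positions r_e near r_r; a voxel
passes when the minimum (the gamma value) is <= 1.  The evaluated field is
sampled by trilinear interpolation on a sub-voxel step; the search is
truncated at a radius beyond which the distance term alone already exceeds
the running minimum.

Scalar agreement metrics (accuracy = mean absolute error, bias = mean
error, both as % of the maximum reference SAR in the volume of interest)
complement the gamma passing rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.interpolate import RegularGridInterpolator

from .grid import RectilinearGrid


@dataclass
class GammaConfig:
    """Gamma criteria: DD in % of the normalisation SAR, DTA in mm."""

    dd_percent: float
    dta_mm: float
    normalization: float | None = None  # default: global max reference SAR in VOI
    search_radius: float | None = None  # default: 3 * DTA
    interp_step: float | None = None    # default: DTA / 3
    pass_leq: bool = True               # pass criterion gamma <= 1 (ties at 1 pass)
    local_normalization: bool = False

    def __post_init__(self):
        if self.dd_percent <= 0 or self.dta_mm <= 0:
            raise ValueError("DD and DTA must be > 0")
        if self.search_radius is None:
            self.search_radius = 3.0 * self.dta_mm
        if self.search_radius < self.dta_mm:
            raise ValueError("search_radius must be >= DTA")
        if self.interp_step is None:
            self.interp_step = self.dta_mm / 3.0


@dataclass
class GammaResult:
    """Gamma volume over the VOI plus scalar agreement metrics."""

    gamma: np.ndarray
    passing_rate: float
    accuracy: float
    bias: float
    config: GammaConfig


@njit(cache=False)
def _gamma_kernel(ref, voi, fine, dd_abs2, off_i, off_j, off_k, off_d2, ratio_i, ratio_j,
                  ratio_k, margin_i, margin_j, margin_k):
    nx, ny, nz = ref.shape
    out = np.full(ref.shape, np.nan)
    n_off = off_i.size
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if not voi[i, j, k]:
                    continue
                bi = i * ratio_i + margin_i
                bj = j * ratio_j + margin_j
                bk = k * ratio_k + margin_k
                rv = ref[i, j, k]
                dd2 = dd_abs2[i, j, k]
                best = 1e300
                for o in range(n_off):
                    d2 = off_d2[o]
                    if d2 >= best:
                        break  # offsets sorted by distance: no better minimum ahead
                    ev = fine[bi + off_i[o], bj + off_j[o], bk + off_k[o]]
                    diff = rv - ev
                    g2 = diff * diff / dd2 + d2
                    if g2 < best:
                        best = g2
                out[i, j, k] = np.sqrt(best)
    return out


def _sorted_offsets(spacing: np.ndarray, radius: float, dta: float):
    ni = int(np.floor(radius / spacing[0] + 1e-9))
    nj = int(np.floor(radius / spacing[1] + 1e-9))
    nk = int(np.floor(radius / spacing[2] + 1e-9))
    ii, jj, kk = np.meshgrid(
        np.arange(-ni, ni + 1), np.arange(-nj, nj + 1), np.arange(-nk, nk + 1), indexing="ij"
    )
    d2 = (ii * spacing[0]) ** 2 + (jj * spacing[1]) ** 2 + (kk * spacing[2]) ** 2
    keep = d2 <= radius * radius + 1e-12
    ii, jj, kk, d2 = (a[keep] for a in (ii, jj, kk, d2))
    order = np.argsort(d2, kind="stable")
    return (
        ii[order].astype(np.int64),
        jj[order].astype(np.int64),
        kk[order].astype(np.int64),
        (d2[order] / dta**2).astype(np.float64),
        (ni, nj, nk),
    )


def gamma_map(
    reference: np.ndarray,
    evaluated: np.ndarray,
    spacing,
    cfg: GammaConfig,
    voi: np.ndarray | None = None,
    interpolate: bool = True,
) -> np.ndarray:
    """Per-voxel gamma of ``evaluated`` against ``reference`` on a shared uniform grid.

    ``spacing`` is the common (sx, sy, sz) voxel spacing in mm.  With
    ``interpolate=True`` the evaluated volume is linearly resampled to a
    sub-voxel step <= ``cfg.interp_step`` before the minimisation; with
    ``interpolate=False`` only whole-voxel offsets of the evaluated volume
    are searched (the unambiguous brute-force reference mode).
    """
    reference = np.asarray(reference, dtype=float)
    evaluated = np.asarray(evaluated, dtype=float)
    if reference.shape != evaluated.shape:
        raise ValueError("reference and evaluated volumes must share a grid")
    spacing = np.asarray(spacing, dtype=float)
    if voi is None:
        voi = np.ones(reference.shape, dtype=bool)
    if not np.any(voi):
        raise ValueError("empty VOI")

    norm = cfg.normalization
    if norm is None:
        norm = float(reference[voi].max())
    if norm <= 0:
        raise ValueError("gamma normalisation must be > 0")
    if cfg.local_normalization:
        dd_abs2 = (cfg.dd_percent / 100.0 * np.maximum(reference, 1e-12 * norm)) ** 2
    else:
        dd_abs2 = np.full(reference.shape, (cfg.dd_percent / 100.0 * norm) ** 2)

    if interpolate:
        ratios = np.maximum(1, np.ceil(spacing / cfg.interp_step - 1e-9).astype(int))
        fine_spacing = spacing / ratios
        off_i, off_j, off_k, off_d2, margins = _sorted_offsets(fine_spacing, cfg.search_radius, cfg.dta_mm)
        # evaluated volume resampled to the fine grid, padded by the search margin
        axes = [np.arange(n) * s for n, s in zip(evaluated.shape, spacing)]
        interp = RegularGridInterpolator(axes, evaluated, bounds_error=False, fill_value=None)
        fi = [np.arange(-m, (n - 1) * r + m + 1) * fs
              for n, r, m, fs in zip(evaluated.shape, ratios, margins, fine_spacing)]
        pts = np.stack(np.meshgrid(*fi, indexing="ij"), axis=-1)
        fine = interp(pts)
        # out-of-volume samples (beyond the evaluated extent) never win
        out_mask = np.zeros(fine.shape, dtype=bool)
        for ax, (n, s) in enumerate(zip(evaluated.shape, spacing)):
            coord = fi[ax]
            bad = (coord < -1e-9) | (coord > (n - 1) * s + 1e-9)
            sh = [1, 1, 1]
            sh[ax] = -1
            out_mask |= bad.reshape(sh)
        fine[out_mask] = np.inf
        gamma = _gamma_kernel(
            reference, voi, fine, dd_abs2, off_i, off_j, off_k, off_d2,
            int(ratios[0]), int(ratios[1]), int(ratios[2]),
            int(margins[0]), int(margins[1]), int(margins[2]),
        )
    else:
        off_i, off_j, off_k, off_d2, margins = _sorted_offsets(spacing, cfg.search_radius, cfg.dta_mm)
        fine = np.pad(evaluated, [(m, m) for m in margins], constant_values=np.inf)
        gamma = _gamma_kernel(
            reference, voi, fine, dd_abs2, off_i, off_j, off_k, off_d2,
            1, 1, 1, int(margins[0]), int(margins[1]), int(margins[2]),
        )
    return gamma


def passing_rate(gamma: np.ndarray, voi: np.ndarray | None = None, pass_leq: bool = True) -> float:
    """Percentage of VOI voxels with gamma <= 1 (or < 1 with ``pass_leq=False``)."""
    if voi is None:
        voi = np.isfinite(gamma)
    g = gamma[voi]
    if g.size == 0:
        raise ValueError("empty VOI")
    passed = (g <= 1.0) if pass_leq else (g < 1.0)
    return 100.0 * float(passed.sum()) / g.size


def accuracy_bias(
    reference: np.ndarray, evaluated: np.ndarray, voi: np.ndarray | None = None
) -> tuple[float, float]:
    """(accuracy, bias): mean |error| and mean error as % of max reference SAR in VOI."""
    if voi is None:
        voi = np.ones(reference.shape, dtype=bool)
    r = reference[voi]
    e = evaluated[voi]
    norm = float(r.max())
    if norm <= 0:
        raise ValueError("reference SAR is zero in the VOI")
    diff = e - r
    return (
        100.0 * float(np.mean(np.abs(diff))) / norm,
        100.0 * float(np.mean(diff)) / norm,
    )


def resample_to_uniform(
    values: np.ndarray,
    grid: RectilinearGrid,
    spacing: float | tuple[float, float, float],
    box: tuple[tuple[float, float], ...],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Trilinearly resample a cell-centred volume onto a uniform grid over ``box``.

    Returns (volume, origin_mm, spacing_mm); sample positions are voxel
    centres ``origin + (i + 0.5) * spacing``.
    """
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), 3).copy()
    centers = [grid.centers(a) for a in "xyz"]
    interp = RegularGridInterpolator(centers, values, bounds_error=False, fill_value=None)
    origin = np.array([b[0] for b in box])
    n = np.maximum(1, np.round((np.array([b[1] for b in box]) - origin) / spacing).astype(int))
    axes = [origin[a] + (np.arange(n[a]) + 0.5) * spacing[a] for a in range(3)]
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    return interp(pts), origin, spacing


def compare_sar(
    ref_sar: np.ndarray,
    ref_grid: RectilinearGrid,
    eval_sar: np.ndarray,
    eval_grid: RectilinearGrid,
    voi_box: tuple[tuple[float, float], ...],
    cfg: GammaConfig,
    comparison_spacing: float = 0.25,
    exclude=None,
) -> GammaResult:
    """Full simplified-vs-reference comparison on a uniform comparison grid.

    Both SAR volumes are resampled onto a uniform grid of
    ``comparison_spacing`` (mm) covering the VOI box; ``exclude`` is an
    optional callable mapping voxel-centre coordinate arrays (x, y, z of
    shape (n,3)->bool) to a mask of voxels excluded from the VOI (used for
    conductor interiors).
    """
    ref_u, origin, spacing = resample_to_uniform(ref_sar, ref_grid, comparison_spacing, voi_box)
    eval_u, _, _ = resample_to_uniform(eval_sar, eval_grid, comparison_spacing, voi_box)
    voi = np.ones(ref_u.shape, dtype=bool)
    if exclude is not None:
        axes = [origin[a] + (np.arange(ref_u.shape[a]) + 0.5) * spacing[a] for a in range(3)]
        pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
        voi &= ~exclude(pts).reshape(ref_u.shape)
    gamma = gamma_map(ref_u, eval_u, spacing, cfg, voi=voi)
    rate = passing_rate(gamma, voi, pass_leq=cfg.pass_leq)
    acc, bias = accuracy_bias(ref_u, eval_u, voi)
    return GammaResult(gamma=gamma, passing_rate=rate, accuracy=acc, bias=bias, config=cfg)
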