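"""Non-uniform rectilinear voxel grids.

Grids are node-based: each axis carries a strictly increasing array of node
coordinates in millimetres, and materials/fields live on the cells between
nodes.  Around each applicator the transverse (x, y) step is held at a fine
value; away from the applicators the step grows geometrically by at most a
configured expansion factor up to a maximum step.  The longitudinal axis (z)
uses a uniform step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class RectilinearGrid:
    """Rectilinear grid defined by per-axis node coordinates (mm)."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    def __post_init__(self):
        for name in ("x", "y", "z"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.ndim != 1 or arr.size < 2:
                raise ValueError(f"axis {name}: need at least two node coordinates")
            if not np.all(np.diff(arr) > 0):
                raise ValueError(f"axis {name}: node coordinates must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int, int]:
        """Cell-count shape (nx, ny, nz)."""
        return (self.x.size - 1, self.y.size - 1, self.z.size - 1)

    @property
    def n_cells(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    def steps(self, axis: str) -> np.ndarray:
        """Cell sizes along one axis (mm)."""
        return np.diff(getattr(self, axis))

    def centers(self, axis: str) -> np.ndarray:
        """Cell-center coordinates along one axis (mm)."""
        nodes = getattr(self, axis)
        return 0.5 * (nodes[:-1] + nodes[1:])

    def cell_volumes_mm3(self) -> np.ndarray:
        dx, dy, dz = self.steps("x"), self.steps("y"), self.steps("z")
        return dx[:, None, None] * dy[None, :, None] * dz[None, None, :]

    @property
    def bounds(self) -> tuple[tuple[float, float], ...]:
        return ((self.x[0], self.x[-1]), (self.y[0], self.y[-1]), (self.z[0], self.z[-1]))


def _merge_intervals(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    ivs = sorted((min(a, b), max(a, b)) for a, b in intervals)
    merged: list[list[float]] = []
    for lo, hi in ivs:
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [(lo, hi) for lo, hi in merged]


def _graded_steps(width: float, h_left: float, h_right: float, factor: float, h_max: float) -> np.ndarray:
    """Step sequence bridging a gap of ``width`` between regions of step h_left/h_right.

    Steps grow geometrically from both ends by at most ``factor``, capped at
    ``h_max``; the sequence is rescaled slightly at the end so the steps sum
    exactly to ``width`` without violating the growth bound.
    """
    if width <= 0:
        return np.empty(0)
    if width <= max(h_left, h_right):
        return np.array([width])
    left: list[float] = []
    right: list[float] = []
    hl, hr = h_left, h_right
    total = 0.0
    # grow alternately from the smaller side until the gap is covered, then
    # rescale uniformly (<= 1): growth ratios are preserved and no step
    # exceeds its unscaled value
    while total < width:
        if hl <= hr:
            hl = min(hl * factor, h_max)
            left.append(hl)
            total += hl
        else:
            hr = min(hr * factor, h_max)
            right.append(hr)
            total += hr
    steps = np.array(left + right[::-1])
    return steps * (width / total)


def _axis_coords(
    lo: float,
    hi: float,
    fine_intervals: list[tuple[float, float]],
    fine_step: float,
    max_step: float,
    expansion_factor: float,
) -> np.ndarray:
    """Node coordinates for one transverse axis."""
    if fine_step <= 0 or max_step <= 0:
        raise ValueError("grid steps must be > 0")
    if fine_step > max_step:
        raise ValueError("fine_step must not exceed max_step")
    if expansion_factor <= 1:
        raise ValueError("expansion_factor must be > 1")
    merged = _merge_intervals(fine_intervals) if fine_intervals else []
    for a, b in merged:
        if a < lo - 1e-9 or b > hi + 1e-9:
            raise ValueError(f"fine interval ({a}, {b}) outside axis extent ({lo}, {hi})")
    if not merged:
        n = max(1, int(np.ceil((hi - lo) / max_step)))
        return np.linspace(lo, hi, n + 1)

    pieces: list[np.ndarray] = []
    cursor = lo
    prev_h = max_step
    for idx, (a, b) in enumerate(merged):
        if a > cursor + 1e-12:
            gap = _graded_steps(a - cursor, max_step if cursor == lo else prev_h, fine_step, expansion_factor, max_step)
            # coarse->fine entering from a domain edge: reverse so steps shrink toward the fine region
            pieces.append(gap)
        n = max(1, int(np.ceil((b - a) / fine_step - 1e-9)))
        pieces.append(np.full(n, (b - a) / n))
        prev_h = (b - a) / n
        cursor = b
    if hi > cursor + 1e-12:
        pieces.append(_graded_steps(hi - cursor, prev_h, max_step, expansion_factor, max_step))
    steps = np.concatenate([p for p in pieces if p.size])
    coords = lo + np.concatenate([[0.0], np.cumsum(steps)])
    coords[-1] = hi
    return coords


def build_grid(
    extent: tuple[tuple[float, float], tuple[float, float], tuple[float, float]],
    applicator_regions: list[tuple[tuple[float, float], tuple[float, float]]],
    fine_step: float,
    z_step: float = 1.0,
    max_step: float = 2.0,
    expansion_factor: float = 1.2,
) -> RectilinearGrid:
    """Build a non-uniform rectilinear grid for a set of applicator regions.

    Parameters
    ----------
    extent : ((x0, x1), (y0, y1), (z0, z1))
        Full simulation domain in mm (including the outer margin).
    applicator_regions : list of ((x0, x1), (y0, y1))
        Transverse boxes that must be resolved at ``fine_step``.
    fine_step : float
        Transverse step inside applicator regions (mm); 0.02 for detailed
        cylindrical applicator models, 0.1 for the simplified cuboid models.
    z_step : float
        Uniform longitudinal step (mm).
    max_step : float
        Maximum transverse step away from the applicators (mm).
    expansion_factor : float
        Maximum growth ratio between neighbouring transverse steps.
    """
    (x0, x1), (y0, y1), (z0, z1) = extent
    if z_step <= 0:
        raise ValueError("z_step must be > 0")
    for (ax0, ax1), (ay0, ay1) in applicator_regions:
        if ax0 < x0 - 1e-9 or ax1 > x1 + 1e-9 or ay0 < y0 - 1e-9 or ay1 > y1 + 1e-9:
            raise ValueError("applicator region outside the domain extent")
    x = _axis_coords(x0, x1, [r[0] for r in applicator_regions], fine_step, max_step, expansion_factor)
    y = _axis_coords(y0, y1, [r[1] for r in applicator_regions], fine_step, max_step, expansion_factor)
    nz = max(1, int(round((z1 - z0) / z_step)))
    z = np.linspace(z0, z1, nz + 1)
    return RectilinearGrid(x=x, y=y, z=z)
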