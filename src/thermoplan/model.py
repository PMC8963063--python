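"""Voxel model: grid + per-cell material + electrode and VOI masks."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .applicators import (
    ApplicatorSpec,
    rasterize_applicator_detailed,
    rasterize_applicator_simplified,
)
from .grid import RectilinearGrid, build_grid
from .materials import EPS0, Material, tissue_table

#: ideal-conductor placeholder; excluded from the solve as a Dirichlet region
COPPER = Material(name="Copper", sigma=5.8e7, eps_r=1.0, rho=8960.0, c=385.0, k=401.0)

#: margin between the volume of interest / applicators and the domain boundary (mm)
BOUNDARY_MARGIN = 10.0


@dataclass
class VoxelModel:
    """Rectilinear voxel model with per-cell materials and electrode labelling.

    ``material_id`` holds an index into ``materials``; ``electrode_mask`` is
    -1 outside electrodes and the electrode index (2 per applicator:
    distal = 2i, proximal = 2i+1) inside the conductor shells.  ``voi`` is
    the half-open [min, max) metric box over which agreement metrics are
    computed.
    """

    grid: RectilinearGrid
    material_id: np.ndarray
    materials: list[Material]
    electrode_mask: np.ndarray
    voi: tuple[tuple[float, float], tuple[float, float], tuple[float, float]]
    applicators: list[ApplicatorSpec] = field(default_factory=list)
    mode: str = "detailed"
    #: material ids >= this belong to applicator bodies (used for overlap checks)
    first_applicator_material_id: int = 0
    #: subcell mixing for boundary cells: flat (C-order) cell indices, the
    #: per-cell volume fractions of ``mix_materials``, and those material ids.
    #: Mixed cells get the harmonic (series) admittivity mix, which preserves
    #: the series impedance of thin coating layers cut by the grid.
    mix_cells: np.ndarray | None = None
    mix_fractions: np.ndarray | None = None
    mix_materials: np.ndarray | None = None

    @property
    def n_electrodes(self) -> int:
        return int(self.electrode_mask.max()) + 1

    def register_mix(self, flat_cells: np.ndarray, fractions: np.ndarray) -> None:
        """Record subcell volume fractions for boundary cells (C-order indices)."""
        self.mix_materials = np.arange(len(self.materials))
        if self.mix_cells is None:
            self.mix_cells = flat_cells
            self.mix_fractions = fractions
        else:
            if fractions.shape[1] != self.mix_fractions.shape[1]:
                raise ValueError("mixing tables must share the material basis")
            self.mix_cells = np.concatenate([self.mix_cells, flat_cells])
            self.mix_fractions = np.vstack([self.mix_fractions, fractions])

    def admittivity(self, omega: float) -> np.ndarray:
        """Per-cell complex admittivity sigma + j*omega*eps (S/m).

        Cells registered as subcell mixtures receive the harmonic mean of the
        constituent admittivities weighted by volume fraction (series
        layering, appropriate for the radially layered applicator coating).
        """
        kap = np.array([m.admittivity(omega) for m in self.materials])
        out = kap[self.material_id]
        if self.mix_cells is not None and self.mix_cells.size:
            kmix = kap[self.mix_materials]  # (k,)
            inv = self.mix_fractions @ (1.0 / kmix)
            out.ravel()[self.mix_cells] = 1.0 / inv
        return out

    def property_map(self, attr: str, fill: float = 0.0) -> np.ndarray:
        """Per-cell map of a scalar material property (None -> ``fill``)."""
        vals = np.array(
            [fill if getattr(m, attr) is None else getattr(m, attr) for m in self.materials],
            dtype=float,
        )
        return vals[self.material_id]

    def voi_mask(self) -> np.ndarray:
        """Boolean per-cell mask of the half-open VOI box."""
        cx, cy, cz = (self.grid.centers(a) for a in "xyz")
        (x0, x1), (y0, y1), (z0, z1) = self.voi
        mx = (cx >= x0) & (cx < x1)
        my = (cy >= y0) & (cy < y1)
        mz = (cz >= z0) & (cz < z1)
        return mx[:, None, None] & my[None, :, None] & mz[None, None, :]

    def conductor_enclosed_mask(self) -> np.ndarray:
        """Cells enclosed by (or part of) an electrode conductor shell.

        For each applicator this is the full electrode cross-section
        (everything within the conductor's outer boundary) over the
        electrode axial extents, in whichever geometry the model uses.
        These cells carry no physical SAR and are excluded from comparison
        metrics.
        """
        mask = np.zeros(self.grid.shape, dtype=bool)
        cx, cy, cz = (self.grid.centers(a) for a in "xyz")
        for spec in self.applicators:
            if not spec.is_z_parallel():
                # generic-axis applicators: mark electrode-shell cells only
                mask |= self.electrode_mask >= 0
                continue
            sgn = 1.0 if spec.direction[2] > 0 else -1.0
            tx, ty, tz = spec.tip_position
            if self.mode == "detailed":
                r = spec.electrode_od / 2.0
                trans = ((cx - tx) ** 2)[:, None] + ((cy - ty) ** 2)[None, :] <= r * r
            else:
                h = spec.simplified_electrode_outer / 2.0
                trans = (np.abs(cx - tx) <= h)[:, None] & (np.abs(cy - ty) <= h)[None, :]
            behind = sgn * (tz - cz)
            inz = np.zeros_like(cz, dtype=bool)
            for a, b in spec.electrode_spans():
                inz |= (behind >= a) & (behind < b)
            mask |= trans[:, :, None] & inz[None, None, :]
        return mask


def _material_list(extra_tissues: list[str]) -> tuple[list[Material], dict[str, int]]:
    table = tissue_table()
    names = list(dict.fromkeys(extra_tissues)) + ["Air", "POM", "Parylene C"]
    mats = [table[n] for n in names] + [COPPER]
    ids = {m.name: i for i, m in enumerate(mats)}
    return mats, ids


def build_model(
    applicators: list[ApplicatorSpec],
    voi: tuple[tuple[float, float], tuple[float, float], tuple[float, float]],
    background: str | np.ndarray = "Muscle",
    tissues: list[str] | None = None,
    mode: str = "detailed",
    fine_step: float | None = None,
    z_step: float = 1.0,
    max_step: float = 2.0,
    expansion_factor: float = 1.2,
    frequency: float = 27e6,
    region_assigner=None,
) -> VoxelModel:
    """Assemble a voxel model: grid, tissue background and rasterized applicators.

    The domain extends ``BOUNDARY_MARGIN`` beyond the VOI (and beyond every
    applicator footprint).  ``region_assigner(model)`` may paint
    heterogeneous tissue regions onto the background before the applicators
    are rasterized.
    """
    if mode not in ("detailed", "simplified"):
        raise ValueError(f"unknown mode {mode!r}")
    if fine_step is None:
        fine_step = 0.02 if mode == "detailed" else 0.1
    if mode == "detailed":
        for spec in applicators:
            if not spec.is_z_parallel():
                raise ValueError("detailed mode requires z-parallel applicators")

    (vx0, vx1), (vy0, vy1), (vz0, vz1) = voi
    lo = np.array([vx0, vy0, vz0]) - BOUNDARY_MARGIN
    hi = np.array([vx1, vy1, vz1]) + BOUNDARY_MARGIN
    regions = []
    for spec in applicators:
        hw = spec.transverse_halfwidth(mode) + 0.2
        tx, ty, _ = spec.tip_position
        regions.append(((tx - hw, tx + hw), (ty - hw, ty + hw)))
        lo[:2] = np.minimum(lo[:2], [tx - hw - BOUNDARY_MARGIN, ty - hw - BOUNDARY_MARGIN])
        hi[:2] = np.maximum(hi[:2], [tx + hw + BOUNDARY_MARGIN, ty + hw + BOUNDARY_MARGIN])
    grid = build_grid(
        ((lo[0], hi[0]), (lo[1], hi[1]), (lo[2], hi[2])),
        regions,
        fine_step=fine_step,
        z_step=z_step,
        max_step=max_step,
        expansion_factor=expansion_factor,
    )

    tissue_names = list(tissues or [])
    if isinstance(background, str) and background not in tissue_names:
        tissue_names.insert(0, background)
    mats, ids = _material_list(tissue_names)
    first_app_id = ids["Air"]

    material_id = np.full(grid.shape, ids[background] if isinstance(background, str) else 0, dtype=np.int16)
    model = VoxelModel(
        grid=grid,
        material_id=material_id,
        materials=mats,
        electrode_mask=np.full(grid.shape, -1, dtype=np.int16),
        voi=voi,
        applicators=list(applicators),
        mode=mode,
        first_applicator_material_id=first_app_id,
    )
    if region_assigner is not None:
        region_assigner(model, ids)

    if mode == "detailed":
        for i, spec in enumerate(applicators):
            rasterize_applicator_detailed(spec, model, ids, i)
    else:
        # one adapted-permittivity dielectric per distinct spec geometry
        diel_ids: dict[float, int] = {}
        parylene = tissue_table()["Parylene C"]
        for i, spec in enumerate(applicators):
            eps_prime = spec.adapted_permittivity(parylene.eps)
            key = round(eps_prime / EPS0, 9)
            if key not in diel_ids:
                model.materials.append(
                    Material(
                        name=f"Adapted dielectric ({key:.3f})",
                        sigma=parylene.sigma,
                        eps_r=key,
                        rho=parylene.rho,
                        c=parylene.c,
                        k=parylene.k,
                    )
                )
                diel_ids[key] = len(model.materials) - 1
            rasterize_applicator_simplified(spec, model, ids, i, diel_ids[key])
    return model
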