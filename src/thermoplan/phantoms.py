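"""Benchmark phantoms for validating the simplified applicator model.

Two families of phantoms are provided:

* a **homogeneous** phantom — parallel applicators on a 9 mm lattice in
  uniform muscle, mimicking a prostate implant (the full 18-applicator
  layout leaves the two upper-central lattice positions empty where the
  urethra runs);
* a **complex** phantom — fat/muscle/prostate heterogeneity both across and
  along the applicators plus non-uniform applicator spacing: applicators
  cross a transverse prostate-fat interface, one applicator is centred on a
  longitudinal prostate-fat interface, and inter-applicator distances
  deviate from the nominal 9 mm.

Both accept a reduced applicator count so that desk-scale reference solves
stay tractable; the geometry rules are identical at every size.
"""

from __future__ import annotations

import numpy as np

from .applicators import ApplicatorSpec
from .model import BOUNDARY_MARGIN, VoxelModel, build_model

#: nominal lattice spacing between applicators (mm)
DEFAULT_SPACING = 9.0


def _lattice_positions(n_applicators: int, spacing: float) -> list[tuple[float, float]]:
    """(x, y) applicator positions on a rectangular lattice.

    For the full 18-applicator layout: 4 rows of 5 columns with the two
    upper-central positions removed (urethra location).  Reduced counts fill
    the lattice row-major from the bottom row.
    """
    if n_applicators == 18:
        pos = []
        for r in range(4):
            for c in range(5):
                if r == 3 and c in (2, 3):
                    continue
                pos.append((c * spacing, r * spacing))
        return pos[:18]
    cols = n_applicators if n_applicators <= 3 else max(1, int(np.ceil(np.sqrt(n_applicators))))
    pos = []
    r = c = 0
    for _ in range(n_applicators):
        pos.append((c * spacing, r * spacing))
        c += 1
        if c == cols:
            c = 0
            r += 1
    return pos


#: VOI margins (mm) around the active applicator lattice; with the full
#: 18-applicator layout these reproduce the 54 x 43 x 54 mm volume of interest
DEFAULT_VOI_MARGINS = (9.0, 8.0, 4.5)


def _voi_for(positions: list[tuple[float, float]], spec: ApplicatorSpec,
             margins, tip_z: float) -> tuple:
    mx, my, mz = np.broadcast_to(np.asarray(margins, dtype=float), 3)
    xs = [p[0] for p in positions]
    ys = [p[1] for p in positions]
    spans = spec.electrode_spans()
    z_active_lo = tip_z - spans[1][1]  # back of proximal electrode
    z_active_hi = tip_z - spans[0][0]  # front of distal electrode
    return (
        (min(xs) - mx, max(xs) + mx),
        (min(ys) - my, max(ys) + my),
        (z_active_lo - mz, z_active_hi + mz),
    )


def homogeneous_benchmark(
    spacing: float = DEFAULT_SPACING,
    n_applicators: int = 18,
    mode: str = "detailed",
    fine_step: float | None = None,
    voi_margins=DEFAULT_VOI_MARGINS,
    **grid_kwargs,
) -> VoxelModel:
    """Parallel applicators on a ``spacing`` lattice in homogeneous muscle.

    With the default 18 applicators the volume of interest is the
    54 x 43 x 54 mm box containing the active electrode lengths; reduced
    applicator counts shrink the VOI proportionally (same margins).
    """
    if n_applicators < 1:
        raise ValueError("need at least one applicator")
    tip_z = 0.0
    spec0 = ApplicatorSpec(tip_position=(0.0, 0.0, tip_z))
    positions = _lattice_positions(n_applicators, spacing)
    applicators = [ApplicatorSpec(tip_position=(x, y, tip_z)) for x, y in positions]
    voi = _voi_for(positions, spec0, voi_margins, tip_z)
    return build_model(applicators, voi, background="Muscle", mode=mode,
                       fine_step=fine_step, **grid_kwargs)


def complex_benchmark(
    n_applicators: int = 18,
    spacing: float = DEFAULT_SPACING,
    mode: str = "detailed",
    fine_step: float | None = None,
    voi_margins=DEFAULT_VOI_MARGINS,
    **grid_kwargs,
) -> VoxelModel:
    """Heterogeneous phantom with prostate/fat interfaces and varied spacing.

    Relative to the homogeneous lattice layout:

    * the lattice spacing of the first inter-column gap is reduced and the
      last increased by 2 mm (non-uniform applicator distances);
    * a transverse prostate-fat interface crosses all applicators at the
      level of the distal third of the proximal electrode;
    * a longitudinal prostate-fat interface runs along z through the centre
      of the right-most applicator column (that applicator sits midway on
      the interface);
    * muscle surrounds the prostate/fat block.
    """
    if n_applicators < 2:
        raise ValueError("complex phantom needs at least two applicators")
    tip_z = 0.0
    base = _lattice_positions(n_applicators, spacing)
    # perturb column spacing: first inter-column gap 2 mm closer, last 2 mm farther
    xs = sorted({p[0] for p in base})
    new_x = {xs[0]: xs[0]}
    for i in range(1, len(xs)):
        gap = xs[i] - xs[i - 1]
        if i == 1:
            gap -= 2.0
        if i == len(xs) - 1 and len(xs) > 1:
            gap += 2.0
        new_x[xs[i]] = new_x[xs[i - 1]] + gap
    positions = [(new_x[x], y) for x, y in base]
    spec0 = ApplicatorSpec(tip_position=(0.0, 0.0, tip_z))
    applicators = [ApplicatorSpec(tip_position=(x, y, tip_z)) for x, y in positions]
    voi = _voi_for(positions, spec0, voi_margins, tip_z)

    x_interface = max(p[0] for p in positions)  # through the right-most applicator axis
    spans = spec0.electrode_spans()
    z_interface = tip_z - (spans[1][0] + spans[1][1] * 2) / 3.0  # within the proximal electrode span

    def paint(model: VoxelModel, ids: dict[str, int]) -> None:
        cx, cy, cz = (model.grid.centers(a) for a in "xyz")
        (x0, x1), (y0, y1), (z0, z1) = model.voi
        m = BOUNDARY_MARGIN / 2.0
        block = (
            ((cx >= x0 - m) & (cx < x1 + m))[:, None, None]
            & ((cy >= y0 - m) & (cy < y1 + m))[None, :, None]
            & ((cz >= z0 - m) & (cz < z1 + m))[None, None, :]
        )
        fat = (cx >= x_interface)[:, None, None] | (cz < z_interface)[None, None, :]
        model.material_id[block & fat] = ids["Fat"]
        model.material_id[block & ~fat] = ids["Prostate"]

    return build_model(
        applicators, voi, background="Muscle", tissues=["Muscle", "Fat", "Prostate"],
        mode=mode, fine_step=fine_step, region_assigner=paint, **grid_kwargs,
    )
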