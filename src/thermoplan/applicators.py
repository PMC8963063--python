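"""Applicator geometry: detailed cylindrical and simplified cuboid models.

The dual-electrode applicator is a hollow POM catheter (2.0 mm OD, 1.66 mm
ID) carrying two 20 mm copper electrode shells separated by a 5 mm gap and
coated by a thin Parylene C dielectric.  Two voxelisations are supported:

* **detailed** — concentric cylindrical shells resolved on a fine
  (<= 0.02 mm) transverse grid; restricted to z-parallel axes.
* **simplified** — concentric cuboid shells with half-edge 0.5 mm (POM
  core), 0.7 mm (electrode) and 0.9 mm (dielectric), the dielectric carrying
  the capacitance-preserving adapted permittivity; usable on a ~0.1 mm grid
  and for arbitrary axis directions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .equivalence import adapted_permittivity_for_layer


@dataclass(frozen=True)
class ApplicatorSpec:
    """Geometry of one dual-electrode applicator.

    ``tip_position`` is the distal end of the catheter; the applicator body
    extends from the tip opposite to ``direction`` (toward the external
    feed).  The distal electrode starts ``tip_offset`` behind the tip.
    All lengths in mm.
    """

    tip_position: tuple[float, float, float]
    direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    catheter_od: float = 2.0
    catheter_id: float = 1.66
    electrode_od: float = 2.06
    dielectric_od: float = 2.12
    electrode_length: float = 20.0
    electrode_gap: float = 5.0
    tip_offset: float = 5.0
    simplified_electrode_inner: float = 1.0
    simplified_electrode_outer: float = 1.4
    simplified_dielectric_inner: float = 1.4
    simplified_dielectric_outer: float = 1.8
    eps_prime_reference: str = "cuboid"

    def __post_init__(self):
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("applicator direction must be a non-zero vector")
        object.__setattr__(self, "direction", tuple(d / n))
        if not (0 < self.catheter_id < self.catheter_od < self.electrode_od < self.dielectric_od):
            raise ValueError("applicator diameters must satisfy id < od < electrode_od < dielectric_od")
        if not (0 < self.simplified_electrode_inner < self.simplified_electrode_outer):
            raise ValueError("simplified electrode edges invalid")
        if not (0 < self.simplified_dielectric_inner < self.simplified_dielectric_outer):
            raise ValueError("simplified dielectric edges invalid")
        if self.electrode_length <= 0 or self.electrode_gap <= 0:
            raise ValueError("electrode length and gap must be > 0")

    # ---- electrode axial extents (distances behind the tip) -----------------
    def electrode_spans(self) -> list[tuple[float, float]]:
        """Axial extents of (distal, proximal) electrodes, as distance-behind-tip intervals."""
        d0 = self.tip_offset
        d1 = d0 + self.electrode_length
        p0 = d1 + self.electrode_gap
        p1 = p0 + self.electrode_length
        return [(d0, d1), (p0, p1)]

    @property
    def active_length(self) -> float:
        """Tip offset + both electrodes + gap (mm)."""
        return self.tip_offset + 2 * self.electrode_length + self.electrode_gap

    def adapted_permittivity(self, eps_dielectric: float) -> float:
        """Adapted absolute permittivity (F/m) of the simplified dielectric shell."""
        return adapted_permittivity_for_layer(
            eps_dielectric,
            self.electrode_od,
            self.dielectric_od,
            self.simplified_dielectric_inner,
            self.simplified_dielectric_outer,
            reference=self.eps_prime_reference,
        )

    def transverse_halfwidth(self, mode: str) -> float:
        """Half-width of the transverse footprint (mm) used for grid refinement."""
        if mode == "detailed":
            return self.dielectric_od / 2.0
        return self.simplified_dielectric_outer / 2.0

    def is_z_parallel(self) -> bool:
        return abs(abs(self.direction[2]) - 1.0) < 1e-12


def _supersample_offsets(h: np.ndarray, n: int = 3) -> np.ndarray:
    """Stratified supersample offsets (n strip centres) for each cell size h."""
    k = (np.arange(n) - (n - 1) / 2.0) / n
    return h[..., None] * k


def rasterize_applicator_detailed(spec: ApplicatorSpec, model, material_ids: dict[str, int],
                                  applicator_index: int) -> None:
    """Voxelise the detailed cylindrical applicator into ``model`` (in place).

    Cells are classified from the axis outward: air lumen, POM catheter
    shell, copper electrode shell (within the electrode axial extents, with
    the electrode mask set), Parylene dielectric coating.  Classification
    uses 3x3 transverse supersampling with majority vote to stabilise the
    thin shells on non-uniform grids.  The axis must be z-parallel.
    """
    if not spec.is_z_parallel():
        raise ValueError("detailed applicator models require a z-parallel axis")
    sgn = 1.0 if spec.direction[2] > 0 else -1.0
    grid = model.grid
    cx, cy, cz = spec.tip_position
    r_out = spec.dielectric_od / 2.0

    xs = grid.centers("x")
    ys = grid.centers("y")
    zs = grid.centers("z")
    ix = np.nonzero(np.abs(xs - cx) <= r_out + grid.steps("x"))[0]
    iy = np.nonzero(np.abs(ys - cy) <= r_out + grid.steps("y"))[0]
    if ix.size == 0 or iy.size == 0:
        return
    # distance behind the tip along the axis; the catheter shaft continues
    # beyond the proximal electrode toward the external feed (domain edge)
    behind = sgn * (cz - zs)
    iz = np.nonzero(behind >= 0.0)[0]
    if iz.size == 0:
        return

    # supersampled transverse radii: (nx, ny, ns, ns)
    ns = 5
    ox = _supersample_offsets(grid.steps("x")[ix], ns)  # (nx, ns)
    oy = _supersample_offsets(grid.steps("y")[iy], ns)
    px = xs[ix, None] + ox - cx  # (nx, ns)
    py = ys[iy, None] + oy - cy
    r2 = px[:, None, :, None] ** 2 + py[None, :, None, :] ** 2  # (nx, ny, ns, ns)

    radii = np.array([spec.catheter_id / 2.0, spec.catheter_od / 2.0,
                      spec.electrode_od / 2.0, spec.dielectric_od / 2.0]) ** 2
    # class 0=air,1=POM,2=electrode shell,3=dielectric,4=outside
    cls = np.searchsorted(radii, r2.reshape(ix.size, iy.size, ns * ns))
    # majority vote over the subsamples
    counts = np.stack([(cls == c).sum(axis=2) for c in range(5)], axis=0)
    winner = np.argmax(counts, axis=0)  # ties broken toward the inner class
    fractions = counts.astype(float) / (ns * ns)  # (5, nx, ny)

    spans = spec.electrode_spans()
    in_electrode_z = np.zeros(iz.size, dtype=bool)
    which_span = np.full(iz.size, -1)
    for s, (a, b) in enumerate(spans):
        m = (behind[iz] >= a) & (behind[iz] < b)
        in_electrode_z |= m
        which_span[which_span < 0] = np.where(m[which_span < 0], s, -1)

    mat = model.material_id
    emask = model.electrode_mask
    sub = np.ix_(ix, iy, iz)
    occupied = winner < 4
    prev = mat[sub]
    clash = occupied[:, :, None] & (prev >= model.first_applicator_material_id)
    if np.any(clash):
        raise ValueError("applicator overlaps a previously placed applicator")

    air, pom, cu, par = (material_ids[n] for n in ("Air", "POM", "Copper", "Parylene C"))
    new = prev.copy()
    w3 = np.broadcast_to(winner[:, :, None], new.shape)
    new[w3 == 0] = air
    new[w3 == 1] = pom
    # electrode shell: copper within electrode spans, dielectric-coated POM elsewhere
    ez = np.broadcast_to(in_electrode_z[None, None, :], new.shape)
    new[(w3 == 2) & ez] = cu
    new[(w3 == 2) & ~ez] = pom
    new[w3 == 3] = par
    mat[sub] = new

    # Dirichlet conductor region: the full disc out to the copper outer radius
    # within each electrode span.  Marking only the thin shell cells leaves
    # azimuthal gaps whenever the 30 um shell straddles cell boundaries; the
    # enclosed interior is field-free anyway, so including it changes nothing
    # outside while making the equipotential surface watertight.
    em = emask[sub]
    r2c = (xs[ix, None] - cx) ** 2 + (ys[iy, None].T - cy) ** 2  # (nx, ny)
    disc = r2c <= (spec.electrode_od / 2.0) ** 2
    for s in range(2):
        sz = np.broadcast_to((which_span[None, None, :] == s), em.shape)
        em[disc[:, :, None] & sz] = 2 * applicator_index + s
    emask[sub] = em

    # subcell mixing: boundary cells cut by the shell radii get the volume
    # fractions of their constituents so the solver can apply a harmonic
    # (series) admittivity mix — the 30 um coating then presents its true
    # series impedance at every angle instead of a cell-quantized thickness
    mixed_col = counts.max(axis=0) < ns * ns
    cand = mixed_col[:, :, None] & (em < 0)
    if np.any(cand):
        a, b, c = np.nonzero(cand)
        ny_full, nz_full = grid.shape[1], grid.shape[2]
        flat = (ix[a] * ny_full + iy[b]) * nz_full + iz[c]
        fr = np.zeros((a.size, len(model.materials)))
        for ci, name in enumerate(("Air", "POM", "Copper", "Parylene C")):
            fr[:, material_ids[name]] += fractions[ci, a, b]
        bg = prev[a, b, c]  # pre-applicator (tissue) material of each cell
        np.add.at(fr, (np.arange(a.size), bg), fractions[4, a, b])
        model.register_mix(flat, fr)


def rasterize_applicator_simplified(spec: ApplicatorSpec, model, material_ids: dict[str, int],
                                    applicator_index: int, dielectric_id: int) -> None:
    """Voxelise the simplified cuboid applicator into ``model`` (in place).

    Concentric square shells in the applicator frame: POM core out to the
    electrode inner edge, conductor shell (electrode mask) between the
    electrode edges within the electrode axial extents, adapted-permittivity
    dielectric between the dielectric edges.  Cells are classified by their
    centre point in the applicator frame, with 3x3 transverse supersampling
    on the z-parallel fast path.
    """
    grid = model.grid
    xs, ys, zs = grid.centers("x"), grid.centers("y"), grid.centers("z")
    h_el_in = spec.simplified_electrode_inner / 2.0
    h_el_out = spec.simplified_electrode_outer / 2.0
    h_di_in = spec.simplified_dielectric_inner / 2.0
    h_di_out = spec.simplified_dielectric_outer / 2.0
    if abs(h_di_in - h_el_out) > 1e-9:
        raise ValueError("simplified dielectric inner edge must meet the electrode outer edge")
    tip = np.asarray(spec.tip_position)
    d = np.asarray(spec.direction)

    if spec.is_z_parallel():
        sgn = 1.0 if d[2] > 0 else -1.0
        ix = np.nonzero(np.abs(xs - tip[0]) <= h_di_out + grid.steps("x"))[0]
        iy = np.nonzero(np.abs(ys - tip[1]) <= h_di_out + grid.steps("y"))[0]
        behind = sgn * (tip[2] - zs)
        iz = np.nonzero(behind >= 0.0)[0]
        if ix.size == 0 or iy.size == 0 or iz.size == 0:
            return
        ox = _supersample_offsets(grid.steps("x")[ix])
        oy = _supersample_offsets(grid.steps("y")[iy])
        ax = np.abs(xs[ix, None] + ox - tip[0])  # (nx, 3)
        ay = np.abs(ys[iy, None] + oy - tip[1])
        cheb = np.maximum(ax[:, None, :, None], ay[None, :, None, :]).reshape(ix.size, iy.size, 9)
        edges = np.array([h_el_in, h_el_out, h_di_out])
        cls = np.searchsorted(edges, cheb, side="right")  # 0 core, 1 electrode shell, 2 dielectric, 3 outside
        counts = np.stack([(cls == c).sum(axis=2) for c in range(4)], axis=0)
        winner = np.argmax(counts, axis=0)
        spans = spec.electrode_spans()
        bz = behind[iz]
    else:
        # generic axis: classify cell centres in the applicator frame
        X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
        rel = np.stack([X - tip[0], Y - tip[1], Z - tip[2]], axis=-1)
        behind3 = -(rel @ d)
        # transverse part
        trans = rel + behind3[..., None] * d
        # build an orthonormal transverse frame
        ref = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        u = np.cross(d, ref); u /= np.linalg.norm(u)
        v = np.cross(d, u)
        cheb3 = np.maximum(np.abs(trans @ u), np.abs(trans @ v))
        inside = (behind3 >= 0.0) & (cheb3 <= h_di_out)
        _assign_simplified_generic(spec, model, material_ids, applicator_index, dielectric_id,
                                   inside, cheb3, behind3, h_el_in, h_el_out)
        return

    mat = model.material_id
    emask = model.electrode_mask
    sub = np.ix_(ix, iy, iz)
    prev = mat[sub]
    occupied = winner < 3
    if np.any(occupied[:, :, None] & (prev >= model.first_applicator_material_id)):
        raise ValueError("applicator overlaps a previously placed applicator")

    pom = material_ids["POM"]
    cu = material_ids["Copper"]
    new = prev.copy()
    w3 = np.broadcast_to(winner[:, :, None], new.shape)
    in_el_z = np.zeros(iz.size, dtype=bool)
    which_span = np.full(iz.size, -1)
    for s, (a, b) in enumerate(spans):
        m = (bz >= a) & (bz < b)
        in_el_z |= m
        which_span[which_span < 0] = np.where(m[which_span < 0], s, -1)
    ez = np.broadcast_to(in_el_z[None, None, :], new.shape)

    new[w3 == 0] = pom
    new[(w3 == 1) & ez] = cu
    new[(w3 == 1) & ~ez] = pom
    new[w3 == 2] = dielectric_id
    mat[sub] = new

    # Dirichlet region: full conductor box cross-section per span (see the
    # detailed rasterizer for why the enclosed interior is included)
    em = emask[sub]
    box = (np.abs(xs[ix, None] - tip[0]) <= h_el_out) & (np.abs(ys[iy] - tip[1])[None, :] <= h_el_out)
    for s in range(2):
        sz = np.broadcast_to((which_span[None, None, :] == s), em.shape)
        em[box[:, :, None] & sz] = 2 * applicator_index + s
    emask[sub] = em


def _assign_simplified_generic(spec, model, material_ids, applicator_index, dielectric_id,
                               inside, cheb, behind, h_el_in, h_el_out):
    mat = model.material_id
    emask = model.electrode_mask
    if np.any(inside & (mat >= model.first_applicator_material_id)):
        raise ValueError("applicator overlaps a previously placed applicator")
    pom = material_ids["POM"]
    cu = material_ids["Copper"]
    core = inside & (cheb <= h_el_in)
    shell = inside & (cheb > h_el_in) & (cheb <= h_el_out)
    diel = inside & (cheb > h_el_out)
    in_el = np.zeros_like(inside)
    for s, (a, b) in enumerate(spec.electrode_spans()):
        span = (behind >= a) & (behind < b)
        emask[inside & (cheb <= h_el_out) & span] = 2 * applicator_index + s
        in_el |= shell & span
    mat[core] = pom
    mat[shell & in_el] = cu
    mat[shell & ~in_el] = pom
    mat[diel] = dielectric_id
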