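"""Voxelisation of applicators and benchmark phantoms."""

import numpy as np
import pytest

from thermoplan.applicators import ApplicatorSpec
from thermoplan.materials import EPS0, tissue_table
from thermoplan.model import build_model
from thermoplan.phantoms import complex_benchmark, homogeneous_benchmark


def _material_name(model, i, j, k):
    return model.materials[model.material_id[i, j, k]].name


def _cell_index(grid, axis, coord):
    centers = grid.centers(axis)
    return int(np.argmin(np.abs(centers - coord)))


@pytest.fixture(scope="module")
def detailed_one():
    spec = ApplicatorSpec(tip_position=(0.0, 0.0, 0.0))
    voi = ((-3.0, 3.0), (-3.0, 3.0), (-51.0, -4.0))
    return build_model([spec], voi, mode="detailed", fine_step=0.04)


def test_detailed_radial_classification(detailed_one):
    """Cells classify by radius: electrode shell at 1.04 mm, coating at 1.05, tissue at 1.2."""
    m = detailed_one
    # a z inside the proximal electrode span (30-50 mm behind the tip)
    k = _cell_index(m.grid, "z", -40.0)
    # shell radii: lumen < 0.83, POM < 1.0, copper < 1.03, coating < 1.06 mm;
    # the Dirichlet mask covers the whole conductor-enclosed disc (r <= 1.03)
    for radius, expected, in_mask in [
        (0.0, "Air", True),
        (0.92, "POM", True),
        (1.01, "Copper", True),
        (1.045, "Parylene C", False),
        (1.2, "Muscle", False),
    ]:
        i = _cell_index(m.grid, "x", radius)
        j = _cell_index(m.grid, "y", 0.0)
        assert _material_name(m, i, j, k) == expected, radius
        assert (m.electrode_mask[i, j, k] >= 0) == in_mask
    # in the 5 mm inter-electrode gap the shell ring is insulating, not copper
    k_gap = _cell_index(m.grid, "z", -27.5)
    i = _cell_index(m.grid, "x", 1.04)
    j = _cell_index(m.grid, "y", 0.0)
    assert m.electrode_mask[i, j, k_gap] == -1
    assert _material_name(m, i, j, k_gap) in ("POM", "Parylene C")


def test_detailed_electrode_shell_volume_converges():
    """Voxelised electrode shell volume approaches the analytic annulus under refinement.

    The 30 um copper shell is 1-2 cells thick at practical steps, so the
    whole-cell volume carries a grid-alignment quantization of a few percent
    that vanishes with refinement; the voxelised shell must also stay within
    one cell of the true annulus (radial containment).
    """
    spec = ApplicatorSpec(tip_position=(0.0, 0.0, 0.0))
    voi = ((-3.0, 3.0), (-3.0, 3.0), (-51.0, -4.0))
    analytic = np.pi / 4 * (2.06**2 - 2.0**2) * 20.0  # one 20 mm copper annulus
    disc = np.pi / 4 * 2.06**2 * 20.0  # full conductor-enclosed disc per electrode
    errs = []
    for fs in (0.02, 0.01):
        m = build_model([spec], voi, mode="detailed", fine_step=fs)
        vol = m.grid.cell_volumes_mm3()
        cu = next(i for i, mm in enumerate(m.materials) if mm.name == "Copper")
        errs.append(abs(vol[m.material_id == cu].sum() / (2 * analytic) - 1.0))
        # the Dirichlet disc volume is robust (boundary quantization only)
        assert vol[m.electrode_mask == 0].sum() == pytest.approx(disc, rel=0.05)
        # containment: copper cells lie within one cell of the true shell radii
        cx, cy = m.grid.centers("x"), m.grid.centers("y")
        r = np.hypot(cx[:, None], cy[None, :])[:, :, None] * np.ones(m.grid.shape)
        rc = r[m.material_id == cu]
        assert rc.min() >= 1.0 - 1.5 * fs and rc.max() <= 1.03 + 1.5 * fs
    assert errs[1] < errs[0]
    assert errs[1] < 0.05


def test_simplified_cuboid_classification():
    spec = ApplicatorSpec(tip_position=(0.0, 0.0, 0.0))
    voi = ((-3.0, 3.0), (-3.0, 3.0), (-51.0, -4.0))
    m = build_model([spec], voi, mode="simplified", fine_step=0.1)
    k = _cell_index(m.grid, "z", -40.0)  # inside proximal electrode
    j = _cell_index(m.grid, "y", 0.0)
    # (0.55, 0): between electrode half-edges 0.5 and 0.7 -> conductor
    i = _cell_index(m.grid, "x", 0.55)
    assert m.electrode_mask[i, j, k] >= 0
    # (0.8, 0): between 0.7 and 0.9 -> adapted dielectric
    i = _cell_index(m.grid, "x", 0.8)
    name = _material_name(m, i, j, k)
    assert name.startswith("Adapted dielectric")
    eps_r = m.materials[m.material_id[i, j, k]].eps_r
    expected = 2.4 * np.log(1.8 / 1.4) / np.log(2.12 / 2.06)
    assert eps_r == pytest.approx(expected, rel=1e-6)
    # same transverse position in the gap: not an electrode
    k_gap = _cell_index(m.grid, "z", -27.5)
    i = _cell_index(m.grid, "x", 0.55)
    assert m.electrode_mask[i, j, k_gap] == -1
    # Dirichlet box volume: 1.4^2 * 20 mm per electrode within 5%
    vol = m.grid.cell_volumes_mm3()
    for e in range(2):
        assert vol[m.electrode_mask == e].sum() == pytest.approx(1.4**2 * 20.0, rel=0.05)
    # the copper shell material occupies (1.4^2 - 1.0^2) * 20 mm per electrode
    cu = next(i for i, mm in enumerate(m.materials) if mm.name == "Copper")
    assert vol[m.material_id == cu].sum() == pytest.approx(2 * (1.4**2 - 1.0**2) * 20.0, rel=0.05)


def test_overlapping_applicators_rejected():
    a = ApplicatorSpec(tip_position=(0.0, 0.0, 0.0))
    b = ApplicatorSpec(tip_position=(1.0, 0.0, 0.0))
    voi = ((-3.0, 4.0), (-3.0, 3.0), (-51.0, -4.0))
    with pytest.raises(ValueError, match="overlap"):
        build_model([a, b], voi, mode="simplified", fine_step=0.1)


def test_detailed_mode_requires_z_parallel_axis():
    spec = ApplicatorSpec(tip_position=(0.0, 0.0, 0.0), direction=(0.0, 1.0, 1.0))
    voi = ((-3.0, 3.0), (-3.0, 3.0), (-51.0, -4.0))
    with pytest.raises(ValueError, match="z-parallel"):
        build_model([spec], voi, mode="detailed")


def test_homogeneous_phantom_layout():
    m = homogeneous_benchmark(n_applicators=2, mode="simplified")
    assert len(m.applicators) == 2
    assert m.n_electrodes == 4
    # everything outside the applicators is muscle
    names = {m.materials[i].name for i in np.unique(m.material_id)}
    assert "Muscle" in names and "Fat" not in names
    # applicators 9 mm apart
    tips = [a.tip_position for a in m.applicators]
    assert abs(tips[1][0] - tips[0][0]) == pytest.approx(9.0)
    # VOI covers the active electrode lengths
    (x0, x1), (y0, y1), (z0, z1) = m.voi
    assert z1 - z0 == pytest.approx(54.0)


def test_full_homogeneous_phantom_has_18_applicators_and_36_electrodes():
    # grid coarsened via fine_step for speed; the layout logic is unchanged
    m = homogeneous_benchmark(mode="simplified", fine_step=0.3)
    assert len(m.applicators) == 18
    assert m.n_electrodes == 36
    (x0, x1), (y0, y1), (z0, z1) = m.voi
    assert (x1 - x0, y1 - y0, z1 - z0) == pytest.approx((54.0, 43.0, 54.0))


def test_complex_phantom_interfaces_and_spacing():
    m = complex_benchmark(n_applicators=3, mode="simplified")
    xs = sorted(a.tip_position[0] for a in m.applicators)
    gaps = np.diff(xs)
    assert gaps[0] < 9.0 < gaps[1]  # one pair closer, one farther
    # transverse prostate-fat interface crossed by the applicators: the cells
    # beside an applicator see prostate at one z and fat at another
    a = m.applicators[0]
    i = _cell_index(m.grid, "x", a.tip_position[0] + 1.5)
    j = _cell_index(m.grid, "y", a.tip_position[1])
    names = {m.materials[m.material_id[i, j, k]].name for k in range(m.grid.shape[2])}
    assert {"Prostate", "Fat"} <= names
    # applicator centred on the longitudinal interface: prostate one side, fat the other
    mid = m.applicators[-1]
    k = _cell_index(m.grid, "z", -20.0)
    j = _cell_index(m.grid, "y", mid.tip_position[1])
    left = _cell_index(m.grid, "x", mid.tip_position[0] - 1.5)
    right = _cell_index(m.grid, "x", mid.tip_position[0] + 1.5)
    assert _material_name(m, left, j, k) == "Prostate"
    assert _material_name(m, right, j, k) == "Fat"
    # partition: every cell has exactly one material, from the expected set
    allowed = {"Muscle", "Fat", "Prostate", "Air", "POM", "Parylene C", "Copper"}
    for i in np.unique(m.material_id):
        name = m.materials[i].name
        assert name in allowed or name.startswith("Adapted dielectric")


def test_phantom_regeneration_is_bit_identical():
    a = homogeneous_benchmark(n_applicators=2, mode="simplified")
    b = homogeneous_benchmark(n_applicators=2, mode="simplified")
    assert np.array_equal(a.material_id, b.material_id)
    assert np.array_equal(a.electrode_mask, b.electrode_mask)
    assert np.array_equal(a.grid.x, b.grid.x)


def test_boundary_margin_from_voi_and_applicators():
    m = homogeneous_benchmark(n_applicators=2, mode="simplified")
    (x0, x1), (y0, y1), (z0, z1) = m.voi
    assert m.grid.x[0] <= x0 - 10 and m.grid.x[-1] >= x1 + 10
    assert m.grid.z[0] <= z0 - 10 and m.grid.z[-1] >= z1 + 10
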