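"""Electro-quasistatic solver: analytic oracles and structural properties."""

import math

import numpy as np
import pytest

from thermoplan.materials import tissue_table
from thermoplan.grid import RectilinearGrid
from thermoplan.model import VoxelModel
from thermoplan.solver import (
    EQSSystem,
    Excitation,
    electrode_power,
    normalize_power,
    sar_from_field,
)

from conftest import make_concentric_cylinders, make_parallel_plate


def test_excitation_validation():
    with pytest.raises(ValueError):
        Excitation(np.array([-1.0]))
    with pytest.raises(ValueError):
        Excitation(np.array([13.0]), np.array([0.5]))
    with pytest.raises(ValueError):
        Excitation(np.array([13.0]), frequency=0.0)


def test_parallel_plate_linear_ramp_and_field():
    """Uniform slab between plates: exact linear potential and constant E."""
    m = make_parallel_plate(n=9)
    sys_ = EQSSystem(m, grounded_boundary=False)
    sol = sys_.solve(Excitation(np.array([13.0, 0.0])))
    centers = m.grid.centers("x")
    # analytic ramp between the plate faces (PEC plates fill the end cells)
    x0, x1 = m.grid.x[1], m.grid.x[-2]
    expected = 13.0 * (x1 - centers) / (x1 - x0)
    inner = slice(1, -1)
    assert np.real(sol.V[inner, 2, 2]) == pytest.approx(expected[inner], rel=1e-9)
    e_expected = 13.0 / ((x1 - x0) * 1e-3)
    assert np.real(sol.E[0][inner, 2, 2]) == pytest.approx(
        np.full(7, e_expected), rel=1e-9
    )
    assert np.allclose(sol.E[1][inner], 0.0, atol=1e-6)


def test_parallel_plate_power_matches_circuit_formula():
    """P = 0.5*G*V^2 with G the slab conductance; grounded plate absorbs the rest."""
    m = make_parallel_plate(n=9)
    sys_ = EQSSystem(m, grounded_boundary=False)
    sol = sys_.solve(Excitation(np.array([13.0, 0.0])))
    p = electrode_power(sol, m, sys_)
    mus = tissue_table()["Muscle"]
    dx = (10.0 / 9) * 1e-3
    gap = 10e-3 - 2 * dx
    g_slab = mus.sigma * (10e-3) ** 2 / gap
    assert p[0] == pytest.approx(0.5 * g_slab * 13.0**2, rel=1e-9)
    sar = sar_from_field(sol.E, m)
    assert sar.total_power == pytest.approx(p.sum(), rel=1e-9)


def test_hand_assembled_three_cell_stack():
    """Layered 1D stack: assembled rows equal the hand-built two-face flux balance."""
    mus = tissue_table()["Muscle"]
    fat = tissue_table()["Fat"]
    g = RectilinearGrid(
        x=np.array([0.0, 1.0, 3.0, 4.0, 6.0, 7.0]),  # non-uniform on purpose
        y=np.array([0.0, 2.0]),
        z=np.array([0.0, 2.0]),
    )
    em = np.full(g.shape, -1, dtype=np.int16)
    em[0] = 0
    em[-1] = 1
    mat = np.array([0, 0, 0, 1, 1], dtype=np.int16)[:, None, None] * np.ones(g.shape, dtype=np.int16)
    m = VoxelModel(grid=g, material_id=mat, materials=[mus, fat], electrode_mask=em,
                   voi=g.bounds, applicators=[], mode="detailed", first_applicator_material_id=99)
    sys_ = EQSSystem(m, grounded_boundary=False)
    omega = sys_.omega
    k = [mus.admittivity(omega), mus.admittivity(omega), mus.admittivity(omega),
         fat.admittivity(omega), fat.admittivity(omega)]
    dxs = np.diff(g.x) * 1e-3
    area = 2e-3 * 2e-3
    # face conductance: half-cell series resistances (PEC end cells contribute none)
    def G(i, j, pec_i=False, pec_j=False):
        r = 0.0
        if not pec_i:
            r += dxs[i] / (2 * k[i])
        if not pec_j:
            r += dxs[j] / (2 * k[j])
        return area / r
    g01 = G(0, 1, pec_i=True)
    g12 = G(1, 2)
    g23 = G(2, 3)
    g34 = G(3, 4, pec_j=True)
    expected = np.array([
        [g01 + g12, -g12, 0],
        [-g12, g12 + g23, -g23],
        [0, -g23, g23 + g34],
    ])
    assert np.allclose(sys_.A.toarray(), expected, rtol=1e-12)
    b = sys_.rhs(np.array([13.0, 0.0]))
    assert np.allclose(b, np.array([13.0 * g01, 0, 0]), rtol=1e-12)


def test_zero_excitation_gives_zero_potential(mini_model, mini_system):
    sol = mini_system.solve(Excitation(np.zeros(mini_model.n_electrodes)))
    assert np.all(sol.V == 0)
    assert np.all(sol.E == 0)


def test_concentric_cylinders_match_log_potential():
    """V(r) proportional to ln(r_out/r): the classic coaxial solution."""
    m = make_concentric_cylinders(h=0.125)
    sys_ = EQSSystem(m, grounded_boundary=False, direct_limit=100_000)
    sol = sys_.solve(Excitation(np.array([13.0, 0.0])))
    cx = m.grid.centers("x")
    cy = m.grid.centers("y")
    r = np.hypot(cx[:, None], cy[None, :])
    mid = (r > 3.0) & (r < 7.0)
    v_num = np.real(sol.V[:, :, 1][mid])
    v_ana = 13.0 * np.log(8.0 / r[mid]) / np.log(8.0 / 2.0)
    assert np.max(np.abs(v_num - v_ana)) / 13.0 < 0.01
    # |E| proportional to 1/r off the shells
    e_mag = np.abs(sol.E[0][:, :, 1]) ** 2 + np.abs(sol.E[1][:, :, 1]) ** 2
    e_mag = np.sqrt(e_mag)[mid]
    e_ana = 13.0 / (np.log(8.0 / 2.0) * r[mid] * 1e-3)
    assert np.median(np.abs(e_mag - e_ana) / e_ana) < 0.02


def _blocky_coax_model(h, coarse=0.5, halfwidth=9.0, r_in=2.0, r_out=8.0):
    """Coaxial-like model whose electrode outline is fixed on the coarse lattice.

    Nested refinements then share the exact same (blocky) geometry, so the
    measured convergence reflects the discretization rather than a changing
    staircase approximation of the circle.
    """
    from thermoplan.materials import tissue_table

    n_c = int(round(2 * halfwidth / coarse))
    cc = -halfwidth + (np.arange(n_c) + 0.5) * coarse
    rc = np.hypot(cc[:, None], cc[None, :])
    lab = np.full((n_c, n_c), -1, np.int16)
    lab[rc <= r_in] = 0
    lab[rc >= r_out] = 1
    k = int(round(coarse / h))
    lab_f = np.repeat(np.repeat(lab, k, 0), k, 1)
    n = n_c * k
    g = RectilinearGrid(
        x=np.linspace(-halfwidth, halfwidth, n + 1),
        y=np.linspace(-halfwidth, halfwidth, n + 1),
        z=np.linspace(0, 3, 2),
    )
    return VoxelModel(
        grid=g, material_id=np.zeros(g.shape, np.int16),
        materials=[tissue_table()["Muscle"]], electrode_mask=lab_f[:, :, None].copy(),
        voi=g.bounds, applicators=[], mode="detailed", first_applicator_material_id=99,
    )


def test_grid_convergence_is_approximately_second_order():
    """Against a 4x finer reference solve, the potential error drops ~quadratically."""
    from scipy.interpolate import RegularGridInterpolator

    sols = {}
    for h in (0.25, 0.125, 0.0625):
        m = _blocky_coax_model(h)
        sys_ = EQSSystem(m, grounded_boundary=False, direct_limit=300_000)
        sols[h] = (m, sys_.solve(Excitation(np.array([13.0, 0.0]))))
    m_ref, ref = sols[0.0625]
    cxr = m_ref.grid.centers("x")
    interp = RegularGridInterpolator((cxr, cxr), np.real(ref.V[:, :, 0]))
    errs = []
    for h in (0.25, 0.125):
        m, sol = sols[h]
        cx = m.grid.centers("x")
        r = np.hypot(cx[:, None], cx[None, :])
        mid = (r > 3.5) & (r < 6.5)
        pts = np.stack(np.meshgrid(cx, cx, indexing="ij"), axis=-1).reshape(-1, 2)
        vr = interp(pts).reshape(r.shape)
        errs.append(np.sqrt(np.mean((np.real(sol.V[:, :, 0]) - vr)[mid] ** 2)))
    order = math.log2(errs[0] / errs[1])
    assert order > 1.5


def test_voltage_scaling_quadratic_sar(mini_model, mini_system, mini_solution):
    """Scaling the drive by c scales V and E by c and SAR by c^2 (to round-off)."""
    c = 2.5
    sol2 = mini_system.solve(Excitation.uniform(mini_model.n_electrodes, 13.0 * c))
    scale = np.max(np.abs(sol2.V - c * mini_solution.V)) / np.max(np.abs(sol2.V))
    assert scale < 1e-10
    sar1 = sar_from_field(mini_solution.E, mini_model)
    sar2 = sar_from_field(sol2.E, mini_model)
    rel = np.max(np.abs(sar2.sar - c**2 * sar1.sar)) / sar2.sar.max()
    assert rel < 1e-10


def test_sar_formula_and_conductor_zeroing(mini_model, mini_solution):
    """SAR = sigma|E|^2/(2 rho) cell-wise; zero where sigma = 0 or in conductors."""
    sar = sar_from_field(mini_solution.E, mini_model)
    sigma = mini_model.property_map("sigma")
    rho = mini_model.property_map("rho")
    e2 = sum(np.abs(mini_solution.E[a]) ** 2 for a in range(3))
    assert np.allclose(sar.sar, sigma * e2 / (2 * rho))
    assert np.all(sar.sar[mini_model.electrode_mask >= 0] == 0)
    assert np.all(sar.sar >= 0)
    # hand value: muscle cell with |E| = 100 V/m
    mus = tissue_table()["Muscle"]
    assert mus.sigma * 100.0**2 / (2 * mus.rho) == pytest.approx(3.0, abs=0.01)


def test_energy_balance_between_electrodes_and_volume():
    """Sum of electrode input powers equals the volume-integrated deposition within 2%.

    Checked on the resolved coaxial case: with the field smooth over cells,
    the cell-averaged |E|^2 integration is consistent with the face-flux
    electrode powers.
    """
    m = make_concentric_cylinders(h=0.125)
    sys_ = EQSSystem(m, grounded_boundary=False, direct_limit=100_000)
    exc = Excitation(np.array([13.0, 0.0]))
    sol = sys_.solve(exc)
    p = electrode_power(sol, m, sys_)
    sar = sar_from_field(sol.E, m)
    assert p.sum() == pytest.approx(sar.total_power, rel=0.02)


def test_power_normalisation_reaches_target(mini_model, mini_system):
    exc0 = Excitation.uniform(mini_model.n_electrodes)
    target = 0.7
    exc, sol = normalize_power(mini_model, exc0, target, system=mini_system)
    p = electrode_power(sol, mini_model, mini_system)
    assert np.all(np.abs(p - target) <= 0.01 * target)
    # two electrodes of one applicator in homogeneous muscle: near-symmetric drive
    assert exc.amplitudes[0] == pytest.approx(exc.amplitudes[1], rel=0.05)
    exc_zero, _ = normalize_power(mini_model, exc0, 0.0, system=mini_system)
    assert np.all(exc_zero.amplitudes == 0)


def test_solution_linearity_in_electrode_voltages(mini_model, mini_system):
    """Solving with both electrodes driven equals the sum of single-electrode solves."""
    n = mini_model.n_electrodes
    both = mini_system.solve(Excitation(np.array([13.0, 9.0])))
    parts = []
    for i, amp in enumerate([13.0, 9.0]):
        amps = np.zeros(n)
        amps[i] = amp
        parts.append(mini_system.solve(Excitation(amps)))
    v_sum = sum(p.V for p in parts)
    assert np.max(np.abs(both.V - v_sum)) / np.max(np.abs(both.V)) < 1e-8
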