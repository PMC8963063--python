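"""Electro-quasistatic voxel solver.

Solves div((sigma + j*omega*eps) grad V) = 0 on a non-uniform rectilinear
grid with cell-centred complex potentials, using a conservative two-point
flux (finite-volume) discretization: the face admittance between two cells
is the series combination of the two half-cell admittances (harmonic mean
weighted by the half-cell widths), which is exact for layered media.

Electrode conductor cells are treated as perfect conductors: they are
excluded from the unknowns and act as Dirichlet equipotentials whose
half-cell resistance is zero.  The outer domain boundary is grounded
(V = 0 Dirichlet), placed at least 10 mm from the volume of interest.

Because the Dirichlet data enter only the right-hand side, one assembled
operator serves every excitation of the same model: per-electrode basis
solves, power normalisation and plan re-evaluation all reuse the same
factorisation/preconditioner.

Large systems are solved iteratively (BiCGSTAB) with a symmetric block
Gauss-Seidel preconditioner over z-planes, each plane solved by a direct
sparse factorisation.  This targets the strong transverse coupling of the
fine in-plane steps (down to 0.02 mm against a 1 mm longitudinal step);
identical planes share one factorisation.  Small systems use a direct
sparse solve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .materials import DEFAULT_FREQUENCY
from .model import VoxelModel

MM = 1e-3

#: reference electrode drive voltage (V), matching the potential observed on
#: the electrodes under the generator drive
REFERENCE_VOLTAGE = 13.0


@dataclass
class Excitation:
    """Per-electrode drive: amplitudes in volts, polarity +1 (0 deg) or -1 (180 deg)."""

    amplitudes: np.ndarray
    polarities: np.ndarray | None = None
    frequency: float = DEFAULT_FREQUENCY

    def __post_init__(self):
        self.amplitudes = np.atleast_1d(np.asarray(self.amplitudes, dtype=float))
        if np.any(self.amplitudes < 0):
            raise ValueError("amplitudes must be >= 0")
        if self.polarities is None:
            self.polarities = np.ones_like(self.amplitudes)
        self.polarities = np.atleast_1d(np.asarray(self.polarities, dtype=float))
        if not np.all(np.isin(self.polarities, (-1.0, 1.0))):
            raise ValueError("polarities must be +1 or -1")
        if self.polarities.shape != self.amplitudes.shape:
            raise ValueError("amplitudes and polarities must have the same length")
        if self.frequency <= 0:
            raise ValueError("frequency must be > 0")

    @property
    def omega(self) -> float:
        return 2.0 * math.pi * self.frequency

    @property
    def voltages(self) -> np.ndarray:
        """Signed electrode voltages (V)."""
        return self.amplitudes * self.polarities

    @classmethod
    def uniform(cls, n_electrodes: int, amplitude: float = REFERENCE_VOLTAGE,
                frequency: float = DEFAULT_FREQUENCY) -> "Excitation":
        return cls(amplitudes=np.full(n_electrodes, float(amplitude)), frequency=frequency)


@dataclass
class FieldSolution:
    """Complex potential (V) and cell-centred E-field (V/m) on the model grid."""

    V: np.ndarray
    E: np.ndarray  # shape (3, nx, ny, nz)
    residual: float
    excitation: Excitation


@dataclass
class SARVolume:
    """Per-cell specific absorption rate (W/kg) and total deposited power (W)."""

    sar: np.ndarray
    total_power: float


class ConvergenceError(RuntimeError):
    pass


class EQSSystem:
    """Assembled EQS operator for one voxel model at one frequency.

    The operator, preconditioner and Dirichlet coupling matrices are built
    once; :meth:`solve` then maps any set of electrode voltages to a full
    potential volume.
    """

    def __init__(self, model: VoxelModel, frequency: float = DEFAULT_FREQUENCY,
                 rtol: float = 1e-9, direct_limit: int = 60_000,
                 grounded_boundary: bool = True):
        if model.n_electrodes < 1:
            raise ValueError("model has no electrodes")
        self.model = model
        self.frequency = frequency
        self.omega = 2.0 * math.pi * frequency
        self.rtol = rtol
        self.grounded_boundary = grounded_boundary
        grid = model.grid
        nx, ny, nz = grid.shape

        kappa = model.admittivity(self.omega)
        emask = model.electrode_mask
        is_el = emask >= 0
        n_el = model.n_electrodes

        # transposed (z-major) layout so unknowns are ordered plane by plane
        kap_t = kappa.transpose(2, 0, 1)
        el_t = emask.transpose(2, 0, 1)
        free_t = el_t < 0
        self._free_t = free_t
        nfree = int(free_t.sum())
        num = np.full(free_t.shape, -1, dtype=np.int64)
        num[free_t] = np.arange(nfree)
        self.n_free = nfree

        dx = grid.steps("x") * MM
        dy = grid.steps("y") * MM
        dz = grid.steps("z") * MM
        # half-cell resistance-area products per axis (Ohm*m^2); 0 in conductors
        with np.errstate(divide="ignore", invalid="ignore"):
            rx = (dx[:, None, None] / 2.0) / kappa
            ry = (dy[None, :, None] / 2.0) / kappa
            rz = (dz[None, None, :] / 2.0) / kappa
        for r in (rx, ry, rz):
            r[is_el] = 0.0
        self._kappa = kappa
        self._is_el = is_el
        self._half_steps_m = (dx / 2.0, dy / 2.0, dz / 2.0)

        ax = (dy[:, None] * dz[None, :])  # (ny, nz)
        ay = (dx[:, None] * dz[None, :])  # (nx, nz)
        az = (dx[:, None] * dy[None, :])  # (nx, ny)

        diag = np.zeros(nfree, dtype=np.complex128)
        rows: list[np.ndarray] = []
        cols: list[np.ndarray] = []
        vals: list[np.ndarray] = []
        b_rows: list[np.ndarray] = []
        b_cols: list[np.ndarray] = []
        b_vals: list[np.ndarray] = []
        s_diag = np.zeros(n_el, dtype=np.complex128)
        c_rows: list[np.ndarray] = []
        c_cols: list[np.ndarray] = []
        c_vals: list[np.ndarray] = []

        rx_t = rx.transpose(2, 0, 1)
        ry_t = ry.transpose(2, 0, 1)
        rz_t = rz.transpose(2, 0, 1)
        ax_t = np.broadcast_to(ax.T[:, None, :], (nz, nx, ny))   # (nz, nx, ny) area for x-faces
        ay_t = np.broadcast_to(ay.T[:, :, None], (nz, nx, ny))
        az_t = np.broadcast_to(az[None, :, :], (nz, nx, ny))

        def add_faces(r_t, area_t, axis):
            # faces between transposed-neighbours along `axis` of (nz, nx, ny)
            sl_lo = [slice(None)] * 3
            sl_hi = [slice(None)] * 3
            sl_lo[axis] = slice(None, -1)
            sl_hi[axis] = slice(1, None)
            sl_lo, sl_hi = tuple(sl_lo), tuple(sl_hi)
            rsum = r_t[sl_lo] + r_t[sl_hi]
            both_el = rsum == 0
            with np.errstate(divide="ignore", invalid="ignore"):
                g = area_t[sl_lo] / np.where(both_el, 1.0, rsum)
            g[both_el] = 0.0
            p = num[sl_lo]
            q = num[sl_hi]
            ep = el_t[sl_lo]
            eq = el_t[sl_hi]
            ff = (p >= 0) & (q >= 0)
            np.add.at(diag, p[ff], g[ff])
            np.add.at(diag, q[ff], g[ff])
            pf = p[ff].astype(np.int32); qf = q[ff].astype(np.int32); gf = -g[ff]
            rows.append(pf); cols.append(qf); vals.append(gf)
            rows.append(qf); cols.append(pf); vals.append(gf)
            # free cell next to an electrode: Dirichlet coupling -> rhs matrix
            for fr, di in (((p >= 0) & (eq >= 0), eq), ((q >= 0) & (ep >= 0), ep)):
                pp = np.where(fr, np.where(p >= 0, p, q), -1)
                if np.any(fr):
                    np.add.at(diag, pp[fr], g[fr])
                    b_rows.append(pp[fr]); b_cols.append(di[fr]); b_vals.append(g[fr])
                    np.add.at(s_diag, di[fr], g[fr])
            # electrode-electrode faces between different electrodes
            ee = (ep >= 0) & (eq >= 0) & (ep != eq) & ~both_el
            if np.any(ee):
                c_rows.append(ep[ee]); c_cols.append(eq[ee]); c_vals.append(g[ee])
                c_rows.append(eq[ee]); c_cols.append(ep[ee]); c_vals.append(g[ee])
                np.add.at(s_diag, ep[ee], g[ee])
                np.add.at(s_diag, eq[ee], g[ee])

        add_faces(rx_t, ax_t, 1)
        add_faces(ry_t, ay_t, 2)
        add_faces(rz_t, az_t, 0)

        # grounded outer boundary: ghost faces with half-cell resistance only
        def add_boundary(r_t, area_t, axis, side):
            sl = [slice(None)] * 3
            sl[axis] = 0 if side == 0 else -1
            sl = tuple(sl)
            rb = r_t[sl]
            g = np.where(rb != 0, area_t[sl] / np.where(rb != 0, rb, 1), 0.0)
            p = num[sl]
            fr = p >= 0
            np.add.at(diag, p[fr], g[fr])

        if grounded_boundary:
            for r_t, a_t, axis in ((rx_t, ax_t, 1), (ry_t, ay_t, 2), (rz_t, az_t, 0)):
                add_boundary(r_t, a_t, axis, 0)
                add_boundary(r_t, a_t, axis, 1)

        del rx, ry, rz, rx_t, ry_t, rz_t
        idx32 = np.arange(nfree, dtype=np.int32)
        all_vals = np.concatenate(vals + [diag])
        del vals[:], diag
        all_rows = np.concatenate(rows + [idx32]); del rows[:]
        all_cols = np.concatenate(cols + [idx32]); del cols[:]
        A = sp.coo_matrix((all_vals, (all_rows, all_cols)), shape=(nfree, nfree)).tocsr()
        del all_vals, all_rows, all_cols
        A.sum_duplicates()
        # int32 index arrays: halves index memory on multi-million-cell models
        A.indices = A.indices.astype(np.int32)
        A.indptr = A.indptr.astype(np.int32)
        self.A = A
        if b_rows:
            self.B = sp.coo_matrix(
                (np.concatenate(b_vals), (np.concatenate(b_rows), np.concatenate(b_cols))),
                shape=(nfree, n_el),
            ).tocsr()
        else:
            self.B = sp.csr_matrix((nfree, n_el))
        self._S = s_diag
        if c_rows:
            self._C = sp.coo_matrix(
                (np.concatenate(c_vals), (np.concatenate(c_rows), np.concatenate(c_cols))),
                shape=(n_el, n_el),
            ).tocsr()
        else:
            self._C = sp.csr_matrix((n_el, n_el))
        self._num_t = num

        # plane extents in the unknown numbering
        counts = free_t.reshape(nz, -1).sum(axis=1)
        self._plane_ptr = np.concatenate([[0], np.cumsum(counts)])
        self._direct = nfree <= direct_limit
        self._lu = None
        self._plane_data = None

    # ------------------------------------------------------------------ setup
    def _setup_direct(self):
        if self._lu is None:
            self._lu = spla.splu(self.A.tocsc())
        return self._lu

    def _setup_planes(self):
        if self._plane_data is not None:
            return self._plane_data
        ptr = self._plane_ptr
        blocks = []
        lus: dict = {}
        for k in range(len(ptr) - 1):
            s, e = int(ptr[k]), int(ptr[k + 1])
            blk = self.A[s:e, s:e].tocsc()
            key = (blk.shape[0], blk.nnz,
                   hash(blk.indptr.tobytes()), hash(blk.indices.tobytes()),
                   hash(blk.data.tobytes()))
            if key not in lus:
                # symmetric-pattern ordering without pivoting: the plane blocks
                # are diagonally dominant complex-symmetric, and MMD on A^T+A
                # gives far less fill than the default unsymmetric ordering
                lus[key] = spla.splu(blk, permc_spec="MMD_AT_PLUS_A",
                                     options={"SymmetricMode": True},
                                     diag_pivot_thresh=0.0)
            blocks.append(lus[key])
        # coarse correction over plane averages: captures the slow longitudinal
        # error modes that plane-wise relaxation propagates only one plane per sweep
        nk = len(ptr) - 1
        cols = np.repeat(np.arange(nk), np.diff(ptr).astype(int))
        R = sp.csr_matrix(
            (np.ones(self.n_free), (cols, np.arange(self.n_free))), shape=(nk, self.n_free)
        )
        A_c = (R @ self.A @ R.T).toarray()
        self._plane_data = (blocks, R, np.linalg.inv(A_c))
        return self._plane_data

    def _block_gs(self, r: np.ndarray) -> np.ndarray:
        """Two-level preconditioner: symmetric plane-block Gauss-Seidel sweeps
        around a coarse longitudinal (plane-average) correction.

        Row blocks are sliced from the operator on the fly rather than stored,
        keeping the memory footprint at one copy of the matrix.
        """
        blocks, R, A_c_inv = self._setup_planes()
        ptr = self._plane_ptr
        nk = len(blocks)
        x = np.zeros_like(r)
        for k in range(nk):
            s, e = int(ptr[k]), int(ptr[k + 1])
            if e == s:
                continue
            rk = r[s:e] - self.A[s:e, :] @ x
            x[s:e] = blocks[k].solve(rk)
        x += R.T @ (A_c_inv @ (R @ (r - self.A @ x)))
        for k in range(nk - 1, -1, -1):
            s, e = int(ptr[k]), int(ptr[k + 1])
            if e == s:
                continue
            rk = r[s:e] - self.A[s:e, :] @ x
            x[s:e] += blocks[k].solve(rk)
        return x

    # ------------------------------------------------------------------ solve
    def rhs(self, voltages: np.ndarray) -> np.ndarray:
        return self.B @ np.asarray(voltages, dtype=np.complex128)

    def solve_free(self, voltages: np.ndarray, x0: np.ndarray | None = None) -> np.ndarray:
        """Solve for the free-cell potentials given per-electrode voltages.

        ``x0`` warm-starts the iterative path (e.g. the rescaled previous
        iterate during power normalisation).
        """
        b = self.rhs(voltages)
        if not np.any(b):
            return np.zeros(self.n_free, dtype=np.complex128)
        if self._direct:
            x = self._setup_direct().solve(b)
        else:
            M = spla.LinearOperator(self.A.shape, matvec=self._block_gs, dtype=np.complex128)
            x, info = spla.bicgstab(self.A, b, M=M, rtol=self.rtol * 0.3, atol=0.0,
                                    maxiter=400, x0=x0)
            if info != 0:
                # restart kept small enough that the Krylov basis fits in memory
                restart = max(5, min(30, int(2e8 / (16 * self.n_free))))
                x, info = spla.gmres(self.A, b, M=M, rtol=self.rtol * 0.3, atol=0.0,
                                     restart=restart, maxiter=8, x0=x)
        res = np.linalg.norm(self.A @ x - b) / np.linalg.norm(b)
        if res > self.rtol:
            raise ConvergenceError(f"EQS solve did not reach rtol={self.rtol:g}: residual {res:.3e}")
        self._last_residual = res
        return x

    def full_potential(self, x_free: np.ndarray, voltages: np.ndarray) -> np.ndarray:
        """Scatter free/Dirichlet potentials back to the full cell volume."""
        v_t = np.zeros(self._free_t.shape, dtype=np.complex128)
        v_t[self._free_t] = x_free
        el_t = self.model.electrode_mask.transpose(2, 0, 1)
        volt = np.asarray(voltages, dtype=np.complex128)
        sel = el_t >= 0
        v_t[sel] = volt[el_t[sel]]
        return v_t.transpose(1, 2, 0)

    def solve(self, excitation: Excitation) -> FieldSolution:
        """Solve the model under an excitation; returns potential and E-field."""
        voltages = self._expand_voltages(excitation)
        x = self.solve_free(voltages)
        V = self.full_potential(x, voltages)
        E = self.efield(V)
        return FieldSolution(V=V, E=E, residual=getattr(self, "_last_residual", 0.0),
                             excitation=excitation)

    def _expand_voltages(self, excitation: Excitation) -> np.ndarray:
        v = excitation.voltages
        if v.size != self.model.n_electrodes:
            raise ValueError(
                f"excitation has {v.size} electrodes, model has {self.model.n_electrodes}"
            )
        return v

    # ----------------------------------------------------------------- fields
    def efield(self, V: np.ndarray) -> np.ndarray:
        """Cell-centred complex E-field (V/m) from the cell potentials.

        Face current densities from the two-point flux (consistent with the
        discretization, including at material interfaces and Dirichlet
        faces) are converted to the cell-side E via the cell's own
        admittivity and averaged per cell; E is zero inside conductors.
        """
        nx, ny, nz = self.model.grid.shape
        E = np.zeros((3, nx, ny, nz), dtype=np.complex128)
        kappa = self._kappa
        shapes = [(-1, 1, 1), (1, -1, 1), (1, 1, -1)]
        for axis in range(3):
            with np.errstate(divide="ignore", invalid="ignore"):
                r = self._half_steps_m[axis].reshape(shapes[axis]) / kappa
            r[self._is_el] = 0.0
            j_faces = np.zeros((nx + (axis == 0), ny + (axis == 1), nz + (axis == 2)),
                               dtype=np.complex128)
            sl_lo = [slice(None)] * 3
            sl_hi = [slice(None)] * 3
            sl_lo[axis] = slice(None, -1)
            sl_hi[axis] = slice(1, None)
            rsum = r[tuple(sl_lo)] + r[tuple(sl_hi)]
            with np.errstate(divide="ignore", invalid="ignore"):
                j_int = (V[tuple(sl_lo)] - V[tuple(sl_hi)]) / rsum
            j_int[rsum == 0] = 0.0
            sl_faces = [slice(None)] * 3
            sl_faces[axis] = slice(1, -1)
            j_faces[tuple(sl_faces)] = j_int
            # grounded boundary faces
            first = [slice(None)] * 3
            first[axis] = 0
            last = [slice(None)] * 3
            last[axis] = -1
            r0 = r[tuple(first)]
            r1 = r[tuple(last)]
            f0 = [slice(None)] * 3
            f0[axis] = 0
            f1 = [slice(None)] * 3
            f1[axis] = -1
            if self.grounded_boundary:
                with np.errstate(divide="ignore", invalid="ignore"):
                    j_faces[tuple(f0)] = np.where(r0 != 0, (0.0 - V[tuple(first)]) / np.where(r0 != 0, r0, 1), 0.0)
                    j_faces[tuple(f1)] = np.where(r1 != 0, (V[tuple(last)] - 0.0) / np.where(r1 != 0, r1, 1), 0.0)
            lo = [slice(None)] * 3
            lo[axis] = slice(None, -1)
            hi = [slice(None)] * 3
            hi[axis] = slice(1, None)
            E[axis] = 0.5 * (j_faces[tuple(lo)] + j_faces[tuple(hi)]) / kappa
        E[:, self._is_el] = 0.0
        return E

    # ----------------------------------------------------------- diagnostics
    def electrode_currents(self, x_free: np.ndarray, voltages: np.ndarray) -> np.ndarray:
        """Total complex current (A) leaving each electrode into the model."""
        v = np.asarray(voltages, dtype=np.complex128)
        return self._S * v - self.B.T @ x_free - self._C @ v

    def electrode_powers(self, x_free: np.ndarray, voltages: np.ndarray) -> np.ndarray:
        """Time-averaged input power (W) per electrode: 0.5*Re(V conj(I))."""
        i_el = self.electrode_currents(x_free, np.asarray(voltages))
        return 0.5 * np.real(np.asarray(voltages) * np.conj(i_el))


def solve_fields(model: VoxelModel, excitation: Excitation, system: EQSSystem | None = None,
                 **kwargs) -> FieldSolution:
    """Convenience wrapper: assemble (or reuse) the system and solve."""
    if system is None:
        system = EQSSystem(model, frequency=excitation.frequency, **kwargs)
    return system.solve(excitation)


def sar_from_field(E: np.ndarray, model: VoxelModel,
                   frequency: float = DEFAULT_FREQUENCY) -> SARVolume:
    """SAR = sigma*|E|^2 / (2*rho) per cell (W/kg) and total deposited power (W).

    The effective conductivity is Re of the cell admittivity, so subcell-mixed
    boundary cells dissipate consistently with the field they were solved with.
    """
    sigma = np.real(model.admittivity(2.0 * math.pi * frequency))
    rho = model.property_map("rho")
    e2 = np.abs(E[0]) ** 2 + np.abs(E[1]) ** 2 + np.abs(E[2]) ** 2
    sar = sigma * e2 / (2.0 * rho)
    vol = model.grid.cell_volumes_mm3() * 1e-9
    total = float(np.sum(sar * rho * vol))
    return SARVolume(sar=sar, total_power=total)


def electrode_power(solution: FieldSolution, model: VoxelModel, system: EQSSystem) -> np.ndarray:
    """Per-electrode input power (W) of a solved excitation."""
    voltages = solution.excitation.voltages
    x_free = solution.V.transpose(2, 0, 1)[system._free_t]
    return system.electrode_powers(x_free, voltages)


def normalize_power(
    model: VoxelModel,
    excitation: Excitation,
    target_power: float,
    system: EQSSystem | None = None,
    tol: float = 0.01,
    max_iter: int = 20,
) -> tuple[Excitation, FieldSolution]:
    """Rescale per-electrode amplitudes until each input power matches the target.

    Fixed-point iteration on a_e <- a_e * sqrt(P_target / P_e); polarities
    are unchanged.  Returns the normalised excitation and its solution.
    Convergence is fast because each electrode's input power is dominated by
    its own drive amplitude.
    """
    if system is None:
        system = EQSSystem(model, frequency=excitation.frequency)
    amps = excitation.amplitudes.copy()
    if target_power == 0:
        exc = Excitation(np.zeros_like(amps), excitation.polarities, excitation.frequency)
        return exc, system.solve(exc)
    sol = None
    x_prev = None
    for _ in range(max_iter):
        exc = Excitation(amps, excitation.polarities, excitation.frequency)
        voltages = exc.voltages
        x = system.solve_free(voltages, x0=x_prev)
        p = system.electrode_powers(x, voltages)
        active = amps > 0
        if np.any(p[active] <= 0):
            raise ConvergenceError("non-positive electrode input power during normalisation")
        if np.all(np.abs(p[active] - target_power) <= tol * target_power):
            V = system.full_potential(x, voltages)
            E = system.efield(V)
            sol = FieldSolution(V=V, E=E, residual=getattr(system, "_last_residual", 0.0),
                                excitation=exc)
            return exc, sol
        s = np.where(active, np.sqrt(np.where(p > 0, target_power / np.where(p > 0, p, 1.0), 1.0)), 0.0)
        # near-uniform rescale (e.g. symmetric phantoms): apply it analytically —
        # scaling every drive voltage by a common factor scales the solution linearly
        s_mean = np.exp(np.mean(np.log(s[active])))
        if np.all(np.abs(p[active] * s_mean**2 - target_power) <= 0.9 * tol * target_power):
            amps = np.where(active, amps * s_mean, 0.0)
            exc = Excitation(amps, excitation.polarities, excitation.frequency)
            V = system.full_potential(x * s_mean, exc.voltages)
            E = system.efield(V)
            sol = FieldSolution(V=V, E=E, residual=getattr(system, "_last_residual", 0.0),
                                excitation=exc)
            return exc, sol
        x_prev = x * s_mean  # warm start for the re-solve
        amps = np.where(active, amps * s, 0.0)
    raise ConvergenceError(
        f"power normalisation did not converge within {max_iter} iterations; last powers {p}"
    )
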