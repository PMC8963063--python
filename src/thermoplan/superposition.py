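"""Per-electrode field bases and their superposition.

The electro-quasistatic problem is linear in the electrode voltages, so the
field of any amplitude/polarity setting is the weighted sum of per-electrode
basis fields, each solved with one electrode at a reference voltage and all
others grounded.  A pre-computed basis therefore lets treatment-plan
settings be re-evaluated without touching the solver — the key enabler for
interactive/automated plan optimisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import VoxelModel
from .solver import (
    REFERENCE_VOLTAGE,
    EQSSystem,
    Excitation,
    FieldSolution,
    SARVolume,
    sar_from_field,
)


@dataclass
class FieldBasis:
    """Per-electrode complex E-field volumes and electrode current couplings.

    ``fields[i]`` is the E-field (V/m, shape (3, nx, ny, nz)) with electrode
    ``i`` driven at ``reference_voltage`` and all others grounded.
    ``currents[e, i]`` is the complex current into electrode ``e`` in basis
    solution ``i``, used to evaluate per-electrode input powers for arbitrary
    settings without re-solving.
    """

    fields: list[np.ndarray]
    reference_voltage: float
    frequency: float
    currents: np.ndarray | None = None

    @property
    def n_electrodes(self) -> int:
        return len(self.fields)

    def weights(self, excitation: Excitation) -> np.ndarray:
        """Dimensionless per-electrode weights (signed multiples of the reference)."""
        if excitation.amplitudes.size != self.n_electrodes:
            raise ValueError(
                f"excitation has {excitation.amplitudes.size} electrodes, "
                f"basis has {self.n_electrodes}"
            )
        return excitation.voltages / self.reference_voltage

    def electrode_powers(self, excitation: Excitation) -> np.ndarray:
        """Per-electrode input power (W) for a setting, from the current couplings."""
        if self.currents is None:
            raise ValueError("basis was built without electrode current couplings")
        w = self.weights(excitation)
        i_el = self.currents @ w
        v_el = excitation.voltages
        return 0.5 * np.real(v_el * np.conj(i_el))


def compute_basis(
    model: VoxelModel,
    reference_voltage: float = REFERENCE_VOLTAGE,
    system: EQSSystem | None = None,
    frequency: float | None = None,
) -> FieldBasis:
    """Solve one EQS problem per electrode (others grounded), in electrode order."""
    from .materials import DEFAULT_FREQUENCY

    freq = frequency if frequency is not None else DEFAULT_FREQUENCY
    if system is None:
        system = EQSSystem(model, frequency=freq)
    n = model.n_electrodes
    fields = []
    currents = np.zeros((n, n), dtype=np.complex128)
    for i in range(n):
        voltages = np.zeros(n)
        voltages[i] = reference_voltage
        try:
            x = system.solve_free(voltages)
        except Exception as err:  # annotate solver failures with the electrode
            raise RuntimeError(f"basis solve failed for electrode {i}") from err
        V = system.full_potential(x, voltages)
        fields.append(system.efield(V))
        currents[:, i] = system.electrode_currents(x, voltages)
    return FieldBasis(fields=fields, reference_voltage=reference_voltage,
                      frequency=system.frequency, currents=currents)


def combine_fields(basis: FieldBasis, excitation: Excitation) -> np.ndarray:
    """Superpose basis fields: E_tot = sum_i w_i E_i with signed weights w_i."""
    w = basis.weights(excitation)
    etot = np.zeros_like(basis.fields[0])
    for wi, ei in zip(w, basis.fields):
        if wi != 0.0:
            etot += wi * ei
    return etot


def total_sar(etot: np.ndarray, model: VoxelModel) -> SARVolume:
    """SAR of a superposed field (identical to the direct-solve SAR by linearity)."""
    return sar_from_field(etot, model)


def normalize_power_superposed(
    basis: FieldBasis,
    excitation: Excitation,
    target_power: float,
    tol: float = 0.01,
    max_iter: int = 50,
) -> Excitation:
    """Equal-input-power normalisation evaluated entirely on the basis couplings."""
    amps = excitation.amplitudes.copy()
    if target_power == 0:
        return Excitation(np.zeros_like(amps), excitation.polarities, excitation.frequency)
    for _ in range(max_iter):
        exc = Excitation(amps, excitation.polarities, excitation.frequency)
        p = basis.electrode_powers(exc)
        active = amps > 0
        if np.any(p[active] <= 0):
            raise RuntimeError("non-positive electrode input power during normalisation")
        if np.all(np.abs(p[active] - target_power) <= tol * target_power):
            return exc
        amps = np.where(active, amps * np.sqrt(np.where(p > 0, target_power / np.where(p > 0, p, 1.0), 1.0)), 0.0)
    raise RuntimeError(f"power normalisation did not converge; last powers {p}")
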