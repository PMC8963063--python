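"""Simplified-vs-detailed benchmark comparisons.

Runs the full validation workflow on a benchmark phantom: solve the
simplified cuboid model and a fine-grid detailed cylindrical-geometry
reference of the same phantom, normalise every electrode to equal input
power, and score the agreement with 3D gamma analysis (strict 1%/0.5 mm and
lenient 2%/2 mm criteria) plus voxel-wise accuracy/bias.

The detailed reference is the expensive part; its power normalisation is
warm-started from the simplified model's normalised amplitudes so that it
typically converges within a single solve.
"""

from __future__ import annotations

import numpy as np

from .gamma import GammaConfig, compare_sar
from .phantoms import complex_benchmark, homogeneous_benchmark
from .pipeline import _conductor_exclusion
from .solver import EQSSystem, Excitation, normalize_power, sar_from_field

PHANTOMS = {"homogeneous": homogeneous_benchmark, "complex": complex_benchmark}


def _solve_normalized(model, target_power, initial_amplitudes=None, rtol=1e-9):
    system = EQSSystem(model, rtol=rtol)
    n = model.n_electrodes
    amps = np.full(n, 13.0) if initial_amplitudes is None else np.asarray(initial_amplitudes)
    exc, sol = normalize_power(model, Excitation(amps.astype(float)), target_power,
                               system=system)
    sar = sar_from_field(sol.E, model)
    x = sol.V.transpose(2, 0, 1)[system._free_t]
    powers = system.electrode_powers(x, exc.voltages)
    return sar, exc, powers


def benchmark_comparison(
    kind: str = "homogeneous",
    n_applicators: int = 2,
    detailed_fine_step: float = 0.02,
    simplified_fine_step: float = 0.1,
    target_power: float = 0.7,
    comparison_spacing: float = 0.25,
    criteria: tuple = ((1.0, 0.5), (2.0, 2.0)),
) -> dict:
    """Simplified-model SAR vs detailed-geometry reference on one phantom.

    Returns a dict with per-criterion gamma passing rates, accuracy (MAE) and
    bias as % of max reference SAR, per-electrode powers and model sizes.
    """
    if kind not in PHANTOMS:
        raise ValueError(f"unknown phantom kind {kind!r}")
    build = PHANTOMS[kind]

    simp = build(n_applicators=n_applicators, mode="simplified",
                 fine_step=simplified_fine_step)
    sar_s, exc_s, powers_s = _solve_normalized(simp, target_power)

    det = build(n_applicators=n_applicators, mode="detailed",
                fine_step=detailed_fine_step)
    sar_d, exc_d, powers_d = _solve_normalized(det, target_power,
                                               initial_amplitudes=exc_s.amplitudes)

    exclude = _conductor_exclusion(det, simp)
    out = {
        "kind": kind,
        "n_applicators": n_applicators,
        "n_electrodes": simp.n_electrodes,
        "cells_detailed": det.grid.n_cells,
        "cells_simplified": simp.grid.n_cells,
        "electrode_powers_detailed_w": [float(p) for p in powers_d],
        "electrode_powers_simplified_w": [float(p) for p in powers_s],
        "criteria": [],
    }
    for dd, dta in criteria:
        res = compare_sar(
            sar_d.sar, det.grid, sar_s.sar, simp.grid, simp.voi,
            GammaConfig(dd_percent=dd, dta_mm=dta),
            comparison_spacing=comparison_spacing,
            exclude=exclude,
        )
        out["criteria"].append({
            "dd_percent": dd,
            "dta_mm": dta,
            "passing_rate": float(res.passing_rate),
            "accuracy_pct_max_sar": float(res.accuracy),
            "bias_pct_max_sar": float(res.bias),
        })
    return out
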