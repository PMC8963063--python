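"""Pipeline orchestration: phantom -> solve -> SAR -> gamma/bioheat -> report.

A run is described by a YAML mapping (see ``load_config``) and is
reproducible bit-for-bit: every stage is deterministic.  The pipeline
builds the requested phantom, solves the field either directly or through
the per-electrode basis, normalises electrode input powers when requested,
and writes SAR (and optionally temperature and gamma) volumes plus a JSON
metrics report.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np

from . import io as tio
from .bioheat import ThermalModel, constraint_report, solve_pennes
from .gamma import GammaConfig, compare_sar
from .model import VoxelModel
from .phantoms import complex_benchmark, homogeneous_benchmark
from .solver import EQSSystem, Excitation, normalize_power, sar_from_field
from .superposition import combine_fields, compute_basis, normalize_power_superposed, total_sar

PHANTOMS = {"homogeneous": homogeneous_benchmark, "complex": complex_benchmark}


def build_phantom(cfg: dict) -> VoxelModel:
    kind = cfg.get("phantom")
    if kind not in PHANTOMS:
        raise KeyError(f"config key 'phantom' must be one of {sorted(PHANTOMS)}, got {kind!r}")
    kwargs = {k: cfg[k] for k in ("n_applicators", "spacing", "fine_step", "voi_margins") if k in cfg}
    return PHANTOMS[kind](mode=cfg.get("mode", "simplified"), **kwargs)


def solve_phantom(model: VoxelModel, cfg: dict):
    """Solve a model per the excitation config; returns (sar, excitation, powers, system)."""
    exc_cfg = cfg.get("excitation", {})
    amplitude = exc_cfg.get("amplitude", 13.0)
    n = model.n_electrodes
    pol = np.asarray(exc_cfg.get("polarities", np.ones(n)), dtype=float)
    exc = Excitation(np.full(n, float(amplitude)), pol)
    system = EQSSystem(model)
    target = exc_cfg.get("normalize_power_w")
    method = cfg.get("method", "direct")
    if method == "superposition":
        basis = compute_basis(model, system=system)
        if target is not None:
            exc = normalize_power_superposed(basis, exc, float(target))
        etot = combine_fields(basis, exc)
        sar = total_sar(etot, model)
        powers = basis.electrode_powers(exc)
    elif method == "direct":
        if target is not None:
            exc, sol = normalize_power(model, exc, float(target), system=system)
        else:
            sol = system.solve(exc)
        sar = sar_from_field(sol.E, model)
        x_free = sol.V.transpose(2, 0, 1)[system._free_t]
        powers = system.electrode_powers(x_free, exc.voltages)
    else:
        raise KeyError(f"config key 'method' must be 'direct' or 'superposition', got {method!r}")
    return sar, exc, powers, system


def run_pipeline(cfg: dict, output_dir=None) -> dict:
    """Execute a full run from a configuration mapping; returns the metrics report."""
    out = Path(output_dir or cfg.get("output_dir", "thermoplan_out"))
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": cfg, "stages": {}}

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as err:
            raise RuntimeError(f"pipeline stage '{name}' failed: {err}") from err
        report["stages"][name] = {"wall_time_s": round(time.perf_counter() - t0, 3)}
        return result

    model = stage("phantom", lambda: build_phantom(cfg))
    sar, exc, powers, _ = stage("solve", lambda: solve_phantom(model, cfg))
    stage("export", lambda: tio.export_volume(sar.sar, model.grid, out / "sar.mhd", units="W/kg"))
    report["per_electrode_power_w"] = [float(p) for p in powers]
    report["electrode_amplitudes_v"] = [float(a) for a in exc.amplitudes]
    report["total_deposited_power_w"] = sar.total_power

    if "reference" in cfg:
        ref_cfg = {**cfg, **cfg["reference"]}
        ref_cfg.pop("reference", None)
        ref_model = stage("reference_phantom", lambda: build_phantom(ref_cfg))
        ref_sar, _, _, _ = stage("reference_solve", lambda: solve_phantom(ref_model, ref_cfg))
        excl = _conductor_exclusion(ref_model, model)
        gamma_sets = cfg.get("gamma", [{"dd_percent": 1.0, "dta_mm": 0.5},
                                       {"dd_percent": 2.0, "dta_mm": 2.0}])
        report["gamma"] = []
        for gs in gamma_sets:
            res = stage(
                f"gamma_{gs['dd_percent']}_{gs['dta_mm']}",
                lambda gs=gs: compare_sar(
                    ref_sar.sar, ref_model.grid, sar.sar, model.grid, model.voi,
                    GammaConfig(dd_percent=gs["dd_percent"], dta_mm=gs["dta_mm"]),
                    comparison_spacing=cfg.get("comparison_spacing", 0.25),
                    exclude=excl,
                ),
            )
            report["gamma"].append({
                "dd_percent": gs["dd_percent"], "dta_mm": gs["dta_mm"],
                "passing_rate": res.passing_rate,
                "accuracy_pct_max_sar": res.accuracy,
                "bias_pct_max_sar": res.bias,
            })

    if "thermal" in cfg:
        th = cfg["thermal"] or {}
        thermal = ThermalModel(duration=60.0 * float(th.get("minutes", 20)),
                               dt=float(th.get("dt", 1.0)))
        temp = stage("bioheat", lambda: solve_pennes(model, sar.sar, thermal))
        stage("export_temperature",
              lambda: tio.export_volume(temp.T, model.grid, out / "temperature.mhd", units="degC"))
        report["thermal"] = constraint_report(temp, {}, limits={"all tissue": 47.0})

    (out / "metrics.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def _conductor_exclusion(ref_model: VoxelModel, eval_model: VoxelModel):
    """Point-classifier excluding conductor-enclosed positions of either model."""

    def exclude(pts: np.ndarray) -> np.ndarray:
        mask = np.zeros(pts.shape[0], dtype=bool)
        for model in (ref_model, eval_model):
            for spec in model.applicators:
                if not spec.is_z_parallel():
                    continue
                tx, ty, tz = spec.tip_position
                sgn = 1.0 if spec.direction[2] > 0 else -1.0
                behind = sgn * (tz - pts[:, 2])
                inz = np.zeros(pts.shape[0], dtype=bool)
                for a, b in spec.electrode_spans():
                    inz |= (behind >= a) & (behind < b)
                if model.mode == "detailed":
                    r = spec.electrode_od / 2.0
                    trans = (pts[:, 0] - tx) ** 2 + (pts[:, 1] - ty) ** 2 <= r * r
                else:
                    h = spec.simplified_electrode_outer / 2.0
                    trans = (np.abs(pts[:, 0] - tx) <= h) & (np.abs(pts[:, 1] - ty) <= h)
                mask |= trans & inz
        return mask

    return exclude
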