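#!/usr/bin/env python
"""Example: exhaustive polarity search on a pre-computed field basis.

Demonstrates the plan-evaluation workflow enabled by superposition: the
per-electrode basis is solved once, after which every candidate setting is
scored without touching the solver.  Here the score is the fraction of the
volume of interest reaching at least 25% of the peak SAR (a crude coverage
surrogate); a real planner would optimise temperature-based objectives.

Usage:
    python scripts/plan_search_example.py
"""

import itertools

import numpy as np

from thermoplan.phantoms import homogeneous_benchmark
from thermoplan.solver import Excitation
from thermoplan.superposition import combine_fields, compute_basis, total_sar


def main() -> None:
    model = homogeneous_benchmark(n_applicators=2, mode="simplified")
    basis = compute_basis(model)
    voi = model.voi_mask()

    best = None
    for pol in itertools.product((1.0, -1.0), repeat=model.n_electrodes):
        exc = Excitation(np.full(model.n_electrodes, 13.0), np.array(pol))
        sar = total_sar(combine_fields(basis, exc), model)
        v = sar.sar[voi]
        coverage = float((v >= 0.25 * v.max()).mean())
        print(f"polarities {pol}: coverage {100 * coverage:5.2f} %, "
              f"total power {sar.total_power:.3f} W")
        if best is None or coverage > best[0]:
            best = (coverage, pol)
    print(f"\nbest polarity setting: {best[1]} ({100 * best[0]:.2f} % coverage)")


if __name__ == "__main__":
    main()
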