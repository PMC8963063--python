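# Full homogeneous benchmark: 18 applicators on a 9 mm lattice (4 rows of 5
# with the two upper-central positions empty), homogeneous muscle, simplified
# cuboid applicator model, every electrode normalised to 0.7 W input power.
phantom: homogeneous
n_applicators: 18
spacing: 9.0
mode: simplified
fine_step: 0.1
method: superposition
excitation:
  amplitude: 13.0
  normalize_power_w: 0.7
gamma:
  - {dd_percent: 1.0, dta_mm: 0.5}
  - {dd_percent: 2.0, dta_mm: 2.0}
output_dir: thermoplan_out
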