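# Methods

This note documents the models, numerical choices and their limits, in the
order the pipeline applies them.

## Electro-quasistatic model

At the 27 MHz operating frequency the free-space wavelength is ~11 m and the
in-tissue wavelength still exceeds a metre, two orders of magnitude above
the applicator dimensions, so displacement and conduction currents are
carried by a curl-free field: `E = -grad V` with
`div((sigma + j*omega*eps) grad V) = 0`.  Tissue admittivities at 27 MHz
come from the packaged material table (muscle `sigma = 0.654 S/m`,
`eps_r = 95.8`; prostate 0.838 / 120.1; fat 0.061 / 17.9; applicator
materials POM, Parylene C, air).  Copper parts are treated as perfect
conductors: electrode cells are Dirichlet equipotentials excluded from the
unknowns.  All six outer domain faces are grounded (V = 0); the domain
extends at least 10 mm beyond the volume of interest and every applicator,
where the field has decayed far enough that the choice of outer condition is
immaterial.

### Discretization

Cell-centred potentials on a non-uniform rectilinear grid; two-point flux
(finite-volume) faces with the series combination of half-cell admittances
(harmonic mean weighted by half-cell widths).  This is exact for 1D layered
media, which is the regime that matters: the dominant potential drop crosses
the thin coating radially.  Around each applicator the transverse step is
held at 0.02 mm (detailed cylindrical models) or 0.1 mm (simplified cuboid
models) and grows geometrically away from the applicators by a factor of at
most 1.2 up to 2 mm; the longitudinal step is a uniform 1 mm.  Graded gaps
are built by growing steps from both ends until the gap is covered and then
rescaling uniformly downward, so the growth bound is never exceeded.

### Thin layers on coarse cells: subcell mixing

The 30 um coating and the 30 um copper shell are thinner than any practical
cell.  Two measures keep the voxelised applicator faithful:

* the Dirichlet region of each electrode is the full conductor-enclosed
  cross-section (disc / box) over the electrode length, not just the shell
  cells — the interior of a perfect conductor carries no field, and marking
  only the 1-2-cell-thick shell leaves azimuthal gaps wherever the shell
  straddles cell boundaries, which would short the electrode into tissue at
  some angles;
* boundary cells cut by the material interfaces store their subcell volume
  fractions (5x5 stratified transverse sampling) and receive the harmonic
  (series) admittivity mix.  The series mix reproduces the true radial
  series impedance of the coating regardless of how the grid slices it;
  without it the local coating impedance is quantized to whole cells and
  the near-surface SAR acquires large spurious angular structure.  SAR in
  mixed cells uses `Re` of the mixed admittivity so dissipation stays
  consistent with the field the cell was solved with.

Majority vote over the same subsamples assigns the nominal material (used
for density and the thermal solve); the mixing refines only the electrical
admittivity.

### Linear solver

The Dirichlet data enter only the right-hand side, so one assembled
operator serves every excitation of a model.  Systems up to 60k unknowns
are factorised directly (sparse LU).  Larger systems (the detailed
references reach 4-8 million complex unknowns) use BiCGSTAB with a
two-level preconditioner: symmetric block Gauss-Seidel over z-planes — each
plane solved by a direct 2D factorisation, with identical planes sharing
one factorisation — around a coarse correction on plane averages that
removes the slow longitudinal error modes.  The plane solves address the
strong transverse coupling of 0.02 mm in-plane steps against the 1 mm
longitudinal step.  Convergence is verified against the true residual
(relative 1e-9, configurable) and failure raises.  Everything is
deterministic: repeated runs are bit-identical.

The 1e-9 residual tolerance is far below the ~1% discretization agreement
the gamma analysis probes; it is kept tight so that superposition identities
hold to 1e-8 and scaling identities to 1e-10 in tests.

### E-field, SAR, electrode power

Face current densities from the two-point flux are converted to the
cell-side E via the cell's own admittivity and averaged per cell (E = 0
inside conductors); SAR per cell is `sigma |E|^2 / (2 rho)` in W/kg.
Per-electrode input power is `0.5 Re(V conj(I))` with `I` the total complex
current through the faces bounding the electrode's Dirichlet region; on
resolved smooth cases electrode power and the volume integral of the
deposition agree to well under 2%, while cells hugging the thin coating
carry a few percent of local quadrature error (the cell-averaged |E|^2 under-
resolves the interface jump) — one reason validation uses gamma analysis
rather than raw voxel differences at the surface.

### Equal-power normalisation

Benchmarks drive every electrode at 0.7 W input power.  A fixed-point
iteration rescales amplitudes by `sqrt(P_target/P_e)` (tolerance 1%, the
drive starts at the 13 V reference).  Two accelerations matter for the big
reference solves: when the required rescale is uniform across electrodes
(symmetric phantoms) it is applied analytically by linearity without
re-solving; and re-solves warm-start the Krylov iteration from the rescaled
previous solution.  The detailed reference's normalisation also starts from
the simplified model's normalised amplitudes.

## Simplified applicator equivalence

The coating makes the electrode a capacitive current source into tissue;
preserving its capacitance preserves the exterior field.  The cylindrical
electrode (2.06 mm OD) and coating (2.12 mm OD) map to square shells of
equal lateral surface (`edge = pi*d/4`), and the shells are then thickened
to practical sizes — electrode edges 1.0 -> 1.4 mm, dielectric 1.4 -> 1.8 mm
— with the dielectric's permittivity adapted as
`eps' = eps * ln(a_o'/a_i')/ln(a_o/a_i)` so the layer capacitance is
unchanged (an exact algebraic identity, asserted to 1e-12).  For the
standard geometry `eps_r' = 21.01` (matching the capacitance of the
equal-surface cuboid shell; matching the cylindrical-layer capacitance
directly is available via `eps_prime_reference="coaxial"`, giving 33.0 —
the cuboid-to-cuboid route is the default because the thickening step
operates on the cuboid geometry).  The conductivity of the adapted
dielectric keeps the Parylene value; it is five orders below tissue
conductivity either way.

The simplified model holds on a 0.1 mm transverse grid whose cells align
exactly with the cuboid edges, needs no subcell mixing, and supports
arbitrary (non-axis-parallel) applicator axes; detailed cylindrical models
are restricted to z-parallel axes.

## Benchmark phantoms

Applicators sit on a 9 mm lattice (HDR-BT practice recommends <= 10 mm
catheter spacing).  The full homogeneous phantom has 18 applicators in 4
rows of 5 with the two upper-central positions empty (urethra location), in
uniform muscle; the volume of interest is the 54 x 43 x 54 mm box around
the active electrode lengths (lattice + 9 / 8 / 4.5 mm margins).  Reduced
phantoms keep the same lattice rules, margins and applicator geometry with
fewer applicators, because a fine-grid detailed-geometry reference solve of
the full 18-applicator model does not fit a desk-scale budget; validation
runs use 2 applicators (homogeneous) and 3 (heterogeneous).

The heterogeneous phantom adds, relative to the lattice: a first
inter-column gap 2 mm closer and a last 2 mm farther than 9 mm; a
transverse prostate-fat interface crossing all applicators within the
proximal electrode span; and a longitudinal prostate-fat interface through
the right-most applicator axis (that applicator sits midway on the
interface), with muscle surrounding the prostate/fat block.  Exact
row/column arrangements and interface planes are parameterized defaults,
reproducible from the configuration rather than asserted to match any
particular implant.

Phantom generation is deterministic and bit-identical across runs.

## Per-electrode superposition

Basis fields are solved with one electrode at the 13 V reference and the
rest grounded, in electrode order, reusing the assembled operator.
Combination weights are signed multiples of the reference voltage.  Because
both paths share the same linear operator, the superposed field matches a
direct multi-electrode solve to the solver tolerance (asserted < 1e-8
relative max-norm), hence identical SAR and gamma metrics — this is what
makes plan optimisation without re-solving exact rather than approximate.
Bases persist to HDF5 at full complex precision together with the
electrode-current couplings, so per-electrode input powers of any setting
are available without the solver.

## Gamma analysis

For each reference voxel in the VOI,
`Gamma^2 = (SAR_r - SAR_e)^2 / DD_abs^2 + ||r_r - r_e||^2 / DTA^2` is
minimised over evaluated positions within a search radius (default 3 DTA;
minima beyond it would need gamma > 3), with the evaluated volume
trilinearly resampled at a sub-voxel step (default DTA/3) and offsets
scanned in order of increasing distance with early termination.  DD is a
percentage of the global maximum reference SAR in the VOI (local
normalisation available).  A voxel passes at gamma <= 1; exact ties are a
measure-zero convention, configurable.  A brute-force whole-voxel mode with
no interpolation serves as the unambiguous oracle and is tested to match an
independent exhaustive search exactly.  Monotonicity in the criteria holds
at fixed search sampling; the defaults tie the sampling to DTA, so the
property is asserted with sampling pinned.

Reference (detailed, non-uniform) and evaluated (simplified) SAR volumes
are compared on a uniform 0.25 mm grid covering the VOI; conductor-enclosed
positions of either model are excluded.  Accuracy (mean absolute error) and
bias (mean error) are reported as % of the maximum reference SAR on the
same grid.

What the benchmarks show — and their limits: agreement between the two
*geometry representations* under identical physics, solver and
normalisation.  Residual disagreement concentrates within ~1.5 mm of the
applicator surfaces, where the cuboid's corner geometry genuinely differs
from the cylinder (diagonal shadowing) and where the reference's own
near-surface discretization is hardest; in tissue a few mm away the two
models agree to a few percent of the local value.  The phantoms do not
emulate patient anatomy (curved interfaces, non-parallel applicators,
organ-scale heterogeneity), so passing rates here bound the geometric
simplification error, not total planning error in a patient.

## Pennes bioheat solve

`rho c dT/dt = div(k grad T) - rho_b c_b w_v (T - T_b) + rho SAR`, with the
volumetric perfusion rate `w_v = perfusion * rho_tissue * 1e-6 / 60` (the
table lists mL/kg/min).  Blood parameters default to
`rho_b = 1050 kg/m^3`, `c_b = 3617 J/kg/K`, `T_b = 37 C` (standard
literature values, configurable).  Implicit Euler with dt = 1 s and a
single factorisation of the constant system matrix; Dirichlet baseline
(37 C) on the domain faces, weakly influential at the >= 10 mm margin.
Applicator materials conduct with their tabulated thermal properties, zero
perfusion, and no SAR inside conductors; thermal subcell mixing is not
applied (boundary-cell thermal conductivity uses the majority material).
The default heating time is 20 min.  Uniform-SAR tests recover the analytic
perfusion balance `dT = rho*SAR/(rho_b c_b w_v)` within 2%, the maximum
principle, linearity in the source, and near-steady insensitivity to the
time step.  The clinical constraint report checks per-region maxima against
47 C (any tissue) and 43.5 / 42.5 / 41.5 C (urethra / bladder / rectum).

## Problem sizes and runtimes

The validation workflow solves, per phantom, one simplified model
(~0.4-0.6 M cells, seconds per solve) and one detailed reference (2
applicators: ~4.5 M cells; 3 applicators: ~8 M cells; a few minutes per
solve with the plane-block preconditioner, ~4 GB peak memory).  The
reduced applicator counts were chosen so a complete two-phantom validation,
including gamma analysis, runs in roughly a quarter of an hour on one CPU
core.
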