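# Methods

## Transport model

The chip cross-section is modelled in 1D as four regions in series: source
media channel (500 µm), collagen gel (1000 µm, porosity φ = 0.8), endothelial
barrier (2 µm), and vessel media channel (1000 µm); channel height 250 µm
(vessel width:height ≈ 4:1) does not enter the 1D balance. The governing
equation is diluted-species transport in porous media,

    φ(x) ∂C/∂t = ∂/∂x ( D(x) ∂C/∂x ),

with φ = 1 and D_channel = 4.0×10⁻¹¹ m²/s in the channels (a free-solution
value for a ~70 kDa solute; configurable), D_gel = 3.0×10⁻¹¹ m²/s in the
gel used directly as the effective diffusivity (no extra tortuosity
correction, since the gel value is itself an effective measurement), and
the endothelial barrier as either

- a resolved 2 µm layer with D_b = K·P·x₀ = 7.4×10⁻¹⁴ m²/s (K = 1,
  paracellular transport only), or
- an interface flux condition J = P·(C_gel − C_vessel) with
  P = 3.70×10⁻⁸ m/s.

The two are algebraically equivalent for a passive layer; the test suite
checks they agree on the vessel filling within 5% (measured: <1%).

**Discretization.** Cell-centred finite volumes with harmonic-mean face
conductances (this composes half-cell resistances in series, so a resolved
barrier reproduces exactly the membrane conductance P between the adjacent
cell centres). Time stepping is implicit — backward Euler by default,
Crank–Nicolson optional — with dt = 10 s and dx = 1 µm by default; halving
both moves the 4 h vessel mean by <0.5%. Outer boundaries are no-flux. The
matrix is prefactorized (sparse LU) once, so the full 12 h solve takes
about a second. Backward Euler on a diffusion operator is an M-matrix
scheme, hence unconditionally stable and positivity-preserving;
porosity-weighted total mass is audited at every stored time and a relative
drift above 10⁻³ raises a numerical-failure error (direct solves stay at
machine precision, ~10⁻¹¹).

**Source treatment.** The source channel is a finite well-mixed reservoir:
it starts at C₀ = 10 µg/mL (1.4286×10⁻⁴ mol/m³ at 70 kDa) and is
homogenised every step, with no replenishment. This matches the observed
behaviour that the gel concentration plateaus below the dose. A maintained
(Dirichlet) mode — implemented as identity rows in the implicit matrices so
held cells supply flux at full concentration — and a plain diffusive mode
are config options. Concentrations are stored in µg/mL (= g/m³); the
diffusion problem is linear, so unit conversion is a scale factor and
round-trips exactly.

**Verification oracles.** Three closed forms anchor the solver: (i) a
uniform field with no-flux boundaries is a steady state; (ii) a maintained
source at the end of a barrier-free gel approaches C₀·erfc(x/2√(Dt))
(agreement ≤2% of C₀ at interior nodes); (iii) two well-mixed compartments
across a membrane lose their concentration difference as
exp(−t·P·(1/V₁+1/V₂)) (decay constant within 2%).

**Known limitation — absolute vessel concentration.** With these parameters
the gel Biot number is Bi = P·L_gel/D_gel ≈ 1.2. In a 1D cross-section this
couples three observables: a vessel held far below the gel concentration
requires a sustained barrier flux, which in turn sustains a gel-internal
gradient of order Bi·C. A full 3D chip geometry decouples them: solute
entering the vessel channel also spreads along the channel axis and into
reservoir necks, diluting the local vessel concentration without touching
the gel profile. The 1D default therefore reproduces the shape of the
published behaviour — monotone, near-linear vessel filling; a pronounced
concentration drop across the barrier; a gel profile whose relative range
(max−min)/mean shrinks monotonically (0.55 → 0.33 → 0.23 over 4 → 8 → 12 h)
— but its absolute 4 h vessel mean (≈0.50 µg/mL) is several-fold above the
value a 3D geometry with reservoirs yields. Modelling the reservoirs and
the along-channel dimension is deliberately out of scope; the geometry is
fully config-overridable for users with measured chip dimensions.

## Synthetic imagery

The generator emulates the structure the quantification procedure depends
on, not confocal optics: no point-spread function, photobleaching, or 3D
cell morphology. Fields are 8-bit, 1024×1024 at 0.5 µm/px with 5 z-slices
by default (512×512, 3 slices in tests for speed); signals are spread
through z with a focus-weighted profile whose peak slice carries the full
amplitude, so the maximum-intensity projection recovers the planted 2D
scene while the average projection differs (exercising both projection
paths; deliberately saturating actin "stress fibers" motivate the average
option).

**Endothelium.** A Voronoi tessellation of uniformly seeded points
(350 cells per 1024² field ≈ 26 µm cell diameter); junctions are the
tessellation edges dilated to ~5 px (2.5 µm); a 2% cell-free fraction
mimics monolayer gaps. Nuclei are one ellipse (8–12 µm) per cell.

**Background noise.** Per-slice exponential gray levels calibrated so the
*projected* marker background has a 99th percentile equal to the configured
target (the quantity the top-1% dummy rule thresholds): the per-slice scale
is q99 / −ln(1 − (1 − 0.99^(1/n_z))). Targets 9 and 14 reproduce the
published ICAM-1 and VE-cadherin exclusions (thresholds 10 and 15).

**Planted marker signal.** Positive pixels are the top round(f·|cell
area|) pixels of a Gaussian-smoothed random field restricted to the
admissible region (coherent patches, exact planted count); amplitudes are
drawn strictly above the noise floor, so the planted fraction is
recoverable by construction. For junction stacks the admissible region is
the edge network, and the unclaimed junction pixels are rendered as actin
(neighbouring cells close the contact where junctional staining retracts),
which makes the denominator of the VE-cadherin ratio — cell area ∪ VE⁺ —
equal to the monolayer footprint for both truth and measurement. The
achievable junction ratio is bounded by the network area; exceeding it
raises an error stating the maximum.

**THP-1 scenes.** Tracker-labelled disks (radius 10 px = 5 µm) on integer
centres — so a blob's extreme pixel is exactly r pixels from its centre —
placed by rejection sampling without overlap: `n_adhered` wholly on the
channel side of the wall line, one blob per requested migration distance
with its closest pixel at wall + d (±0.5 px after rounding).

**Calibration table.** Per-condition defaults (normal / LPS 4 h / 8 h /
12 h) use the study's reported condition means as generator set-points and
SEM·√n as the between-image spread; migration distances are gamma with the
matched mean and spread. These are inputs, not measurements: recovery tests
show the pipeline returns what was planted, which says nothing about real
confocal data (illumination gradients, out-of-focus haze, segmentation
errors on real morphology are all absent). Scene counts are per default
field; the pipeline scales the ~10³ adhered cells per device by 1/20 (and
by field area) because they cannot be packed without overlap into a single
field of view — count *recovery* is exact regardless of magnitude, which is
what is being validated.

## Quantification choices

- **Threshold rule.** T = smallest integer with pooled fraction of dummy
  pixels ≥ T at most 1%; "intensity more than 9" and "10–255" are the same
  rule at T = 10. An all-zero dummy gives T = 1. Adding brighter pixels to
  the dummy pool can only raise T (monotonicity is property-tested). The
  rule admits up to 1% of background pixels as signal; on synthetic fields
  this appears as a ≤0.7 pp positive offset in area ratios, within the
  ±1 pp recovery tolerance and inherent to the published procedure.
- **Cell-area mask.** Otsu on average-projected actin ∪ dilated Otsu
  nucleus mask, closing, speck removal, hole filling. On a confluent
  monolayer Otsu has no background class to find and splits inside the
  cells; the implementation detects this (the "background" side of the
  split still looks signal-like, mean > 0.25× foreground) and falls back to
  the dummy-derived noise floor. Validated against truth masks
  (Jaccard ≥ 0.9; measured ≈0.99), not against the study.
- **VE-cadherin denominator.** "Cell area + VE-cadherin area" is read as
  the union (bounded by 100%, no double counting); a strict-sum mode is
  available behind a flag for sensitivity analysis.
- **THP-1.** Tracker threshold by the same top-1% rule from tracker-free
  stacks; components with ≥20 px (8-connectivity) after a 1 px opening
  (speckle otherwise attaches to silhouettes and perturbs closest-pixel
  distances). The wall is a vertical line x = x_wall (0-based pixels, gel
  side x > x_wall, from the truth sidecar or config); a cell with any pixel
  strictly on the gel side is transmigrated, distance = pixel size × min
  gel-side (x − x_wall) — for a straight wall, perpendicular and
  nearest-point distances coincide. Touching blobs merge into one
  component; this undercounting is a documented limitation, excluded from
  the exactness guarantee (which covers non-overlapping cells).
- **Sampling unit.** The image (n = images per condition, matching the
  "3 images × 3 devices" design); per-image denominators, not pooled.
  Device-level aggregation can be done on the tidy records CSV.

## Statistics

Mean ± SEM with sample (n−1) standard deviation; SEM undefined (NaN) at
n = 1. "Student's t-test" is read classically: two-sided, unpaired, pooled
variance (Welch behind a flag), p from the t distribution;
an independent reference implementation must agree to 10⁻¹⁰ in tests. Tier
maps are per-figure because the published captions use different
star-to-cutoff conventions (one panel's stars start at p < 10⁻⁴); they are
implemented verbatim as named maps, most stringent satisfied cutoff wins,
"n.s." otherwise. No multiple-testing correction is applied, matching the
reporting being mirrored.

## Reproducibility

All randomness flows from `numpy.random.default_rng` seeds; stage seeds are
derived from the run seed by hashing stage/condition/index tags (stable,
<2³¹). Identical seed + config give bit-identical stacks and CSVs (hash
equality is tested). The transport stage has no randomness at all.
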