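# Methods

## The vorticity metric

A transect through the channel is discretised on a structured cell-centered
grid in the cross-flow plane: y transverse (m, left bank at 0, facing
downstream), z vertical (m, positive upward from the channel invert). Each
cell carries the in-plane velocity components v_y, v_z (m/s) and a wet/dry
flag; the bed elevation z_bed(y) is stored per column.

The streamwise vorticity of a cell is the magnitude of the discrete curl,

    Omega = | dv_z/dy - dv_y/dz |        [1/s]

with one-sided differences: dv_z/dy toward the right neighbour, dv_y/dz
toward the cell above. Where that neighbour is dry or absent the opposite
one-sided difference is substituted, and where neither neighbour is wet the
derivative is zero for that cell. This keeps every wet cell defined while
using only wet-cell velocities; finite differences are exact on linear
fields, so solid-body rotation is recovered exactly, boundaries included,
and on smooth fields the scheme is first-order accurate (observed order
1.0 on an h, h/2, h/4 refinement ladder against the analytic curl).

The magnitude is taken per cell *before* averaging, so counter-rotating
eddies do not cancel. The cross-sectional mean is the area-weighted average
over the wetted section,

    mean = Gamma / A_TOT = sum(Omega dA) / sum(dA),

with dA = dy*dz per cell (uniform grid), Gamma the circulation and A_TOT
the wetted area.

### Section summaries

Summaries are reported for two layers — the full section and the near-bed
layer from the bed to 1.3 m above it, where high-intensity vorticity
concentrates in natural spawning sections — and for three transverse bands.
Layer membership is by cell center (z_bed <= z <= z_bed + height), a simple
and resolution-consistent rule; the bottom-most wet cell of each column is
always included so the layer degenerates to the near-bed row, never the
empty set, as the height shrinks below the cell size.

The wetted top width is split into three equal-width bands (left / middle /
right facing downstream) and cells are assigned by y center. No published
definition of the band geometry exists, so equal thirds is this package's
documented choice. The section "mean" is the **unweighted average of the
three band means** — this rule reproduces the published reference tables
cell-for-cell at five decimals — and the area-weighted whole-section mean
is exposed separately (`area_weighted_mean`) because the two do not
coincide when band areas differ. A band with no wet cells is reported as
missing, excluded from the average, and warned about.

## The synthetic flow generator

Field velocimetry of natural vortices is impractical and the original flow
fields came from a terrain-specific two-phase CFD model, so the package
generates cross-sections with *known* vorticity content:

- **Bed profiles.** `compound` (trapezoidal main channel flanked by berm
  shelves — the spawning-section shape), `vee` (the non-spawning shape) and
  `flat`. Parameters are the total width, maximum depth, and dimensionless
  berm-width, berm-height and side-slope fractions. Closed-form wetted
  areas are available for validating the discretisation.
- **Vortices.** Lamb–Oseen by default: tangential speed
  v_theta(r) = Gamma/(2 pi r) (1 - exp(-r^2/r_c^2)) with the finite-core
  limit at r = 0, and exact curl omega(r) = Gamma/(pi r_c^2)
  exp(-r^2/r_c^2). The model is smooth everywhere, which keeps convergence
  tests clean; Rankine (solid-body core, irrotational exterior) is retained
  as an option but its core-edge curl discontinuity makes it unsuitable for
  refinement studies.
- **Background floor.** Post-processed transects of the reference study
  report ~0.100 1/s in non-spawning sections rather than zero. The
  generator emulates this with a uniform vertical shear in v_y whose curl
  equals the floor rate exactly; the floor value is a scenario-template
  constant (0.10 1/s; 0.098 1/s in the non-spawning template so that weak
  vortices can be calibrated up to exactly 0.10).
- **Noise.** Seeded isotropic Gaussian noise on both components, applied
  after superposition; default sd 0 m/s. Dry cells always keep zero
  velocity. The exact-curl oracle is only defined for noise-free scenarios
  and refuses otherwise.

### Scenario templates and calibration

Scenario labels fix the study conditions:

| label       | bed      | width x depth, surface | vortices               | floor  | target mean |
|-------------|----------|------------------------|------------------------|--------|-------------|
| spawning    | compound | 30 m x 2.2 m, 1.8 m    | 5, near-bed, mid-channel heavy | 0.10  | 0.26 1/s |
| transition  | compound (low berms) | 34 m x 2.6 m, 2.2 m | 3, weaker     | 0.10  | 0.17 1/s |
| nonspawning | vee      | 40 m x 3.2 m, 2.6 m    | 2, faint               | 0.098 | 0.10 1/s |

Widths and depths are typical of the mountain-river reach the scenarios
emulate (tens of metres wide, a few metres deep); spawning vortex centers
are jittered by the seed but always placed within 1.3 m of the local bed,
mirroring where high-intensity vorticity is observed, and the strongest
vortices sit mid-channel so the transverse distribution is middle-heavy.
Default grids are 60 x 36 cells (0.5 m x ~0.06 m cells), enough to resolve
vortex cores of 0.3–0.5 m while keeping a full pipeline run under a second.

`calibrate_spec` scales all vortex circulations by one common multiplier,
found by bracketing + Brent root-finding on the measured cross-sectional
mean, until it is within a relative tolerance (default 0.1%) of the target.
Because all vorticity contributions are positive the measured mean is
monotone in the multiplier and the root is unique; a target below the
background floor is reported as unreachable rather than silently clipped.
`generate_scenario` applies the calibration per label, with per-label
default targets (table above) matching the section means observed in
natural reaches; the demo reach uses per-section targets 0.26/0.30/0.23
(spawning), 0.177/0.157 (transition) and 0.10 (non-spawning).

Determinism: a scenario (including its seed) reproduces its grids bit for
bit. The pipeline fans one global seed into per-section sub-seeds through
`numpy.random.SeedSequence(entropy=[seed, index])`, so appending a section
never perturbs existing ones, and grid CSVs are written with `%.17g` and
read with round-trip float parsing so a write/read cycle is bit-exact.

### What the generator does and does not emulate

It reproduces the *statistical structure* relevant to the metrics: bed
shapes, wetted geometry, a vorticity floor, coherent near-bed vortices of
controlled total strength, and optional measurement-like noise. It does not
emulate turbulence spectra, secondary currents, streamwise variation, a
deforming free surface, sediment or temperature. Passing tests therefore
validate the *metrics, statistics and scoring pipeline* — not any claim
that real transects look like these fields.

## The rank-sum comparison

Cell-level vorticity values (cells, not section means) are pooled per group
and compared with the Wilcoxon rank-sum statistic: mid-ranks for ties, W =
rank sum of the non-spawning group, and

    Z = (W - n2 (N+1)/2) / sqrt( n1 n2 / 12 * ( (N+1) - sum(t^3 - t) / (N (N-1)) ) )

with the standard tie-corrected variance (the discretised floor guarantees
ties, so the correction matters). The default decision rule is
**lower-tailed at alpha = 0.05** (reject when Z < -1.645): the scientific
expectation is directional — spawning sections should carry more vorticity —
and this is the decision rule used in the reference analysis, although its
hypotheses are written two-sided; both modes are exposed and the report
records which was used. No continuity correction by default (an optional
flag). All pooled values identical is a degenerate input and raises.

For pooled sizes up to 12 an exact oracle enumerates every C(N, n2)
assignment of the pooled mid-ranks and returns the lower-tail probability
P(W' <= W); `compare_groups` attaches it and lets it drive the decision
when available. Validation compares the normal lower-tail p with the exact
**mid-p** (P(W' < W) + P(W' = W)/2), the continuity-matched quantity: for
every achievable rank sum at every size with both groups >= 2 and N <= 10
the discrepancy is at most 0.031. With a group of size 1 the normal
approximation is irreparably coarse (the discrepancy reaches 0.34 at
n1 = n2 = 1) — a structural limit of the approximation, not of the
implementation; use the exact oracle there. Under the null (both groups
drawn from one non-spawning scenario with independent noise seeds) the
empirical one-sided rejection rate over 2,000 replicates is ~4–5%,
within two points of the nominal 5% despite the mild spatial correlation
that differencing shared noise induces between neighbouring cells.

## The vague-set similarity model

A vague set assigns each element a support degree t and an opposition
degree f, represented as the interval [t, 1-f] with hesitation
pi = 1 - t - f. A reach's mean vorticity x is mapped to (t, 1-f) by a
piecewise-linear family anchored on the suitable interval [0.17, 0.35] 1/s
and boundary interval [0.02, 1.0] 1/s (breakpoints 0.02, 0.2, 0.35, 1.0):

    x <= 0.02 :  (0, 0)
    0.02<x<0.2:  t = (x-0.02)/0.33,  1-f = (x-0.02)/0.18
    0.2<=x<0.35: t = (x-0.02)/0.33,  1-f = (1-x)/0.9
    0.35<=x<1 :  t = (1-x)/0.8,      1-f = (1-x)/0.65
    x >= 1    :  (0, 0)

Two deliberate fidelity choices: (1) the 1 - 0.1 denominator of the third
branch is kept exactly as published even though the 0.1 anchor appears in
no other constant (plausibly a slip for 1 - 0.2) — including its jump
discontinuities of 1-f at x = 0.2 and 0.35; (2) on x in ~(0.283, 0.35) the
family violates the vague condition t <= 1-f. The violation is preserved
and surfaced (`vague_condition_violated`, negative hesitation); clamping
t to 1-f is available behind an explicit `clamp=True`, off by default.
Only one family is published — defined for the natural reference — so the
restored reach is evaluated with the same family, and a single shared set
of interval anchors (overridable in config) is used for both reaches.

Similarity, classification and effectiveness:

    SIM = 1 - |dt - df|/4 - (|dt| + |df|)/4,   dt = t_A - t_B, df = f_A - f_B

SIM is symmetric, bounded in [0, 1], and 1 exactly when the vague values
coincide. Classes are left-closed bands [0,0.15) Extremely low,
[0.15,0.35) Lower, [0.35,0.65) Low, [0.65,0.75) General, [0.75,1.00] Good.
The restoration rate R = (SIM_after - SIM_prev)/SIM_prev x 100% is
*effective* only when strictly greater than 5% (an exactly-5% rise is not
effective; the comparison is guarded against float round-off at 1e-9).

## Numerical and design notes

- Wet cells are those whose center lies at or above the bed and below the
  surface; the discrete wetted area converges to the closed-form bed-profile
  area at first order in the cell size.
- Calibration: Brent's method with xtol = rtol = 1e-12 on the multiplier,
  bracket capped at 2^20; relative tolerance must be positive (a zero
  tolerance is rejected rather than iterated forever).
- Report formatting: summary CSV cells are fixed at five decimals, making
  golden-file comparisons byte-stable; reruns of a config (or of its echo
  embedded in a report) are bit-identical.
- Problem sizes: default scenario grids 60 x 36; discretization ladder
  16/32/64 on a unit section; 2,000 replicates (8 x 8 grids, ~26 wet cells
  per group) for the null rejection rate; 1,000 random points for the
  membership re-derivation. These sizes make the full suite and the
  reproduction script run in seconds while leaving every check
  well-resolved.

## Known limitations

- The Eq.-style one-sided stencil is first-order; no higher-order or
  centered scheme is offered because the summaries target parity with the
  reference post-processing, not maximal accuracy.
- The band split (equal thirds of wetted top width) and the layer rule
  (cell-center membership) are this package's documented conventions;
  other conventions would shift band values slightly.
- The published group rank summary of the reference analysis is internally
  inconsistent (its group mean ranks cannot average to the pooled mean rank
  and no standard rank-sum formula yields its Z from them); this package
  implements the standard statistic and makes no attempt to reproduce those
  printed values.
- Absolute vorticity values of real terrain cannot be recomputed here:
  they depend on surveyed bathymetry and a two-phase CFD solver, both out
  of scope. The synthetic scenarios are calibrated to the *reported* means
  instead.
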