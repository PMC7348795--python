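# Methods

This note records the models the package implements, the defaults and why,
what the synthetic generator does and does not emulate, and the numerical
and design choices made where more than one reasonable option existed.

## Transport model

Both assay platforms reduce to one transport axis. Ligand concentration
C(x, t) obeys

    ∂C/∂t + ū ∂C/∂x = D ∂²C/∂x²

on the channel (microfluidic device) or membrane (transwell), with the bulk
velocity ū defaulting to 0: the assays impose no flow — reagents are loaded
and left to transport passively — but the advective term is implemented and
exposed because pressure- or perfusion-driven variants of these devices
exist. Advection is upwinded, so ū > 0 transports source → sink.

### Geometry reduction

The reservoirs (98 µL each in the microfluidic device; 100 µL top / 600 µL
bottom in the transwell) are modelled as well-mixed 0-D compartments coupled
to the 1-D domain by flux continuity at its ends. This is justified by the
volume ratio: the default microchannel holds 0.48 µL, about 0.5% of a
reservoir, so intra-reservoir gradients relax much faster than they can be
fed by the channel. A `boundary_mode="fixed"` option clamps the reservoir
concentrations instead (an infinite-reservoir idealisation); the finite,
mass-conserving mode is the default. The device specifies only a hydraulic
diameter (192.6 µm), not a cross-section shape; a square of side D_H is
assumed and the area is configurable for other aspect ratios.

The transwell membrane (10 µm thick, 8 µm pores, default 1×10⁵ pores/cm²
giving porosity ε ≈ 0.05, membrane area 0.33 cm² as in 24-well inserts) is
treated as a quasi-1-D porous layer. The model tracks the pore-liquid
concentration with flux D·(A·ε/τ_t)·∂C/∂x — equivalently an effective
diffusivity D_eff = D·ε/τ_t referred to total membrane area — with
tortuosity τ_t defaulting to 1 for straight track-etched pores. Compartment
volumes and pore density are not fixed by the membrane part number alone and
are configurable.

### Numerics

Space: conservative finite volume, cell-centred, with half-cell faces
coupling the end cells to the compartments; volume-weighted columns of the
system matrix sum to zero, so spatial mass conservation is exact by
construction. Default 130 cells for the 1.3 cm channel (100 µm resolution)
and 20 cells across the 10 µm membrane; halving the spacing moves the
solution by well under 1% of C₀ (sup-norm), which is the tested convergence
criterion.

Time: the semi-discrete system is linear, y′ = M y, and small (≈130
unknowns), so it is advanced exactly with the dense matrix exponential,
cached per distinct output interval. This sidesteps the stiffness of the
compartment/channel time-scale split (the membrane relaxes in ~20 s while
the compartments equilibrate over hours) and keeps the total-mass drift at
rounding level, ~10⁻¹³ relative, against the 10⁻⁶ tolerance asserted in
tests. Negative concentrations beyond −10⁻⁹·C₀ raise a numerical error
advising grid refinement; values inside that tolerance are clipped to zero
on output.

Units: the interface speaks the laboratory's units (µL, cm, µm, ng/mL,
hours); everything is converted to cm/s/cm³ internally (1 ng/mL = 1 ng/cm³)
and converted back on output. Positions originate at the source-side end of
the domain, +x toward the sink (the top compartment, for the transwell,
where ligand is loaded below).

### Validation oracles

Two closed forms pin the solver down in the tests and acceptance script:

* early times in the channel, before the far end is reached, follow the
  semi-infinite solution C = C₀·erfc(x/2√(Dt)); agreement is required to 2%
  wherever C/C₀ > 0.05 (measured ≈ 0.2% at default resolution, t = 2 h);
* the transwell compartment difference decays as exp(−t/τ) with
  τ = (V_t·V_b/(V_t+V_b))·Th/(D_eff·A) once the membrane is quasi-steady;
  the fitted constant must be within 5% (measured ≈ 0.004%).

Equilibrium is checked against the global mass/volume ratio at ten times the
slowest analytic time constant; for the default microfluidic geometry the
equilibrium concentration is C₀·V_src/(V_src+V_sink+V_chan) ≈ 0.499·C₀.

### Steady-state detection

`steady_state_time` returns the earliest output time at which the maximum
relative change of the field over a following window falls below a
threshold (default 5%). The relative change is evaluated only where
C/C₀ > 0.01 (configurable floor), because in the far channel near-zero
concentrations make relative change a 0/0 amplifier. Where and over what
window such a criterion is measured is an experimental convention, not a
property of the model; both are therefore explicit arguments and no
particular "time to steady state" is claimed for the default geometry. The
returned value is checked against the closed-form inversion
t* = τ·ln((a+θ)/θ), a = 1−e^(−w/τ), on the two-compartment system.

## Migration quantification

Path length is the accumulated inter-frame distance (13 frames at 30-min
spacing over 6 h; 12 intervals); net displacement is first-to-last distance.
Motility is path length strictly greater than 20 µm — the wording defining
the threshold is "greater than", so equality at 20.0 µm is non-motile — with
an optional switch to threshold net displacement instead for sensitivity
analysis. SDs use the n−1 sample denominator. Trajectories must start at
t = 0 (cells appearing later are rejected at ingestion, with a logged count,
to exclude cells born or arrived mid-recording); shorter-than-full tracks
are analysed over their available frames and flagged incomplete.

Per-condition path-length summaries can be restricted to motile cells (the
reporting convention for the published per-condition figures) or taken over
all tracked cells. Both modes are emitted by the reproduction pipeline
because the two disagree strongly for weakly motile cohorts: a cohort with
mean PL 14 µm and a 20 µm motility floor has a motile-only mean well above
its all-cell mean, and published control-condition numbers cannot satisfy
both conventions at once. The generator calibrates to all-cell moments (see
below) and the summaries expose the discrepancy rather than resolve it.

Transwell data carry only per-device counts of membrane-crossing cells;
summaries are mean ± SD over devices and fold change = condition mean /
control mean (undefined and flagged when the control mean is zero). A
motile *fraction* cannot be computed on this platform since non-crossing
cells are not counted.

## ΔΔCT expression analysis

ΔCT = mean CT(gene) − mean CT(reference) within a condition, replicates
averaged before differencing (mean-of-CT convention; the alternative —
per-replicate ΔCTs averaged afterwards — differs only for unbalanced
replication). Fold change = 2^−(ΔCT_treated − ΔCT_control), assuming exact
doubling per cycle; no amplification-efficiency correction is applied. The
module is gene-label agnostic: any reference gene and any receptor labels
may be used, and requested (condition, gene) pairs missing from the table
are reported together. CT values outside (0, 45) are rejected as
physically implausible for a 40-cycle protocol.

## Gated statistics

Normality gate: every group is Shapiro–Wilk tested at α = 0.05; any failure
routes the whole comparison non-parametric. The aggregation rule (any-fail)
is the conservative choice where a per-dataset convention is not stated.
Constant groups cannot be tested and route non-parametric with a warning.

Parametric branch: one-way ANOVA, Tukey HSD all-pairs post-hoc (Tukey's own
familywise control, no further adjustment). Non-parametric branch:
Kruskal–Wallis omnibus (scipy, cross-checked in tests against a
first-principles mid-rank computation on exhaustive small instances), then
Dunn's z tests on pooled mid-ranks with tie correction — implemented
in-package — and Holm step-down over the all-pairs family. Flags: `**` for
p < 0.01, `*` for p < 0.05, `ns` otherwise, applied to adjusted p-values.
An explicit `branch=` override exists for analyses where the branch was
fixed a priori. The procedure's null calibration (type-I error within
[0.03, 0.07] at α = 0.05 over 1000 seeded simulations) is part of the test
suite; published p-values from live-cell data are not reproduction targets,
since they depend on the unpublished raw recordings.

## Synthetic-data generator

### Trajectory model and calibration

Each cell takes n steps of displacement (drift, 0) + isotropic Gaussian
noise of SD σ per axis, so the step length is Rice(ν=drift, σ) and the path
length — the sum of n iid step lengths — has mean n·E[r] and variance
n·Var[r] in closed form. This is the simplest family with closed-form
path-length moments, but it has a hard ceiling: the Rice step-length CV is
at most √(4/π − 1), so an n-step path length cannot exceed CV
√((4/π−1)/n) ≈ 0.151 at n = 12. Measured cohorts are wider than that (CV
0.12–0.40 across the five conditions), which real cohorts achieve through
cell-to-cell variability. The generator therefore adds a per-cell speed
multiplier s ~ Gamma(mean 1, SD τ) scaling both drift and noise, giving
Var[PL] = (1+τ²)·n·Var[r] + τ²·(n·E[r])².

`calibrate_walk` inverts the target (mean, SD): if the pair is reachable by
the homogeneous family it solves the drift-to-noise ratio k by root-finding
on the Rice moment ratio (τ = 0); otherwise it fixes k at a configurable
default (1.0 — comparable directed and random motion) and assigns the excess
variance to τ. The Rice mean uses scipy's Laguerre form, switching to the
asymptotic √(k²+1) above k = 30 where the Laguerre evaluation overflows;
tests verify the moments against direct quadrature of the Rice density.
With `allow_heterogeneity=False`, unreachable targets raise an error stating
the feasible SD bound. Calibration targets are all-cell moments, not
motile-only ones: calibrating to a motile-only mean under a threshold would
require inverting a truncated distribution and, for weakly motile cohorts,
has no solution consistent with the published motile fractions.

Start positions are uniform over a configurable window (default a 500 µm
square, mirroring seeding near the sink end of the channel). Optional
gradient coupling replaces the constant drift with sensitivity × (−∂C/∂x)
sampled from a simulated concentration profile at the cell's current
position and elapsed time, giving walks that climb the gradient with
position-dependent bias; only the monotone dependence of displacement on
sensitivity is asserted, since no measured chemotactic sensitivity exists
to calibrate against.

What the generator does **not** emulate: persistence/autocorrelation of
real cell motion, contact interactions, proliferation and death, drift of
the imaging frame, and any coupling between a cell's speed and its
directionality. Passing the round-trip tests therefore shows the *analysis
chain* is correct and the calibration self-consistent — not that the walk
is a mechanistic model of glial migration.

### CT tables and counts

CT tables place the reference gene at CT 18 and control-condition targets at
CT 25 (both configurable), shift treated-condition targets by −log₂(fold),
and add independent Gaussian noise per replicate (SD 0 by default, so the
ΔΔCT analysis recovers the target matrix exactly; noisy tables recover it
in expectation, verified within 3 SE over 100 seeded tables). Transwell
counts are Gaussian draws rounded to integers and truncated at zero; for
the published condition means (≥ 2.8 SDs above zero) the truncation bias is
negligible.

All generators take an explicit integer seed and are bit-reproducible; the
reproduction pipeline derives per-condition, per-device sub-seeds by fixed
offsets so bundles are deterministic end to end.

## Problem sizes

Defaults reflect the experimental design: 15 cells per device cohort, 6
devices per condition (the design used 10–15 cells and 5–7 devices), 12
steps of 30 min, triplicate CT replicates, 6-device count experiments. The
round-trip acceptance checks average 200 seeded cohorts (3000 cells per
condition) and 200 count experiments, and the null calibration uses 1000
simulated comparisons — sizes chosen so Monte-Carlo error is several times
smaller than the asserted tolerances (e.g. SE of a cohort-mean estimate
≈ 0.1 µm against a 2% ≈ 0.3 µm tolerance at the control condition).

## Known limitations

* The transport model is 1-D plus compartments; entrance effects at the
  reservoir–channel junctions and any 2-D structure in the reservoirs are
  outside its scope, as are ligand uptake/degradation by cells and binding
  to device surfaces.
* The transwell compartment volumes, pore density and membrane area are
  manufacturer-typical defaults, not measured values; the equilibration
  time constant scales directly with them.
* The Dunn implementation uses the normal approximation; exact small-sample
  Dunn p-values are not provided.
* The motile-only vs all-cells summary ambiguity for weakly motile cohorts
  is surfaced, not resolved (both modes are reported).
* Directionality of motion is not quantified beyond net displacement along
  the gradient axis; no directionality statistic is claimed.
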