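# Methods

This note documents the model semantics, numerical choices, default
parameters, and the design decisions behind `cellgrammar`, together with
what the synthetic-data generators do and do not emulate.

## Rule grammar and response mathematics

A rule is the statement "In cell type T, signal S increases/decreases
behavior B", stored as one CSV row with a saturation value, half-max, Hill
power, and a dead-cell applicability flag. Three response-curve forms are
supported:

* **Hill** (default): R(s) = (s/s\*)^p / (1 + (s/s\*)^p). Strictly
  increasing, R(0) = 0, R(s\*) = ½, R < 1. Evaluation switches to log space
  when (s/s\*)^p would exceed 10³⁰⁰, so large powers at large signals cannot
  overflow; the output is additionally capped at the largest double below 1
  so the open upper bound survives floating-point rounding.
* **Capped linear**: R(s) = min(s/(2s\*), 1 − 10⁻⁹). The 2s\* slope makes
  R(s\*) = ½, so the half-max parameter keeps its meaning; the cap keeps the
  stated open bound. No closed form is published for this variant, so the
  slope convention is this package's choice.
* **Step**: R = 0 below s\*, 1 at or above — again reusing the half-max.

Multiple rules on one behavior pool into total up/down responses U and D
(sums of Hill numerators over terms, each term's numerator over 1 + the
sum), combined as b = (1−D)·[(1−U)·b₀ + U·b_M] + D·b_m. The evaluated value
always lies in the interval spanned by {b₀, b_m, b_M}; with the standard
orientation b_m ≤ b₀ ≤ b_M it is non-decreasing in every up signal and
non-increasing in every down signal. Inside a pooled response a linear term
contributes x/(1−x) (so a lone linear term reproduces its curve exactly) and
a step term contributes 0 below threshold or a fixed 10⁶ at/above it —
effectively saturating the pooled response. Up/down saturations from
multiple rules resolve as max over increase-rule saturations (b_M) and min
over decrease-rule saturations (b_m): the bilinear combination admits a
single pair, and the extreme values honor every individual hypothesis as an
upper/lower envelope.

Dead cells only feel rule terms flagged applies-to-dead; U and D are
computed over the permitted terms only, and a behavior with no permitted
terms falls back to its base value.

## Microenvironment solver

Substrates live on a shared rectilinear voxel grid (default 20 µm voxels)
and evolve by ∂ρ/∂t = D∇²ρ − λρ plus cellular exchange. One step applies a
locally one-dimensional operator split — a backward-Euler tridiagonal solve
per axis — followed by an implicit decay factor 1/(1 + λ·dt). The scheme is
unconditionally stable, preserves nonnegativity (M-matrix solves), and with
no-flux boundaries and no decay conserves mass to machine precision (the
Neumann system matrix has unit column sums). Dirichlet boundaries pin the
boundary voxels to the far-field value each step. Accuracy is first order in
time; the implicit decay factor stays within 1% of exp(−λt) for λ·dt ≤ 0.01.

Cellular secretion and uptake use the implicit voxel update
ρ ← (ρ + Δt·(V/V_vox)·S·ρ\*) / (1 + Δt·(V/V_vox)·(S+U)): secretion alone can
never push a voxel beyond the saturation density ρ\*, uptake alone only
removes mass. The engine aggregates all cells sharing a voxel into a single
joint implicit update per substrate per diffusion substep (the per-agent
sequential form is exposed as `SubstrateField.apply_cell_exchange` and
coincides for one cell per voxel). Sampling returns the containing voxel's
value; gradients are central differences, one-sided at boundaries.

Oxygen defaults: D = 10⁵ µm²/min, decay 0.1/min, Dirichlet boundary at the
38 mmHg physioxic far field. Secreted signalling factors are dimensionless
(ρ\* = 1) with D = 10⁴ µm²/min, decay 0.01/min, no-flux boundaries. ECM is a
non-diffusing, non-decaying field written by fibroblast secretion — an
interpretation: it behaves as a deposited material, not a diffusible factor.

## Agents, signals, and the engine

Agents are off-lattice circles (default radius 8.4 µm ≈ 2,500 µm³) with
live/apoptotic/necrotic substate, accumulated damage, and a motility state.
Signals per agent: substrate concentration and gradient magnitude at the
containing voxel, mechanical pressure Σ(1 − d/(rᵢ+rⱼ))² over overlapping
neighbors (a dimensionless crowding score; no formula is standard, this one
is monotone in overlap and zero at first contact), contact counts per cell
type within 1.25·(rᵢ+rⱼ), contact with dead cells, own damage and volume,
simulation time, and dead status. Neighbor queries use a k-d tree rebuilt
per sweep with exact per-pair distance filtering.

Time advances on three nested steps (defaults: diffusion 0.01 min, mechanics
0.1 min, phenotype 6 min; each coarser step an integer multiple of the
finer). Each phenotype step: signals are read, rules applied, then per agent
mutually exclusive events are drawn in a fixed order — death (apoptosis,
then necrosis), transformation (first success among targets in randomized
order), division — followed by the attack sweep, phagocytosis, clearance of
dead cells whose clocks expired (defaults: apoptotic clearance 516 min,
necrotic lysis 24 h, both configurable per cell type), and volume relaxation
toward the type target at 0.05/min. A rate r becomes a per-step probability
1 − exp(−r·dt).

Division places daughters at ± radius/2 along a uniform random direction
with half the parent volume (radii rescaled by 2^(−1/3)). Asymmetric
division applies when a type defines a fate table: one daughter keeps the
parent type, the other's type is looked up in the table's time window at
division time. Attack is non-exclusive (several attackers may damage one
target); an engaged attacker deals damage_rate·dt per phenotype step while
contact with the live target persists, and damage feeds the target's damage
signal so rules such as "damage increases apoptosis" close the killing loop.
Dead agents do not move, divide, transform, attack, secrete, or take up.

Motility redraws an agent's direction when its persistence timer expires:
direction = normalize(bias·ĝ + (1 − bias)·û) with ĝ the chemotaxis unit
gradient (± per type) and û a uniform random unit vector; velocity adds
pairwise mechanics (quadratic-overlap repulsion, quadratic adhesion within
the 1.25× interaction distance, strengths averaged per pair) in an
overdamped update. Positions are clamped to the domain. All randomness comes
from one numpy Generator with a documented draw order, so a seed fully
determines a trajectory across platforms.

## Scenarios and their desk-scale variants

Each bundled scenario encodes its source model's stated rules and initial
conditions exactly (hypoxia: 2,000 cells in a 400 µm disk at 38 mmHg;
extended immune: 2,000 tumor + 400 M0 + 400 naive CD8 in a ring; TAM-EGF:
200 tumor + 10 per immune type; virtual trial: 1,000 tumor agents split
PD-L1 hi/lo; base immune: 100 per non-tumor type). Most rates and half-maxes
are not published; the scenario files carry package defaults chosen for
biological plausibility and annotated "unstated" in their notes.

Desk-scale (`reduced=True`) variants shrink domain and counts at equal cell
density and shorten horizons to minutes of wall time. Two deliberate
rescalings keep the qualitative physics at the smaller size: the hypoxia and
immune scenarios raise per-cell oxygen uptake (to 80/min) so the reduced
tumor spans the same number of oxygen penetration depths √(D/U) as the
grown full-scale tumor — without this, a 200 µm tumor cannot become hypoxic
regardless of density — and the extended immune scenario uses faster
activation/exhaustion kinetics (saturations 0.02–0.05/min, factor half-maxes
0.1) so the full activation-then-exhaustion arc, which the full-scale model
traverses in five simulated days, completes within the one-day desk-scale
horizon.

The cortical-development scenario realizes lamination with asymmetric
division (fate windows over simulation time, deep layers first), a
time-decreases-cycling rule on the stem pool, and fated neurons that migrate
up a static pial-cue ramp and stop on contact with the pial row; cohorts
stack beneath it in arrival order. Variants of active stop-on-contact
layering (halting on earlier cohorts, strong-repulsion packing) proved
numerically brittle at desk scale — transit collisions froze cells
mid-column — so the shipped design uses fast unobstructed ascent with a
single pial stop rule, which yields clean cohort bands whose thickness
tracks cohort size.

## Metrics

Population AUC is the trapezoidal integral of a count curve. Radial
distributions are histograms of distances from a center, normalized to sum
1, overflow in the last bin; their distance is the exact 1-D Wasserstein
metric Σ|CDF_p − CDF_q|·binwidth. Invasive projections rasterize cells as
intensity disks whose brightness falls linearly to zero at the rim (0.4
px/µm default, i.e. 4 px per 10 µm), add a normalized ECM layer, binarize by
Otsu's threshold, trace the longest mask contour, smooth its radial profile
with a scale-free circular moving average (window = contour length / 50, ≥3
points), and count maximal contiguous arcs exceeding the baseline median
radius by a 5% relative margin, ignoring arcs shorter than 3 points; the
smoothing window and margin suppress raster noise so the count is invariant
under rotation and resolution doubling. Layer thickness is the 2.5–97.5
percentile spread of agent coordinates along the laminar axis — robust to
stragglers — with empty layers reported as 0 plus a warning record; layer
RSS is the sum of squared thickness differences against a reference.

## Sensitivity and calibration

Rule parameters are addressed as `rule<N>_<field>` (N = 1-based insertion
order; field ∈ base, sat, hfm, hp). A sweep runs θ·(1+ε) and θ·(1−ε) with
perturbed and reference runs sharing each replicate's seed, and reports the
normalized central-difference elasticity |QoI₊ − QoI₋| / (2ε·|QoI_ref|),
averaged over replicates, with mean and SD across QoIs per parameter. The
elasticity definition is this package's choice: it is dimensionless and
comparable across QoIs; no published formula exists for the index. Paired
seeds make a pure-noise model yield exactly zero index.

The biphasic motility fit models speed as (1 − D(x))·U(x)·b_M with the same
density x feeding one increasing and one decreasing Hill term (base and
minimum 0), fit by bounded least squares from ≥10 Latin-hypercube starts
(half-maxes sampled in log space) to escape the biphasic model's local
minima. Monotone data push the down half-max to its upper bound, recovering
a single Hill curve. Layer calibration is an exhaustive grid search
minimizing the mean layer RSS over ≥3 replicate simulations per grid point.

## Synthetic-data generators

Fixture generators stand in for the study's omics-derived inputs: an
annotated **spot table** (hexagonal lattice, epithelial core / mesenchymal
fringe / fibroblast collar with dense ECM / inert scaffold, 10% label
noise), **cohort counts** (Dirichlet-multinomial compositions over the
PD-1/CD137 taxonomy with exact library sizes and a Beta-distributed PD-L1hi
tumor fraction), a **motility dataset** ((density, speed) pairs on a known
biphasic combined-Hill curve with optional lognormal noise), and a **layer
reference** (per-layer thicknesses with the deep-to-superficial ordering of
a mouse cortical column). They reproduce the *schemas and qualitative
structure* of annotated spatial/single-cell data, not its biology: no
spatial transcriptional gradients, no segmentation error beyond label
flips, no patient covariance structure. Tests passing on these fixtures
demonstrate the machinery (mapping, composition, fitting, recovery), not
fidelity to any real tissue.

## Known limitations

2-D simulations only (the data structures carry 2-D positions); no
advection or anisotropic diffusion; no cell–cell fusion; attack is
non-exclusive with additive damage across attackers, a stated
interpretation; therapies act as initial-composition edits, not
pharmacokinetics; intracellular networks are out of scope. Mechanics uses a
single global RNG stream and serial sweeps — reproducibility was preferred
over parallel speed.
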