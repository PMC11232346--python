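# Methods

`autoplan` implements a script-style automated planning workflow for
external-beam radiotherapy of cervical cancer (prescription 50.4 Gy in 28
fractions) and exercises it end-to-end on synthetic pelvic phantoms.  This
note records the models, the parameters that matter, and the design choices
made where the design was genuinely open.

## Workflow

For one case (a voxelized structure set + prescription) the pipeline runs:

1. **Auxiliary structures** — rings around the PTV, the normal-tissue
   remainder, and the overlap-capping contraction loop (below).
2. **Influence model** — a sparse beamlet→voxel dose operator on a 3 mm
   dose grid.
3. **Objective template** — the built-in 25-row template, with the
   bowel-helper row's volume parameter computed per patient.
4. **Optimization** — projected-gradient descent on nonnegative beamlet
   weights, two rounds of 100 iterations.
5. **Normalization** — global rescaling so the prescription isodose covers
   95 % of the PTV.
6. **Evaluation** — DVH statistics, HI/CI/GI indices and the protocol
   constraint table.

Every stage is deterministic given the master seed.

## Auxiliary-structure preprocessing

The planning strategy concentrates unavoidable PTV dose deficits inside
OAR overlaps.  For each of bladder, rectum and bowel bag, the PTV is
contracted inward in 0.5 mm increments until the OAR's overlap with the
contracted PTV falls to its cap: ≤ 45 % of organ volume for bladder and
rectum, ≤ 110 cc for the bowel bag.  Then

    oar_new   = oar ∩ contracted PTV
    oar-ptv   = oar − oar_new
    PTV_new   = PTV − (bladder-ptv ∪ rectum-ptv ∪ bowel bag-ptv)

Each OAR's loop runs independently with its own depth (the subtraction
structures are defined separately, so a shared depth would only over-contract).
The returned step count is minimal by construction: the loop evaluates the
overlap at every step against the precomputed interior distance field of the
PTV, so one fewer step always leaves the overlap above threshold.

Margins are Euclidean, implemented as thresholds on distance transforms
measured between voxel centers (expansion: background distance ≤ margin;
contraction: interior distance > margin).  This makes 0.5 mm steps
meaningful on a 2.5 mm grid — the voxelized result changes in discrete
jumps, but the jump locations are exact — and supports the monotonicity and
minimality guarantees above.  Whether a clinical TPS applies per-axis or
Euclidean margins is not observable from outside; Euclidean is assumed.
Ring structures (0–5, 5–10, 10–20, 20–30 mm) are clipped to the body so
that body = PTV ⊎ rings ⊎ nt holds voxelwise.

The bowel helper `bag` is the bowel bag within 20 mm of the PTV; its DVH
objective volume parameter is `floor(100·195/V_bag)` %, clamped to
[0, 100] (a DVH volume cannot exceed the ROI), and the objective is omitted
when the helper is empty.

## Synthetic phantoms

The generator emulates only the cohort statistics that the objective
template and preprocessing key on:

| statistic | distribution (mean ± SD, range) |
|---|---|
| PTV volume | 1347.45 ± 179.28 cc, 1122.82–1862.99 |
| bladder-in-PTV | 37 ± 11 %, 13–64 |
| rectum-in-PTV | 52 ± 13 %, 24–72 |
| bowel-bag-in-PTV | 115.79 ± 52.09 cc, 8.05–205.67 |

Each statistic is drawn from a truncated normal whose underlying location
and scale are moment-matched by least squares so the *truncated*
distribution itself carries the stated mean and SD; truncating a normal
parameterized directly with those moments would bias the mean (the PTV
range is strongly asymmetric, shifting it by ≈ +35 cc).

Geometry is deliberately schematic: an elliptic-cylinder body
(340 × 240 × 250 mm) on a 2.5 mm grid, a deformed-ellipsoid CTV whose 7 mm
isotropic expansion forms the PTV (the CTV is rescaled by secant iteration
until the PTV volume matches its draw within 1 %), and ellipsoidal OARs with
low-frequency multiplicative boundary noise.  Bladder (anterior-inferior)
and rectum (posterior) are *placed* by bisection along an approach axis so
their in-PTV fractions hit the drawn targets; the bowel bag (superior,
lobulated) is placed the same way on absolute overlap volume.  Femoral heads
and kidneys sit lateral/superior, forced outside the PTV.  Organ volumes are
not part of the cohort statistics; typical adult values are used (bladder
300 cc, rectum 70 cc, bowel bag 1300 cc, femoral head 55 cc, kidney 150 cc).

What the phantoms do **not** emulate: CT intensities and heterogeneity,
realistic organ shapes and contact topology, organ motion, positioning
differences.  Tests passing on phantoms therefore demonstrate the
*algorithmic* guarantees (caps reached minimally, normalization exact,
protocol met under the modeled dose physics), not clinical performance on
patients.

## Dose engine

The influence model is intentionally the cheapest transport that still
produces realistic DVH trade-offs: parallel (non-divergent) coplanar beams
at 36 equispaced gantry angles, single-energy exponential attenuation
(μ = 0.005 /mm) along the body path, and a 3-D Gaussian lateral kernel
(σ = 3 mm).  A beamlet is indexed by (angle, lateral offset, axial slice):
lateral spacing 5 mm across the PTV projection plus a 10 mm margin, one
beamlet row per 3 mm dose slice over the PTV's axial extent plus margin.
The influence of a beamlet on a voxel is

    exp(−μ·depth) · exp(−r² / 2σ²),   r² = Δu² + Δz²,

truncated below 10⁻⁴ of the beamlet's maximum.  The in-plane part is stored
as a sparse matrix (≈ 3·10⁷ nonzeros at default settings); the axial
Gaussian factor is a separable convolution composed into the same linear
map, and dose is masked to the body.  Body-entry depths are computed per
lateral bin (bin width = dose-grid spacing), exact for convex axial body
sections — all phantoms — and approximate for concave bodies.  A dual-arc
preset (2° spacing, 180 angles) exists as configuration only; no machine
constraints, scatter, heterogeneity or deliverability are modeled, and
delivery parameters (pitch 0.43, jaw 2.51 cm, delivery-time factor 1.7) are
carried on plans as metadata only.

## Objectives and optimizer

Five penalty kinds, all one-sided quadratics normalized by the squared
prescription dose so the template's printed weights (10⁸–10⁹ for target and
ring objectives, 0.01–5 for mean-dose gEUD terms) are usable as printed:

* **Max/Min Dose** — mean over ROI voxels of squared excess/deficit.
* **Max/Min DVH** (target t, volume v) — the same penalty restricted to the
  excess-volume voxels cheapest to move: those between t and the current
  dose at volume v (inclusive).  The selection is re-identified at every
  objective evaluation.
* **Max EUD** (target t, exponent a) — squared excess of the generalized
  equivalent uniform dose, gEUD = (mean dᵃ)^(1/a), with the analytic
  chain-rule gradient (d_i/gEUD)^(a−1)/N.  gEUD is evaluated in a
  max-scaled form that is stable at a = 150 (the template's near-maximum
  PTV objective; the exponent is configurable).

The optimizer is projected-gradient descent with backtracking (halving on
failure, 1.4× growth on acceptance), uniform positive initial weights scaled
so the mean PTV dose equals the prescription, and an initial step from a
Cauchy-like estimate f₀/‖g₀‖².  "Two rounds" is interpreted as a restart of
the step-size schedule at the round boundary; with stopping tolerance 0
every iteration runs.  The objective is nonincreasing by construction; a
persistent increase raises a diagnostic error.

ROI masks are resampled to the dose grid by voxel-center containment and a
dose voxel may belong to several ROIs.

## Evaluation

Cumulative DVHs use the "volume receiving ≥ dose" convention with 0.05 Gy
bins and linear interpolation; D_x% is the interpolated inverse, D_0.03cc is
evaluated on the dose grid.  Inverse queries agree with a sort-based oracle
to within two bin widths (one bin of curve quantization plus one of inverse
interpolation).  Normalization uses the interpolated 5th percentile of PTV
dose directly, so the 95 % coverage is exact up to that interpolation.

Indices: HI = (D₂% − D₉₈%)/D₅₀%; CI = TV²/(V_PTV·V_TVP) where TV is the
prescription-isodose volume inside the PTV and V_TVP the full
prescription-isodose volume; GI_x = V_x/V_TVP for x ∈ {40, 30, 20, 10} Gy.
The protocol table contains 11 rows (PTV maximum-dose limits are read
relative to the prescription, i.e. 115 % of 50.4 Gy); rows covering paired
organs evaluate both sides and report the worse one, passing only if both
pass.  Comparators carry a 10⁻⁶ relative epsilon so a quantity normalized
to sit exactly on its limit (PTV coverage = 95 %) is not failed by float
round-off.

## Statistics

Plan arms are compared metric-by-metric with the two-sided Wilcoxon
signed-rank test: zero differences dropped before ranking, exact null
enumeration over all 2ⁿ sign assignments for ≤ 12 nonzero pairs, normal
approximation with tie and continuity corrections otherwise; all-zero
differences give p = 1 with a degeneracy flag.  The mean-dose regression
(OAR EUD at a = 1 against PTV overlap fraction, or cc for the bowel bag) is
ordinary least squares with the Pearson r reported; its clinical
coefficients depend on patient anatomy and are not reproduced here.

## Problem sizes and numerical choices

Default phantom grid 2.5 mm (≈ 1.5 M voxels), dose grid 3 mm; the default
influence model has ≈ 40 k beamlets and builds in ≈ 15 s; a full two-round
optimization takes 2–4 minutes on one CPU.  Unit and property tests run the
same code on coarser instances (5 mm phantoms, 8–12 angles, short
optimizations); cohort-statistics tests generate 200 phantoms at 5 mm,
volumes and overlap fractions being resolution-independent.  Bisection
placements run 45 iterations (far below voxel resolution); the CTV volume
secant stops at 1 % relative error; the contraction loop is capped at 400
steps (20 cm) as a termination guard that no realistic geometry approaches.

## Known limitations

* The dose engine is a surrogate: no collapsed-cone physics, scatter,
  heterogeneity or machine model; absolute OAR metrics are not clinically
  meaningful, only the workflow's internal guarantees are.
* The penalty forms behind the template's printed weights follow standard
  inverse-planning practice; a commercial optimizer's internal formulas are
  proprietary and will differ in detail.
* Phantom anatomy is schematic; organ volumes and positions are fixed
  defaults with noise, not sampled from population shape models.
* Body-entry depth assumes convex axial body sections when computing
  attenuation.
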