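# Methods

## Overview

`glioshadow` studies whether sequential data assimilation can keep an
imperfect ensemble forecast of a growing glioblastoma close to the true
tumor when the only information arriving is a noisy image every 60 days.
The package implements (i) two reaction–diffusion growth models on a
labeled 2-D brain raster, (ii) a synthetic MR observation operator,
(iii) the Local Ensemble Transform Kalman Filter (LETKF), and (iv) an
observing-system simulation experiment (OSSE) driver that wires them
into twin experiments with deliberate, quantified model error.

## Growth models

**Logistic Swanson model** (one field, the forecast model):

    ∂g/∂t = ∇·(D(x)∇g) + α g (1 − g/T_max)

with g the tumor cell density (cells·mm⁻² in 2-D), α the growth rate
(day⁻¹), T_max the carrying capacity (cells·mm⁻²; nominal 10⁴) and D a
piecewise-constant diffusivity by tissue class (nominal 0.0065 white /
0.0013 gray / 0.001 CSF, mm²·day⁻¹).

**Two-phenotype model** (three fields, the truth model): proliferating
cells g, migrating cells m, and the extracellular-matrix (ECM) density
w ∈ [0, 1]:

    ∂g/∂t = ∇·(D_G∇g) + α g (1 − (g+m)/T_max) − ∇·(χ g ∇w)
    ∂m/∂t = ∇·(D_M∇m) + ∇·(χ g ∇w)
    ∂w/∂t = −ρ_ecm w (g+m)/(θ_W + g+m) + α_W w (1 − w)

Nominal values: α = 0.025 day⁻¹, T_max = 10⁴, α_W = 0.01 day⁻¹
(ECM recovery), ρ_ecm = 0.02 day⁻¹ (remodeling), θ_W = 100 cells·mm⁻²
(half-max degradation density); per-class D_G = 0.002/0.0004/0.001,
D_M = 0.10/0.02/0.001 (mm²·day⁻¹) and χ = 0.25/0.05/0 for
white/gray/CSF. The haptotaxis term moves one and the same flux of
cells out of the proliferating class and into the migrating class, so
it cancels identically in g + m — an algebraic identity that the
discretisation preserves to roundoff and the tests check.

Glial voxels receive white-matter coefficients at parameter-expansion
time; the input labels are never rewritten. The logistic source acts on
the whole brain mask, including CSF voxels — the coefficient tables
already single out CSF through its diffusion and haptotaxis values, and
suppressing growth there is a modeling refinement we deliberately do
not add.

## Numerics

Spatial derivatives use a conservative 5-point flux-form stencil on the
1-mm raster: the interface diffusivity is the arithmetic mean of the
two adjacent voxel values, and any face between a brain voxel and a
non-brain voxel carries zero flux. This makes total cell mass exactly
conserved by transport (≤ 1e-9 relative over a 90-day run, tested).
The haptotactic face flux is χ_face · g_upwind · Δw/h with the donor
cell chosen by the sign of the ECM gradient; upwinding buys stability
at the cost of O(h) smearing of the advected front, which the
resolution study below bounds.

Time stepping is Heun's second-order predictor–corrector with a fixed
step of 0.1 day. After each corrector, negative densities are clamped
to zero and w to [0, 1]; clamp counts are logged and are a vanishing
fraction of voxel updates at the default step. Non-finite values abort
with the offending simulation time. On a 0-D logistic reduction the
global error decreases as O(dt²) (tested over dt = 2 → 0.25).

Stability at the defaults: the strictest diffusion number is
4·D_M·dt/h² = 0.04 (white matter, 1 mm), and the haptotactic CFL number
stays below ~0.03; explicit stepping is comfortably stable, and an
implicit solver is out of scope.

**Resolution robustness.** Integrating the two-phenotype model for 90
days from a fixed smooth (Gaussian) initial distribution on the same
physical phantom rasterised at 2 mm, 1 mm, and 0.5 mm changes the total
population by at most ≈1.3% (well under the 10% the protocol demands).
The phantom geometry is defined in fractional coordinates precisely so
that one seed yields the same anatomy at every spacing.

## Tissue phantom

The built-in phantom emulates a coronal slice: an elliptical brain with
a gray-matter shell, a contiguous white-matter core (more white than
gray area, matching the slice the experiments assume), two
ventricle-like CSF pockets plus small CSF sulci, glial arcs at the
gray/white interface, and non-brain background. All shapes are
deterministic functions of one integer seed. It is a geometric fixture,
not an anatomical claim: it has no cortical folding, no left–right
asymmetry, and its tissue boundaries are smooth ellipse arcs. External
atlas slices in the documented raster format (plain text or 8-bit raw,
with a JSON sidecar carrying shape, spacing, and the label → class map)
can be used instead.

## Observation model

A synthetic MR image reads, per voxel,
h(x) = clamp₀¹[u(x,t)/T_max + η(x)] with u the total cell density and η
i.i.d. uniform on [−0.1, 0.1]. Every brain voxel is observed. Because
the noise is additive on the *fraction* scale, it is proportionally
largest where the density is low — the edema fringe is genuinely harder
to pin down than the core, and the filter output reflects that.

Member predictions of the image divide by the member's *own* carrying
capacity and are noise-free by default, as in standard square-root
filtering where observation error enters only through R; a
`perturbed` mode adds a per-member η draw for fidelity experiments.
The filter's R is diagonal Gaussian with the uniform noise's variance
b²/3 = 1/300 — a documented Gaussian approximation to noise that is
actually uniform (and clamped).

## The LETKF

Each brain voxel is updated independently from the observations inside
its 7×7 mm local region (halfwidth 3 at 1-mm spacing), through the
ensemble-space solve

    C = Y_bᵀR⁻¹,  P̃_a = [(k−1)I/ρ + C Y_b]⁻¹,
    W̃_a = [(k−1)P̃_a]^{1/2} (symmetric root via eigendecomposition),
    w̄_a = P̃_a C (y_o − ȳ_b),  x_a^i = x̄_b + X_b(W̃_a + w̄_a1ᵀ)_i .

The symmetric square root keeps the analysis a continuous function of
P̃_a so adjacent local analyses stay consistent. Eigenvalues are floored
at 1e-12 of the largest; since the precision matrix is bounded below by
(k−1)/ρ·I this only triggers on non-finite input. Diagonal R uses an
elementwise fast path; a general R is handled by solving R·Cᵀ = Y_b.

Properties the tests enforce: with one global region, ρ = 1 and linear
observations the analysis mean and covariance match the exact Kalman
recursion to 1e-6; observation-free (or signal-free) regions return the
background mean with perturbations scaled by √ρ; analysis perturbations
sum to zero (≤1e-10) and lie in the span of the background
perturbations; the result is independent of voxel processing order.

**Inflation semantics.** ρ enters exactly as written above, so ρ < 1
*contracts* perturbations (by √ρ where observations carry no ensemble
signal) — deflation, despite the name. The default follows the
protocol's literal ρ = 0.1; ρ is a config knob and values > 1 give
genuine inflation. Our experiments (below) behave qualitatively the
same at ρ = 0.1 and ρ = 1.1.

Two implementation fast paths are algebraically exact and tested as
such: an ensemble-vectorised, numba-compiled Heun stepper for Swanson
ensembles (roundoff-equivalent to the per-member reference integrator),
and a vectorised √ρ update for voxels whose local window contains no
observation with ensemble spread (the filter's no-information limit).

## OSSE protocol

Truth: two-phenotype model, nominal parameters, seeded with 100
proliferating + 10 migrating cells in one white-matter voxel and spun
up 365 days; t = 0 is the end of spin-up. Ensemble: k members (50 by
default; 25 in the scaled experiments) of the Swanson model, each with
fixed parameters drawn uniformly from experiment-specific intervals —

| experiment | α (day⁻¹) | D_white (mm²·day⁻¹) | T_max |
|---|---|---|---|
| 1 | 0.01767 – 0.035347 | 2e-3 – 2e-2 | 8000 – 12000 |
| 2 | 0.0153 – 0.0612 | 2e-4 – 2e-2 | 8000 – 12000 |
| 3 | 0.0153 – 0.10 | 2e-4 – 2e-1 | 8000 – 12000 |

(gray and CSF diffusivities stay nominal). The α intervals correspond
to 1%→99% logistic transition times of 520–260, 600–150, and 600–90
days via t = (2 ln 99)/α. Each member seeds U[50, 150] cells in a brain
voxel within 3 mm (Euclidean) of the truth seed and spins up 365 days
under its own parameters. A noisy image of the truth is assimilated at
t = 0, 60, …, 360 days — seven analyses, six 60-day forecasts. The
whole run is a pure function of its four named seeds (truth, params,
init, obs).

Skill is measured as RMSE, over the brain mask, between fields
expressed as fractions of carrying capacity: the ensemble mean of
g_k/T_max^k against the truth's (g+m)/T_max. The contour-spread
diagnostic operationalises the spaghetti plots: cast angular rays from
the density-weighted centroid of the ensemble-mean field and average
over rays the (max − min) radius at which member half-max contours
(level T_max^k/2, marching squares) cross each ray.

## What the scaled experiments show — and two honest discrepancies

On a 96×96 phantom with k = 25 and three replicate seeds, the day-360
analysis-mean RMSE is 4–10× smaller than the free-run RMSE in every one
of the nine experiment × seed runs (e.g. 0.052 vs 0.408 for experiment
2, seed set 10–13): assimilating seven images keeps the ensemble on the
truth where the unconstrained forecast drifts badly. That is the
central shadowing claim, and it reproduces robustly.

Two quantitative statements of the original protocol do **not**
reproduce under a faithful implementation of the printed equations, and
we leave the corresponding checks red rather than tune toward them:

1. **Spin-up population.** The 365-day truth spin-up yields ≈7.9×10⁵
   cells over ≈680 mm², not ~10⁵ over ~150 mm². The spatial operators
   were cross-checked against an independent fine-grid radial solver
   (which reproduces our haptotaxis-free limit, 1.96×10⁵ vs 1.93×10⁵),
   and the result is insensitive to resolution (0.5 mm: 7.84×10⁵) and
   to the advection scheme (central: 8.4×10⁵). Even deleting the
   haptotaxis term entirely leaves ≈1.9×10⁵ — the printed parameter set
   cannot produce ~10⁵. We note the printed haptotaxis coefficient's
   unit (mm⁻¹) is not dimensionally consistent with ∇·(χg∇w); reading χ
   as scaling the migrating-cell motility (χ·D_M) reproduces the
   ~150 mm² footprint but still gives 4.2×10⁵ cells.

2. **Ordering across experiments.** Analysis error does not degrade
   monotonically from experiment 1 to 3: medians are 0.216 / 0.052 /
   0.087. The truth produced by the printed equations is diffuse and
   never saturates (peak ≈0.35·T_max), while every Swanson member
   saturates toward its own T_max; experiment 1's narrow priors exclude
   the low-density members whose perturbations the analysis needs, so
   the *widest*-but-one prior (experiment 2) wins. The inversion
   persists at ρ = 1.1, so it is not an inflation artifact — it is a
   direct consequence of the truth's character, i.e. of discrepancy 1.

## Default parameters that matter

| parameter | default | units | role |
|---|---|---|---|
| dt | 0.1 | day | Heun step, both models |
| spacing | 1.0 | mm | voxel size |
| k | 50 (25 scaled) | – | ensemble size |
| local halfwidth | 3 | voxels | 7×7 mm local region |
| ρ (inflation) | 0.1 | – | ensemble-space covariance rescaling |
| noise bound b | 0.1 | – | uniform image noise, R = b²/3 |
| seed radius | 3 | mm | member seed offset from truth seed |
| cycle | 60 | days | forecast/assimilation interval |
| w(x, 0) | 1 on brain mask | – | initial ECM |

## Scope and limitations

Single 2-D coronal slice; no mass effect, treatment, registration, or
pixel-intensity calibration; no parameter estimation or state
augmentation (member parameters are frozen); Gaussian-diagonal R
against actually-uniform clamped noise; the phantom is geometric, not
anatomical, so passing tests bound discretisation and filter behavior —
they say nothing about real MR data. Problem sizes in the shipped tests
(96×96 grids, k = 25, three replicate seeds) are the package's scaled
study conditions; the full-scale 50-member run on a 145×143 slice is
available through the same config surface (`run-osse --rows 145 --cols
143 --k 50`) and takes tens of minutes on one core.
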