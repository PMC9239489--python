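# Methods

## Model

Measured parallel-beam projection data are written as `A x = b + λ`: the
system matrix `A` (M × N, M = R·Θ rays, N = n² pixels) applied to the true
attenuation image equals the measured log-attenuation sinogram plus a
sparse "imperfect" component `λ`. Non-uniform detector-bin sensitivity
corrupts entire sinogram rows, so `λ` is supported on a few bins — sparse —
and the reconstruction problem is posed as

min over (x, λ) of S(λ) + β H(x) subject to A x − b = λ,

solved via the augmented Lagrangian
`L_ρ = S(λ) + (ρ/2)‖λ − A x + b + u‖²` with scaled dual `u`. One outer
iteration: (1) L warm-started gradient steps on the image with gradient
`−ρ Aᵀ((λ + b + u) − A x)` plus `β′ ∇H`; (2) `λ ← prox_{S/ρ}(A x − b − u)`
elementwise; (3) `u ← u + (λ − A x + b)`. For convex S (ℓ1, Huber-ℓ1) this
is plain ADMM on a convex problem and the primal residual `‖λ − A x + b‖`
is driven to zero; the ℓ0 variants carry no guarantee but behave well in
practice (see warm start below). The angular-constrained variants apply
the prox to the per-bin mean of `d = A x − b − u` over angles and replicate
the result across views, enforcing bitwise angular constancy of `λ`.

## Sparsity penalties and their proxes

All proxes are exact minimisers of `μ s(x) + ½(x − y)²`, verified against a
dense-grid oracle in the test suite.

| penalty | s(λ) | prox |
|---|---|---|
| ℓ1 | \|λ\| | soft threshold by μ |
| ℓ0 | 1{λ≠0} | keep y iff y²/2 > μ, else 0 (tie → 0, the sparser choice) |
| Huber-ℓ1 | λ²/2 below δ, δ\|λ\| − δ²/2 above | y/(μ+1) for \|y\| ≤ (μ+1)δ, else shrink by μδ |
| Huber-ℓ0 | min(λ²/2, δ²/2) | y/(μ+1) for \|y\| ≤ δ√(μ+1), else identity |

Two deliberate choices. First, the Huber-ℓ1 linear branch uses `−δ²/2`
(the continuous Huber function): that is the unique constant for which the
closed-form prox above is exact. Second, the Huber-ℓ0 penalty is defined as
the *truncated quadratic* `min(λ²/2, δ²/2)` — quadratic at noise scale,
flat (ℓ0-like) beyond δ — and its prox band is `δ√(μ+1)`, which follows
from comparing the shrunk candidate against the identity globally. A
branch-validity derivation that skips the global comparison yields a wider
band `(μ+1)δ`; that operator is *not* the exact prox of any fixed penalty
and fails the oracle check, so the exact form is used.

## Smoothing penalty

`H(x) = Σ_j Σ_{j̃∈U_j} w_jj̃ h(x_j − x_j̃)` over the 8-neighbourhood, `h`
quadratic below the edge threshold η and linear above (continuous Huber,
same sign convention as above). Each unordered pixel pair appears in both
pixels' neighbour sets; the double sum is kept literally and the gradient
therefore carries a factor 2, making value and gradient mutually consistent
(checked by finite differences). Weights default to inverse Euclidean
distance (1 axial, 1/√2 diagonal), the standard MRF convention that
down-weights diagonals; a `weights="distance"` switch provides the literal
distance alternative. Neighbour sets are truncated at image borders.

## Geometry, projector, FBP

Ray-driven Joseph projector: each ray (the line `x cosθ + y sinθ = s`) is
traversed along its dominant axis with linear transverse interpolation and
path-length weight `1/max(|cosθ|, |sinθ|)`. The operator is materialised
once per geometry as a sparse CSR matrix, so the backprojector is the exact
algebraic transpose — the adjoint identity holds to ~1e-16, which the GD
step requires. Conventions: angles counter-clockwise from the x-axis at the
left edge of each uniform interval; detector centred on the rotation axis
with unit spacing; reconstructions supported on the inscribed circle.

FBP applies a Ram-Lak filter per view in the frequency domain (zero-padded
to the next power of two ≥ 2R, frequency axis in cycles per pixel), then
backprojects with `Aᵀ` and scales by π/Θ — a normalisation that covers both
180° and 360° ranges (opposing views average over 360°). A noise-free
360°-view reconstruction of a 128² disk phantom lands at RRMSE ≈ 0.07,
typical for linear-interpolation FBP of a sharp-edged object.

## Synthetic data

Phantoms (`disk`, `shepp_logan`, `chest_like`) are deterministic with
display values in [0, 1]; the chest-like phantom has a soft-tissue body
ellipse, two low-attenuation lungs, a heart-like blob, a dense spine and
rib-like arcs. Study cases project the phantom at a physical attenuation
scale (×22.5/n), giving line integrals up to ≈ 6 — minimum transmission
≈ 0.25%, typical for a thorax — so that the Poisson model at b0 = 10⁶
counts/bin produces realistic noise (σ ≈ 1e-3 at zero attenuation) instead
of photon starvation.

Bad-bin corruption acts additively in the log-sinogram domain, matching the
decomposition the solver assumes (`corrupted = clean − λ_true`, so the
recovered λ estimates λ_true directly); a multiplicative detector-gain mode
is available since sensitivity errors are physically multiplicative.
Offsets default to 2–10% of the sinogram maximum with random sign. The
three study configurations: (1) five isolated bins, angle-constant;
(2) three adjacent runs up to 3 bins wide, angle-constant; (3) as (2) but
modulated over angle by `1 + 0.5 sin(2πθ/Θ)`; "noisy" adds Poisson noise at
b0 = 10⁶ to case 1. Bad bins are placed within detector coordinate
|s| ≤ 0.85·(n/2) so every ring falls inside the object. Geometry scales
from the full-size 512-pixel / 1000-view / 360° acquisition proportionally
to n, with the detector spanning the image diagonal (185 bins, 250 views at
n = 128); an `n_bins` override reproduces the width-matched 512-bin layout.

What the generator does **not** emulate: scatter, beam hardening, detector
cross-talk, fan/cone geometries, and — importantly — textured tissue. The
phantoms are piecewise constant, which the Huber-MRF prior matches almost
perfectly; the near-exact recoveries of the smoothed ℓ0 variants
(RRMSE ~1e-3 on noise-free data) are a real compressed-sensing effect on
piecewise-constant images and should not be extrapolated to textured
clinical data.

## Study protocol parameters

Desk scale: n = 128 (185 bins × 250 views, 360°), K = 500 outer iterations,
L = 2 inner GD steps, chosen so the full protocol runs in minutes on one
CPU. The GD step is always `α = 1.8/(ρ‖A‖²)` with ‖A‖ from 30 power
iterations — just inside the 2/Lipschitz stability limit.

Each penalty's prox imposes a threshold on the sinogram-domain error it can
capture, and the thresholds scale differently with μ = 1/ρ: linearly (ℓ1
soft threshold μ), as a square root (ℓ0 hard threshold √(2μ)), or via δ
(Huber). One ρ therefore cannot position all four thresholds on a given
data scale, and the protocol fixes them per penalty so each threshold sits
just below the smallest plausible bad-bin offset (2% of the sinogram
maximum ≈ 0.12):

| variant | ρ | induced threshold | δ |
|---|---|---|---|
| ℓ1 | 12 | μ = 0.083 | — |
| ℓ0 | 130 | √(2μ) = 0.124 | — |
| Huber-ℓ1 | 2 | shrink μδ = 0.044, band ≈ 0.13 | 0.088 |
| Huber-ℓ0 | 2 | band δ√(μ+1) ≈ 0.22 | 0.18 |

Smoothing uses β′ = 0.005, η = 0.001 image units: η is far below tissue
contrasts (0.05–0.15 after attenuation scaling), so the penalty acts like
total variation on ring-scale ripples while preserving edges.

**Warm start.** The ℓ0-family solvers start from the FBP of the measured
sinogram. From a zero image the residual `d = A x − b − u` equals `−b`,
every entry exceeds the hard threshold, the identity branch of the prox
captures the entire sinogram into λ — and because that branch satisfies the
constraint exactly, the dual update vanishes and the iteration stalls.
Started near the solution, the residual stays below threshold except at the
genuinely bad bins. The convex variants start from zero (the default).

## Numerical details and degenerate inputs

* ℓ0 prox tie `y² = 2μ`: returns 0 (deterministic, sparser).
* Poisson counts are clamped to ≥ 1 before the log (negligible at
  b0 = 10⁶ under the physical attenuation scaling).
* Mildly negative log-attenuation values (a positive bin offset in an air
  region) are allowed by the noise model — expected counts simply exceed b0.
* Overlapping corruption runs are merged with a warning.
* SSIM uses population (1/N) moments, one global window, and the
  reference's dynamic range (pooled option for symmetry); a zero dynamic
  range falls back to 1. RRMSE normalises by the reference norm by default;
  the alternative normalisation by Σxᵢ is available as `variant="printed"`.
* Divergent iterates (non-finite) raise a diagnostic error naming the step
  size and the outer iteration.
* Solvers are deterministic given config and inputs; all generator
  randomness flows from explicit integer seeds.

## Known limitations

* The plain-GD image step limits broadband convergence: at n = 128,
  K = 500, L = 2 the reconstruction floor is RRMSE ≈ 0.07 for the ℓ1-family
  variants (the same floor as reconstructing clean data), so differences
  between well-performing variants below that level are not resolvable at
  desk scale. The smoothed ℓ0 variants escape the floor only because the
  phantoms are piecewise constant.
* ℓ1 solutions retain a small bias (faint residual rings near the centre),
  consistent with the behaviour of ℓ1 data-fidelity models generally; the
  ℓ0 variants remove them but need the warm start.
* Fan-beam/cone-beam geometries, 3-D reconstruction and GPU projectors are
  out of scope.
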