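# Methods

## Model

A voxel is modelled as two non-exchanging compartments sharing one
orientation distribution: a stick compartment (signal fraction `f`,
diffusivity `Da` strictly along the stick axis) and a zeppelin
(axisymmetric Gaussian) extra-neurite compartment with diffusivities
`De∥ ≥ 0` parallel and `De⊥ ≥ 0` perpendicular to the local axis.
Orientations follow a Watson distribution `P(û) ∝ exp(κ (û·μ̂)²)` with main
direction `μ̂` and concentration `κ ≥ 0`.  All diffusivities are in μm²/ms,
b-values in ms/μm², so exponents are dimensionless.  The long-mixing-time /
multi-Gaussian-compartment regime is assumed throughout: a measurement is
fully characterized by its symmetric 3×3 b-tensor, and a parallel-pair
double encoding at (b/2, b/2) is *identically* an SDE measurement at b.
Finite axon radius, exchange, CSF/dot compartments and gradient-waveform
detail are out of scope.

## Watson moments

Every derived quantity reduces to the axial moments of the Watson
distribution, evaluated through the Dawson function F:

    c2(κ) = ⟨(û·μ̂)²⟩ = 1/(2√κ F(√κ)) − 1/(2κ),
    c4(κ) = ⟨(û·μ̂)⁴⟩ = (√κ/F(√κ) − 3 c2)/(2κ),

with p2 = (3c2−1)/2 and p4 = (35c4 − 30c2 + 3)/8 the mean second/fourth
Legendre polynomials (the non-zero spherical-harmonic coefficients of the
ODF), and the projection moments

    h2(ξ,κ) = 1/3 + (2/3) p2 P2(ξ),
    h4(ξ,κ) = 1/5 + (4/7) p2 P2(ξ) + (8/35) p4 P4(ξ),

which give ⟨(û·n̂)²⟩ and ⟨(û·n̂)⁴⟩ for an axis at projection ξ = n̂·μ̂.
Below κ = 0.05 the closed forms cancel catastrophically and are replaced by
the Taylor series of the moment integrals Σ κⁿ/(n!(2n+2m+1)) (14 terms;
the branches agree to ~10⁻¹⁴ at the switch).  `c2` is the bounded,
monotone dispersion summary used for reporting, error scoring and as the
fitting coordinate for κ; its numerical inverse uses Brent bracketing.

## Signal evaluation

Two exact evaluators are implemented and cross-checked:

* **Spherical product quadrature** (reference; any b-tensor): Gauss–Legendre
  in cos θ × uniform in φ, exact for spherical harmonics to the requested
  degree (default 59, i.e. the same exactness class as a 1202-point Lebedev
  grid, without bundling grid tables).  Note the guarantee is about ODF
  bandwidth: at κ = 64 the ODF itself has ~10⁻⁶ of its mass above degree
  59, so oracle-grade comparisons at high concentration use degree ≥ 120.
* **Rank-2 reduction** (linear/planar/zero b-tensors — every protocol in
  this package): each compartment integral has the form
  ∫ exp(ûᵀQû) dS with Q = κ μ̂μ̂ᵀ + a n̂n̂ᵀ, because a planar tensor
  (b/2)(I−v̂v̂ᵀ) contributes a scalar factor times a rank-1 term along its
  normal.  Q is diagonalized in closed form in the (μ̂, n̂) plane and the
  spherical integral collapses to a 1-D integral of
  exp(c t²)·I0e(|a′|(1−t²)/2), evaluated on the positive half of an even
  Gauss–Legendre rule whose size grows like 8√κ (96 nodes up to κ ≈ 150).
  Scaled Bessel functions keep it overflow-free for any eigenvalue spread.
  The two paths agree to ~10⁻¹³ across κ ∈ [0, 10³]; above κ = 10⁵ the
  aligned (δ-ODF) limit is used outright.

Rician noise replaces each value by √((S+g1)² + g2²) with independent
zero-mean Gaussians of σ = S0/SNR, σ defined from the noise-free b = 0
signal (SNR 50 in all study conditions), under seeded generators.

## Protocols

The DDEa+b families put `a` parallel and `b` perpendicular direction pairs
(a+b = 60, split evenly over shells b = 1 and 2 ms/μm², both pair members
at b/2) plus five b = 0 measurements; DDE60+0 is the two-shell SDE protocol
and DDE0+60 purely planar.  For DDE30+30 the planar normals reuse the
parallel directions; other mixes generate fresh normal sets.  Directions
come from electrostatic-repulsion minimization over points and antipodes
(L-BFGS with analytic gradients, best of four seeded restarts; n = 6
reaches the icosahedral optimum of 63.4°, n = 30 about 26°).  The achieved
minimum antipodal angle is recorded on each scheme.  Direction sets are a
fixed part of the experimental design: experiments vary noise seeds, not
scheme seeds.

## Cumulant representation and degeneracy

To O(b²), log(S/S0) = −B:D + ½ B:C:B with D the diffusion tensor and C the
diffusion tensor covariance (minor and major index symmetries; its totally
symmetric part carries the kurtosis tensor via D̄²W = 3C_(ijkl),
D̄ = tr D/3).  For a Watson ODF both are transversely isotropic:
W = ω1P + ω2Q + ω3I and C = ⅓D̄²W + ζ1R + ζ2J in the standard tensor-form
basis, so the scalar content is the DK quintuple (D∥, D⊥, W∥, W⊥, W̄) plus
the two covariance invariants.  The fifth DK relation evaluates the moment
equations at the oblique projection ξ = 1/√2, which identifies W̄ as the
orientational average of the directional kurtosis — this reproduces the
reference worked example exactly (W̄ = 0.926).

The inverse problem is organized through α = fDa+(1−f)Δe, β = (1−f)De⊥,
γ = fDa²+(1−f)Δe², δ = (1−f)ΔeDe⊥, ε = (1−f)De⊥² (Δe = De∥−De⊥): at fixed
κ these solve a 2×2 and a 3×3 linear system whose determinants are p2 and
−p2·p4/2 (hence singular only at κ = 0, the *proper* degeneracy), and the
constraint that five auxiliaries stem from four parameters yields the
coupling equation γ(ε−β²) = α²ε + δ² − 2αβδ.  Roots in κ are found by
scanning 4000 points uniform in c2 ∈ (1/3, c2(10³)), Brent-polishing sign
changes, and additionally polishing local minima of |residual| to catch
tangential double roots (which arise as De⊥ → 0 or f → 0 and would
otherwise be missed); tangential candidates are accepted only when the
back-mapped parameters reproduce the source DK values to 10⁻⁶.  Back-mapping
uses f = 1−β²/ε, Da = (αε−βδ)/(ε−β²), Δe = δ/β, De⊥ = ε/β; ε ≤ 0 or
ε = β² are the apparent degeneracies f = 0/1 and are reported as boundary
cases.  Infeasible solutions (e.g. negative De⊥) are flagged, not dropped.
Root counts are 1, 2 or 4; a censused ~0.1% of boundary-region samples show
3 (a merged double root counted once) and are returned in an `anomalies`
list.

With the DDE invariants, κ is the unique root of
h4(1,κ)/h4(0,κ) = [⅓W∥D̄² − (3/2)(ζ1+ζ2) + (D∥−D⊥)²]/[⅓W⊥D̄² − (3/2)ζ2];
the left side is strictly increasing (verified on a dense grid), and with κ
fixed the linear systems make the inverse map single-valued — the model's
injectivity under combined linear+planar encoding.

## Estimation

Stage 1: weighted linear least squares of log S against the b-tensor
contraction gives the fiber direction (principal eigenvector) and the
apparent tensor.  Only the innermost shell (b ≤ 1) enters this fit: with
both shells the O(b²) terms tilt the eigenvector by ~0.5° under 30-direction
sampling, which would dominate the noiseless cost floor.  S0 is taken as
the mean of the b = 0 measurements (the log-linear intercept is biased low
by ~5% at b ≤ 2 on dispersed substrates); the Rician bias of that mean is
+S0/(4·SNR²), negligible at SNR 50.

Stage 2: bounded nonlinear least squares on (f, Da, De∥, De⊥, c2) with
bounds f ∈ [0,1], diffusivities ∈ [0,4] μm²/ms, c2 ∈ (1/3+10⁻³, 0.999),
Gaussian objective F(θ) = Σᵢ (Sᵢ − S(Bᵢ,θ))² (adequate at SNR 50), and 30
random initializations drawn uniformly within bounds from per-realization
seeds.  All starts are first advanced together by a batched projected
Levenberg–Marquardt probe (vectorized across starts and noise realizations;
single precision with a polynomial I0e approximation accurate to 1.3×10⁻⁴,
18 iterations, survivor trimming after 6), then the best basins per
realization are polished with scipy's trust-region-reflective solver on the
exact double-precision model (tolerances 10⁻¹²).  This is functionally the
classic "30 random starts + trust region, keep the lowest residue"
procedure at ~0.2 s per fit.  Limitations: the prefit assumes a prolate
diffusion tensor, so parameter regions with De⊥ ≫ De∥ and high alignment
(oblate voxels, outside the study's feasible region) mis-estimate μ̂ and are
not recovered; near f = 1 the extra-neurite parameters are weakly
identified by any estimator.

## Experiments and scaling

*Bimodality experiment*: ground truths
SET A = (0.38, 0.50, 2.10, 0.74, κ=64) and SET B = (0.77, 2.23, 0.16,
1.48, κ=4) (posterior-limb-of-internal-capsule estimates), protocols SDE
and DDE30+30, SNR 50, default 2500 Rician realizations, 30 starts.  The
acceptance run uses 200 realizations — enough that the two-means silhouette
of the SDE Da estimates (a bimodality score) exceeds 0.6 with well-separated
centers near 0.5 and 2.65 while the DDE histogram is unimodal at the truth.
On noiseless data the SDE cost at the spurious point is ~2×10⁻⁴, two orders
below the SNR-50 noise floor (Σσ² ≈ 0.026), whereas the DDE30+30 cost there
is ~0.18 — the quantitative form of "DDE separates the minima".

*Grid experiment*: the 5×5×3×3×6 = 1350-point grid over
f ∈ {0.1…0.9}, Da ∈ {0.3…2.3}, De∥ ∈ {0.8,1.3,1.8}, De⊥ ∈ {0.5,1.0,1.5},
κ ∈ {0.84…33.7} (c2 = 0.41…0.97), five protocols, 50 noise realizations
per cell at full scale.  Per-cell seeds are keyed to (grid index, protocol,
purpose), so any subset reproduces exactly its slice of the full sweep and
results are independent of batching/execution order.  The desk-scale
acceptance run uses a 27-point subgrid (f, Da, κ corners/centers at the
central De∥, De⊥) with 10 realizations — about 1350 fits, minutes of CPU —
and reproduces the reference protocol ranking: mixed protocols (DDE40+20,
DDE30+30) clearly best on every parameter; SDE and pure-planar DDE0+60
essentially tied worst on Da; DDE0+60 distinctly worst on f and c2.
Dispersion errors are always scored on the c2 scale.  RMSE maps project
onto axis subsets by the quadratic mean over the remaining dimensions.

The solution-count census samples f ~ U(0,1), diffusivities ~ U(0,3),
κ via c2 ~ U(1/3, 0.98) — the sampling law behind the reference
percentages is unstated, so those are matched approximately, and both the
all-roots and feasibility-filtered tallies are reported.

## Numerical choices

Tolerances: root polishing to relative 10⁻¹²–10⁻¹⁴ in κ; duplicate roots
merged at 10⁻⁴ relative; DK back-map closure asserted at 10⁻⁸ in tests.
Degenerate inputs: κ = 0 raises on inversion (singular systems); isotropic
D raises in the unique-κ solve; f = 0/1 raise as boundary cases.  Ties in
multi-start selection resolve to the lowest stable index.  File formats
round-trip bit-identically via repr-precision floats.

## What the synthetic data does and does not show

The generator *is* the study's forward model: passing tests demonstrate
internal correctness of the theory (forward maps, degeneracy structure,
injectivity) and estimator behaviour under idealized Rician noise with a
known, spatially uniform, single-fiber-population substrate.  It does not
emulate finite axon radius, exchange, crossing fibers or non-Watson
dispersion, multi-voxel spatial structure, motion/eddy artefacts, or
noise-floor effects at low SNR — conclusions about real acquisitions
require the corresponding validations.
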