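# Methods

This note records the models, numerical choices and known limitations of
`gaussfr`, in the spirit of a statistical-software methods appendix.

## The manifold and its chart conventions

We work on M = ℝⁿ × SPD(n) with the Fisher information metric of the
normal family,
⟨(x₁,B₁),(x₂,B₂)⟩_θ = x₁ᵀΣ⁻¹x₂ + ½ tr(Σ⁻¹B₁Σ⁻¹B₂).
Affine maps ψ_(c,Q)(μ,Σ) = (Qμ+c, QΣQᵀ), Q invertible, are isometries;
every two-point problem is first *canonicalized* by whitening with the
first argument (Q = Σ₁^{-1/2}, c = −Qμ₁), reducing it to the base point
(0, Iₙ) against a single Gaussian θ₃. Whitening by the first argument is a
fixed convention; symmetry of every distance is a property we test, not
something the construction gives for free.

Univariate normals are treated in the half-plane chart (u, σ) with
u = μ/√2, in which the Fisher metric is √2 times the standard hyperbolic
half-plane metric. The explicit scaling matters in two places: the
distance formula d = √2·acosh(1 + ((u₁−u₂)² + (σ₁−σ₂)²)/(2σ₁σ₂)), and the
map onto the Minkowski hyperboloid x = (u²+v²−1)/(2v), y = u/v,
z = (u²+v²+1)/(2v), chosen precisely so that
√2·acosh(z₁z₂ − x₁x₂ − y₁y₂) reproduces the Fisher–Rao distance exactly —
the property the linear-averaging (Galperin) centroid construction needs.
The quotient-log form of the same distance is implemented as an
independent cross-check only.

## SPD matrix functions and validation

All matrix functions (sqrt, inverse sqrt, log, exp) go through the
symmetric eigendecomposition, not Schur or Padé forms: every input is
symmetric, and the spectral form extends naturally to the kernel limits
needed by the geodesic formula. Validation tolerances: symmetry within
1e-9 of the matrix scale (symmetrized on construction), smallest
eigenvalue above 1e-12 of scale. Eigen-basis order and sign are
unconstrained; every downstream formula is invariant to them except the
diagonalization upper bound UB1, where each eigenvalue is paired with the
mean coordinate of its own eigenvector (for repeated eigenvalues any
orthonormal basis gives *a* valid bound, not a canonical one).

## Closed forms

* Fixed covariance: d = √((μ₁−μ₂)ᵀΣ₀⁻¹(μ₁−μ₂)) (Mahalanobis). Not
  totally geodesic — an upper bound on the true distance of the pair.
* Fixed mean: d = √(½Σ log²λᵢ), λᵢ eigenvalues of Σ₁^{-1/2}Σ₂Σ₁^{-1/2},
  computed as a generalized symmetric eigenproblem. Totally geodesic.
* Diagonal covariances: product metric over per-coordinate univariate
  distances. Not totally geodesic.
* Diagonal + mean on the e₁ axis: same sum but exact in M (totally
  geodesic submanifold).
* Common covariance (exact in M): Householder P with
  P(μ₂−μ₁) = |μ₂−μ₁|e₁ (sign-stable variant: reflect through u + sign(u₁)e₁
  and flip the first coordinate when needed; P = I when already aligned),
  then PΣPᵀ = UDUᵀ with U unit-upper-triangular, computed by Cholesky of
  the index-reversed matrix conjugated back. Unit-triangularity is what
  keeps an e₁-aligned mean on the axis (U⁻¹e₁ = e₁). The distance is the
  e₁-axis closed form between (0, D) and (|μ₂−μ₁|e₁, D); only the first
  diagonal entry contributes a mean term.
* "Same covariance" is decided at relative Frobenius tolerance 1e-9.

## The explicit geodesic and its kernels

In natural coordinates (δ, Δ) = (Σ⁻¹μ, Σ⁻¹) the geodesic from (0, I) with
tangent (x, B) is a closed form in cosh(tG), sinh(tG), G² = B² + 2xxᵀ.
We never form a generalized inverse of G: the three scalar kernels
cosh(tg)−1, (cosh(tg)−1)/g², sinh(tg)/g are applied to the eigenvalues of
G², with two-term series limits below g = 1e-6 (errors O(g⁴), far below
solver tolerances). The geodesic has constant speed √(½trB² + |x|²),
which is therefore the distance to the time-1 endpoint.

## Geodesic shooting

The boundary-value problem is solved in the whitened frame: find (x, B)
such that the time-1 endpoint matches the target natural coordinates.
The residual stacks the upper triangle of Δ(1) − Δ* (off-diagonals
weighted by √2 so the 2-norm is Frobenius) and δ(1) − δ*, solved by
Levenberg–Marquardt with finite-difference Jacobians from four starts
(matrix-log heuristic B₀ = −log Δ*, x₀ = δ*; scaled variants; zero).
Residuals for tangents of speed above 50 are clamped to keep the cosh
terms in range. Among converged starts the smallest-speed solution is
returned: the boundary system can have several genuine geodesic branches,
and only the shortest is the distance. The default endpoint tolerance is
1e-8, which empirically yields distances accurate to better than 1e-5 on
pairs with closed-form answers (n = 2, 3).

## Mirrored pairs

A pair is *mirrored* when, after rotating the mean difference onto e₁
(the "canonical frame"), both means lie on the e₁ axis and
Σ₂ = M₁Σ₁M₁, M₁ = diag(−1, 1, …, 1). The geodesic midpoint then has mean
((μ₁+μ₂)/2, η) and block-diagonal covariance Σ_½ = blockdiag(d₁₁², D),
and the midpoint tangent has the arrowhead form (x e₁, B) with B carrying
only first-row/column entries b. With L = Σ_½^{1/2} (block form), the
time-1 endpoint condition

    Δ(1) = L Σ₂⁻¹ L,   δ(1) = L Σ₂⁻¹ (μ₂ − μ_½)

is a square system of order n + n(n+1)/2 in (x, b, η, log d₁₁, log D),
solved by the Powell hybrid method with finite-difference Jacobians.
Log-parametrization keeps the midpoint covariance SPD; log-parameters are
clipped to ±12 during exploration. The distance is 2√(Σbₗ² + x²).
For widely separated means (separation ≳ 4 for the reference covariances)
the direct multistart stalls, and the solver switches to homotopy
continuation: shrink both means toward the origin, solve the easy
problem, then walk the separation back up warm-starting each step.
All solutions are verified by the residual max-norm (tolerance 1e-10)
and, in tests, by round-tripping γ(−1) = θ₁ and cross-checking against
geodesic shooting for moderate separations.

**Frame convention for the reference distances.** The reference mirrored
distances (2.77395, 3.67027, … , 7.87896) are indexed by the *separation*
of the means: the pair at index s has means ±s/2 on the e₁ axis. This is
forced by arithmetic, not choice: for means ±1 the Calvo–Oller lower
bound of the pair is already 3.4679 > 2.77395, so the printed values can
only correspond to the half-separation construction — which the solver
reproduces to five significant figures at every index, and which the
shooting solver confirms independently at separations 1–3.

## Bounds

* Lower (Calvo–Oller): embed θ = (μ, Σ) as the SPD block matrix
  [[Σ+μμᵀ, μ],[μᵀ, 1]] of order n+1 and take √(½Σ log²λᵢ) of the
  generalized eigenvalues. A true metric on M.
* UB1: whiten, diagonalize A = QΛQᵀ, pair each √λᵢ (standard deviation,
  not variance — only this choice collapses UB1 to the exact fixed-mean
  distance on commuting diagonal pairs) with the mean coordinate of its
  eigenvector, and sum univariate squared distances.
* UB3 (analytic): triangle inequality through (μ₃, Σ̄) with
  Σ̄ = Pᵀ diag(σ*², 1, …, 1) P and σ*² = (|μ₃|² + 2)/2 — the foot of the
  hyperbolic perpendicular from (0,1) onto the line μ = |μ₃|, verified in
  tests against a brute-force 1-D minimization.
* UB2 (numeric): the same decomposition with the whole intermediate
  diagonal optimized, in log standard-deviation coordinates, by
  Nelder–Mead from two starts (the UB3 point and the identity). Any
  output is a valid bound whether or not the optimizer converged; by
  construction UB2 ≤ UB3.

Empirically (and reproduced in tests): UB1 is the best bound for small
mean offsets; UB2/UB3 win for large offsets *except* near rotation angles
0 and π/2, where the pair is diagonal-with-axis-mean and UB1 = UB2 =
exact. A strict "UB2/UB3 always best at large offset" claim is therefore
false at and near those angles; the tests assert the orderings pointwise
and document this edge honestly rather than averaging it away.

## Mixture simplification

Components of a diagonal Gaussian mixture are clustered agglomeratively
(naive O(m³) scan per merge — intended for m ≤ 64; ties broken toward the
smallest id pair) under single/complete/average linkage of the diagonal
product-metric distance. Complete linkage is the default. Each cluster is
replaced either by the per-coordinate hyperbolic centroid (Minkowski
averaging, then projection) or by per-coordinate moment matching — the
left-sided KL centroid of the exponential family, i.e. the single
Gaussian minimizing KL(cluster-submixture ‖ g). Replacement weights are
member-weight sums, so simplified mixtures stay normalized exactly.

KL(f‖g) between mixtures has no closed form and is estimated by Monte
Carlo with n = 5000 draws by default (standard error reported; identical
mixtures give exactly 0 by term-wise cancellation). Model-size selection
scans l = 1..m upward and stops at the first l meeting the KL budget τ —
the scan is explicit because KL need not be monotone in l. Pixel
classification uses the maximum unweighted component density (ties to the
lowest index); mixture weights are deliberately ignored in that rule.
EM fitting of diagonal mixtures delegates to scikit-learn's
`GaussianMixture` (diagonal covariances, variance floor 1e-6, k-means++
initialization).

## Synthetic data

The generators produce exactly-structured fixtures: rotated-eigenvalue
pairs with prescribed spectrum {λ₁, λ₂} (defaults 2 and 0.5, mean offsets
1 and 10, a 65-point rotation grid on [0, π/2] — the regimes in which the
bounds are compared); mirrored pairs with means ±s/2 and conjugated
covariances; planted mixtures with `groups` clusters of near-duplicate
components (group centers 12 apart per coordinate, mean jitter 0.15,
±20% log-σ jitter — between/within distance ratios well above any linkage
ambiguity); and RGB images sampled pixel-wise from a 3-D mixture with
ground-truth labels. Every generator is bit-reproducible from its seed.

What the planted fixtures do *not* emulate: real image mixtures have
overlapping, anisotropic, weight-skewed components, so partition recovery
there is harder than on these fixtures. Passing the planted tests shows
the clustering machinery is correct, not that segmentation of natural
images at a given l is optimal.

## Problem sizes and determinism

Tests and the reproduction script run at n = 2 and 3 (where closed forms
exist to cross-check against), 200 random pairs for bound sandwiches,
50 pairs per closed-form family for shooting agreement, and 12-component
planted mixtures with 5 Monte-Carlo seeds — sizes at which every check is
exact or statistically decisive while the whole suite stays in the
minutes range. All randomness is seeded; solver multistarts use fixed
internal seeds so distances are deterministic functions of their inputs.

## Known limitations

* Geodesic shooting is reliable for moderate separations and dimensions
  (tested n ≤ 3); for strongly separated mirrored pairs use the system
  solver (the dispatcher does this automatically).
* UB1 is basis-dependent under repeated eigenvalues of the whitened
  covariance.
* The agglomeration is quadratic-memory/cubic-time in the component
  count; it is not meant for mixtures beyond a few hundred components.
* `fisher_rao` returns shooting results for generic pairs; these carry
  the solver's endpoint tolerance rather than closed-form accuracy.
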