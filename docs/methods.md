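# Methods

This note documents the statistical model behind chronopick, the numerical
choices made in implementing it, what the synthetic generators do and do not
emulate, and the known limitations. It is the reference for anyone auditing
the package's behaviour or adapting it.

## Problem statement

Given n example curves sampled on a common grid τ₁ < … < τ_N (gene
expression over a time course, temperatures over a year, growth rates over
age, …), choose the subset **t** = {t₁ < … < t_M} ⊂ **τ** of M time points
such that, when a *future* curve is observed only at **t** and interpolated,
the expected squared L² distance to the fully sampled curve is minimal. The
expectation is over a probability density of curves fitted to the examples —
the selection is meant to generalise to perturbed repeats of the experiment,
not to re-fit the training curves.

## The curve density

Curves are compared elastically through the square-root slope function
(SRSF), q(t) = sign(ḟ(t))·√|ḟ(t)|, under which reparameterisation acts by
(q, γ) ↦ (q∘γ)·√γ̇ and the elastic distance is the plain L² distance.
Fitting proceeds as:

1. **Template alignment.** All curves are mapped to a normalised [0, 1]
   grid. The template SRSF is initialised as the cross-sectional mean of
   the input SRSFs; each round aligns every curve to the template with a
   pairwise dynamic program and replaces the template with the mean of the
   aligned SRSFs. The iteration stops when the template's sup-norm change
   drops below 1e−4, when it stops decreasing (the warping paths are
   grid-quantised, so the change typically plateaus at a small oscillation
   that further rounds only revisit), or after 20 rounds.
2. **Warp geometry.** The SRSF of a warp, ψ = √γ̇, has unit L² norm, so
   warps live on the unit sphere in L². The Karcher (Fréchet) mean of the
   warps is computed by iterative tangent averaging; each warp is then
   mapped to the tangent space at the mean with the sphere log map.
3. **Functional PCA, separately for phase and amplitude.** One fPCA is
   fitted to the warp tangent vectors (phase), one to the aligned curves
   (amplitude, already in a linear space). Components are retained up to a
   cumulative explained-variance fraction of 0.95 (configurable,
   `variance_threshold`, applied independently to both models). Dropping
   the residual smooths the sampled curves and damps measurement noise.
4. **The density.** Independent zero-mean Gaussians with variances equal to
   the eigenvalues along each retained axis. A sample is drawn by drawing
   scores, reconstructing a tangent vector and an amplitude function,
   exponentiating the tangent vector to a warp γ, and evaluating the
   amplitude at γ(t).

**Composition convention.** The alignment produces warps γ_a with
f_a(γ_a(t)) aligned; the generative warp of f_a = a∘γ is therefore γ_a⁻¹.
The phase fPCA is fitted on the *inverses* of the alignment warps, so that
sampling composes amplitude∘γ and fitting/sampling are mutually consistent.

## The selection objectives

With w(t; **t**, μ) the sample curve μ interpolated from the points **t**
(linear by default, B-spline of degree R optionally; outside [t₁, t_M] the
reconstruction is held constant at the nearest selected value), the
Monte-Carlo estimator over J samples (default J = 1000, factor 1/J kept for
scale stability) scores:

* **f1** = mean_j ‖w_j(·; **τ**) − w_j(·; **t**)‖²_{L²[τ₁,τ_N]} — curve
  shape. Optional per-curve importance weights multiply the summands (f1
  only; weights with f2/f3 are rejected).
* **f2** — the same applied to d_j = g − w_j for a control curve g (or one
  control draw per sample when the control is itself a fitted density).
  f1 is exactly f2 with g ≡ 0.
* **f3** — the inverse-coefficient-of-variation criterion: d_j is divided
  by its pointwise standard deviation across the J draws (floored at
  ε·max SD, ε = 1e−6) before the f2 machinery is applied. Windows whose
  variability is noise contribute O(1) normalised error regardless of their
  raw magnitude, so systematic differences in quiet windows dominate the
  selection. The alternative reading — normalising the subset-dependent
  reconstruction error z by Var(z) — is available (`cv_target=False`) but
  is *not* the default because it is degenerate as a selection objective:
  a selection anchored at a high-noise time point inflates Var(z)
  everywhere, cancelling its own systematic error, so the optimiser is
  drawn into noisy regions instead of away from them (we measured the f3
  fraction of points inside a pure-noise window at ~0.85 under that
  reading, versus ~0.05 under the default and ~0.4 for f1).
* When the population carries no variability at all (pointwise SD ≡ 0 up to
  round-off), the f3 normalisation is skipped and f3 degrades gracefully to
  f2.

All integrals are trapezoid sums on the observed grid in original time
units; no uniform spacing is assumed.

## Exact search

Nodes 0 (start), 1..N (time points), N+1 (end) form a DAG with forward
edges only; edge(i, k) is the mean (over the J samples) squared L² error on
[τᵢ, τₖ] when only τᵢ and τₖ are sampled (start/end edges use constant
extrapolation from their single real point, so the first/last grid times
are *not* forced into the selection; `pin_endpoints` forces them). The
optimal M-point design is the cheapest start→end path with exactly M+1
edges, computed by the fixed-edge-count shortest-path recursion
Θ(j, k) = min_{i<j}[Θ(i, k−1) + edge(i, j)] — exact, O(N²M). Ties break
toward the lexicographically smallest index sequence, identically in the DP
and in the brute-force enumerator used as its oracle, and the enumerator
accumulates edge costs in the same associative order so that agreement is
bitwise.

**Spline mode.** With degree-R interpolation the edge cost depends on the R
previous points; these are recovered approximately from the traceback. The
DP is run on the forward and on the time-reversed grid (the paper-style
remedy for the de Boor edge effects), the exact linear-mode selection is
kept as a third candidate, and the best of the three under exact full-spline
re-scoring is returned — so spline mode never returns anything worse than
re-scoring the linear selection with splines.

## Numerical choices

* **Curve derivatives** (for the SRSF): central differences in the
  interior, one-sided at the boundaries; on uniform grids the scalar-spacing
  formula is used so constants and straight lines transform exactly.
  Reconstruction (cumulative trapezoid of q|q|) is first-order in the grid
  spacing.
* **Warp ψ representation**: ψ values live at grid-segment midpoints,
  ψ_i = √(Δγ_i/Δt_i), with segment lengths as quadrature weights. Then
  Σψ²Δt telescopes to exactly γ(1) − γ(0) = 1, so the unit-norm invariant
  and the γ↔ψ round-trip hold to machine precision even for warps with
  unbounded derivative; the sphere exp/log maps are mutually inverse
  exactly. Tangent vectors (and the phase fPCA) use the same midpoint
  representation.
* **Alignment DP**: warping paths are piecewise-linear through grid nodes,
  with per-segment slopes from the coprime step lattice |di|,|dj| ≤ 6 and
  slope ∈ [1/4, 4] (both configurable); q₂ is linearly interpolated.
* **Elastic regularisation.** `align_pair` accepts a penalty weight on
  ∫(√γ̇ − 1)² dt. Pairwise alignment and D_y default to penalty 0 (the pure
  elastic distance). *Density fitting* defaults to penalty 1.0: wherever a
  curve is flat its SRSF is ≈ 0 and the warp is unidentified from the data,
  so unpenalised alignment fills those regions with arbitrary path jitter
  that inflates the phase variance (we measured a persistent +35–50%
  inflation of the leading phase eigenvalue on data with known warps); the
  penalty pins the slope to 1 there while barely biasing regions the data
  identifies, bringing recovery errors to a few percent. The reported D_y
  always excludes the penalty term.
* **Monotonicity repair**: a sampled tangent vector long enough to push
  ψ negative has the negative values clipped to zero and the warp
  renormalised to end at 1; occurrences are counted and reported via a
  warning.
* **fPCA**: eigen-decomposition of the quadrature-weighted covariance
  (sample covariance, n−1); eigenfunctions orthonormal under the grid inner
  product; eigenvalues below 1e−12 of the leading one are discarded as
  round-off. Identical inputs yield an explicitly flagged zero-variance
  model whose samples reproduce the common curve exactly.
* **Tie-breaks and determinism**: one seed drives a run; per-stage
  generators are spawned from it, recorded in every output, and all seeds
  stay below 2³¹.

## Synthetic generators

The generators define controlled populations with known structure; all are
pure functions of (config, seed) on the unit grid.

* `skew_gaussian`: f(t) = A·2·φ((t−m)/s)·Φ(α(t−m)/s) with
  m ∈ [0.3, 0.7], s ∈ [0.05, 0.2], α ∈ [−5, 5], A ∈ [0.5, 1.5] drawn
  uniformly — small families of uni-modal bursts with varied location,
  width, asymmetry and height, the minimal realistic input (triplets
  upward) for density fitting.
* `warped_template`: a Gaussian-bump template composed with warps
  γ(t) = (e^{at} − 1)/(e^a − 1), a ~ U(−strength, strength) — pure phase
  variability with ground truth returned for recovery tests.
* `noisy_window`: control baseline 1 + 0.3·sin(2πt); experimental curves
  add a systematic bump (height 1.0, per-curve amplitude jitter SD 0.1)
  inside an informative window (0.55–0.9) and two smooth random bumps
  (coefficient SD 0.8) inside a disjoint noisy window (0.05–0.35) — the
  setting in which f3 should, and f1 should not, avoid the noisy region.

What they do *not* emulate: measurement noise at the grid level (curves are
smooth by construction), heteroscedastic replicate structure, correlated
gene families, or the scale and autocorrelation of any real dataset.
Passing tests on these populations demonstrate the estimators and the
search behave as designed, not that the fitted density is adequate for any
particular experiment — always plot draws from the fitted density against
the real curves before trusting a selection.

## Evaluation design and problem sizes

Held-out evaluation splits the curves (default 50/50; a one-third training
fraction is supported), fits the density and selects on the training half
only, and scores every strategy by the per-curve squared L² error of
reconstructing the held-out curves from the selected points (differences
from the control when one is given; the test reconstruction uses the same
interpolation the selection was made with). The package's own acceptance
checks run, per replicate, on 40 skew-Gaussian curves on a 25-point grid
with M = 8 and J = 1000 (10 replicates), and on 12 noisy-window curves on a
41-point grid with M = 6 and J = 500 (20 replicates); registration
recovery and variance recovery use 101-point grids (200 curves for the
latter). These sizes resolve the structures involved — the 101-point grid
is needed because the variance-recovery warps deviate from identity by only
~2 grid cells at 101 points — while keeping a full run of the suite in the
low minutes.

## Known limitations

* The tangent-space linearisation of the warp sphere is faithful near the
  Karcher mean but exaggerates distances between pairs of outlying warps;
  no correction is applied.
* Phase–amplitude separation is identifiable only where curves have slope:
  amplitude changes that mimic feature shifts (anything other than scaling)
  are partially absorbed into phase by *any* elastic method, biasing the
  phase variance upward. The elastic penalty mitigates, not eliminates,
  this.
* The DP returns a single optimal selection with no confidence measure;
  near-ties between quite different designs are invisible in the output.
* Spline-mode selection is approximate (history via traceback); only the
  final re-scoring is exact.
* The monotone-refinement property (adding a point never hurts) holds for
  interior refinements and, empirically, for refining the DP optimum, but
  not for arbitrary selections: a point added beyond the current endpoints
  moves the constant-extrapolated tails and can increase the error.
* Input curves must be complete on a common grid; missing values are
  rejected rather than imputed.
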