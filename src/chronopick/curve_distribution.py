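"""Non-parametric probability density over curves.

The density is built in two independent pieces, following the standard
phase/amplitude decomposition of functional data:

* **phase (x-deformations)** — the generative warps of the input curves are
  linearised at their Karcher mean via the sphere log map, and a functional
  PCA is fitted to the resulting tangent vectors;
* **amplitude (y-deformations)** — a functional PCA is fitted directly to
  the aligned curves (L² is already linear, no linearisation needed).

Independent zero-mean Gaussians with variances equal to the eigenvalues are
fitted along each retained principal axis, so a curve sample is obtained by
drawing scores, reconstructing a tangent vector and an amplitude function,
exponentiating the tangent vector to a warp γ, and evaluating the amplitude
at γ(t).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .curve_io import AffineMap, CurveSet, TimeGrid
from .registration import (
    AlignmentResult,
    WarpingFunction,
    _exp_psi,
    _psi_to_gamma,
    align_set,
    karcher_mean_warps,
    log_map,
    trapezoid_weights,
)

__all__ = ["FPCAModel", "CurveDistribution", "SampledCurves",
           "fit_fpca", "fit_distribution", "sample_curves"]


@dataclass
class FPCAModel:
    """Functional PCA of a set of functions on a common grid.

    Eigenfunctions are orthonormal under the trapezoid-weighted grid inner
    product; eigenvalues are the per-axis score variances (sample covariance
    with n−1 in the denominator), in non-increasing order.
    """

    times: np.ndarray
    mean_function: np.ndarray
    eigenfunctions: np.ndarray      # (k, N), rows = components
    eigenvalues: np.ndarray         # (k,), non-increasing, >= 0
    scores: np.ndarray              # (n_inputs, k)
    n_components: int               # retained for sampling/smoothing
    total_variance: float
    degenerate: bool = False        # no variability in the inputs

    def reconstruct(self, scores: np.ndarray, n_components: Optional[int] = None) -> np.ndarray:
        """mean + Σ score_i · φ_i using the first ``n_components`` axes."""
        k = self.eigenfunctions.shape[0] if n_components is None else n_components
        s = np.atleast_2d(np.asarray(scores, dtype=float))[:, :k]
        out = self.mean_function + s @ self.eigenfunctions[:k]
        return out if np.asarray(scores).ndim > 1 else out[0]

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        if self.total_variance <= 0:
            return np.zeros_like(self.eigenvalues)
        return self.eigenvalues / self.total_variance


def fit_fpca(
    functions: np.ndarray,
    times: np.ndarray,
    variance_threshold: float = 0.95,
    quad_weights: Optional[np.ndarray] = None,
) -> FPCAModel:
    """Eigen-decompose the grid-weighted covariance of a set of functions.

    Retains the smallest number of components whose cumulative eigenvalue
    fraction reaches ``variance_threshold``.  With fewer than two distinct
    inputs the model is all-zero and flagged ``degenerate``.  The inner
    product defaults to trapezoid quadrature on ``times``; pass
    ``quad_weights`` for functions represented at segment midpoints.
    """
    X = np.atleast_2d(np.asarray(functions, dtype=float))
    if X.shape[0] < 2:
        raise ValueError("fit_fpca needs at least 2 functions")
    if not (0 < variance_threshold <= 1):
        raise ValueError("variance_threshold must be in (0, 1]")
    t = np.asarray(times, dtype=float)
    n, N = X.shape
    mean = X.mean(axis=0)
    Xc = X - mean

    w = trapezoid_weights(t) if quad_weights is None else np.asarray(quad_weights)
    if w.shape != (N,):
        raise ValueError("quadrature weights must match the function length")
    sw = np.sqrt(w)
    A = Xc * sw                                   # rows in the weighted space
    C = (A.T @ A) / (n - 1)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    evecs = evecs[:, order]

    total = float(evals.sum())
    if total <= 0 or evals[0] <= 1e-15 * max(1.0, float(np.abs(X).max()) ** 2):
        return FPCAModel(
            times=t, mean_function=mean,
            eigenfunctions=np.zeros((0, N)), eigenvalues=np.zeros(0),
            scores=np.zeros((n, 0)), n_components=0,
            total_variance=0.0, degenerate=True,
        )

    keep = evals > evals[0] * 1e-12
    keep[min(n - 1, N):] = False                  # rank bound
    evals = evals[keep]
    phis = (evecs[:, keep] / sw[:, None]).T       # orthonormal under ⟨·,·⟩_w
    scores = Xc @ (w[:, None] * phis.T)

    frac = np.cumsum(evals) / total
    n_comp = int(np.searchsorted(frac, variance_threshold - 1e-12) + 1)
    n_comp = min(n_comp, evals.size)
    return FPCAModel(
        times=t, mean_function=mean, eigenfunctions=phis,
        eigenvalues=evals, scores=scores, n_components=n_comp,
        total_variance=total, degenerate=False,
    )


@dataclass
class CurveDistribution:
    """The fitted probability density over curves P(μ).

    ``warp_model`` is an fPCA of tangent vectors (at the Karcher mean) of the
    *generative* warps, i.e. the inverses of the alignment warps, so that a
    sampled curve is amplitude∘γ.  ``amplitude_model`` is an fPCA of the
    aligned curves.
    """

    grid: TimeGrid                  # original sampling grid
    unit_grid: TimeGrid
    affine: AffineMap
    karcher_warp: WarpingFunction
    warp_model: FPCAModel
    amplitude_model: FPCAModel
    alignment: Optional[AlignmentResult] = None

    @property
    def component_variances(self) -> dict[str, np.ndarray]:
        return {
            "warp": self.warp_model.eigenvalues[: self.warp_model.n_components],
            "amplitude": self.amplitude_model.eigenvalues[: self.amplitude_model.n_components],
        }

    def mean_curve(self) -> np.ndarray:
        """The curve obtained with every score set to zero."""
        u = self.unit_grid.times
        gamma = _mean_warp_gamma(self)
        return np.interp(gamma, u, self.amplitude_model.mean_function)


def _mean_warp_gamma(dist: CurveDistribution) -> np.ndarray:
    u = dist.unit_grid.times
    vbar = dist.warp_model.mean_function
    psi, _ = _exp_psi(dist.karcher_warp.psi(), vbar, u)
    return _psi_to_gamma(psi, u)


@dataclass
class SampledCurves:
    """J perturbation curves drawn from a CurveDistribution."""

    grid: TimeGrid
    values: np.ndarray              # (J, N)
    seed: Optional[int] = None
    parameters: Optional[np.ndarray] = None   # drawn score vectors, (J, kx+ky)
    weights: Optional[np.ndarray] = None      # optional per-sample weights

    @property
    def n_samples(self) -> int:
        return int(self.values.shape[0])


def fit_distribution(
    curves: CurveSet,
    variance_threshold: float = 0.95,
    tol: float = 1e-4,
    max_iter: int = 20,
    penalty: float = 1.0,
    keep_alignment: bool = True,
) -> CurveDistribution:
    """Fit the curve density: align, take Karcher mean, fPCA phase+amplitude.

    ``penalty`` is the elastic-regularisation weight of the alignment
    (see :func:`chronopick.registration.align_pair`).  Density fitting
    defaults to 1.0: wherever a curve is flat its SRSF is ~0 and the warp is
    unidentified from the data, so unpenalised alignment fills those regions
    with arbitrary path jitter that inflates the phase variance; the penalty
    pins the warp slope to 1 there while barely biasing data-identified
    regions.  Set 0.0 for the pure elastic objective.
    """
    if curves.n_curves < 2:
        raise ValueError("fit_distribution needs at least 2 curves "
                         "(3 or more recommended)")
    ar = align_set(curves, tol=tol, max_iter=max_iter, penalty=penalty)
    u = ar.grid.times

    gen_warps = [w.inverse() for w in ar.warps]
    gmean = karcher_mean_warps(gen_warps)
    tangents = np.stack([log_map(gmean, w).v for w in gen_warps])

    mid = 0.5 * (u[:-1] + u[1:])
    warp_model = fit_fpca(tangents, mid, variance_threshold,
                          quad_weights=np.diff(u))
    amplitude_model = fit_fpca(ar.aligned_values, u, variance_threshold)
    return CurveDistribution(
        grid=curves.grid,
        unit_grid=ar.grid,
        affine=ar.affine,
        karcher_warp=gmean,
        warp_model=warp_model,
        amplitude_model=amplitude_model,
        alignment=ar if keep_alignment else None,
    )


def sample_curves(dist: CurveDistribution, J: int, seed: int) -> SampledCurves:
    """Draw J curves from the density (deterministic given the seed).

    Per sample: independent N(0, λ_i) scores on each retained axis of both
    models; the tangent-space draw is exponentiated to a warp γ and the
    amplitude draw is evaluated at γ(t).
    """
    if J < 1:
        raise ValueError("J must be >= 1")
    rng = np.random.default_rng(seed)
    u = dist.unit_grid.times
    wm, am = dist.warp_model, dist.amplitude_model
    kx, ky = wm.n_components, am.n_components

    sx = rng.standard_normal((J, kx)) * np.sqrt(wm.eigenvalues[:kx])
    sy = rng.standard_normal((J, ky)) * np.sqrt(am.eigenvalues[:ky])
    tangents = wm.mean_function + (sx @ wm.eigenfunctions[:kx] if kx else 0.0)
    amplitudes = am.mean_function + (sy @ am.eigenfunctions[:ky] if ky else 0.0)
    tangents = np.broadcast_to(np.atleast_2d(tangents), (J, u.size - 1))
    amplitudes = np.broadcast_to(np.atleast_2d(amplitudes), (J, u.size))

    psi_base = dist.karcher_warp.psi()
    values = np.empty((J, u.size))
    n_repaired = 0
    for j in range(J):
        psi, clipped = _exp_psi(psi_base, tangents[j], u)
        n_repaired += clipped
        gamma = _psi_to_gamma(psi, u)
        values[j] = np.interp(gamma, u, amplitudes[j])
    if n_repaired:
        warnings.warn(
            f"sample_curves repaired monotonicity on {n_repaired}/{J} sampled warps",
            RuntimeWarning,
        )
    return SampledCurves(
        grid=dist.grid,
        values=values,
        seed=int(seed),
        parameters=np.hstack([sx, sy]),
    )
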