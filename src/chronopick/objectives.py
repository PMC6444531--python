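"""Reconstruction-from-subset interpolation, L² errors, and the Monte-Carlo
estimators of the three selection criteria.

* **f1** — expected squared L² error between each sampled curve and its
  reconstruction from the selected time points only.
* **f2** — the same, applied to the difference d = g − w between a control
  curve g and each sample (f1 is the special case g ≡ 0).
* **f3** — the same, applied to a variance-normalised difference (the
  inverse-coefficient-of-variation criterion); regions whose variability is
  pure noise are thereby down-weighted.  By default the *target* d = g − w
  is normalised by its pointwise standard deviation across the Monte-Carlo
  draws before the f2 machinery is applied (``cv_target=True``).  The
  alternative reading — normalising the subset-dependent reconstruction
  error z by its own pointwise variance — is available via
  ``cv_target=False``, but it is degenerate as a selection objective: a
  selection that anchors its reconstruction at a high-noise time point
  inflates Var(z) everywhere and thereby cancels its own systematic error,
  so the optimiser is *drawn into* noisy regions instead of away from them.

All integrals use the trapezoid rule on the observed grid, in original time
units.  The 1/J factor of the Monte-Carlo estimator is kept (it does not
change the argmin, and keeps values comparable across J).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy.interpolate import make_interp_spline

from .curve_io import Selection
from .curve_distribution import CurveDistribution, SampledCurves, sample_curves

__all__ = ["ObjectiveSpec", "interpolate_subset", "l2_error_sq",
           "difference_curves", "estimate_objective"]

CRITERIA = ("f1", "f2", "f3")


@dataclass
class ObjectiveSpec:
    """Configuration of a selection objective."""

    criterion: str = "f1"
    control: Optional[Union[np.ndarray, CurveDistribution]] = None
    J: int = 1000
    seed: int = 0
    interpolation: str = "linear"       # {"linear", "spline"}
    spline_degree: int = 3
    variance_floor: float = 1e-6        # ε for the f3 variance floor
    cv_target: bool = True              # f3: normalise the target d = g − w
                                        # (False: literal Var(z) normalisation)

    def __post_init__(self) -> None:
        if self.criterion not in CRITERIA:
            raise ValueError(f"criterion must be one of {CRITERIA}")
        if self.criterion in ("f2", "f3") and self.control is None:
            raise ValueError(f"criterion {self.criterion} requires a control curve")
        if self.J < 1:
            raise ValueError("J must be >= 1")
        if self.interpolation not in ("linear", "spline"):
            raise ValueError("interpolation must be 'linear' or 'spline'")
        if self.spline_degree < 1:
            raise ValueError("spline_degree must be >= 1")
        if self.control is not None and isinstance(self.control, np.ndarray):
            self.control = np.asarray(self.control, dtype=float)

    @property
    def effective_degree(self) -> int:
        return 1 if self.interpolation == "linear" else self.spline_degree


def interpolate_subset(
    values: np.ndarray,
    times: np.ndarray,
    subset: Sequence[int],
    interpolation: str = "linear",
    spline_degree: int = 3,
) -> np.ndarray:
    """Reconstruct curves on the full grid from their values at ``subset``.

    ``subset`` holds 0-based grid indices.  Outside [t_first, t_last] of the
    subset the reconstruction is held constant at the nearest selected value.
    If the spline degree is infeasible for the number of points, the largest
    feasible degree is used instead.
    """
    v = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    sub = np.asarray(sorted(set(int(i) for i in subset)), dtype=int)
    if sub.size == 0:
        raise ValueError("subset must be non-empty")
    if sub[0] < 0 or sub[-1] >= t.size:
        raise ValueError("subset indices out of grid range")
    st, sv = t[sub], v[..., sub]
    if sub.size == 1:
        return np.broadcast_to(sv[..., :1], v.shape).copy()
    tc = np.clip(t, st[0], st[-1])          # constant extrapolation at the ends
    k = 1 if interpolation == "linear" else min(spline_degree, sub.size - 1)
    if k == 1:
        # np.interp is exact at the nodes (unlike generic segment formulas)
        flat = sv.reshape(-1, sub.size)
        out = np.empty(flat.shape[:-1] + (t.size,))
        for i, row in enumerate(flat):
            out[i] = np.interp(tc, st, row)
        return out.reshape(v.shape[:-1] + (t.size,))
    return np.asarray(make_interp_spline(st, sv, k=k, axis=-1)(tc))


def l2_error_sq(
    a: np.ndarray,
    b: np.ndarray,
    times: np.ndarray,
    interval: Optional[tuple[int, int]] = None,
) -> np.ndarray | float:
    """Trapezoid approximation of ∫(a−b)² dt over a grid-index interval.

    ``interval`` is an inclusive (start, stop) pair of 0-based grid indices;
    the default is the whole grid.  Accepts batched inputs on the last axis.
    """
    t = np.asarray(times, dtype=float)
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    if interval is not None:
        i0, i1 = interval
        if i1 <= i0:
            return 0.0 if d.ndim == 1 else np.zeros(d.shape[:-1])
        d = d[..., i0:i1 + 1]
        t = t[i0:i1 + 1]
    out = np.trapezoid(d * d, t, axis=-1)
    return float(out) if out.ndim == 0 else out


def difference_curves(
    samples: SampledCurves,
    control: Union[np.ndarray, CurveDistribution],
    control_seed: Optional[int] = None,
) -> np.ndarray:
    """d_j(t) = g(t; ν_j) − w_j(t) on the full grid.

    A single control curve fixes ν; a CurveDistribution control draws one
    control per sample (product measure over experiment and control).
    """
    w = samples.values
    if isinstance(control, CurveDistribution):
        seed = samples.seed if control_seed is None else control_seed
        seed = 0 if seed is None else (int(seed) + 0x5F3759) % (2**31)
        g = sample_curves(control, samples.n_samples, seed).values
        if g.shape != w.shape:
            raise ValueError("control distribution grid does not match samples")
    else:
        g = np.asarray(control, dtype=float)
        if g.shape != (w.shape[1],):
            raise ValueError("control curve grid does not match samples")
        g = g[None, :]
    return g - w


def _criterion_curves(samples: SampledCurves, spec: ObjectiveSpec) -> np.ndarray:
    """The curves the L² machinery is applied to, per criterion."""
    if spec.criterion == "f1":
        return samples.values
    d = difference_curves(samples, spec.control)
    if spec.criterion == "f3" and spec.cv_target:
        sd = d.std(axis=0, ddof=1)
        scale = float(np.abs(d).max(initial=0.0))
        if float(sd.max(initial=0.0)) > 1e-12 * max(scale, 1e-300):
            d = d / np.maximum(sd, spec.variance_floor * float(sd.max()))
        # else: no population variability — f3 degrades gracefully to f2
    return d


def _interval_cost(
    curves: np.ndarray,
    times: np.ndarray,
    subset: Sequence[int],
    spec: ObjectiveSpec,
    interval: Optional[tuple[int, int]] = None,
    weights: Optional[np.ndarray] = None,
) -> float:
    """Mean (weighted) squared L² reconstruction error over an interval."""
    recon = interpolate_subset(curves, times, subset,
                               spec.interpolation, spec.spline_degree)
    if spec.criterion == "f3" and not spec.cv_target:
        z = recon - curves
        if curves.shape[0] < 3:
            raise ValueError("f3 needs at least 3 Monte-Carlo samples "
                             "to estimate the variance")
        i0, i1 = (0, times.size - 1) if interval is None else interval
        zi = z[:, i0:i1 + 1]
        var = zi.var(axis=0, ddof=1)
        vmax = float(var.max(initial=0.0))
        if vmax > 0:
            zi = zi / np.sqrt(np.maximum(var, spec.variance_floor * vmax))
        errs = np.trapezoid(zi * zi, times[i0:i1 + 1], axis=-1)
    else:
        errs = l2_error_sq(curves, recon, times, interval)
    errs = np.atleast_1d(errs)
    if weights is not None:
        return float(np.sum(weights * errs) / weights.size)
    return float(np.mean(errs))


def estimate_objective(
    selection: Union[Selection, Sequence[int]],
    samples: SampledCurves,
    spec: ObjectiveSpec,
) -> float:
    """Monte-Carlo estimate of f1/f2/f3 for a selection of time points.

    ``selection`` may be a Selection (1-based indices) or a plain sequence of
    1-based indices.  Per-sample weights (if the SampledCurves carry any) are
    honoured for f1 only.
    """
    if isinstance(selection, Selection):
        subset = selection.indices0
    else:
        subset = tuple(int(i) - 1 for i in selection)
    t = samples.grid.times
    if any(i < 0 or i >= t.size for i in subset):
        raise ValueError("selection indices out of grid range")
    weights = samples.weights
    if weights is not None and spec.criterion != "f1":
        raise ValueError("per-curve weights are supported for f1 only")
    curves = _criterion_curves(samples, spec)
    return _interval_cost(curves, t, subset, spec, weights=weights)
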