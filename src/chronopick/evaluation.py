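"""Held-out evaluation of time-point selections.

Mirrors the standard design for scoring a selection strategy: split the
curves into a training and a testing partition, fit the curve density and
select points on the training half only, then measure the L² error between
each held-out curve and its reconstruction from the selected points, and
compare against evenly spaced and random baselines over replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd

from .curve_io import CurveSet, Selection
from .curve_distribution import fit_distribution, sample_curves
from .objectives import ObjectiveSpec, interpolate_subset, l2_error_sq
from .selector import baseline_select, build_edge_matrix, dp_select, spline_select

__all__ = ["EvaluationReport", "train_test_split", "test_error",
           "compare_strategies"]


def train_test_split(
    curves: CurveSet, train_fraction: float, seed: int
) -> tuple[CurveSet, CurveSet]:
    """Disjoint, exhaustive, seeded split of the curves by row."""
    if not (0 < train_fraction < 1):
        raise ValueError("train_fraction must be in (0, 1)")
    n = curves.n_curves
    n_train = int(round(train_fraction * n))
    if n_train < 2 or n - n_train < 1:
        raise ValueError(
            f"split of {n} curves at fraction {train_fraction} leaves "
            "too small a partition (need >= 2 train, >= 1 test)"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return curves.subset(sorted(perm[:n_train])), curves.subset(sorted(perm[n_train:]))


def test_error(
    selection: Selection,
    test: CurveSet,
    interpolation: str = "linear",
    spline_degree: int = 3,
    control: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Per-curve squared L² error of reconstructing held-out curves.

    With a control curve the error is measured on the difference
    control − curve (the f2-style evaluation); otherwise on the curve
    itself.
    """
    t = test.grid.times
    if max(selection.indices) > t.size:
        raise ValueError("selection indices exceed the test grid")
    target = test.values if control is None else np.asarray(control) - test.values
    recon = interpolate_subset(target, t, selection.indices0,
                               interpolation, spline_degree)
    return np.atleast_1d(l2_error_sq(target, recon, t))


@dataclass
class EvaluationReport:
    """Per-replicate, per-strategy held-out errors with full provenance."""

    strategies: list[str]
    replicate_means: pd.DataFrame        # rows = replicates, cols = strategies
    per_curve_errors: dict[str, list[np.ndarray]]
    selections: dict[str, list[Selection]]
    replicate_seeds: list[int]
    config: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        return self.replicate_means.agg(["mean", "std", "min", "max"]).T

    def win_fraction(self, strategy: str, against: str) -> float:
        """Fraction of replicates where ``strategy`` has mean error <= rival."""
        m = self.replicate_means
        return float(np.mean(m[strategy] <= m[against]))


def compare_strategies(
    curves: CurveSet,
    M: int,
    spec: ObjectiveSpec,
    replicates: int,
    seed: int,
    train_fraction: float = 0.5,
    variance_threshold: float = 0.95,
) -> EvaluationReport:
    """Split/fit/select/score over replicates for DP vs even vs random.

    Per replicate: split the curves, fit the curve density on the training
    half, draw J samples, run the DP selection, draw the two baselines, and
    score every selection on the testing half.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    master = np.random.default_rng(seed)
    rep_seeds = [int(s) for s in master.integers(0, 2**31 - 1, size=replicates)]
    strategies = ["dp", "even", "random"]
    means = {s: [] for s in strategies}
    per_curve: dict[str, list[np.ndarray]] = {s: [] for s in strategies}
    selections: dict[str, list[Selection]] = {s: [] for s in strategies}
    control = spec.control if isinstance(spec.control, np.ndarray) else None

    for rseed in rep_seeds:
        train, test = train_test_split(curves, train_fraction, rseed)
        dist = fit_distribution(train, variance_threshold=variance_threshold)
        samples = sample_curves(dist, spec.J, (rseed + 1) % 2**31)
        N = curves.grid.n
        if spec.interpolation == "spline" and spec.spline_degree > 1:
            sel_dp = spline_select(samples, spec, M)
        else:
            sel_dp = dp_select(build_edge_matrix(samples, spec), M)
        sels = {
            "dp": sel_dp,
            "even": baseline_select(N, M, "even", times=curves.grid.times),
            "random": baseline_select(N, M, "random", seed=(rseed + 2) % 2**31,
                                      times=curves.grid.times),
        }
        for name, sel in sels.items():
            errs = test_error(sel, test, spec.interpolation, spec.spline_degree,
                              control=control)
            means[name].append(float(np.mean(errs)))
            per_curve[name].append(errs)
            selections[name].append(sel)

    return EvaluationReport(
        strategies=strategies,
        replicate_means=pd.DataFrame(means),
        per_curve_errors=per_curve,
        selections=selections,
        replicate_seeds=rep_seeds,
        config={
            "M": M, "criterion": spec.criterion, "J": spec.J,
            "interpolation": spec.interpolation,
            "spline_degree": spec.spline_degree,
            "train_fraction": train_fraction,
            "variance_threshold": variance_threshold,
            "replicates": replicates, "seed": seed,
        },
    )
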