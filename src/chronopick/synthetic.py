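"""Synthetic curve populations with known structure.

Three families cover the situations the selection machinery has to handle:

* ``skew_gaussian`` — small sets (triplets by default) of skew-normal bumps
  with randomly varied location, width, skewness and amplitude; the minimal
  realistic input for fitting a curve density.
* ``warped_template`` — a fixed template composed with random monotone time
  warps of known strength; ground-truth warps are returned so registration
  can be scored.
* ``noisy_window`` — a control baseline plus experimental curves carrying a
  systematic offset in an "informative" window and high-variance smooth
  noise in a disjoint "noisy" window; the scenario in which the
  variance-normalised criterion (f3) should steer sampling away from the
  noisy region.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.stats import norm

from .curve_io import CurveSet, TimeGrid
from .registration import WarpingFunction

__all__ = ["ScenarioConfig", "skew_gaussian_curves", "warped_template_curves",
           "noisy_window_curves"]

FAMILIES = ("skew_gaussian", "warped_template", "amplitude_components",
            "noisy_window")

# Default parameter ranges for the skew-Gaussian family (unit time grid):
# location m, width s, skewness alpha, amplitude A.
SKEW_GAUSSIAN_DEFAULTS: dict[str, tuple[float, float]] = {
    "m": (0.3, 0.7),
    "s": (0.05, 0.2),
    "alpha": (-5.0, 5.0),
    "amplitude": (0.5, 1.5),
}


@dataclass
class ScenarioConfig:
    """Configuration of a synthetic curve population."""

    family: str
    n_curves: int = 3
    n_times: int = 101
    seed: int = 0
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        if self.n_curves < 1:
            raise ValueError("n_curves must be >= 1")
        if self.n_times < 3:
            raise ValueError("n_times must be >= 3")

    def param(self, key: str, default: Any) -> Any:
        return self.params.get(key, default)


def _unit_grid(n_times: int) -> TimeGrid:
    return TimeGrid(np.linspace(0.0, 1.0, n_times))


def skew_gaussian_curves(cfg: ScenarioConfig) -> CurveSet:
    """Skew-normal bumps f(t) = A·2·φ((t−m)/s)·Φ(α(t−m)/s)."""
    if cfg.family != "skew_gaussian":
        raise ValueError("config family must be 'skew_gaussian'")
    ranges = {k: tuple(cfg.param(k, v)) for k, v in SKEW_GAUSSIAN_DEFAULTS.items()}
    if ranges["s"][0] <= 0:
        raise ValueError("width range must be positive")
    rng = np.random.default_rng(cfg.seed)
    grid = _unit_grid(cfg.n_times)
    t = grid.times
    values = np.empty((cfg.n_curves, cfg.n_times))
    for i in range(cfg.n_curves):
        m = rng.uniform(*ranges["m"])
        s = rng.uniform(*ranges["s"])
        alpha = rng.uniform(*ranges["alpha"])
        A = rng.uniform(*ranges["amplitude"])
        x = (t - m) / s
        values[i] = A * 2.0 * norm.pdf(x) * norm.cdf(alpha * x)
    labels = [f"curve_{i:03d}" for i in range(cfg.n_curves)]
    return CurveSet(grid=grid, values=values, labels=labels)


def _exp_warp(t: np.ndarray, a: float) -> np.ndarray:
    """γ(t) = (e^{at} − 1)/(e^a − 1); monotone for any a, identity as a→0."""
    if abs(a) < 1e-8:
        return t.copy()
    return np.expm1(a * t) / np.expm1(a)


def warped_template_curves(
    cfg: ScenarioConfig,
) -> tuple[CurveSet, list[WarpingFunction]]:
    """A fixed template composed with random exponential-family warps.

    Each curve is template(γ_i(t)) with γ_i(t) = (e^{a_i t}−1)/(e^{a_i}−1),
    a_i ~ U(−strength, strength); the true warps γ_i are returned.
    """
    if cfg.family != "warped_template":
        raise ValueError("config family must be 'warped_template'")
    strength = float(cfg.param("strength", 1.0))
    if strength < 0:
        raise ValueError("warp strength must be >= 0")
    center = float(cfg.param("template_center", 0.45))
    width = float(cfg.param("template_width", 0.12))
    rng = np.random.default_rng(cfg.seed)
    grid = _unit_grid(cfg.n_times)
    t = grid.times
    template = np.exp(-0.5 * ((t - center) / width) ** 2)

    values = np.empty((cfg.n_curves, cfg.n_times))
    warps: list[WarpingFunction] = []
    for i in range(cfg.n_curves):
        a = rng.uniform(-strength, strength) if strength > 0 else 0.0
        gamma = _exp_warp(t, a)
        warps.append(WarpingFunction(grid=grid, gamma=gamma))
        values[i] = np.interp(gamma, t, template)
    return CurveSet(grid=grid, values=values), warps


def _window_bump(t: np.ndarray, lo: float, hi: float, center_frac: float = 0.5,
                 width_frac: float = 0.25) -> np.ndarray:
    """A smooth Gaussian bump supported (effectively) inside [lo, hi]."""
    c = lo + center_frac * (hi - lo)
    w = width_frac * (hi - lo)
    return np.exp(-0.5 * ((t - c) / w) ** 2)


def noisy_window_curves(
    cfg: ScenarioConfig,
) -> tuple[CurveSet, np.ndarray, dict[str, tuple[float, float]]]:
    """Control baseline plus offset-in-informative-window experimental curves.

    Experimental curves add (i) a systematic bump of height ``offset`` (with
    mild per-curve amplitude jitter) inside the informative window and (ii)
    smooth high-variance random bumps inside the noisy window.  Returns
    (experimental curves, control curve, window boundaries).
    """
    if cfg.family != "noisy_window":
        raise ValueError("config family must be 'noisy_window'")
    noisy = tuple(cfg.param("noisy_window", (0.05, 0.35)))
    info = tuple(cfg.param("informative_window", (0.55, 0.9)))
    if max(noisy[0], info[0]) < min(noisy[1], info[1]):
        raise ValueError("noisy and informative windows must not overlap")
    offset = float(cfg.param("offset", 1.0))
    noise_sd = float(cfg.param("noise_sd", 0.8))
    jitter_sd = float(cfg.param("jitter_sd", 0.1 * abs(offset)))

    rng = np.random.default_rng(cfg.seed)
    grid = _unit_grid(cfg.n_times)
    t = grid.times
    baseline = 1.0 + 0.3 * np.sin(2.0 * np.pi * t)
    info_bump = _window_bump(t, *info)
    noise_shapes = np.stack([
        _window_bump(t, *noisy, center_frac=0.3, width_frac=0.2),
        _window_bump(t, *noisy, center_frac=0.7, width_frac=0.2),
    ])

    values = np.empty((cfg.n_curves, cfg.n_times))
    for i in range(cfg.n_curves):
        amp = offset + (rng.normal(0.0, jitter_sd) if jitter_sd > 0 else 0.0)
        coeffs = rng.normal(0.0, noise_sd, size=2) if noise_sd > 0 else np.zeros(2)
        values[i] = baseline + amp * info_bump + coeffs @ noise_shapes
    windows = {"noisy": noisy, "informative": info}
    return CurveSet(grid=grid, values=values), baseline.copy(), windows
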