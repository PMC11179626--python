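"""Umbrella-window selection with histogram-overlap control.

Starting configurations for umbrella sampling are drawn from a steered
trajectory spanning the CV range.  Candidate window sets (evenly spaced
centers, count swept from ``n_min`` to ``n_max``) are vetted by running a
short seeded equilibration in each window and requiring the normalized
histogram intersection of every adjacent pair to reach ``overlap_target``
— the "adequate overlap between consecutive regions" criterion that
makes WHAM well conditioned.  Spacing effectively adapts to local
stiffness because stiff regions shrink the sampled spread and force a
higher window count before the criterion is met.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .landscapes import Landscape
from .sampling import langevin_simulate

__all__ = ["BiasWindow", "WindowInfeasibilityError", "histogram_overlap", "select_windows"]


class WindowInfeasibilityError(RuntimeError):
    """Overlap target unreachable within n_max windows."""

    def __init__(self, message: str, suggested_k_force: float | None = None):
        super().__init__(message)
        self.suggested_k_force = suggested_k_force


@dataclass(frozen=True)
class BiasWindow:
    """One harmonic umbrella window.

    ``center`` and ``samples`` are in CV units (nm or degrees);
    ``k_force`` in kT per unit^2.  ``start`` is the configuration the
    production run should begin from (taken from the steered path).
    """

    center: float
    k_force: float
    samples: np.ndarray = field(default_factory=lambda: np.empty(0))
    start: float | None = None

    def __post_init__(self) -> None:
        if self.k_force <= 0:
            raise ValueError("k_force must be > 0")
        object.__setattr__(
            self, "samples", np.asarray(self.samples, dtype=float).ravel()
        )

    def with_samples(self, samples) -> "BiasWindow":
        return replace(self, samples=np.asarray(samples, dtype=float))


def histogram_overlap(a, b, bins: int = 50) -> float:
    """Normalized histogram intersection of two sample sets, in [0, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if hi == lo:
        return 1.0
    edges = np.linspace(lo, hi, bins + 1)
    pa, _ = np.histogram(a, bins=edges, density=False)
    pb, _ = np.histogram(b, bins=edges, density=False)
    pa = pa / pa.sum()
    pb = pb / pb.sum()
    return float(np.minimum(pa, pb).sum())


def select_windows(
    smd_trajectory,
    landscape: Landscape,
    k_force: float,
    n_min: int = 28,
    n_max: int = 39,
    overlap_target: float = 0.1,
    n_equil_steps: int = 4000,
    dt: float = 1e-3,
    kT: float = 1.0,
    friction: float = 1.0,
    seed: int = 0,
) -> list[BiasWindow]:
    """Choose umbrella windows along a steered trajectory.

    Returns between ``n_min`` and ``n_max`` windows, each carrying its
    short equilibration samples, such that adjacent sample histograms
    overlap by at least ``overlap_target``.  Raises
    ``WindowInfeasibilityError`` (with a softer suggested force constant)
    if even ``n_max`` windows cannot satisfy the target.
    """
    if n_min < 1 or n_min > n_max:
        raise ValueError("need 1 <= n_min <= n_max")
    if not (0.0 <= overlap_target <= 1.0):
        raise ValueError("overlap_target must be in [0, 1]")
    traj = np.asarray(smd_trajectory, dtype=float)
    lo, hi = float(traj.min()), float(traj.max())
    if hi <= lo:
        raise ValueError("steered trajectory does not span a CV range")

    for n_windows in range(n_min, n_max + 1):
        centers = np.linspace(lo, hi, n_windows)
        windows = []
        for i, c in enumerate(centers):
            start = float(traj[np.argmin(np.abs(traj - c))])
            samples = langevin_simulate(
                landscape,
                start,
                n_equil_steps,
                dt=dt,
                kT=kT,
                friction=friction,
                seed=seed + 1000 * i + n_windows,
                bias_center=float(c),
                bias_k=k_force,
            )
            windows.append(
                BiasWindow(float(c), k_force, samples[n_equil_steps // 4 :], start)
            )
        overlaps = [
            histogram_overlap(w1.samples, w2.samples)
            for w1, w2 in zip(windows, windows[1:])
        ]
        if not overlaps or min(overlaps) >= overlap_target:
            return windows

    raise WindowInfeasibilityError(
        f"adjacent-window overlap {min(overlaps):.3f} < target {overlap_target} "
        f"even with {n_max} windows",
        suggested_k_force=k_force / 2.0,
    )
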