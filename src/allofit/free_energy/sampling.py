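"""Overdamped Langevin sampling, harmonic restraints and steered pulling.

The engine integrates the overdamped (Brownian) Euler-Maruyama update

    x_{t+1} = x_t - (dt / friction) * U'(x_t) + sqrt(2 kT dt / friction) * xi_t

with i.i.d. standard normal ``xi_t``; trajectories are bit-reproducible
for a fixed seed.  Steered pulling adds a harmonic restraint whose
center moves along a schedule, accumulating the external work

    W = sum_t k_force * (c_t - x_t) * (c_{t+1} - c_t),

and is used to generate a transition path whose frames seed umbrella
windows.  Reduced units: kT = 1 unless stated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landscapes import Landscape

__all__ = ["UnstableStepError", "PullResult", "langevin_simulate", "steered_pull"]


class UnstableStepError(RuntimeError):
    """Trajectory left the landscape domain; reduce dt or friction."""


@dataclass(frozen=True)
class PullResult:
    """Steered-pull output: trajectory, restraint centers and work series."""

    trajectory: np.ndarray
    centers: np.ndarray
    work: np.ndarray

    @property
    def total_work(self) -> float:
        return float(self.work[-1]) if self.work.size else 0.0


def _check_domain(x: float, landscape: Landscape, step: int) -> None:
    lo, hi = landscape.domain
    if not (lo <= x <= hi) or not np.isfinite(x):
        raise UnstableStepError(
            f"position {x!r} left domain [{lo}, {hi}] at step {step}; "
            "try a smaller dt"
        )


def langevin_simulate(
    landscape: Landscape,
    start: float,
    n_steps: int,
    dt: float = 1e-3,
    kT: float = 1.0,
    friction: float = 1.0,
    seed: int = 0,
    bias_center: float | None = None,
    bias_k: float = 0.0,
) -> np.ndarray:
    """Sample the landscape; returns positions of shape (n_steps + 1,).

    An optional static harmonic bias ``0.5 * bias_k * (x - bias_center)^2``
    turns the run into one umbrella window.  ``kT = 0`` gives pure
    gradient descent (a start at a minimum stays there).
    """
    if dt <= 0 or friction <= 0 or kT < 0:
        raise ValueError("dt, friction must be > 0 and kT >= 0")
    rng = np.random.default_rng(seed)
    noise_scale = np.sqrt(2.0 * kT * dt / friction)
    noise = rng.standard_normal(n_steps) * noise_scale if kT > 0 else np.zeros(n_steps)
    mob = dt / friction

    x = float(start)
    _check_domain(x, landscape, 0)
    traj = np.empty(n_steps + 1)
    traj[0] = x
    grad = landscape.grad
    use_bias = bias_center is not None and bias_k > 0
    for t in range(n_steps):
        f = -grad(x)
        if use_bias:
            f -= bias_k * (x - bias_center)
        x = x + mob * f + noise[t]
        if not (landscape.domain[0] <= x <= landscape.domain[1]):
            _check_domain(x, landscape, t + 1)
        traj[t + 1] = x
    return traj


def steered_pull(
    landscape: Landscape,
    cv_path,
    k_force: float,
    n_steps: int | None = None,
    dt: float = 1e-3,
    kT: float = 1.0,
    friction: float = 1.0,
    seed: int = 0,
) -> PullResult:
    """Pull the system along a monotone schedule of restraint centers.

    ``cv_path`` is the schedule of centers; if ``n_steps`` is given the
    path is linearly resampled to ``n_steps + 1`` points (one center per
    integration step).  The pulling rate is therefore set by the path
    span divided by ``n_steps * dt``.
    """
    centers = np.asarray(cv_path, dtype=float)
    if centers.ndim != 1 or centers.size < 2:
        raise ValueError("cv_path must be a 1-D schedule of >= 2 centers")
    d = np.diff(centers)
    if not (np.all(d >= 0) or np.all(d <= 0)):
        raise ValueError("cv_path must be monotone")
    if k_force <= 0:
        raise ValueError("k_force must be > 0")
    if n_steps is not None:
        centers = np.interp(
            np.linspace(0.0, 1.0, n_steps + 1),
            np.linspace(0.0, 1.0, centers.size),
            centers,
        )
    n = centers.size - 1

    rng = np.random.default_rng(seed)
    noise_scale = np.sqrt(2.0 * kT * dt / friction)
    noise = rng.standard_normal(n) * noise_scale if kT > 0 else np.zeros(n)
    mob = dt / friction

    x = float(centers[0])
    _check_domain(x, landscape, 0)
    traj = np.empty(n + 1)
    work = np.empty(n + 1)
    traj[0] = x
    work[0] = 0.0
    w = 0.0
    grad = landscape.grad
    for t in range(n):
        c = centers[t]
        f = -grad(x) - k_force * (x - c)
        dc = centers[t + 1] - c
        w += k_force * (c - x) * dc
        x = x + mob * f + noise[t]
        if not (landscape.domain[0] <= x <= landscape.domain[1]):
            _check_domain(x, landscape, t + 1)
        traj[t + 1] = x
        work[t + 1] = w
    return PullResult(traj, centers, work)
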