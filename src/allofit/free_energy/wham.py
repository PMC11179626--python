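"""Weighted histogram analysis (WHAM) and free-energy profile read-out.

Given umbrella windows *w* with harmonic biases ``U_w(x) = 0.5 k_w (x -
c_w)^2``, histogram counts ``n_w(b)`` on shared bins *b* and totals
``N_w``, WHAM iterates the self-consistent equations

    P(b)  = sum_w n_w(b) / sum_w N_w exp((f_w - U_w(b)) / kT)
    f_w   = -kT ln sum_b P(b) exp(-U_w(b) / kT)

until the window free energies ``f_w`` stop moving, anchored by f_1 = 0.
The unbiased profile is ``dG(b) = -kT ln P(b)`` shifted so its minimum
is zero.  Dihedral CVs use periodic (360-degree minimum-image) bias
distances and bin topology; distances and planar angles are aperiodic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .windows import BiasWindow

__all__ = [
    "FreeEnergyProfile",
    "WhamConvergenceError",
    "wham_1d",
    "delta_g_at_target",
    "profile_difference",
]


class WhamConvergenceError(RuntimeError):
    """Self-consistent iteration did not converge; carries the f history."""

    def __init__(self, message: str, f_history=None):
        super().__init__(message)
        self.f_history = f_history


@dataclass(frozen=True)
class FreeEnergyProfile:
    """Free energy (kT units) per CV bin; empty-bin gaps are NaN."""

    bins: np.ndarray
    delta_g: np.ndarray
    reference_bin: int
    f_windows: np.ndarray | None = None
    n_iter: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "bins", np.asarray(self.bins, dtype=float))
        object.__setattr__(self, "delta_g", np.asarray(self.delta_g, dtype=float))

    @property
    def gaps(self) -> np.ndarray:
        """Boolean mask of interior bins with no counts."""
        return ~np.isfinite(self.delta_g)


def _bias_matrix(windows, bin_centers, period):
    centers = np.array([w.center for w in windows])
    ks = np.array([w.k_force for w in windows])
    d = bin_centers[None, :] - centers[:, None]
    if period is not None:
        d = d - period * np.round(d / period)
    return 0.5 * ks[:, None] * d**2


def wham_1d(
    windows: list[BiasWindow],
    n_bins: int = 200,
    kT: float = 1.0,
    tol: float = 1e-8,
    max_iter: int = 100_000,
    bin_range: tuple[float, float] | None = None,
    periodic: float | None = None,
) -> FreeEnergyProfile:
    """Reconstruct the unbiased free-energy profile from biased windows.

    ``periodic`` is the CV period (e.g. 360 for dihedrals in degrees) or
    None for aperiodic CVs.  Empty interior bins are reported as NaN
    gaps, never interpolated.
    """
    windows = [w for w in windows if w.samples.size > 0]
    if not windows:
        raise ValueError("need at least one window with samples")
    if tol <= 0:
        raise ValueError("tol must be > 0")

    all_samples = np.concatenate([w.samples for w in windows])
    if bin_range is None:
        if periodic is not None:
            half = periodic / 2.0
            bin_range = (-half, half)
        else:
            bin_range = (float(all_samples.min()), float(all_samples.max()))
    edges = np.linspace(bin_range[0], bin_range[1], n_bins + 1)
    bin_centers = 0.5 * (edges[:-1] + edges[1:])

    counts = np.stack([np.histogram(w.samples, bins=edges)[0] for w in windows])
    totals = counts.sum(axis=1).astype(float)  # in-range samples per window
    u = _bias_matrix(windows, bin_centers, periodic)  # (n_windows, n_bins)
    boltz = np.exp(-u / kT)

    n_tot = counts.sum(axis=0).astype(float)
    f = np.zeros(len(windows))
    f_history = [f.copy()]
    for it in range(1, max_iter + 1):
        # denominator: sum_w N_w exp((f_w - U_w(b))/kT)
        denom = np.einsum("w,wb->b", totals * np.exp(f / kT), boltz)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(denom > 0, n_tot / denom, 0.0)
        z = boltz @ p  # sum_b P(b) exp(-U_w(b)/kT)
        f_new = -kT * np.log(z)
        f_new -= f_new[0]  # anchor f_1 = 0
        delta = float(np.max(np.abs(f_new - f)))
        f = f_new
        if it <= 50 or it % 100 == 0:
            f_history.append(f.copy())
        if delta < tol:
            break
    else:
        raise WhamConvergenceError(
            f"WHAM did not converge in {max_iter} iterations (last df={delta:.2e})",
            f_history=np.array(f_history),
        )

    with np.errstate(divide="ignore"):
        dg = np.where(n_tot > 0, -kT * np.log(np.where(n_tot > 0, p, 1.0)), np.nan)
    finite = np.isfinite(dg)
    ref = int(np.nanargmin(np.where(finite, dg, np.inf)))
    dg = dg - dg[ref]
    return FreeEnergyProfile(bin_centers, dg, ref, f_windows=f, n_iter=it)


def delta_g_at_target(profile: FreeEnergyProfile, target: float) -> float:
    """Free energy (kT) at a target CV value by linear interpolation.

    This is the closed-state read-out: the profile value at the CV value
    the reference (closed) structure adopts.  Targets outside the binned
    finite range are refused rather than extrapolated.
    """
    finite = np.isfinite(profile.delta_g)
    bins = profile.bins[finite]
    dg = profile.delta_g[finite]
    if bins.size == 0:
        raise ValueError("profile has no finite bins")
    if not (bins[0] <= target <= bins[-1]):
        raise ValueError(
            f"target {target} outside profile range [{bins[0]:.4g}, {bins[-1]:.4g}]; "
            "extrapolation refused"
        )
    return float(np.interp(target, bins, dg))


def profile_difference(
    profiles: dict[str, FreeEnergyProfile],
    targets: dict[str, float] | float,
    reference: str,
) -> dict[str, float]:
    """Per-system closed-state dG relative to a named reference system.

    ``profiles`` maps system labels to profiles along the same CV;
    ``targets`` is the closed-state CV value (one number, or one per
    system).  Returns ``dG_sys(target) - dG_ref(target)`` per system.
    """
    if reference not in profiles:
        raise KeyError(f"reference system {reference!r} not in profiles")

    def tgt(label):
        return targets[label] if isinstance(targets, dict) else targets

    ref_val = delta_g_at_target(profiles[reference], tgt(reference))
    return {
        label: delta_g_at_target(prof, tgt(label)) - ref_val
        for label, prof in profiles.items()
    }
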