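"""Equilibrium forward model for independent classes of ligand-binding sites.

A macromolecule M carries several *classes* of mutually independent,
identical sites.  Class *i* has stoichiometry ``n_i`` (sites per
macromolecule), association constant ``K_i`` (M^-1) and molar binding
enthalpy ``dH_i`` (J per mol of sites).  At free-ligand concentration
``x`` each class saturates independently,

    theta_i = K_i * x / (1 + K_i * x),

and the free concentration is fixed by mass balance

    x_total = x + m_total * sum_i n_i * theta_i(x).

The left-hand side is strictly increasing in ``x``, so the root on
``[0, x_total]`` is unique and a bracketed solver is globally convergent.

All quantities are SI (mol/L, L, J); presentation-unit conversion happens
at the reporting layer only.  Association constants are concentration
based; activity coefficients are ignored, as is standard in ITC analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "SiteClass",
    "BindingModel",
    "CellState",
    "SolverError",
    "solve_free_ligand",
    "heat_content",
]


class SolverError(RuntimeError):
    """Free-ligand root search failed; carries the last bracket examined."""

    def __init__(self, message: str, bracket: tuple[float, float] | None = None):
        super().__init__(message)
        self.bracket = bracket


@dataclass(frozen=True)
class SiteClass:
    """One class of independent, identical binding sites.

    Parameters
    ----------
    n_sites
        Stoichiometry per macromolecule (dimensionless, >= 0).
    k_assoc
        Association constant in M^-1 (> 0).
    d_h
        Molar binding enthalpy in J per mol of sites (any sign).
    """

    n_sites: float
    k_assoc: float
    d_h: float = 0.0

    def __post_init__(self) -> None:
        if self.n_sites < 0:
            raise ValueError(f"n_sites must be >= 0, got {self.n_sites}")
        if self.k_assoc <= 0:
            raise ValueError(f"k_assoc must be > 0, got {self.k_assoc}")


@dataclass(frozen=True)
class BindingModel:
    """Ordered collection of independent site classes.

    Classes are canonicalized to decreasing ``k_assoc`` on construction so
    that "class 1" always denotes the highest-affinity set of sites.
    """

    site_classes: tuple[SiteClass, ...]

    def __init__(self, site_classes) -> None:
        classes = tuple(sorted(site_classes, key=lambda c: -c.k_assoc))
        object.__setattr__(self, "site_classes", classes)

    def __len__(self) -> int:
        return len(self.site_classes)

    @property
    def capacity(self) -> float:
        """Total sites per macromolecule, sum of class stoichiometries."""
        return float(sum(c.n_sites for c in self.site_classes))

    def scale_first_class(self, occupancy: float) -> "BindingModel":
        """Return a copy with the highest-affinity stoichiometry scaled.

        ``occupancy`` plays the role of the per-isotherm site occupation
        in global fits: it multiplies ``n_sites`` of the first (highest
        K) class only.
        """
        if occupancy < 0:
            raise ValueError("occupancy must be >= 0")
        if not self.site_classes:
            return self
        first, *rest = self.site_classes
        scaled = SiteClass(first.n_sites * occupancy, first.k_assoc, first.d_h)
        return BindingModel([scaled, *rest])


@dataclass(frozen=True)
class CellState:
    """Equilibrium composition of the calorimeter cell contents."""

    m_total: float
    x_total: float
    x_free: float
    theta: tuple[float, ...] = field(default_factory=tuple)


def _bound_ligand(model: BindingModel, m_total: float, x_free: float) -> float:
    return m_total * sum(
        c.n_sites * c.k_assoc * x_free / (1.0 + c.k_assoc * x_free)
        for c in model.site_classes
    )


def _theta(model: BindingModel, x_free: float) -> tuple[float, ...]:
    return tuple(
        c.k_assoc * x_free / (1.0 + c.k_assoc * x_free) for c in model.site_classes
    )


def solve_free_ligand(
    model: BindingModel,
    m_total: float,
    x_total: float,
    rel_tol: float = 1e-12,
) -> CellState:
    """Solve the mass-balance equation for the free-ligand concentration.

    Parameters
    ----------
    model
        Binding model defining the site classes.
    m_total, x_total
        Total macromolecule and ligand concentrations in the cell (mol/L).
    rel_tol
        Relative tolerance on the mass balance, ``|residual| <=
        rel_tol * max(x_total, eps)``.

    Returns
    -------
    CellState
        With ``x_free`` and per-class fractional saturations ``theta``.
    """
    if m_total < 0 or x_total < 0:
        raise ValueError("concentrations must be >= 0")
    if rel_tol <= 0:
        raise ValueError("rel_tol must be > 0")

    if x_total == 0.0:
        return CellState(m_total, 0.0, 0.0, tuple(0.0 for _ in model.site_classes))
    if m_total == 0.0 or model.capacity == 0.0:
        return CellState(m_total, x_total, x_total, _theta(model, x_total))

    def residual(x: float) -> float:
        return x + _bound_ligand(model, m_total, x) - x_total

    lo, hi = 0.0, x_total
    try:
        # Bracketed root search on [0, x_total]; the residual is strictly
        # increasing, with residual(0) < 0 <= residual(x_total).
        x_free = brentq(residual, lo, hi, xtol=1e-300, rtol=8.9e-16, maxiter=300)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - defensive
        raise SolverError(f"free-ligand solve failed: {exc}", (lo, hi)) from exc

    tol = rel_tol * max(x_total, np.finfo(float).tiny)
    if abs(residual(x_free)) > tol:
        raise SolverError(
            f"mass balance residual {residual(x_free):.3e} exceeds tolerance {tol:.3e}",
            (lo, hi),
        )
    return CellState(m_total, x_total, x_free, _theta(model, x_free))


def heat_content(state: CellState, model: BindingModel, v_cell: float) -> float:
    """Total binding heat content of the cell, Q (J).

    ``Q = v_cell * m_total * sum_i n_i * theta_i * dH_i`` — the enthalpy
    released/absorbed so far by forming the equilibrium amount of each
    complex in a cell of volume ``v_cell`` (L).
    """
    if len(state.theta) != len(model.site_classes):
        raise ValueError(
            f"state has {len(state.theta)} classes, model has {len(model.site_classes)}"
        )
    return v_cell * state.m_total * sum(
        c.n_sites * t * c.d_h for c, t in zip(model.site_classes, state.theta)
    )
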