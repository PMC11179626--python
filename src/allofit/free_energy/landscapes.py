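"""Analytic 1-D energy landscapes for the toy sampling engine.

These stand in for the molecular force field when validating the
steering -> window selection -> umbrella sampling -> WHAM protocol:
their Boltzmann free-energy profiles are known in closed form, so the
reconstruction error of the whole chain can be measured exactly.
Reduced units throughout (energies in kT at the reference temperature).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Landscape", "Harmonic", "DoubleWell", "Flat"]


@dataclass(frozen=True)
class Landscape:
    """Base: potential ``u(x)`` and gradient ``grad(x)`` on a finite domain."""

    domain: tuple[float, float] = (-10.0, 10.0)

    def u(self, x):
        raise NotImplementedError

    def grad(self, x):
        raise NotImplementedError


@dataclass(frozen=True)
class Harmonic(Landscape):
    """U(x) = 0.5 * kappa * (x - x0)^2."""

    kappa: float = 1.0
    x0: float = 0.0

    def u(self, x):
        return 0.5 * self.kappa * (np.asarray(x) - self.x0) ** 2

    def grad(self, x):
        return self.kappa * (np.asarray(x) - self.x0)


@dataclass(frozen=True)
class DoubleWell(Landscape):
    """U(x) = barrier * ((x/half_width)^2 - 1)^2.

    Two minima at +-half_width separated by a barrier of ``barrier``
    energy units at x = 0.
    """

    barrier: float = 5.0
    half_width: float = 1.0

    def u(self, x):
        s = (np.asarray(x) / self.half_width) ** 2
        return self.barrier * (s - 1.0) ** 2

    def grad(self, x):
        x = np.asarray(x)
        s = (x / self.half_width) ** 2
        return 4.0 * self.barrier * (s - 1.0) * x / self.half_width**2


@dataclass(frozen=True)
class Flat(Landscape):
    """U(x) = 0 on the domain."""

    def u(self, x):
        return np.zeros_like(np.asarray(x, dtype=float))

    def grad(self, x):
        return np.zeros_like(np.asarray(x, dtype=float))
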