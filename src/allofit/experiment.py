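"""Synthetic ITC stage: injection schedules, cell bookkeeping, forward heats.

Emulates titrations on a perfusion-cell instrument (MicroCal VP-ITC
family): the cell of volume ``v_cell`` is always full, so each injection
of ``dV`` displaces an equal volume of cell contents into the overflow.
With cumulative injected volume ``DV_k`` after injection *k*, the standard
Origin-style bookkeeping gives the in-cell totals

    m_total_k = m_cell_0 * (1 - DV_k/(2 v_cell)) / (1 + DV_k/(2 v_cell))
    x_total_k = x_syringe * (DV_k/v_cell)       / (1 + DV_k/(2 v_cell))

and the measured heat of injection *k* is the change in cell heat content
plus a displacement correction and a constant dilution offset,

    q_k = Q_k - Q_{k-1} + (dV_k / v_cell) * (Q_k + Q_{k-1}) / 2 + q_dil.

The default study conditions mirror a Zn2+ -> albumin titration: 1.5 mM
ligand titrated into 50 uM macromolecule with 35 injections (2 ul then
34 x 8 ul) at 25 C, in a 1.4 mL cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .binding import BindingModel, SiteClass, heat_content, solve_free_ligand

__all__ = [
    "InjectionSchedule",
    "TitrationConfig",
    "Isotherm",
    "CellOverflowError",
    "paper_schedule",
    "zinc_titration_config",
    "myristate_titration_config",
    "zinc_binding_model",
    "myristate_binding_model",
    "dilution_trajectory",
    "simulate_isotherm",
    "make_synthetic_panel",
]


class CellOverflowError(ValueError):
    """Cumulative injected volume exceeds the cell volume."""


@dataclass(frozen=True)
class InjectionSchedule:
    """Sequence of injection volumes in litres (each > 0)."""

    volumes: tuple[float, ...]

    def __init__(self, volumes) -> None:
        vols = tuple(float(v) for v in volumes)
        if any(v <= 0 for v in vols):
            raise ValueError("injection volumes must be > 0")
        object.__setattr__(self, "volumes", vols)

    def __len__(self) -> int:
        return len(self.volumes)

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.volumes)


def paper_schedule() -> InjectionSchedule:
    """35-injection schedule: one 2 ul injection then 34 of 8 ul."""
    return InjectionSchedule([2e-6] + [8e-6] * 34)


@dataclass(frozen=True)
class TitrationConfig:
    """Cell/syringe composition and schedule of one titration.

    ``dilution_heat`` is the constant per-injection background heat (J),
    the in-model stand-in for the blank-subtracted heat of dilution.
    """

    v_cell: float
    m_cell_0: float
    x_syringe: float
    temperature: float
    schedule: InjectionSchedule
    dilution_heat: float = 0.0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0 K")
        if self.v_cell <= 0:
            raise ValueError("v_cell must be > 0")
        if self.m_cell_0 < 0 or self.x_syringe < 0:
            raise ValueError("concentrations must be >= 0")
        total = float(np.sum(self.schedule.volumes)) if len(self.schedule) else 0.0
        if total > self.v_cell:
            raise CellOverflowError(
                f"cumulative injected volume {total:.3e} L exceeds cell volume "
                f"{self.v_cell:.3e} L"
            )
        if total > 0.5 * self.v_cell:
            warnings.warn(
                "cumulative injected volume exceeds half the cell volume; "
                "the displacement correction becomes inaccurate",
                stacklevel=2,
            )


def zinc_titration_config(dilution_heat: float = 0.0) -> TitrationConfig:
    """1.5 mM ZnCl2 titrated into 50 uM albumin, 25 C, 1.4 mL cell."""
    return TitrationConfig(
        v_cell=1.4e-3,
        m_cell_0=50e-6,
        x_syringe=1.5e-3,
        temperature=298.15,
        schedule=paper_schedule(),
        dilution_heat=dilution_heat,
    )


def myristate_titration_config(dilution_heat: float = 0.0) -> TitrationConfig:
    """500 uM myristate titrated into 12.5 uM albumin, 25 C, 1.4 mL cell."""
    return TitrationConfig(
        v_cell=1.4e-3,
        m_cell_0=12.5e-6,
        x_syringe=500e-6,
        temperature=298.15,
        schedule=paper_schedule(),
        dilution_heat=dilution_heat,
    )


def zinc_binding_model(
    k1: float = 2.9e5,
    k2: float = 2.5e4,
    dh1: float = -12e3,
    dh2: float = -30e3,
    n1: float = 1.0,
    n2: float = 2.0,
) -> BindingModel:
    """Two-sets-of-sites Zn2+ model: one high-affinity site (site A) and
    a set of two weaker sites (site B plus tertiary binding)."""
    return BindingModel([SiteClass(n1, k1, dh1), SiteClass(n2, k2, dh2)])


def myristate_binding_model() -> BindingModel:
    """Three-sets-of-sites fatty-acid model with stoichiometries 2/1/4."""
    return BindingModel(
        [
            SiteClass(2.0, 1.76e6, -20e3),
            SiteClass(1.0, 3.91e5, -15e3),
            SiteClass(4.0, 3.11e4, -8e3),
        ]
    )


@dataclass(frozen=True)
class Isotherm:
    """One titration: configuration, per-injection heats and molar ratios.

    ``occupancy`` records the scaling of the first (highest-affinity)
    site-class stoichiometry used when the isotherm was simulated; for
    measured data it is 1 by convention.
    """

    config: TitrationConfig
    heats: tuple[float, ...]
    molar_ratio: tuple[float, ...]
    occupancy: float = 1.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.config.schedule)
        if not (len(self.heats) == len(self.molar_ratio) == n):
            raise ValueError(
                f"inconsistent lengths: {len(self.heats)} heats, "
                f"{len(self.molar_ratio)} ratios, {n} injections"
            )
        mr = np.asarray(self.molar_ratio)
        if mr.size and np.any(np.diff(mr) <= 0):
            raise ValueError("molar_ratio must be strictly increasing")

    def __len__(self) -> int:
        return len(self.heats)

    def with_heats(self, heats) -> "Isotherm":
        return replace(self, heats=tuple(float(q) for q in heats))


def dilution_trajectory(config: TitrationConfig) -> np.ndarray:
    """Per-injection in-cell totals ``(m_total, x_total)``.

    Returns an array of shape ``(n_injections, 2)``; row *k* holds the
    totals after injection *k* under the perfusion-cell displacement
    model (see module docstring).
    """
    if len(config.schedule) == 0:
        return np.empty((0, 2))
    dv = config.schedule.cumulative
    if dv[-1] > config.v_cell:
        raise CellOverflowError("schedule overflows the cell")
    ratio = dv / config.v_cell
    m_tot = config.m_cell_0 * (1.0 - ratio / 2.0) / (1.0 + ratio / 2.0)
    x_tot = config.x_syringe * ratio / (1.0 + ratio / 2.0)
    return np.column_stack([m_tot, x_tot])


def simulate_isotherm(
    model: BindingModel,
    config: TitrationConfig,
    occupancy: float = 1.0,
) -> Isotherm:
    """Forward-simulate the per-injection heats of a titration.

    ``occupancy`` scales the stoichiometry of the first (highest-K)
    class only, mimicking partial availability of the high-affinity site.
    """
    if occupancy < 0:
        raise ValueError("occupancy must be >= 0")
    eff = model.scale_first_class(occupancy)
    traj = dilution_trajectory(config)

    # Pre-injection cell: macromolecule only, no ligand.
    state0 = solve_free_ligand(eff, config.m_cell_0, 0.0)
    q_prev = heat_content(state0, eff, config.v_cell)

    heats = []
    ratios = []
    for (m_tot, x_tot), dv in zip(traj, config.schedule.volumes):
        state = solve_free_ligand(eff, m_tot, x_tot)
        q_cell = heat_content(state, eff, config.v_cell)
        q_inj = (
            q_cell
            - q_prev
            + (dv / config.v_cell) * (q_cell + q_prev) / 2.0
            + config.dilution_heat
        )
        heats.append(q_inj)
        ratios.append(x_tot / m_tot if m_tot > 0 else np.inf)
        q_prev = q_cell

    return Isotherm(config, tuple(heats), tuple(ratios), occupancy)


def make_synthetic_panel(
    seed: int,
    theta_schedule,
    noise_sd: float | None = None,
    model: BindingModel | None = None,
    config: TitrationConfig | None = None,
    metadata=None,
) -> list[Isotherm]:
    """Simulate a panel of isotherms sharing one model and configuration.

    Each entry of ``theta_schedule`` gives the first-class occupancy of
    one isotherm; i.i.d. Gaussian noise of standard deviation
    ``noise_sd`` (J) is added to every heat.  ``noise_sd=None`` uses the
    default 1% of the largest |heat| of the noiseless occupancy-1
    isotherm; pass 0 for noiseless panels.  Reproducible for fixed seed.

    ``metadata``, if given, is a list of dicts attached per isotherm
    (e.g. ``{"condition": "WT", "fa_mol_eq": 3}``).
    """
    if model is None:
        model = zinc_binding_model()
    if config is None:
        config = zinc_titration_config()
    if noise_sd is None:
        ref = simulate_isotherm(model, config, 1.0)
        noise_sd = 0.01 * float(np.max(np.abs(ref.heats)))
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if metadata is not None and len(metadata) != len(theta_schedule):
        raise ValueError("metadata length must match theta_schedule")

    rng = np.random.default_rng(seed)
    panel = []
    for i, theta in enumerate(theta_schedule):
        iso = simulate_isotherm(model, config, theta)
        heats = np.asarray(iso.heats)
        if noise_sd > 0:
            heats = heats + rng.normal(0.0, noise_sd, size=heats.shape)
        iso = replace(
            iso,
            heats=tuple(heats),
            metadata=dict(metadata[i]) if metadata is not None else {},
        )
        panel.append(iso)
    return panel


def normalized_heats(iso: Isotherm, unit: str = "kcal/mol") -> np.ndarray:
    """Heats per mole of injectant, the conventional ITC presentation.

    ``unit`` is ``"kcal/mol"`` (default, figure convention) or
    ``"kJ/mol"``.
    """
    moles = np.asarray(iso.config.schedule.volumes) * iso.config.x_syringe
    q = np.asarray(iso.heats) / moles
    if unit == "kcal/mol":
        return q / 4184.0
    if unit == "kJ/mol":
        return q / 1e3
    raise ValueError(f"unknown unit {unit!r}")
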