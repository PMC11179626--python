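"""Least-squares inference for sets-of-sites ITC models.

Single-isotherm fits reproduce the classic workflow: minimize the sum of
squared differences between measured and modelled per-injection heats,
with any subset of {n_i, K_i, dH_i, dilution heat} fixed or bounded.
Global fits treat a panel of isotherms jointly: the thermodynamic
parameters (K_i, dH_i) are shared across isotherms while the degree of
occupation of the high-affinity site, theta_i (the analogue of N1 in a
single-isotherm fit), floats per isotherm.  The decline of theta with
fatty-acid load is the headline readout of the analysis.

Parameter naming convention: ``n1, k1, dh1, n2, k2, dh2, ...`` index the
site classes in decreasing-affinity order; ``dilution_heat`` is the
constant per-injection offset; ``theta`` (global fits) is the occupancy.
Association constants are fitted as log10(K) internally for conditioning
(disable with ``log_k=False``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd

from .binding import BindingModel, SiteClass
from .experiment import Isotherm, simulate_isotherm

__all__ = [
    "ParameterSpec",
    "FitParameter",
    "FitResult",
    "GlobalFitResult",
    "fit_single_isotherm",
    "fit_global",
    "bootstrap_standard_errors",
    "occupancy_vs_condition",
]

CORRELATION_FLAG_THRESHOLD = 0.95
THETA_BOUNDS = (0.0, 1.5)  # >1 allowed to expose misfit rather than clamp

# Tight trust-region tolerances: heats are O(1e-5) J, and the two-class
# problem has shallow valleys that stall the default 1e-8 criteria.
_LSQ_OPTS = {"ftol": 1e-15, "xtol": 1e-15, "gtol": 1e-15, "x_scale": "jac"}


@dataclass(frozen=True)
class ParameterSpec:
    """Status of one fit parameter.

    ``shared`` matters only in global fits: shared parameters take a
    single value across all isotherms, per-isotherm ones are replicated.
    """

    name: str
    value: float | None = None
    fixed: bool = False
    lower: float = -np.inf
    upper: float = np.inf
    shared: bool = True

    def __post_init__(self) -> None:
        if self.value is not None and not (self.lower <= self.value <= self.upper):
            raise ValueError(
                f"{self.name}: value {self.value} outside [{self.lower}, {self.upper}]"
            )


@dataclass(frozen=True)
class FitParameter:
    value: float
    stderr: float | None = None


@dataclass
class FitResult:
    """Outcome of a least-squares fit."""

    params: dict[str, FitParameter]
    chi2: float
    chi2_reduced: float
    residuals: np.ndarray
    converged: bool
    model: BindingModel
    flags: list[str] = field(default_factory=list)
    n_obs: int = 0
    n_free: int = 0
    multistart_chi2: list[float] = field(default_factory=list)

    def __getitem__(self, name: str) -> float:
        return self.params[name].value


@dataclass
class GlobalFitResult:
    """Outcome of a joint fit over a panel of isotherms."""

    shared: dict[str, FitParameter]
    occupancy: list[FitParameter]
    per_isotherm: list[FitResult]
    chi2: float
    chi2_reduced: float
    converged: bool
    model: BindingModel
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# parameter bookkeeping


def _default_specs(model0: BindingModel) -> dict[str, ParameterSpec]:
    specs: dict[str, ParameterSpec] = {}
    for i, cls in enumerate(model0.site_classes, start=1):
        specs[f"n{i}"] = ParameterSpec(f"n{i}", cls.n_sites, lower=0.0, upper=20.0)
        specs[f"k{i}"] = ParameterSpec(f"k{i}", cls.k_assoc, lower=1.0, upper=1e12)
        specs[f"dh{i}"] = ParameterSpec(f"dh{i}", cls.d_h, lower=-1e6, upper=1e6)
    specs["dilution_heat"] = ParameterSpec("dilution_heat", 0.0, fixed=True)
    return specs


def _merge_specs(model0: BindingModel, specs) -> dict[str, ParameterSpec]:
    merged = _default_specs(model0)
    for spec in specs or []:
        if spec.name not in merged:
            raise ValueError(f"unknown parameter {spec.name!r}")
        base = merged[spec.name]
        value = spec.value if spec.value is not None else base.value
        merged[spec.name] = ParameterSpec(
            spec.name, value, spec.fixed, spec.lower, spec.upper, spec.shared
        )
    return merged


def _add_param(params: lmfit.Parameters, spec: ParameterSpec, log_k: bool) -> str:
    """Add one spec to an lmfit.Parameters set; returns the internal name."""
    if log_k and spec.name.startswith("k"):
        lo = math.log10(spec.lower) if spec.lower > 0 else -12.0
        hi = math.log10(spec.upper) if np.isfinite(spec.upper) else 15.0
        params.add(
            f"log_{spec.name}",
            value=math.log10(spec.value),
            vary=not spec.fixed,
            min=lo,
            max=hi,
        )
        return f"log_{spec.name}"
    params.add(
        spec.name,
        value=spec.value,
        vary=not spec.fixed,
        min=spec.lower,
        max=spec.upper,
    )
    return spec.name


def _get(params, name: str, log_k: bool) -> float:
    if log_k and name.startswith("k") and f"log_{name}" in params:
        return 10.0 ** params[f"log_{name}"].value
    return params[name].value


def _model_from_params(params, n_classes: int, log_k: bool) -> BindingModel:
    return BindingModel(
        [
            SiteClass(
                params[f"n{i}"].value,
                _get(params, f"k{i}", log_k),
                params[f"dh{i}"].value,
            )
            for i in range(1, n_classes + 1)
        ]
    )


def _external_params(result_params, log_k: bool) -> dict[str, FitParameter]:
    """Convert internal (possibly log-scale) parameters to the k/dh/n view."""
    out = {}
    for name, par in result_params.items():
        if name.startswith("log_k"):
            k = 10.0 ** par.value
            # delta method: se(K) = K ln(10) se(log10 K)
            se = k * math.log(10.0) * par.stderr if par.stderr is not None else None
            out[name[4:]] = FitParameter(k, se)
        else:
            out[name] = FitParameter(par.value, par.stderr)
    return out


def _correlation_flags(minimizer_result) -> list[str]:
    flags = []
    covar = getattr(minimizer_result, "covar", None)
    if covar is None:
        return flags
    names = [n for n in minimizer_result.var_names]
    d = np.sqrt(np.diag(covar))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = covar / np.outer(d, d)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            r = corr[i, j]
            if np.isfinite(r) and abs(r) > CORRELATION_FLAG_THRESHOLD:
                flags.append(
                    f"high parameter correlation |r|={abs(r):.3f} between "
                    f"{names[i]} and {names[j]}"
                )
    return flags


# ---------------------------------------------------------------------------
# single-isotherm fit


def _residual_single(params, iso, n_classes, log_k, mask):
    model = _model_from_params(params, n_classes, log_k)
    from dataclasses import replace

    cfg = replace(iso.config, dilution_heat=params["dilution_heat"].value)
    sim = simulate_isotherm(model, cfg, occupancy=1.0)
    res = np.asarray(iso.heats) - np.asarray(sim.heats)
    return res[mask]


def fit_single_isotherm(
    iso: Isotherm,
    model0: BindingModel,
    specs=None,
    *,
    n_starts: int = 8,
    seed: int = 0,
    log_k: bool = True,
    exclude_first: bool = False,
) -> FitResult:
    """Fit one isotherm by bounded nonlinear least squares.

    Parameters
    ----------
    iso
        The isotherm to fit.
    model0
        Starting binding model; its class count fixes the model family
        and its values seed any parameter without an explicit spec.
    specs
        ParameterSpec overrides (fix, bound or re-seed parameters).
    n_starts
        Multi-start count; initial values of free parameters are
        perturbed (seeded) and the best-SSR solution returned.
    exclude_first
        Drop the first injection from the residual, a common ITC
        practice for the small first aliquot.
    """
    if not np.all(np.isfinite(iso.heats)):
        raise ValueError("heats must be finite")
    merged = _merge_specs(model0, specs)
    if all(s.fixed for s in merged.values()):
        raise ValueError("at least one parameter must be free")

    n_classes = len(model0.site_classes)
    params = lmfit.Parameters()
    for spec in merged.values():
        _add_param(params, spec, log_k)

    mask = np.ones(len(iso), dtype=bool)
    if exclude_first:
        mask[0] = False

    rng = np.random.default_rng(seed)
    best = None
    chi2s = []
    for start in range(max(1, n_starts)):
        p0 = params.copy()
        if start > 0:
            for name, par in p0.items():
                if not par.vary:
                    continue
                if name.startswith("log_"):
                    par.value = par.value + rng.uniform(-0.5, 0.5)
                else:
                    scale = abs(par.value) if par.value != 0 else 1.0
                    par.value = par.value + rng.normal(0.0, 0.3 * scale)
                par.value = min(max(par.value, par.min), par.max)
        try:
            res = lmfit.minimize(
                _residual_single,
                p0,
                args=(iso, n_classes, log_k, mask),
                method="least_squares",
                **_LSQ_OPTS,
            )
        except Exception:
            continue
        chi2s.append(float(res.chisqr))
        if best is None or res.chisqr < best.chisqr:
            best = res

    if best is None:
        return FitResult({}, np.inf, np.inf, np.array([]), False, model0,
                         ["optimizer failed on all starts"], int(mask.sum()), 0)

    fitted_model = _model_from_params(best.params, n_classes, log_k)
    n_free = int(best.nvarys)
    n_obs = int(mask.sum())
    return FitResult(
        params=_external_params(best.params, log_k),
        chi2=float(best.chisqr),
        chi2_reduced=float(best.chisqr) / max(n_obs - n_free, 1),
        residuals=np.asarray(best.residual),
        converged=bool(best.success),
        model=fitted_model,
        flags=_correlation_flags(best),
        n_obs=n_obs,
        n_free=n_free,
        multistart_chi2=sorted(chi2s),
    )


# ---------------------------------------------------------------------------
# global fit


def _residual_global(params, panel, n_classes, log_k, mask_list):
    from dataclasses import replace

    model = _model_from_params(params, n_classes, log_k)
    chunks = []
    for i, (iso, mask) in enumerate(zip(panel, mask_list)):
        cfg = replace(iso.config, dilution_heat=params[f"dilution_heat_{i}"].value)
        sim = simulate_isotherm(model, cfg, occupancy=params[f"theta_{i}"].value)
        chunks.append((np.asarray(iso.heats) - np.asarray(sim.heats))[mask])
    return np.concatenate(chunks)


def fit_global(
    panel,
    model0: BindingModel,
    specs=None,
    *,
    theta0: float = 1.0,
    theta_bounds: tuple[float, float] = THETA_BOUNDS,
    log_k: bool = True,
    exclude_first: bool = False,
) -> GlobalFitResult:
    """Joint fit of a panel of isotherms with shared thermodynamics.

    K_i and dH_i (and any other shared specs) take one value across all
    isotherms; the occupancy ``theta_i`` of the highest-affinity class
    floats per isotherm within ``theta_bounds``.  Stoichiometries are
    fixed by convention in the global model (set them via specs).

    With a single isotherm the call degenerates to a single fit of that
    isotherm (with theta playing the role of N1 scaling).
    """
    panel = list(panel)
    if not panel:
        raise ValueError("panel must contain at least one isotherm")
    if len(panel) < 2:
        warnings.warn(
            "fewer than 2 isotherms: global fit degenerates to a single-isotherm fit",
            stacklevel=2,
        )

    merged = _merge_specs(model0, specs)
    n_classes = len(model0.site_classes)

    params = lmfit.Parameters()
    for spec in merged.values():
        if spec.name == "dilution_heat":
            continue  # replicated per isotherm below
        if spec.shared:
            _add_param(params, spec, log_k)
        else:
            raise NotImplementedError(
                "per-isotherm thermodynamic parameters are not supported; "
                "only theta and dilution_heat float per isotherm"
            )
    dil = merged["dilution_heat"]
    for i in range(len(panel)):
        params.add(
            f"dilution_heat_{i}",
            value=dil.value,
            vary=not dil.fixed,
            min=dil.lower,
            max=dil.upper,
        )
        params.add(
            f"theta_{i}", value=theta0, vary=True,
            min=theta_bounds[0], max=theta_bounds[1],
        )

    mask_list = []
    for iso in panel:
        mask = np.ones(len(iso), dtype=bool)
        if exclude_first:
            mask[0] = False
        mask_list.append(mask)

    res = lmfit.minimize(
        _residual_global,
        params,
        args=(panel, n_classes, log_k, mask_list),
        method="least_squares",
        **_LSQ_OPTS,
    )

    ext = _external_params(res.params, log_k)
    shared = {
        name: p
        for name, p in ext.items()
        if not (name.startswith("theta_") or name.startswith("dilution_heat_"))
    }
    occupancy = [ext[f"theta_{i}"] for i in range(len(panel))]
    fitted_model = _model_from_params(res.params, n_classes, log_k)
    flags = _correlation_flags(res)
    for i, th in enumerate(occupancy):
        if th.value > theta_bounds[1] - 0.02 or (
            theta_bounds[0] > 0 and th.value < theta_bounds[0] + 0.02
        ):
            flags.append(f"theta_{i}={th.value:.3f} is near its bound")

    n_obs = int(sum(m.sum() for m in mask_list))
    n_free = int(res.nvarys)
    chi2 = float(res.chisqr)

    # per-isotherm decomposition of the joint residual
    per_iso = []
    offset = 0
    residual = np.asarray(res.residual)
    for i, (iso, mask) in enumerate(zip(panel, mask_list)):
        m = int(mask.sum())
        r = residual[offset : offset + m]
        offset += m
        iso_params = dict(shared)
        iso_params["theta"] = ext[f"theta_{i}"]
        iso_params["dilution_heat"] = ext[f"dilution_heat_{i}"]
        per_iso.append(
            FitResult(
                params=iso_params,
                chi2=float(np.sum(r**2)),
                chi2_reduced=float(np.sum(r**2)) / max(m - n_free / len(panel), 1),
                residuals=r,
                converged=bool(res.success),
                model=fitted_model.scale_first_class(ext[f"theta_{i}"].value),
                n_obs=m,
            )
        )

    return GlobalFitResult(
        shared=shared,
        occupancy=occupancy,
        per_isotherm=per_iso,
        chi2=chi2,
        chi2_reduced=chi2 / max(n_obs - n_free, 1),
        converged=bool(res.success),
        model=fitted_model,
        flags=flags,
    )


def bootstrap_standard_errors(
    iso: Isotherm,
    model0: BindingModel,
    specs=None,
    *,
    n_boot: int = 100,
    seed: int = 0,
    **fit_kwargs,
) -> dict[str, float]:
    """Residual-bootstrap standard errors for a single-isotherm fit.

    Refits ``n_boot`` pseudo-isotherms built by resampling the fit
    residuals with replacement onto the fitted heats (seeded).  An
    alternative to the Jacobian-based errors when the noise model is in
    doubt; costs ``n_boot`` extra fits.
    """
    fit_kwargs.setdefault("n_starts", 1)
    base = fit_single_isotherm(iso, model0, specs, **fit_kwargs)
    if not base.converged:
        raise ValueError("base fit did not converge; no bootstrap")
    fitted_heats = np.asarray(iso.heats)[-base.residuals.size :] - base.residuals
    rng = np.random.default_rng(seed)
    draws: dict[str, list[float]] = {}
    for _ in range(n_boot):
        resampled = fitted_heats + rng.choice(
            base.residuals, size=base.residuals.size, replace=True
        )
        heats = list(iso.heats)
        heats[-base.residuals.size :] = resampled
        res = fit_single_isotherm(iso.with_heats(heats), base.model, specs, **fit_kwargs)
        if not res.converged:
            continue
        for name, p in res.params.items():
            draws.setdefault(name, []).append(p.value)
    return {name: float(np.std(vals, ddof=1)) for name, vals in draws.items()}


def occupancy_vs_condition(
    result: GlobalFitResult,
    metadata,
    key: str = "condition",
    sort_key: str | None = None,
) -> pd.DataFrame:
    """Tidy table of fitted occupancies against an experimental condition.

    ``metadata`` is a list of per-isotherm dicts (e.g. taken from
    ``Isotherm.metadata``) that must contain ``key``; the table is sorted
    by ``sort_key`` (default: ``key``).
    """
    if not result.converged:
        raise ValueError("global fit did not converge; no occupancy table")
    if len(metadata) != len(result.occupancy):
        raise ValueError("metadata length must match number of isotherms")
    rows = []
    for meta, th in zip(metadata, result.occupancy):
        if key not in meta:
            raise KeyError(f"metadata entry missing key {key!r}: {meta}")
        row = dict(meta)
        row["theta"] = th.value
        row["theta_se"] = th.stderr
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.sort_values(sort_key or key, kind="stable").reset_index(drop=True)
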