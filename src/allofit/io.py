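"""File formats, manifests and the two analysis pipelines.

Isotherm CSVs are plain comma-separated files with ASCII headers
(``injection_index, inj_volume_uL, heat_ucal, molar_ratio``) and a YAML
or JSON sidecar carrying the titration configuration
(``v_cell_mL, cell_uM, syringe_uM, temp_C, dilution_heat_ucal``).
Heats are stored in microcalories — the instrument's native scale — and
converted to joules on read.  A panel manifest (YAML) lists isotherm
CSVs with per-isotherm metadata (condition label, fatty-acid mol. eq.)
and drives the global occupancy pipeline.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .binding import BindingModel, SiteClass
from .experiment import InjectionSchedule, Isotherm, TitrationConfig, dilution_trajectory
from .fitting import GlobalFitResult, ParameterSpec, fit_global, occupancy_vs_condition

__all__ = [
    "PanelManifest",
    "RunConfig",
    "IsothermParseError",
    "read_isotherm_csv",
    "write_isotherm_csv",
    "model_from_dict",
    "read_manifest",
    "run_pipeline",
]

UCAL_TO_J = 4.184e-6
CSV_COLUMNS = ["injection_index", "inj_volume_uL", "heat_ucal", "molar_ratio"]


class IsothermParseError(ValueError):
    """Malformed isotherm CSV; message names the offending row."""


@dataclass(frozen=True)
class RunConfig:
    """Run-level knobs recorded in every output."""

    seed: int = 0
    unit: str = "kcal/mol"
    log_level: str = "INFO"
    exclude_first: bool = False


@dataclass(frozen=True)
class PanelManifest:
    """A panel of isotherm files plus the shared model specification."""

    entries: list[dict]
    model: dict
    specs: list[dict] = field(default_factory=list)
    out_dir: str = "."


# ---------------------------------------------------------------------------
# isotherm CSV + sidecar


def _plain(obj):
    """Recursively coerce numpy scalars to plain Python for YAML/JSON."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def _config_to_sidecar(config: TitrationConfig) -> dict:
    return {
        "v_cell_mL": config.v_cell * 1e3,
        "cell_uM": config.m_cell_0 * 1e6,
        "syringe_uM": config.x_syringe * 1e6,
        "temp_C": config.temperature - 273.15,
        "dilution_heat_ucal": config.dilution_heat / UCAL_TO_J,
        "inj_volumes_uL": [v * 1e6 for v in config.schedule.volumes],
    }


def _config_from_sidecar(d: dict) -> TitrationConfig:
    return TitrationConfig(
        v_cell=d["v_cell_mL"] * 1e-3,
        m_cell_0=d["cell_uM"] * 1e-6,
        x_syringe=d["syringe_uM"] * 1e-6,
        temperature=d["temp_C"] + 273.15,
        schedule=InjectionSchedule([v * 1e-6 for v in d["inj_volumes_uL"]]),
        dilution_heat=d.get("dilution_heat_ucal", 0.0) * UCAL_TO_J,
    )


def write_isotherm_csv(iso: Isotherm, path) -> None:
    """Write the CSV and its YAML sidecar (``<path>.yaml``)."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "injection_index": np.arange(1, len(iso) + 1),
            "inj_volume_uL": [v * 1e6 for v in iso.config.schedule.volumes],
            "heat_ucal": [q / UCAL_TO_J for q in iso.heats],
            "molar_ratio": iso.molar_ratio,
        }
    )
    # %.17g guarantees exact float round-trip through text
    df.to_csv(path, index=False, float_format="%.17g")
    sidecar = _config_to_sidecar(iso.config)
    sidecar["occupancy"] = iso.occupancy
    if iso.metadata:
        sidecar["metadata"] = dict(iso.metadata)
    with open(path.with_suffix(path.suffix + ".yaml"), "w") as fh:
        yaml.safe_dump(_plain(sidecar), fh, sort_keys=True)


def read_isotherm_csv(path, normalized: bool = False) -> Isotherm:
    """Read an isotherm CSV plus sidecar back into an ``Isotherm``.

    ``normalized=True`` declares the heat column to be per mole of
    injectant (kcal/mol) rather than per injection (ucal); both
    conventions are accepted on read.  A missing ``molar_ratio`` column
    is recomputed from the configuration.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise IsothermParseError(f"{path}: cannot parse CSV: {exc}") from exc
    for col in ("injection_index", "inj_volume_uL", "heat_ucal"):
        if col not in df.columns and not (normalized and col == "heat_ucal"):
            raise IsothermParseError(f"{path}: missing column {col!r}")
    heat_col = "heat_kcal_per_mol" if normalized else "heat_ucal"
    if heat_col not in df.columns:
        raise IsothermParseError(f"{path}: missing column {heat_col!r}")
    bad = df.index[df[heat_col].isna()]
    if len(bad):
        raise IsothermParseError(f"{path}: missing heat value in row {bad[0] + 2}")
    if (df["inj_volume_uL"] <= 0).any():
        row = df.index[df["inj_volume_uL"] <= 0][0]
        raise IsothermParseError(f"{path}: non-positive injection volume in row {row + 2}")

    sidecar_path = path.with_suffix(path.suffix + ".yaml")
    if sidecar_path.exists():
        with open(sidecar_path) as fh:
            side = yaml.safe_load(fh)
    else:
        json_path = path.with_suffix(path.suffix + ".json")
        if not json_path.exists():
            raise IsothermParseError(f"{path}: no sidecar ({sidecar_path.name} or .json)")
        with open(json_path) as fh:
            side = json.load(fh)
    side = dict(side)
    side.setdefault("inj_volumes_uL", list(df["inj_volume_uL"]))
    config = _config_from_sidecar(side)

    if normalized:
        moles = np.asarray(config.schedule.volumes) * config.x_syringe
        heats = np.asarray(df[heat_col], dtype=float) * 4184.0 * moles
    else:
        heats = np.asarray(df[heat_col], dtype=float) * UCAL_TO_J

    if "molar_ratio" in df.columns and not df["molar_ratio"].isna().any():
        ratios = tuple(float(r) for r in df["molar_ratio"])
    else:
        traj = dilution_trajectory(config)
        ratios = tuple(traj[:, 1] / traj[:, 0])

    return Isotherm(
        config,
        tuple(float(q) for q in heats),
        ratios,
        occupancy=float(side.get("occupancy", 1.0)),
        metadata=dict(side.get("metadata", {})),
    )


# ---------------------------------------------------------------------------
# model / manifest configuration


def model_from_dict(d: dict) -> BindingModel:
    """Binding model from a config mapping.

    Expects ``{"site_classes": [{"n_sites": 1, "k_assoc": 2.9e5,
    "dh_kJ_per_mol": -12.0}, ...]}``; enthalpies in kJ/mol for human
    readability, converted to J/mol internally.
    """
    classes = [
        SiteClass(c["n_sites"], c["k_assoc"], c.get("dh_kJ_per_mol", 0.0) * 1e3)
        for c in d["site_classes"]
    ]
    return BindingModel(classes)


def specs_from_dicts(dicts) -> list[ParameterSpec]:
    return [
        ParameterSpec(
            d["name"],
            d.get("value"),
            d.get("fixed", False),
            d.get("lower", -np.inf),
            d.get("upper", np.inf),
            d.get("shared", True),
        )
        for d in dicts
    ]


def read_manifest(path) -> PanelManifest:
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    entries = raw.get("isotherms", [])
    if not entries:
        raise ValueError(f"{path}: manifest lists no isotherms")
    # paths are relative to the manifest file
    for e in entries:
        e["path"] = str((path.parent / e["path"]).resolve())
    return PanelManifest(
        entries=entries,
        model=raw["model"],
        specs=raw.get("parameters", []),
        out_dir=str(raw.get("out_dir", path.parent)),
    )


# ---------------------------------------------------------------------------
# occupancy pipeline


def _sha256_paths(paths) -> str:
    h = hashlib.sha256()
    for p in paths:
        h.update(Path(p).read_bytes())
    return h.hexdigest()


def run_pipeline(manifest: PanelManifest, config: RunConfig, out_dir=None):
    """Read a panel, global-fit it and export the occupancy table.

    Writes ``occupancy.csv``, ``global_fit.json`` (shared parameters,
    chi2, flags, run log with seed/versions/input hash) and a residual
    plot per arm into ``out_dir``.  Returns the table and fit result.
    """
    out = Path(out_dir if out_dir is not None else manifest.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    panel = []
    metadata = []
    for entry in manifest.entries:
        iso = read_isotherm_csv(entry["path"], normalized=entry.get("normalized", False))
        meta = {**iso.metadata, **{k: v for k, v in entry.items() if k != "path"}}
        panel.append(replace(iso, metadata=meta))
        metadata.append(meta)

    model0 = model_from_dict(manifest.model)
    specs = specs_from_dicts(manifest.specs)
    result = fit_global(panel, model0, specs, exclude_first=config.exclude_first)

    sort_key = "fa_mol_eq" if all("fa_mol_eq" in m for m in metadata) else "condition"
    table = occupancy_vs_condition(result, metadata, key="condition", sort_key=sort_key)
    inputs_hash = _sha256_paths(e["path"] for e in manifest.entries)
    with open(out / "occupancy.csv", "w") as fh:
        fh.write(f"# seed={config.seed} inputs_sha256={inputs_hash}\n")
        table.to_csv(fh, index=False)

    report = {
        "seed": config.seed,
        "version": __version__,
        "python": platform.python_version(),
        "inputs_sha256": inputs_hash,
        "shared_parameters": {
            k: {"value": p.value, "stderr": p.stderr} for k, p in result.shared.items()
        },
        "chi2": result.chi2,
        "chi2_reduced": result.chi2_reduced,
        "converged": result.converged,
        "flags": result.flags,
        "occupancy": [
            {"metadata": m, "theta": t.value, "theta_se": t.stderr}
            for m, t in zip(metadata, result.occupancy)
        ],
    }
    with open(out / "global_fit.json", "w") as fh:
        json.dump(_plain(report), fh, indent=2)

    _plot_panel(panel, result, out / "fit_overview.png")
    return table, result


def _plot_panel(panel, result: GlobalFitResult, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .experiment import normalized_heats, simulate_isotherm

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    for iso, fr in zip(panel, result.per_isotherm):
        label = iso.metadata.get("condition", "")
        q = normalized_heats(iso)
        ax1.plot(iso.molar_ratio, q, "o", ms=3, alpha=0.6)
        cfg = replace(iso.config, dilution_heat=fr.params["dilution_heat"].value)
        fit_iso = simulate_isotherm(fr.model, cfg)
        ax1.plot(iso.molar_ratio, normalized_heats(fit_iso), "-", lw=0.8, label=label)
        ax2.plot(fr.residuals / UCAL_TO_J, ".", ms=2)
    ax1.set_xlabel("molar ratio [X]/[M]")
    ax1.set_ylabel("heat (kcal/mol injectant)")
    ax2.set_xlabel("injection")
    ax2.set_ylabel("residual (ucal)")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
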