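"""Readers, writers and configuration for the package's plain-text formats.

Supported formats (all text, no binaries):

* two-column (time, dH/dlambda) derivative tables with ``#``/``@`` comment
  lines, the dialect common MD engines emit;
* CSV trajectories (time_ps, x_nm, y_nm, z_nm) and optional XYZ export;
* CSV escape-event tables (molecule_id, observed_ns, escaped, escape_ns)
  compatible with the survival module;
* YAML configuration for species, sites and run protocols;
* JSON results, each validated against a small shipped schema.
"""

from __future__ import annotations

import hashlib
import json
import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .survival import SurvivalData
from .ti import DerivativeSeries, TIResult
from .toy_model import SiteModel, Species, Trajectory

__all__ = [
    "read_dhdl_table",
    "write_dhdl_table",
    "trajectory_to_csv",
    "trajectory_from_csv",
    "trajectory_to_xyz",
    "events_to_csv",
    "survival_from_csv",
    "species_from_dict",
    "site_from_dict",
    "load_config",
    "default_toy_config",
    "config_hash",
    "write_json",
    "validate_json",
    "TI_RESULT_SCHEMA",
]

_LAMBDA_RE = re.compile(r"lambda[\s=:]+([0-9.eE+-]+)")


def read_dhdl_table(
    path, lam: float | None = None, burn_in: float = 0.0
) -> DerivativeSeries:
    """Parse a two-column (time_ps, dH/dlambda) plain-text table.

    Lines starting with ``#`` or ``@`` are comments; a comment containing
    ``lambda = X`` supplies the window's lambda unless ``lam`` is given
    explicitly.  Malformed numeric rows are reported with their line
    number.
    """
    path = Path(path)
    times, values = [], []
    header_lam = None
    with path.open() as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(("#", "@")):
                m = _LAMBDA_RE.search(line)
                if m:
                    header_lam = float(m.group(1))
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{ln}: expected two columns, got {line!r}")
            try:
                times.append(float(parts[0]))
                values.append(float(parts[1]))
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: malformed numeric row {line!r}") from exc
    if not values:
        raise ValueError(f"{path}: no data rows (empty series)")
    if lam is None:
        lam = header_lam
    if lam is None:
        raise ValueError(
            f"{path}: lambda not given and no 'lambda = ...' header comment found"
        )
    times = np.asarray(times)
    dt = float(times[1] - times[0]) if len(times) > 1 else float(times[0]) or 1.0
    return DerivativeSeries(lam=lam, dt=dt, values=np.asarray(values), burn_in=burn_in)


def write_dhdl_table(path, series: DerivativeSeries) -> None:
    """Write a derivative series in the two-column dialect (round-trip safe)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"@ lambda = {series.lam:.17g}\n")
        fh.write("# time_ps  dH/dlambda_kJ_mol\n")
        for t, v in zip(series.times, series.values):
            fh.write(f"{t:.17g} {v:.17g}\n")


def trajectory_to_csv(path, traj: Trajectory) -> None:
    pd.DataFrame(
        {
            "time_ps": traj.times,
            "x_nm": traj.positions[:, 0],
            "y_nm": traj.positions[:, 1],
            "z_nm": traj.positions[:, 2],
        }
    ).to_csv(path, index=False, float_format="%.10g")


def trajectory_from_csv(path, species: Species, site: SiteModel) -> Trajectory:
    df = pd.read_csv(path)
    return Trajectory(
        times=df["time_ps"].to_numpy(),
        positions=df[["x_nm", "y_nm", "z_nm"]].to_numpy(),
        species=species,
        site=site,
    )


def trajectory_to_xyz(path, traj: Trajectory, element: str = "X") -> None:
    """Minimal XYZ export (positions converted to Angstrom)."""
    with Path(path).open("w") as fh:
        for t, x in zip(traj.times, traj.positions):
            fh.write(f"1\nt = {t} ps\n")
            fh.write(f"{element} {10*x[0]:.6f} {10*x[1]:.6f} {10*x[2]:.6f}\n")


def events_to_csv(path, events) -> None:
    pd.DataFrame(
        {
            "molecule_id": [e.molecule_id for e in events],
            "observed_ns": [e.time for e in events],
            "escaped": [bool(e.escaped) for e in events],
            "escape_ns": [e.time if e.escaped else np.nan for e in events],
        }
    ).to_csv(path, index=False)


def survival_from_csv(path) -> SurvivalData:
    """Read an event table into a SurvivalData record."""
    df = pd.read_csv(path)
    escaped = df["escaped"].astype(bool)
    return SurvivalData(
        escape_times=df.loc[escaped, "escape_ns"].to_numpy(dtype=float),
        censor_times=df.loc[~escaped, "observed_ns"].to_numpy(dtype=float),
    )


# -- configuration ---------------------------------------------------------


def species_from_dict(d: dict) -> Species:
    return Species(
        name=d["name"],
        charge=float(d.get("charge", 0.0)),
        lj_epsilon=float(d.get("lj_epsilon", 0.0)),
        lj_sigma=float(d.get("lj_sigma", 0.3)),
        mass=float(d.get("mass", 18.0)),
    )


def site_from_dict(d: dict) -> SiteModel:
    centers = [
        (
            np.asarray(c["position"], dtype=float),
            float(c.get("charge", 0.0)),
            float(c.get("lj_epsilon", 0.0)),
            float(c.get("lj_sigma", 0.3)),
        )
        for c in d.get("centers", [])
    ]
    return SiteModel(
        centers=centers,
        dielectric=float(d.get("dielectric", 1.0)),
        cage_k=float(d.get("cage_k", 0.0)),
        site_center=np.asarray(d.get("site_center", [0.0, 0.0, 0.0]), dtype=float),
        escape_radius=float(d.get("escape_radius", 0.6)),
        box_halfwidth=float(d.get("box_halfwidth", 1.0)),
    )


def load_config(path) -> dict:
    """Load a YAML run configuration.

    Returns the raw nested dict with ``species`` and ``sites`` entries
    replaced by constructed objects under ``species_objs``/``site_objs``.
    Referenced external files (``dhdl_tables``) are checked to exist.
    """
    path = Path(path)
    with path.open() as fh:
        cfg = yaml.safe_load(fh)
    cfg["species_objs"] = {
        name: species_from_dict({"name": name, **d})
        for name, d in cfg.get("species", {}).items()
    }
    cfg["site_objs"] = {
        name: site_from_dict(d) for name, d in cfg.get("sites", {}).items()
    }
    for entry in cfg.get("dhdl_tables", []):
        p = Path(entry["path"])
        if not p.is_absolute():
            p = path.parent / p
        if not p.exists():
            raise FileNotFoundError(f"config references missing file {p}")
    return cfg


def default_toy_config() -> dict:
    """The packaged toy sites/species/protocol configuration."""
    from importlib import resources

    with resources.files("densassign.data").joinpath("toy_sites.yaml").open() as fh:
        cfg = yaml.safe_load(fh)
    cfg["species_objs"] = {
        name: species_from_dict({"name": name, **d})
        for name, d in cfg.get("species", {}).items()
    }
    cfg["site_objs"] = {
        name: site_from_dict(d) for name, d in cfg.get("sites", {}).items()
    }
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable hash of a configuration (objects excluded)."""
    clean = {k: v for k, v in cfg.items() if not k.endswith("_objs")}
    return hashlib.sha256(
        yaml.safe_dump(clean, sort_keys=True).encode()
    ).hexdigest()[:16]


# -- JSON results ----------------------------------------------------------

TI_RESULT_SCHEMA = {
    "delta_g_kj_mol": float,
    "stderr_kj_mol": float,
    "schedule": list,
    "window_means_kj_mol": list,
    "window_sems_kj_mol": list,
    "covers_unit_interval": bool,
}

LIFETIME_SCHEMA = {
    "tau_ns": float,
    "is_lower_bound": bool,
    "n_molecules": int,
    "n_events": int,
}

ASSIGNMENT_SCHEMA = {"call": str, "evidence": dict, "rationale": str}


def validate_json(obj: dict, schema: dict, where: str = "result") -> None:
    """Check required keys and their types (bool counts as bool, not int)."""
    for key, typ in schema.items():
        if key not in obj:
            raise ValueError(f"{where}: missing key {key!r}")
        val = obj[key]
        if typ is float:
            ok = isinstance(val, (int, float)) and not isinstance(val, bool)
        elif typ is int:
            ok = isinstance(val, int) and not isinstance(val, bool)
        else:
            ok = isinstance(val, typ)
        if not ok:
            raise ValueError(f"{where}: key {key!r} has type {type(val).__name__}, expected {typ.__name__}")


def write_json(path, obj: dict, schema: dict | None = None) -> None:
    if schema is not None:
        validate_json(obj, schema, where=str(path))
    with Path(path).open("w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def ti_result_to_json(path, result: TIResult) -> None:
    write_json(path, result.to_dict(), schema=TI_RESULT_SCHEMA)
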