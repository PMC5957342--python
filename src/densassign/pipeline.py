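"""End-to-end orchestration: simulate -> TI -> cycles -> lifetimes -> verdict.

The pipeline reproduces, on the toy model, the workflow one would run on
an atomistic system: free simulations of both candidate species at the
site (escape statistics -> censored lifetimes), a relative alchemical
transformation at the site and in bulk (ddG_bind), an absolute decoupling
cycle for water (dG_bind), and the combined three-criterion verdict.

Reproducibility: one global seed is fanned out to per-stage child seeds
through a name-keyed counter scheme, so adding or reordering stages does
not perturb the random streams of the others.
"""

from __future__ import annotations

import dataclasses
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .alchemy import AlchemicalHamiltonian, SoftCoreParams
from .assign import SiteAssessment, Thresholds, verdict
from .cycles import (
    AbsoluteCycle,
    LegResult,
    RelativeCycle,
    RestraintSpec,
    assemble_absolute,
    relative_ddg,
    restraint_free_energy,
)
from .fileio import (
    ASSIGNMENT_SCHEMA,
    LIFETIME_SCHEMA,
    TI_RESULT_SCHEMA,
    config_hash,
    default_toy_config,
    events_to_csv,
    write_json,
)
from .metrics import detect_escape, events_to_survival
from .survival import tau_ml
from .ti import TIResult, integrate_ti, lambda_schedule
from .toy_model import SimulationParams, sample_dhdl, simulate_langevin

__all__ = ["stage_seed", "run_ti_leg", "run_pipeline", "PipelineStageError"]

logger = logging.getLogger("densassign")


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def stage_seed(seed: int, stage: str) -> int:
    """Derive a stable per-stage child seed (< 2^31) from a global seed.

    The stage name is hashed independently of every other stage, so
    inserting a new stage never shifts the random streams of existing
    ones.
    """
    key = zlib.crc32(stage.encode()) & 0x7FFFFFFF
    ss = np.random.SeedSequence((int(seed), key))
    return int(ss.generate_state(1)[0] % (2**31))


def run_ti_leg(
    alch,
    params: SimulationParams,
    n_windows: int,
    seed: int,
    leg_name: str,
) -> TIResult:
    """Simulate every lambda window of one leg and integrate.

    Each window gets its own child seed derived from ``(seed, leg_name,
    window index)``.
    """
    schedule = lambda_schedule("uniform", n_windows)
    windows = []
    for i, lam in enumerate(schedule):
        p = dataclasses.replace(
            params, seed=stage_seed(seed, f"{leg_name}/window{i}")
        )
        windows.append(sample_dhdl(alch, float(lam), p))
    return integrate_ti(windows)


def _write_leg(outdir: Path, name: str, result: TIResult) -> None:
    pd.DataFrame(
        {
            "lambda": result.schedule,
            "mean_kj_mol": result.window_means,
            "sem_kj_mol": result.window_sems,
        }
    ).to_csv(outdir / f"leg_{name}.csv", index=False)
    write_json(outdir / f"leg_{name}.json", result.to_dict(), schema=TI_RESULT_SCHEMA)


def _absolute_legs(
    env, species, where: str, k_x: float, params, n_windows: int, seed: int,
    outdir: Path,
) -> list[LegResult]:
    """posre_on + coulomb_off + lj_off for one environment."""
    legs = []
    common = dict(
        site=env,
        species_a=species,
        species_b=None,
        softcore=SoftCoreParams(),
        restraint_k=k_x,
        restraint_center=env.site_center,
    )
    for mode, name in (
        ("restraint_on", "posre_on"),
        ("decouple_coulomb", "coulomb_off"),
        ("decouple_lj", "lj_off"),
    ):
        alch = AlchemicalHamiltonian(mode=mode, **common)
        tag = f"abs_{species.name}_{where}_{name}"
        res = run_ti_leg(alch, params, n_windows, seed, tag)
        _write_leg(outdir, tag, res)
        legs.append(LegResult(name=name, delta_g=res.delta_g, stderr=res.stderr))
    return legs


def run_absolute_cycle(
    site, bulk, species, k_x: float, params, n_windows: int, seed: int,
    outdir: Path, spec: RestraintSpec,
) -> tuple[float, float, AbsoluteCycle]:
    """Full absolute decoupling cycle for one species; returns dG_bind."""
    legs_site = _absolute_legs(site, species, "site", k_x, params, n_windows, seed, outdir)
    legs_bulk = _absolute_legs(bulk, species, "bulk", k_x, params, n_windows, seed, outdir)
    cycle = AbsoluteCycle(legs_site=legs_site, legs_bulk=legs_bulk)
    dg, err = assemble_absolute(cycle, spec)
    return dg, err, cycle


def run_pipeline(config: dict | None = None, outdir="pipeline_out", seed: int | None = None) -> dict:
    """Execute the full toy workflow; returns a dict of output paths.

    ``config`` defaults to the packaged toy configuration; ``seed``
    overrides the config seed.  All artifacts are plain text (CSV/JSON).
    The run is fully reproducible given the seed.
    """
    cfg = config if config is not None else default_toy_config()
    seed = int(seed if seed is not None else cfg.get("seed", 0))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict = {}

    prot = cfg["protocol"]
    species = cfg["species_objs"]
    sites = cfg["site_objs"]
    th_cfg = cfg.get("thresholds", {})
    thresholds = Thresholds(**th_cfg) if th_cfg else Thresholds()

    def params_for(n_steps: int, burn_in: int | None = None) -> SimulationParams:
        return SimulationParams(
            temperature=prot["temperature"],
            friction=prot["friction"],
            dt=prot["dt"],
            n_steps=int(n_steps),
            burn_in_steps=int(prot["burn_in_steps"] if burn_in is None else burn_in),
            sample_stride=int(prot["sample_stride"]),
            seed=0,
        )

    # -- stage 1: free simulations and lifetimes --------------------------
    stage = "free_sim"
    try:
        fs = cfg["free_sim"]
        site = sites[fs["site"]]
        taus: dict = {}
        for role in ("water", "ion"):
            sp = species[fs[role]]
            events = []
            for rep in range(int(fs["replicas"])):
                p = dataclasses.replace(
                    params_for(fs["n_steps"], burn_in=0),
                    seed=stage_seed(seed, f"free/{role}/{rep}"),
                )
                traj = simulate_langevin(site, sp, p)
                events.append(
                    detect_escape(
                        traj, site, persistence=float(fs["persistence_ps"]),
                        molecule_id=f"{sp.name}_{rep}",
                    )
                )
            events_to_csv(outdir / f"events_{role}.csv", events)
            paths[f"events_{role}"] = outdir / f"events_{role}.csv"
            tau, bound = tau_ml(events_to_survival(events))
            taus[role] = (tau, bound)
            obj = {
                "tau_ns": float(tau),
                "is_lower_bound": bool(bound),
                "n_molecules": len(events),
                "n_events": sum(e.escaped for e in events),
            }
            write_json(outdir / f"lifetime_{role}.json", obj, schema=LIFETIME_SCHEMA)
            paths[f"lifetime_{role}"] = outdir / f"lifetime_{role}.json"
            logger.info("lifetime %s: %.3g ns (bound=%s)", role, tau, bound)
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise PipelineStageError(stage, exc) from exc

    # -- stage 2: relative transformation ---------------------------------
    stage = "relative"
    try:
        rel = cfg["relative"]
        sp_a, sp_b = species[rel["species_a"]], species[rel["species_b"]]
        legs = {}
        for where, env_name in (("site", rel["site"]), ("bulk", rel["bulk"])):
            alch = AlchemicalHamiltonian(
                site=sites[env_name], species_a=sp_a, species_b=sp_b,
                softcore=SoftCoreParams(), mode="relative",
            )
            res = run_ti_leg(
                alch, params_for(rel["n_steps"]), int(rel["n_windows"]),
                seed, f"rel_{where}",
            )
            _write_leg(outdir, f"rel_{where}", res)
            legs[where] = LegResult(where, res.delta_g, res.stderr)
        ddg, ddg_err = relative_ddg(
            RelativeCycle(leg_g3=legs["site"], leg_g2=legs["bulk"])
        )
        write_json(
            outdir / "relative.json",
            {"ddg_bind_kj_mol": float(ddg), "stderr_kj_mol": float(ddg_err)},
        )
        paths["relative"] = outdir / "relative.json"
        logger.info("ddG_bind = %.2f +- %.2f kJ/mol", ddg, ddg_err)
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError(stage, exc) from exc

    # -- stage 3: absolute cycle for water --------------------------------
    stage = "absolute"
    try:
        ab = cfg["absolute"]
        spec = RestraintSpec(
            k_x=float(ab["restraint_k"]), temperature=float(prot["temperature"])
        )
        dg_water = None
        for sp_name in ab["species"]:
            sp = species[sp_name]
            dg, err, _ = run_absolute_cycle(
                sites[ab["site"]], sites[ab["bulk"]], sp,
                float(ab["restraint_k"]), params_for(ab["n_steps"]),
                int(ab["n_windows"]), seed, outdir, spec,
            )
            write_json(
                outdir / f"absolute_{sp.name}.json",
                {
                    "dg_bind_kj_mol": float(dg),
                    "stderr_kj_mol": float(err),
                    "restraint_term_kj_mol": float(restraint_free_energy(spec)),
                },
            )
            paths[f"absolute_{sp.name}"] = outdir / f"absolute_{sp.name}.json"
            logger.info("dG_bind(%s) = %.2f +- %.2f kJ/mol", sp.name, dg, err)
            if sp_name == cfg["free_sim"]["water"] or dg_water is None:
                dg_water = (dg, err)
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError(stage, exc) from exc

    # -- stage 4: verdict ---------------------------------------------------
    stage = "assignment"
    try:
        assessment = SiteAssessment(
            ddg=(ddg, ddg_err),
            dg_bind_water=dg_water,
            tau_water=taus["water"],
            tau_ion=taus["ion"],
            thresholds=thresholds,
        )
        v = verdict(assessment)
        write_json(
            outdir / "assignment.json",
            {"call": v.call, "evidence": v.evidence, "rationale": v.rationale},
            schema=ASSIGNMENT_SCHEMA,
        )
        paths["assignment"] = outdir / "assignment.json"
        write_json(
            outdir / "manifest.json",
            {
                "package_version": __version__,
                "seed": seed,
                "config_hash": config_hash(cfg),
            },
        )
        paths["manifest"] = outdir / "manifest.json"
        logger.info("verdict: %s", v.call)
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError(stage, exc) from exc

    return paths
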