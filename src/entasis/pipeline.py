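"""Configuration-driven orchestration: simulate → analyze → report.

A YAML configuration names, per redox state, either file inputs (a gap
table and optionally a trajectory) or a surrogate sampling block backed by
a shared two-state harmonic model. The pipeline computes gap statistics
with per-state equilibration discards, the linear-response reorganization
energy and driving force, variance-based λ per state, a Marcus-rate grid
over configured couplings, geometry summaries and τ4 (both per-frame-mean
and average-structure variants) when trajectories are available, optional
strain energies from supplied surface energies, and the RMSD–gap Pearson
correlation. Everything lands in TSV tables plus a ``report.json`` whose
floats are formatted at fixed precision, so identical configs and seeds
reproduce it byte for byte.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import energetics, geometry, structure_io, surrogate
from .constants import DEFAULT_TEMPERATURE_K
from .errors import ConfigError, UndefinedCorrelationError

__all__ = ["load_config", "run_pipeline", "simulate_to_files"]

logger = logging.getLogger("entasis")

STATES = ("reduced", "oxidized")
# per-state offsets on the user seed so the two trajectories are independent
_SEED_OFFSETS = {"reduced": 0, "oxidized": 1}

#: Experimental reorganization-energy range for the blue-copper site,
#: kcal/mol. Displayed in the report for context, never asserted.
EXPERIMENTAL_LAMBDA_BAND = (16.0, 28.0)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping):
        raise ConfigError("config file must contain a mapping at top level")
    return dict(cfg)


def _cfg_error(path: str, msg: str) -> ConfigError:
    return ConfigError(f"{path}: {msg}")


def _validate(config: Mapping) -> dict:
    cfg = dict(config)
    states = cfg.get("states")
    if not isinstance(states, Mapping) or set(states) != set(STATES):
        raise _cfg_error("states", f"must map exactly {STATES}")
    for state, block in states.items():
        if not isinstance(block, Mapping):
            raise _cfg_error(f"states.{state}", "must be a mapping")
        has_files = "files" in block
        has_surr = "surrogate" in block
        if has_files == has_surr:
            raise _cfg_error(
                f"states.{state}",
                "exactly one of 'files' or 'surrogate' is required",
            )
        if has_files and "gap_table" not in block["files"]:
            raise _cfg_error(f"states.{state}.files", "needs 'gap_table'")
    discard = cfg.get("discard_before", 0.0)
    if isinstance(discard, (int, float)):
        discard = {s: float(discard) for s in STATES}
    else:
        discard = {s: float(discard.get(s, 0.0)) for s in STATES}
    for s, v in discard.items():
        if v < 0:
            raise _cfg_error(f"discard_before.{s}", "must be >= 0")
    cfg["discard_before"] = discard
    cfg.setdefault("temperature", DEFAULT_TEMPERATURE_K)
    cfg.setdefault("coupling_v_grid", [0.01, 0.1, 1.0])
    cfg.setdefault("seed", 0)
    cfg.setdefault("selection", None)
    cfg.setdefault("geometry", [])
    return cfg


def _build_model(cfg: Mapping) -> surrogate.TwoStateModel:
    block = cfg.get("model")
    if block is None or block == "default":
        return surrogate.default_two_state_model(cfg["temperature"])
    try:
        return surrogate.TwoStateModel(
            k_red=np.asarray(block["k_red"], dtype=float),
            k_ox=np.asarray(block["k_ox"], dtype=float),
            displacement_d=np.asarray(block["d"], dtype=float),
            offset_eps=float(block.get("eps", 0.0)),
        )
    except KeyError as exc:
        raise _cfg_error("model", f"missing field {exc}") from exc


def _geometry_specs(cfg: Mapping) -> list[geometry.InternalCoordinateSpec]:
    specs = []
    for i, item in enumerate(cfg["geometry"]):
        try:
            refs = tuple(
                tuple(a) if isinstance(a, list) else a for a in item["atoms"]
            )
            specs.append(geometry.InternalCoordinateSpec(
                kind=item["kind"], atom_refs=refs, label=item["label"]))
        except (KeyError, ValueError) as exc:
            raise _cfg_error(f"geometry[{i}]", str(exc)) from exc
    return specs


def _acquire_state(state: str, cfg: Mapping,
                   model: surrogate.TwoStateModel | None
                   ) -> tuple[structure_io.GapSeries,
                              structure_io.Trajectory | None]:
    """Load or simulate one state's gap series and optional trajectory."""
    block = cfg["states"][state]
    if "files" in block:
        files = block["files"]
        with open(files["gap_table"]) as fh:
            series = structure_io.read_energy_table(fh, state=state)
        traj = None
        if files.get("trajectory"):
            path = Path(files["trajectory"])
            if path.suffix.lower() == ".xyz":
                with open(path) as fh:
                    traj = structure_io.read_xyz_trajectory(fh)
            else:
                with open(path) as fh:
                    frames = structure_io.read_pdb(fh)
                traj = structure_io.Trajectory(frames, times=series.times
                                               if len(frames) == len(series)
                                               else None)
        logger.info("state %s: loaded %d gap frames from %s", state,
                    len(series), files["gap_table"])
        return series, traj

    sb = block["surrogate"]
    seed = int(cfg["seed"]) + _SEED_OFFSETS[state]
    samples, series = surrogate.sample_state(
        model, state,
        temperature=float(cfg["temperature"]),
        n_frames=int(sb.get("n_frames", 2000)),
        seed=seed,
        sampler=sb.get("sampler", "exact"),
        dt=float(sb.get("dt", 0.01)),
        step_size=sb.get("step_size"),
        burn_in=int(sb.get("burn_in", 0)),
        start=sb.get("start"),
    )
    traj = None
    if sb.get("embed", False):
        template = surrogate.default_site_template()
        if model.dimension == len(template.mapping):
            traj = surrogate.embed_trajectory(samples, template,
                                              dt=float(sb.get("dt", 0.01)))
        else:
            logger.warning(
                "state %s: embedding skipped (model dimension %d != %d "
                "template coordinates)", state, model.dimension,
                len(template.mapping))
    logger.info("state %s: sampled %d surrogate frames (seed %d)", state,
                len(series), seed)
    return series, traj


def _tau4_block(traj: structure_io.Trajectory,
                angle_specs: list[geometry.InternalCoordinateSpec],
                subset) -> dict:
    """Per-frame-mean and average-structure τ4 for one trajectory."""
    per_frame = []
    for frame in traj.frames:
        angles = [geometry.internal_coordinate(frame, s) for s in angle_specs]
        per_frame.append(geometry.tau4(angles))
    avg = geometry.ensemble_average_structure(traj, subset)
    avg_angles = [geometry.internal_coordinate(avg, s) for s in angle_specs]
    return {
        "per_frame_mean": float(np.mean(per_frame)),
        "average_structure": geometry.tau4(avg_angles),
        "n_frames": len(per_frame),
    }


def run_pipeline(config: Mapping, outdir: str | Path) -> dict:
    """Run the full analysis described by ``config``; write outputs to ``outdir``.

    Returns the report dictionary; also writes ``report.json``, per-state
    ``gaps_<state>.tsv`` (time, rmsd where available, delta_e) and
    ``geometry_summary_<state>.tsv`` when geometry specs apply.
    """
    cfg = _validate(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    temperature = float(cfg["temperature"])

    needs_model = any("surrogate" in cfg["states"][s] for s in STATES)
    model = _build_model(cfg) if needs_model else None
    specs = _geometry_specs(cfg)
    angle_specs = [s for s in specs if s.kind == "angle"]
    selection = cfg["selection"]

    stats: dict[str, energetics.GapStatistics] = {}
    report: dict[str, Any] = {
        "temperature_K": temperature,
        "seed": int(cfg["seed"]),
        "states": {},
        "reference_bands": {
            "experimental_lambda_kcal_mol": list(EXPERIMENTAL_LAMBDA_BAND),
            "note": "display-only context; not a pass/fail criterion",
        },
    }

    for state in STATES:
        series, traj = _acquire_state(state, cfg, model)
        discard = cfg["discard_before"][state]
        st = energetics.gap_statistics(series, discard_before=discard)
        stats[state] = st
        logger.info(
            "state %s: discard_before=%.3g ps keeps %d of %d frames; "
            "<dE>=%.4g sd=%.4g kcal/mol", state, discard, st.n_frames,
            len(series), st.mean_delta_e, st.sd_delta_e)

        state_report: dict[str, Any] = {
            "mean_delta_e": st.mean_delta_e,
            "sd_delta_e": st.sd_delta_e,
            "n_frames_kept": st.n_frames,
            "n_frames_total": len(series),
            "discard_before_ps": discard,
            "lambda_var": energetics.variance_lambda(st, temperature),
        }

        rmsd_vals = None
        if traj is not None:
            rmsd_vals = geometry.rmsd_series(traj, 0, selection)
            try:
                r = energetics.gap_geometry_correlation(rmsd_vals, series.delta_e)
                state_report["rmsd_gap_pearson_r"] = r
            except UndefinedCorrelationError:
                state_report["rmsd_gap_pearson_r"] = None
                logger.warning("state %s: RMSD-gap correlation undefined "
                               "(constant series)", state)
            if specs:
                summary = geometry.geometry_summary(traj, specs)
                path = outdir / f"geometry_summary_{state}.tsv"
                structure_io.write_table(
                    summary.to_dict("records"), path.open("w"))
                state_report["geometry_summary_table"] = path.name
            if len(angle_specs) >= 2:
                state_report["tau4"] = _tau4_block(traj, angle_specs, selection)

        rows = []
        for i in range(len(series)):
            row = {"time": series.times[i]}
            if rmsd_vals is not None:
                row["rmsd"] = float(rmsd_vals[i])
            row["delta_e"] = series.delta_e[i]
            rows.append(row)
        gaps_path = outdir / f"gaps_{state}.tsv"
        structure_io.write_table(rows, gaps_path.open("w"))
        state_report["gap_table"] = gaps_path.name
        report["states"][state] = state_report

    lam = energetics.reorganization_energy(stats["reduced"], stats["oxidized"])
    dg = energetics.driving_force(stats["reduced"], stats["oxidized"])
    report["lambda"] = lam
    report["lambda_1dp"] = f"{lam:.1f}"
    report["delta_g"] = dg

    rates = {}
    if lam > 0:
        for v in cfg["coupling_v_grid"]:
            inputs = energetics.MarcusInputs(coupling_v=float(v), lambda_=lam,
                                             delta_g=dg,
                                             temperature=temperature)
            rates[f"{float(v):g}"] = energetics.marcus_rate(inputs)
    else:
        logger.warning("lambda = %.4g <= 0: Marcus rate grid skipped", lam)
    report["rates_per_coupling"] = rates

    strain_cfg = cfg.get("strain") or {}
    strain_report = {}
    for state, block in strain_cfg.items():
        res = energetics.strain_energy(
            float(block["e_in_protein_geometry"]),
            float(block["e_optimized"]))
        strain_report[state] = {
            "e_in_protein_geometry": res.e_in_protein_geometry,
            "e_optimized": res.e_optimized,
            "strain": res.strain,
        }
    if strain_report:
        report["strain"] = strain_report

    if model is not None:
        ref = surrogate.analytic_reference(model, temperature)
        report["surrogate_analytic"] = {
            "lambda_red": ref.lambda_red,
            "lambda_ox": ref.lambda_ox,
            "lambda_eq3": ref.lambda_eq3,
            "delta_g_mean_based": ref.delta_g_mean_based,
            "delta_g_minimum": ref.delta_g_minimum,
        }

    _write_report(report, outdir / "report.json")
    return report


def simulate_to_files(config: Mapping, outdir: str | Path) -> dict[str, list[str]]:
    """Surrogate-only front half: sample both states and write input files.

    Writes per-state gap tables and, when embedding is on, multi-MODEL PDB
    trajectories; returns the written filenames so an ``analyze`` config
    can point at them.
    """
    cfg = _validate(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model = _build_model(cfg)
    written: dict[str, list[str]] = {}
    for state in STATES:
        if "surrogate" not in cfg["states"][state]:
            raise _cfg_error(f"states.{state}",
                             "simulate requires a surrogate block")
        series, traj = _acquire_state(state, cfg, model)
        files = []
        gap_path = outdir / f"gaps_{state}.tsv"
        structure_io.write_table(series.to_records(), gap_path.open("w"),
                                 precision=9)
        files.append(gap_path.name)
        if traj is not None:
            traj_path = outdir / f"trajectory_{state}.pdb"
            structure_io.write_pdb(traj.frames, traj_path.open("w"))
            files.append(traj_path.name)
        written[state] = files
        logger.info("state %s: wrote %s", state, ", ".join(files))
    return written


def _round_sig(obj, sig: int = 6):
    """Recursively format floats at ``sig`` significant digits."""
    if isinstance(obj, float):
        return float(f"{obj:.{sig}g}")
    if isinstance(obj, dict):
        return {k: _round_sig(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_sig(v, sig) for v in obj]
    return obj


def _write_report(report: Mapping, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(_round_sig(dict(report)), fh, indent=2, sort_keys=True)
        fh.write("\n")
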