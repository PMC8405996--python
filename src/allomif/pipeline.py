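"""Configured, logged, reproducible multi-stage pipeline runs.

A run is described by a structured config (YAML or dict) with a ``stages``
list; stages execute in order, write their outputs under the run directory,
and every run directory contains exactly one ``manifest.json`` recording
the tool version, resolved parameters, input digests, seeds and timestamps.
Re-running an identical config with the same seed reproduces deterministic
stage outputs bit-identically.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, ParameterError

logger = logging.getLogger("allomif")

STAGE_KINDS = (
    "simulate_displacements",
    "simulate_decays",
    "correlate",
    "waters",
    "hbonds",
    "relax_fit",
    "compare_structures",
)

_STAGE_KEYS = {"name", "kind", "params"}


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def validate_config(config: dict) -> dict:
    """Schema check; raises ConfigError listing every offending key."""
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")
    problems: list[str] = []
    extra = set(config) - {"stages", "seed", "description"}
    if extra:
        problems.append(f"unknown top-level keys: {sorted(extra)}")
    stages = config.get("stages", [])
    if not isinstance(stages, list):
        problems.append("'stages' must be a list")
        stages = []
    seen = set()
    for i, stage in enumerate(stages):
        where = f"stages[{i}]"
        if not isinstance(stage, dict):
            problems.append(f"{where}: must be a mapping")
            continue
        extra = set(stage) - _STAGE_KEYS
        if extra:
            problems.append(f"{where}: unknown keys {sorted(extra)}")
        name = stage.get("name")
        if not isinstance(name, str) or not name:
            problems.append(f"{where}: missing stage name")
        elif name in seen:
            problems.append(f"{where}: duplicate stage name {name!r}")
        else:
            seen.add(name)
        kind = stage.get("kind")
        if kind not in STAGE_KINDS:
            problems.append(f"{where}: unknown kind {kind!r} (choose from {STAGE_KINDS})")
        if "params" in stage and not isinstance(stage["params"], dict):
            problems.append(f"{where}: params must be a mapping")
    if problems:
        raise ConfigError("; ".join(problems))
    return config


def _check_inputs_exist(config: dict) -> list[str]:
    """All declared input files, verified before any stage runs."""
    paths = []
    for stage in config.get("stages", []):
        for key, val in stage.get("params", {}).items():
            if key.endswith(("_file", "_path")) or key in ("traj", "top", "reference", "mobile", "table"):
                if not Path(val).exists():
                    raise FileNotFoundError(
                        f"stage {stage['name']!r}: input {key}={val!r} does not exist"
                    )
                paths.append(str(val))
    return paths


# ---------------------------------------------------------------------------
# stage implementations

def _stage_simulate_displacements(params: dict, seed: int, out: Path, ctx: dict):
    from .synthetic import (
        CorrelatedTrajectorySpec,
        correlation_pair_matrix,
        generate_correlated_trajectory,
    )

    n_frames = int(params.get("n_frames", 10000))
    n_residues = int(params.get("n_residues", 5))
    corr = None
    if "rho" in params:
        pair = params.get("pair", [0, 1])
        corr = correlation_pair_matrix(n_residues, int(pair[0]), int(pair[1]), float(params["rho"]))
    spec = CorrelatedTrajectorySpec(
        n_frames=n_frames,
        n_residues=n_residues,
        correlation=corr,
        per_component_sd=float(params.get("per_component_sd", 1.0)),
        seed=seed,
    )
    series = generate_correlated_trajectory(spec)
    np.save(out / "displacements.npy", series.samples)
    return {"series": series, "n_frames": n_frames, "n_residues": n_residues}


def _stage_simulate_decays(params: dict, seed: int, out: Path, ctx: dict):
    from .relaxation import T1_DELAYS_S, T1_REPLICATE_DELAYS_S
    from .synthetic import DecayCurveSpec, generate_decay_curves

    spec = DecayCurveSpec(
        true_rate=float(params.get("true_rate", 1.5)),
        initial_intensity=float(params.get("initial_intensity", 100.0)),
        delays=np.asarray(params.get("delays", T1_DELAYS_S), float),
        replicate_delays=np.asarray(params.get("replicate_delays", T1_REPLICATE_DELAYS_S), float),
        noise_sd=float(params.get("noise_sd", 0.02)),
        seed=seed,
    )
    table = generate_decay_curves(spec, n_residues=int(params.get("n_residues", 10)))
    table.to_csv(out / "decays.csv", index=False)
    return {"table": table}


def _stage_correlate(params: dict, seed: int, out: Path, ctx: dict):
    from .correlation import correlation_matrix, correlation_from_trajectory
    from .trajectory import load_trajectory

    if "source" in params:
        series = ctx[params["source"]]["series"]
        result = correlation_matrix(
            series,
            method=params.get("method", "knn"),
            k=int(params.get("k", 4)),
            min_samples=int(params.get("min_samples", 1000)),
        )
    else:
        traj = load_trajectory(params["traj"], params.get("top"))
        result = correlation_from_trajectory(
            traj,
            method=params.get("method", "knn"),
            k=int(params.get("k", 4)),
            min_samples=int(params.get("min_samples", 1000)),
        )
    result.to_frame().to_csv(out / "gcorr.csv")
    pd.DataFrame(
        result.mi,
        index=[f"{c}{n}" for c, n in result.labels],
        columns=[f"{c}{n}" for c, n in result.labels],
    ).to_csv(out / "mi.csv")
    a, b, g = result.top_pair()
    summary = {
        "top_pair": [f"{a[0]}{a[1]}", f"{b[0]}{b[1]}"],
        "top_gcorr": g,
        "method": result.metadata["method"],
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return {"result": result, "summary": summary}


def _stage_waters(params: dict, seed: int, out: Path, ctx: dict):
    from .channel import ChannelDefinition, count_channel_waters
    from .trajectory import load_trajectory

    traj = load_trajectory(params["traj"], params.get("top"))

    def parse_gate(text):
        return tuple(
            (item.split(":")[0], int(item.split(":")[1])) for item in text.split(",")
        )

    channel = ChannelDefinition(
        upper_gate=parse_gate(params["upper"]),
        lower_gate=parse_gate(params["lower"]),
        radial_margin=float(params.get("margin", 2.0)),
        mode=params.get("mode", "cylinder"),
    )
    wc = count_channel_waters(traj, channel)
    pd.DataFrame({"frame": np.arange(wc.n_frames), "count": wc.per_frame}).to_csv(
        out / "counts.csv", index=False
    )
    (out / "summary.json").write_text(
        json.dumps({"mean": wc.mean, "n_frames": wc.n_frames,
                    "radial_margin": channel.radial_margin, "mode": channel.mode},
                   indent=2)
    )
    return {"mean": wc.mean}


def _stage_hbonds(params: dict, seed: int, out: Path, ctx: dict):
    from .hbonds import HBondCriteria, pair_frequency
    from .trajectory import load_trajectory

    traj = load_trajectory(params["traj"], params.get("top"))
    dch, dnum = params["donor"].split(":")
    ach, anum = params["acceptor"].split(":")
    criteria = HBondCriteria(
        max_distance=float(params.get("dist", 3.0)),
        max_angle=float(params.get("angle", 30.0)),
    )
    pf = pair_frequency(traj, (dch, int(dnum)), (ach, int(anum)), criteria)
    df = pd.DataFrame({"frame": np.arange(pf.n_frames), "count": pf.per_frame})
    df.loc[len(df)] = ["mean", pf.bonds_per_frame]
    df.to_csv(out / "hbonds.csv", index=False)
    return {"bonds_per_frame": pf.bonds_per_frame}


def _stage_relax_fit(params: dict, seed: int, out: Path, ctx: dict):
    from .relaxation import fit_rates

    if "source" in params:
        table = ctx[params["source"]]["table"]
    else:
        table = pd.read_csv(params["table"])
    fitted = fit_rates(table)
    fitted.to_csv(out / "rates.csv", index=False)
    return {"rates": fitted}


def _stage_compare_structures(params: dict, seed: int, out: Path, ctx: dict):
    from .structure import read_structure, superpose

    reference = read_structure(params["reference"])
    mobile = read_structure(params["mobile"])
    chain_map = params.get("chains")
    sup = superpose(mobile, reference, selection=params.get("selection", "ca"),
                    chain_map=chain_map)
    (out / "superposition.json").write_text(json.dumps(sup.to_dict(), indent=2))
    pd.DataFrame(
        [{"metric": "rmsd", "selection": params.get("selection", "ca"),
          "value_A": sup.rmsd, "n_atoms_used": sup.n_atoms_used}]
    ).to_csv(out / "report.csv", index=False)
    return {"rmsd": sup.rmsd, "n_atoms_used": sup.n_atoms_used}


_STAGE_IMPL = {
    "simulate_displacements": _stage_simulate_displacements,
    "simulate_decays": _stage_simulate_decays,
    "correlate": _stage_correlate,
    "waters": _stage_waters,
    "hbonds": _stage_hbonds,
    "relax_fit": _stage_relax_fit,
    "compare_structures": _stage_compare_structures,
}


def run_pipeline(
    config: dict | str | Path,
    out_dir: str | Path,
    seed: int | None = None,
) -> dict:
    """Execute a configured pipeline; returns the manifest dict.

    ``config`` is a dict or a path to a YAML document. Stages run in listed
    order; each gets a sub-seed derived deterministically from the run seed
    and its position. A failing stage halts the run with the stage named;
    outputs of completed stages are preserved.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    config = validate_config(config)
    input_paths = _check_inputs_exist(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    run_seed = int(config.get("seed", 0)) if seed is None else int(seed)
    manifest: dict = {
        "tool": "allomif",
        "version": __version__,
        "started": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "seed": run_seed,
        "config": config,
        "input_digests": {p: sha256_file(p) for p in input_paths},
        "stages": [],
        "warnings": [],
    }
    ctx: dict = {}
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    try:
        import warnings as _warnings

        for i, stage in enumerate(config.get("stages", [])):
            name, kind = stage["name"], stage["kind"]
            params = stage.get("params", {})
            stage_seed = run_seed * 1000 + i
            stage_dir = out_dir / name
            stage_dir.mkdir(exist_ok=True)
            logger.info("stage %s (%s) starting, seed %d", name, kind, stage_seed)
            with _warnings.catch_warnings(record=True) as caught:
                _warnings.simplefilter("always")
                try:
                    result = _STAGE_IMPL[kind](params, stage_seed, stage_dir, ctx)
                except Exception:
                    logger.exception("stage %s failed", name)
                    manifest["failed_stage"] = name
                    manifest["finished"] = datetime.datetime.now(
                        datetime.timezone.utc
                    ).isoformat()
                    (out_dir / "manifest.json").write_text(
                        json.dumps(manifest, indent=2, default=str)
                    )
                    raise
            for w in caught:
                manifest["warnings"].append(f"{name}: {w.message}")
            ctx[name] = result
            manifest["stages"].append(
                {"name": name, "kind": kind, "params": params, "seed": stage_seed}
            )
            logger.info("stage %s done", name)
    finally:
        logger.removeHandler(handler)
        handler.close()
    manifest["finished"] = datetime.datetime.now(datetime.timezone.utc).isoformat()
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
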