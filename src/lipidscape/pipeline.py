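"""Pipeline orchestration: run selected stages from one YAML config.

A run config selects stages (``simulate_trajectory``, ``density``,
``simulate_image``, ``image_quant``, ``simulate_assay``, ``kinetics``,
``simulate_spectra``, ``fret``) with per-stage parameter blocks and one
global seed. Per-stage seeds are derived deterministically from the global
seed and the stage name, every output lands under the output directory, and
a JSON manifest records versions, seeds, parameters and SHA-256 checksums
of all data files, so identical configs reproduce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from . import synthetic_data as syn
from . import traj_density as td
from . import image_quant as iq
from . import kinase_kinetics as kk
from . import fret_correction as fc
from .trajectory import LipidTrajectory

log = logging.getLogger("lipidscape")

STAGES = (
    "simulate_trajectory", "density",
    "simulate_image", "image_quant",
    "simulate_assay", "kinetics",
    "simulate_spectra", "fret",
)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: global seed offset by a stage-name hash."""
    return (int(global_seed) + zlib.crc32(stage.encode())) % (2 ** 31)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    unknown = set(cfg.get("stages", [])) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    if "seed" in cfg and not isinstance(cfg["seed"], int):
        raise ValueError("config field 'seed': must be an integer")
    positive = {"bin_width", "cell_radius", "ring_width", "sample_ps"}
    non_negative = {"noise_sigma", "blur_sigma", "skip_ns"}
    for stage, block in (cfg.get("params") or {}).items():
        if stage not in STAGES:
            raise ValueError(f"config field 'params.{stage}': unknown stage")
        for key, val in (block or {}).items():
            if not isinstance(val, (int, float)):
                continue
            if key in positive and val <= 0:
                raise ValueError(f"config field 'params.{stage}.{key}': must be > 0")
            if key in non_negative and val < 0:
                raise ValueError(f"config field 'params.{stage}.{key}': must be >= 0")


def _params_from(block: dict, cls, seed: int):
    fields = {f.name for f in dataclasses.fields(cls)}
    kw = {k: v for k, v in (block or {}).items() if k in fields}
    kw.setdefault("seed", seed)
    return cls(**kw)


def run_pipeline(config: dict, out_dir) -> dict:
    """Execute the selected stages in dependency order; return the manifest."""
    validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = list(config.get("stages", STAGES))
    params = config.get("params") or {}
    manifest = {"version": __version__, "seed": seed, "stages": [], "outputs": {},
                "parameters": params}
    ctx: dict = {}

    order = [s for s in STAGES if s in stages]
    for stage in order:
        log.info("running stage %s", stage)
        ss = stage_seed(seed, stage)
        block = params.get(stage) or {}
        try:
            _run_stage(stage, block, ss, ctx, out)
        except Exception:
            log.exception("stage %s failed", stage)
            raise
        manifest["stages"].append({"name": stage, "seed": ss, "params": block})

    for p in sorted(out.glob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][p.name] = _checksum(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _run_stage(stage: str, block: dict, seed: int, ctx: dict, out: Path) -> None:
    if stage == "simulate_trajectory":
        p = _params_from(block, syn.TrajectoryParams, seed)
        ctx["trajectory"] = syn.gen_membrane_trajectory(p)
        ctx["trajectory"].write(out / "trajectory.tsv")
    elif stage == "density":
        traj = ctx.get("trajectory")
        if traj is None:
            traj = LipidTrajectory.read(block["traj"])
        grid = td.GridSpec.for_box(traj.box, block.get("bin_width", 1.0))
        for which, fn in (("density", td.average_density), ("oracle", td.oracle_density)):
            if which == "oracle" and not block.get("oracle", True):
                continue
            m = fn(
                traj, block.get("species"), block.get("leaflet", "embedded"), grid,
                skip_ns=block.get("skip_ns", 100.0),
                sample_interval_ps=block.get("sample_ps", 250.0),
            )
            tag = block.get("species") or "all"
            np.savetxt(out / f"{which}_{tag}_{m.leaflet or 'both'}.txt", m.values)
            meta = {"n_frames_used": m.n_frames_used, "bin_width": grid.bin_width,
                    "nx": grid.nx, "ny": grid.ny, "species": m.species, "leaflet": m.leaflet}
            (out / f"{which}_{tag}_meta.json").write_text(json.dumps(meta, default=str))
    elif stage == "simulate_image":
        p = _params_from(block, syn.ImageParams, seed)
        img, sidecar = syn.gen_cell_image(p)
        tifffile.imwrite(out / "cell.tif", np.clip(img, 0, 65535).astype(np.uint16))
        (out / "cell_truth.json").write_text(json.dumps(sidecar))
        ctx["image"] = img
    elif stage == "image_quant":
        img = ctx.get("image")
        if img is None:
            img = tifffile.imread(block["image"]).astype(float)
        q = iq.auto_quantify_cell(img, block.get("min_prominence", 0.1))
        pd.DataFrame([dataclasses.asdict(q)]).to_csv(out / "cell_quant.csv", index=False)
        ctx["cell_quant"] = q
    elif stage == "simulate_assay":
        p = _params_from(block, syn.AssayParams, seed)
        run = syn.gen_progress_curve_set(p)
        rows = []
        for S, c in run.curves:
            for t, s in zip(c.time, c.signal):
                rows.append((S, t, s))
        pd.DataFrame(rows, columns=["substrate_mol_percent", "time_s", "signal"]).to_csv(
            out / "progress_curves.csv", index=False
        )
        (out / "assay_truth.json").write_text(json.dumps(run.truth))
        ctx["assay_run"] = run
    elif stage == "kinetics":
        run = ctx["assay_run"]
        fit, points = kk.analyze_assay_run(
            run, n_bootstrap=block.get("bootstrap", 0), seed=seed
        )
        pd.DataFrame(points, columns=["substrate_mol_percent", "initial_velocity"]).to_csv(
            out / "initial_velocities.csv", index=False
        )
        report = {"vmax": fit.vmax, "khalf": fit.khalf, "hill": fit.hill,
                  "rss": fit.rss, "converged": fit.converged, "ci": fit.ci,
                  "seed": seed}
        (out / "kinetic_fit.json").write_text(json.dumps(report))
        ctx["kinetic_fit"] = fit
    elif stage == "simulate_spectra":
        p = _params_from(block, syn.SpectraParams, seed)
        spectra = syn.gen_calibration_spectra(p)
        spectra.to_csv(out / "spectra.csv", index=False)
        ctx["spectra"] = spectra
    elif stage == "fret":
        spectra = ctx.get("spectra")
        if spectra is None:
            spectra = pd.read_csv(block["spectra"])
        est = fc.BleedthroughEstimator(variant=block.get("variant", "cfp_venus"))
        est.fit(spectra)
        corrected = est.transform(spectra)
        corrected.to_csv(out / "spectra_corrected.csv", index=False)
        m = est.model_
        (out / "bleedthrough_model.json").write_text(json.dumps(
            {"a": m.a, "b": m.b, "c": m.c, "a_se": m.a_se, "b_se": m.b_se,
             "variant": m.variant}))
        ctx["bleedthrough"] = m
    else:  # pragma: no cover
        raise ValueError(f"unknown stage {stage}")
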