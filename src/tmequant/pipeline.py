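"""Reproducible multi-stage pipeline over the synthetic co-culture.

A run is described by a small config (YAML or dict): which stages to
execute, an output directory, a seed, and per-stage parameters.  All
randomness is funneled through the one seeded generator family of
:class:`~tmequant.simulate.SimConfig`, so a rerun with the same config
reproduces every deterministic output byte-for-byte.  A provenance
manifest records the config hash, seed, package version and the files
each stage wrote.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .morphometry import bin_compactness, records_to_frame, shape_indices
from .motility import ensemble_msd, speed_table
from .proximity import close_far_groups, compare_speeds, pair_distances
from .proximity import records_to_frame as prox_frame
from .secretion import (
    cluster_profiles,
    correlation_matrix,
    impute_oor,
    pca_scores,
    transform,
    write_plate_csv,
)
from .simulate import (
    SimConfig,
    render_masks,
    simulate_population,
    simulate_secretion_plate,
    simulate_single_cell_secretion,
    simulate_trajectories,
)
from .track_io import read_tracks, write_tracks

log = logging.getLogger("tmequant")

STAGES = ("simulate", "motility", "proximity", "morphometry", "secretion")
_TOP_KEYS = {"stages", "output_dir", "seed", "simulate", "motility",
             "proximity", "morphometry", "secretion"}


class PipelineError(RuntimeError):
    pass


@dataclasses.dataclass
class RunConfig:
    stages: list[str]
    output_dir: Path
    seed: int = 0
    simulate: dict = dataclasses.field(default_factory=dict)
    motility: dict = dataclasses.field(default_factory=dict)
    proximity: dict = dataclasses.field(default_factory=dict)
    morphometry: dict = dataclasses.field(default_factory=dict)
    secretion: dict = dataclasses.field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _TOP_KEYS
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        stages = list(raw.get("stages", STAGES))
        bad = [s for s in stages if s not in STAGES]
        if bad:
            raise ValueError(f"unknown stage(s): {', '.join(bad)}")
        sim = dict(raw.get("simulate", {}))
        sim_fields = {f.name for f in dataclasses.fields(SimConfig)}
        unknown_sim = set(sim) - sim_fields
        if unknown_sim:
            raise ValueError(
                f"unknown simulate key(s): {', '.join(sorted(unknown_sim))}"
            )
        return cls(
            stages=stages,
            output_dir=Path(raw.get("output_dir", "tmequant_run")),
            seed=int(raw.get("seed", 0)),
            simulate=sim,
            motility=dict(raw.get("motility", {})),
            proximity=dict(raw.get("proximity", {})),
            morphometry=dict(raw.get("morphometry", {})),
            secretion=dict(raw.get("secretion", {})),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def canonical(self) -> str:
        # the hash covers the analysis parameters, not where they are written
        d = dataclasses.asdict(self)
        d.pop("output_dir")
        return json.dumps(d, sort_keys=True, default=str)


def _write_csv(df, path: Path) -> Path:
    df.to_csv(path, index=False, float_format="%.9g")
    return path


def run_pipeline(config: RunConfig) -> Path:
    """Execute the selected stages in dependency order; returns the manifest path."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim_kwargs = dict(config.simulate)
    sim_kwargs["seed"] = config.seed
    simcfg = SimConfig(**sim_kwargs)
    manifest: dict = {
        "tool": "tmequant",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(config.canonical().encode()).hexdigest(),
        "stages": [],
        "files": {},
    }

    state: dict = {}
    for stage in [s for s in STAGES if s in config.stages]:
        log.info("stage %s", stage)
        try:
            files = _run_stage(stage, config, simcfg, out, state)
        except Exception as exc:  # noqa: BLE001 - annotate failing stage
            raise PipelineError(f"stage '{stage}' failed: {exc}") from exc
        manifest["stages"].append(stage)
        manifest["files"][stage] = [str(f.relative_to(out)) for f in files]

    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return mpath


def _run_stage(
    stage: str, config: RunConfig, simcfg: SimConfig, out: Path, state: dict
) -> list[Path]:
    import tifffile

    files: list[Path] = []
    if stage == "simulate":
        pop = simulate_population(simcfg)
        tracks, truth = simulate_trajectories(pop, simcfg)
        mask, mask_truth = render_masks(simcfg)
        plate, plate_truth = simulate_secretion_plate(simcfg)
        sc, sc_truth = simulate_single_cell_secretion(simcfg)
        files.append(_write_csv(pop.cells, out / "population.csv"))
        files.append(write_tracks(tracks, out / "tracks.csv"))
        tifffile.imwrite(out / "mask.tif", mask.labels)
        files.append(out / "mask.tif")
        files.append(write_plate_csv(plate, out / "plate.csv"))
        files.append(_write_csv(sc.values.reset_index(names="cell"), out / "single_cell.csv"))
        gt = {
            "cells": truth.cells.to_dict(orient="records"),
            "shapes": mask_truth.shapes.to_dict(orient="records"),
            "plate_log_means": plate_truth.plate_log_means.to_dict(),
            "secretor": sc_truth.secretor.astype(bool).to_dict(),
        }
        gpath = out / "ground_truth.json"
        gpath.write_text(json.dumps(gt, indent=1, sort_keys=True, default=float) + "\n")
        files.append(gpath)
        state.update(pop=pop, tracks=tracks, mask=mask, plate=plate, sc=sc)
    elif stage == "motility":
        tracks = state.get("tracks") or read_tracks(out / "tracks.csv")
        interval = float(config.motility.get("interval", simcfg.dt))
        speeds = speed_table(tracks, interval=interval)
        files.append(_write_csv(speeds, out / "speeds.csv"))
        macro = tracks.by_type("macrophage")
        curve = ensemble_msd(macro if len(macro) else tracks)
        files.append(_write_csv(curve.as_frame(), out / "msd_ensemble.csv"))
        state["speeds"] = speeds
        state["tracks"] = tracks
    elif stage == "proximity":
        tracks = state.get("tracks") or read_tracks(out / "tracks.csv")
        if "speeds" not in state:
            state["speeds"] = speed_table(tracks)
        pop = state.get("pop")
        if pop is None:
            import pandas as pd

            cells = pd.read_csv(out / "population.csv")
        else:
            cells = pop.cells
        speeds = {
            int(r.track_id): float(r.average_speed)
            for r in state["speeds"].itertuples()
            if r.usable
        }
        mac = cells[cells["cell_type"] == "macrophage"]
        tum = cells[cells["cell_type"] == "tumor"]
        records = pair_distances(mac, tum, speeds=speeds)
        k = int(config.proximity.get("k", 15))
        close, far = close_far_groups(records, k=k)
        result = compare_speeds(close, far)
        files.append(_write_csv(prox_frame(records), out / "proximity.csv"))
        jpath = out / "close_far_test.json"
        jpath.write_text(
            json.dumps(dataclasses.asdict(result), indent=2, sort_keys=True) + "\n"
        )
        files.append(jpath)
    elif stage == "morphometry":
        mask = state.get("mask")
        if mask is None:
            from .morphometry import LabeledMask

            mask = LabeledMask(tifffile.imread(out / "mask.tif"))
        records = shape_indices(mask)
        files.append(_write_csv(records_to_frame(records), out / "shapes.csv"))
        cut = float(config.morphometry.get("cut", 0.8))
        bins = bin_compactness(records, cut=cut)
        bpath = out / "compactness_bins.json"
        bpath.write_text(json.dumps(bins, indent=2, sort_keys=True) + "\n")
        files.append(bpath)
    elif stage == "secretion":
        plate = state.get("plate")
        if plate is None:
            from .secretion import read_plate_csv

            plate = read_plate_csv(out / "plate.csv")
        imputed = impute_oor(plate)
        z = transform(imputed, "zscore")
        files.append(write_plate_csv(imputed, out / "plate_imputed.csv"))
        zdf = z.values.reset_index(names="sample")
        files.append(_write_csv(zdf, out / "plate_zscores.csv"))
        corr = correlation_matrix(transform(imputed, "ln"))
        files.append(_write_csv(corr.reset_index(names="sample"), out / "sample_correlation.csv"))
        linkage = str(config.secretion.get("linkage", "average"))
        clus = cluster_profiles(z, method=linkage, n_clusters=2)
        cpath = out / "clusters.json"
        cpath.write_text(
            json.dumps(
                {"leaf_order": clus.leaf_order, "labels": clus.labels},
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )
        files.append(cpath)
        scores, evr = pca_scores(z, n_components=2)
        pdf = scores.reset_index(names="sample")
        pdf["explained_variance_ratio_pc"] = list(evr) + [np.nan] * (len(pdf) - len(evr))
        files.append(_write_csv(pdf, out / "pca_scores.csv"))
    return files
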