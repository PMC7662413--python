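"""End-to-end orchestration: simulate/load -> fit -> life tables -> detect.

A single flat YAML config drives every stage. It either names input files
(``mortality_csv`` + ``graph_file``) or carries simulation parameters under
``simulation:``; fitting, life-table and detection settings live under
``model:``, ``lifetable:`` and ``detection:``. Every run writes a JSON
manifest recording the config snapshot, seeds, SHA-256 digests of all
outputs, timestamps and per-stage status, so deterministic stages can be
checked for bit-identical reproduction.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from . import detection as det
from . import io as msio
from . import lifetable as lt
from . import model as msmodel
from . import synthetic as syn

__all__ = ["run_pipeline", "make_fixtures", "PipelineError"]

log = logging.getLogger("mortsurv.pipeline")


class PipelineError(RuntimeError):
    """A stage failure, labeled with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(manifest: dict, name: str):
    class _Ctx:
        def __enter__(self):
            log.info("stage %s: start", name)
            self.t0 = time.time()
            return self

        def __exit__(self, exc_type, exc, tb):
            status = "ok" if exc_type is None else f"failed: {exc}"
            manifest["stages"][name] = {
                "status": status, "seconds": round(time.time() - self.t0, 3),
            }
            log.info("stage %s: %s", name, status)
            if exc_type is not None and not isinstance(exc, PipelineError):
                raise PipelineError(name, str(exc)) from exc
            return False

    return _Ctx()


def run_pipeline(config_path, outdir=None, seed: int | None = None) -> dict:
    """Execute all stages from a config file; returns the run manifest.

    Stage outputs are written under ``outdir`` (default: the config's
    ``outdir`` entry, falling back to the config file's directory / "run").
    Any stage failure aborts with a stage-labeled error; outputs of earlier
    stages are retained on disk.
    """
    config_path = Path(config_path)
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh) or {}
    outdir = Path(outdir or cfg.get("outdir") or config_path.parent / "run")
    outdir.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "config_file": str(config_path),
        "config": cfg,
        "package_version": __import__("mortsurv").__version__,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
        "outputs": {},
        "inputs": {},
        "seeds": {},
    }

    def record(name: str, path: Path):
        manifest["outputs"][name] = {"path": str(path), "sha256": _digest(path)}

    # ---- stage 1: data (simulate or load) -------------------------------
    truth = None
    with _stage(manifest, "data"):
        if "simulation" in cfg:
            sim_kwargs = dict(cfg["simulation"])
            if seed is not None:
                sim_kwargs["seed"] = seed
            sim_kwargs["anomalies"] = [tuple(a) for a in sim_kwargs.get("anomalies", [])]
            spec = syn.SimulationSpec(**sim_kwargs)
            manifest["seeds"]["simulation"] = spec.seed
            data, truth = syn.simulate_dataset(spec)
            graph = syn.make_lattice_graph(spec.rows, spec.cols)
            msio.write_table(data.to_frame(), outdir / "dataset.csv")
            msio.write_region_graph(graph, outdir / "graph.txt")
            record("dataset", outdir / "dataset.csv")
            record("graph", outdir / "graph.txt")
        else:
            for key in ("mortality_csv", "graph_file"):
                if key not in cfg:
                    raise ValueError(f"config needs either 'simulation' or '{key}'")
            data = msio.read_mortality_table(cfg["mortality_csv"], cfg.get("sex", "female"))
            graph = msio.read_region_graph(cfg["graph_file"])
            for key in ("mortality_csv", "graph_file"):
                manifest["inputs"][key] = {
                    "path": cfg[key], "sha256": _digest(Path(cfg[key])),
                }

    # ---- stage 2: fit ----------------------------------------------------
    with _stage(manifest, "fit"):
        model_kwargs = dict(cfg.get("model", {}))
        if seed is not None:
            model_kwargs["seed"] = seed + 1
        config = msmodel.ModelConfig(**model_kwargs)
        manifest["seeds"]["mcmc"] = config.seed
        samples = msmodel.fit(data, graph, config)
        samples.save(outdir / "posterior")
        record("posterior_manifest", outdir / "posterior" / "manifest.json")
        if config.n_chains >= 2:
            report = msmodel.convergence_report(samples)
            msio.write_table(report, outdir / "convergence.csv")
            record("convergence", outdir / "convergence.csv")

    # ---- stage 3: life tables -------------------------------------------
    with _stage(manifest, "lifetable"):
        lt_cfg = cfg.get("lifetable", {})
        table_config = lt.AbridgedLifeTableConfig.from_age_groups(
            data.age_groups,
            a_infant=lt_cfg.get("a_infant", 0.1),
            a_default=lt_cfg.get("a_default", 0.5),
        )
        area_tab = lt.area_year_e0(samples, data, table_config)
        decile_draws = lt.e0_draws_decile_year(samples, data, table_config)
        decile_tab = lt.decile_year_e0(samples, data, table_config)
        msio.write_table(area_tab, outdir / "e0_area_year.csv")
        msio.write_table(decile_tab, outdir / "e0_decile_year.csv")
        record("e0_area_year", outdir / "e0_area_year.csv")
        record("e0_decile_year", outdir / "e0_decile_year.csv")
        period_a = lt_cfg.get("gap_period_a", [2012, 2013])
        period_b = lt_cfg.get("gap_period_b", [2017, 2018])
        if all(y in data.years for y in list(period_a) + list(period_b)):
            gap = lt.e0_gap(decile_draws, data.years, period_a, period_b,
                            labels=list(range(1, decile_draws.shape[1] + 1)),
                            unit_name="decile")
            msio.write_table(gap, outdir / "e0_gap_decile.csv")
            record("e0_gap_decile", outdir / "e0_gap_decile.csv")

    # ---- stage 4: detection ---------------------------------------------
    with _stage(manifest, "detect"):
        det_cfg = cfg.get("detection", {})
        threshold = det_cfg.get("threshold", det.DEFAULT_THRESHOLD)
        window = det_cfg.get("window", list(det.DEFAULT_WINDOW))
        result = det.detect_from_samples(samples, threshold, window)
        msio.write_table(result.to_frame(), outdir / "detection.csv")
        record("detection", outdir / "detection.csv")

    # ---- stage 5: report -------------------------------------------------
    with _stage(manifest, "report"):
        msio.write_table(result.flagged_table(), outdir / "flagged.csv")
        msio.write_table(result.area_summary(), outdir / "flagged_areas.csv")
        record("flagged", outdir / "flagged.csv")
        record("flagged_areas", outdir / "flagged_areas.csv")
        if truth is not None:
            truth_rows = [
                {"area": data.area_ids[a], "year": data.years[t], "shift": s}
                for a, t, s in truth.anomalies
            ]
            import pandas as pd

            msio.write_table(
                pd.DataFrame(truth_rows, columns=["area", "year", "shift"]),
                outdir / "true_anomalies.csv",
            )
            record("true_anomalies", outdir / "true_anomalies.csv")

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest


def make_fixtures(out_dir) -> None:
    """Write the canonical tiny fixtures used across the test suite.

    Deterministic: repeated calls produce byte-identical files. Includes a
    2-area x 3-age x 2-year mortality CSV, a path-graph file, and an S=4
    posterior omega-draw table with hand-computable exceedance
    probabilities.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    deaths = {  # (area, age, year) -> (deaths, population)
        ("A1", "0-0", 2017): (1, 500.0), ("A1", "0-0", 2018): (0, 510.0),
        ("A1", "1-4", 2017): (2, 2000.0), ("A1", "1-4", 2018): (1, 2020.0),
        ("A1", "5+", 2017): (30, 8000.0), ("A1", "5+", 2018): (28, 8100.0),
        ("A2", "0-0", 2017): (2, 600.0), ("A2", "0-0", 2018): (1, 620.0),
        ("A2", "1-4", 2017): (0, 2400.0), ("A2", "1-4", 2018): (3, 2380.0),
        ("A2", "5+", 2017): (45, 9000.0), ("A2", "5+", 2018): (47, 9050.0),
    }
    decile = {"A1": 2, "A2": 9}
    for (area, age, year), (d, p) in sorted(deaths.items()):
        rows.append(f"{area},{age},{year},female,{d},{p},{decile[area]}")
    header = "area,age_group,year,sex,deaths,population,decile"
    (out_dir / "tiny_mortality.csv").write_text(
        header + "\n" + "\n".join(rows) + "\n"
    )

    (out_dir / "tiny_graph.txt").write_text("2\n1 1 2\n2 1 1\n")

    # S=4 draws of omega for 2 areas x 2 years, flattened one row per draw:
    # columns i0t0, i0t1, i1t0, i1t1. Exceedance: 1.0, 0.5, 0.25, 0.0.
    omega_rows = [
        "draw,i0t0,i0t1,i1t0,i1t1",
        "0,0.3,-1.0,-2.0,-0.1",
        "1,0.1,1.0,-1.0,-0.2",
        "2,0.2,-0.5,0.0,-0.3",
        "3,0.4,0.5,1.0,-0.4",
    ]
    (out_dir / "tiny_omega_draws.csv").write_text("\n".join(omega_rows) + "\n")
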