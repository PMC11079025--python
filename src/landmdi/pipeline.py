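"""End-to-end orchestration: generate -> classify -> index -> combos ->
uncertainty -> report, as pure functions of config + inputs.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from . import __version__
from .combos import combo_grid, coarsen_display, enumerate_combos, top_combinations
from .criticality import PROCESS_ORDER, build_critical_stack, compute_aridity, registry_thresholds
from .grid import Grid, LandMask, ZonePartition, area_km2, read_raster, write_raster
from .lmi import classify_lmi, compute_lmi, lmi_histogram, zonal_stats
from .synthetic import (
    AGRICULTURAL_CODES,
    ARABLE_CODES,
    ScenarioConfig,
    gen_process_inputs,
)
from .trends import trend_raster
from .uncertainty import (
    MATRIX_COLUMNS,
    build_input_matrix,
    class_area_error_ranges,
    fit_rf_uncertainty,
    sample_thresholds,
    simulate_lmi_labels,
)

log = logging.getLogger("landmdi")

DEFAULT_UNCERTAINTY = {
    "enabled": True,
    "n_sims": 2000,
    "sd_fraction": 0.1,
    "n_trees": 200,
    "reps": 5,
    "max_rows": 100_000,
    "target": "perturbed",
}

_CSV_KW = dict(index=False, float_format="%.10g")


def scenario_config_from_dict(d: dict | None, seed: int | None = None) -> ScenarioConfig:
    d = dict(d or {})
    if "shape" in d:
        d["shape"] = tuple(d["shape"])
    if seed is not None:
        d["seed"] = seed
    return ScenarioConfig(**d)


def write_scenario(outdir, land, zones, inputs, truth=None) -> None:
    """Persist a generated scenario as GeoTIFFs plus a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"processes": {}, "version": __version__}
    write_raster(outdir / "landuse.tif", land.codes)
    write_raster(outdir / "zones.tif", zones.zones)
    manifest["landuse"] = {
        "file": "landuse.tif",
        "agricultural_codes": sorted(land.agricultural_codes),
        "arable_codes": sorted(land.arable_codes),
    }
    manifest["zones"] = {
        "file": "zones.tif",
        "completeness": {str(k): v for k, v in zones.completeness.items()},
        "missing": {str(k): v for k, v in zones.missing.items()},
    }
    for pid, parts in inputs.items():
        entry: dict = {}
        for name, obj in parts.items():
            if name == "planted_slope":
                entry[name] = obj
            elif name == "metals":
                entry["metals"] = {}
                for metal, g in obj.items():
                    fn = f"{pid}_{metal}.tif"
                    write_raster(outdir / fn, g)
                    entry["metals"][metal] = fn
            elif name == "stack":
                fn = f"{pid}_stack.tif"
                write_raster(outdir / fn, obj)
                entry["stack"] = fn
            else:
                fn = f"{pid}_{name}.tif"
                write_raster(outdir / fn, obj)
                entry[name] = fn
        manifest["processes"][pid] = entry
    if truth is not None:
        (outdir / "truth").mkdir(exist_ok=True)
        for pid, g in truth.masks.items():
            write_raster(outdir / "truth" / f"{pid}.tif", g)
        write_raster(outdir / "truth" / "lmi.tif", truth.lmi)
        manifest["truth"] = {
            "dir": "truth",
            "class_proportions": {str(k): v for k, v in truth.class_proportions.items()},
        }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def load_scenario(indir):
    """Read a scenario directory back into (land, zones, inputs)."""
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    land = LandMask(
        codes=read_raster(indir / manifest["landuse"]["file"]),
        agricultural_codes=frozenset(manifest["landuse"]["agricultural_codes"]),
        arable_codes=frozenset(manifest["landuse"]["arable_codes"]),
    )
    zinfo = manifest["zones"]
    zones = ZonePartition(
        zones=read_raster(indir / zinfo["file"]),
        completeness={int(k): v for k, v in zinfo["completeness"].items()},
        missing={int(k): v for k, v in zinfo["missing"].items()},
    )
    inputs: dict[str, dict] = {}
    for pid, entry in manifest["processes"].items():
        parts: dict = {}
        for name, value in entry.items():
            if name == "planted_slope":
                parts[name] = value
            elif name == "metals":
                parts["metals"] = {m: read_raster(indir / fn) for m, fn in value.items()}
            elif name == "stack":
                parts["stack"] = read_raster(indir / value)
            else:
                parts[name] = read_raster(indir / value)
        inputs[pid] = parts
    return land, zones, inputs


def prepare_classification_inputs(inputs: dict):
    """Derive trend slope/p grids and the aridity index.

    Returns ``(classify_inputs, raw_columns)`` where ``raw_columns``
    maps every uncertainty-matrix column name to its grid.
    """
    classify_inputs: dict[str, dict] = {}
    raw: dict[str, Grid] = {}
    for pid, parts in inputs.items():
        if "stack" in parts or "slope" in parts:
            if "stack" in parts:
                slope, p = trend_raster(parts["stack"])
            else:  # slope/p supplied directly
                slope, p = parts["slope"], parts["p"]
            classify_inputs[pid] = {"slope": slope, "p": p}
            raw[f"{pid}_slope"] = slope
            raw[f"{pid}_p"] = p
        elif pid == "A":
            ai, _, _ = compute_aridity(parts["p"], parts["pet"])
            classify_inputs[pid] = parts
            raw["AI"] = ai
        elif pid == "SPHM":
            classify_inputs[pid] = parts
            for m, g in parts["metals"].items():
                raw[f"SPHM_{m}"] = g
        elif pid == "SNI":
            classify_inputs[pid] = parts
            for name, g in parts.items():
                raw[f"SNI_{name}"] = g
        elif pid in ("SC", "SPP"):
            classify_inputs[pid] = parts
            if "score" in parts:
                raw["SC_score" if pid == "SC" else "SPP_rs"] = parts["score"]
        else:
            classify_inputs[pid] = parts
            raw[pid] = parts["value"]
    return classify_inputs, raw


def run_pipeline(
    config: dict | None = None,
    outdir: str | Path = "run",
    seed: int | None = None,
    strata: tuple[str, ...] = ("agricultural", "arable"),
) -> dict:
    """Run every stage on a synthetic scenario and write all artifacts.

    Returns the in-memory results keyed by stage.  Reports (CSV) are
    written with fixed formatting so reruns are byte-identical.
    """
    config = dict(config or {})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    timings: dict[str, float] = {}

    def tick(stage):
        timings[stage] = round(time.time() - t_start, 3)
        log.info("stage %s done at +%.2fs", stage, timings[stage])

    scen_cfg = scenario_config_from_dict(config.get("scenario"), seed=seed)
    land, zones, inputs, truth = gen_process_inputs(scen_cfg)
    write_scenario(outdir / "scenario", land, zones, inputs, truth)
    tick("generate")

    classify_inputs, raw = prepare_classification_inputs(inputs)
    masks, missing = build_critical_stack(classify_inputs)
    for m in masks:
        write_raster(outdir / f"critical_{m.process_id}.tif", m.mask)
    tick("classify")

    results: dict = {
        "config": config,
        "scenario": scen_cfg,
        "land": land,
        "zones": zones,
        "truth": truth,
        "masks": masks,
        "missing": missing,
    }

    combos_cfg = dict(config.get("combos") or {})
    top_k = int(combos_cfg.get("top_k", 12))
    factor = int(combos_cfg.get("coarsen_factor", 10))

    for stratum in strata:
        lmi = compute_lmi(masks, land, stratum)
        classes = classify_lmi(lmi)
        write_raster(outdir / f"lmi_{stratum}.tif", lmi.counts)
        write_raster(outdir / f"lmi_class_{stratum}.tif", classes)
        report = zonal_stats(classes, lmi, zones, land, stratum)
        report.to_csv(outdir / f"zonal_report_{stratum}.csv", **_CSV_KW)
        hist = lmi_histogram(lmi)
        hist.to_csv(outdir / f"lmi_histogram_{stratum}.csv", **_CSV_KW)

        stratum_area = area_km2(
            land.stratum_mask(stratum).astype(np.uint8), scen_cfg.cell_size_m
        )
        table = enumerate_combos(masks, classes, stratum_area_km2=stratum_area)
        table.to_csv(outdir / f"combos_{stratum}.csv", **_CSV_KW)
        tops = []
        for cls in range(1, 6):
            sub, meets = top_combinations(table, cls, k=top_k)
            sub = sub.assign(meets_half_coverage=meets)
            tops.append(sub)
        import pandas as pd

        pd.concat(tops, ignore_index=True).to_csv(
            outdir / f"combos_top_{stratum}.csv", **_CSV_KW
        )
        keys = combo_grid(masks, classes)
        write_raster(outdir / f"combo_display_{stratum}.tif", coarsen_display(keys, factor))
        results[stratum] = {
            "lmi": lmi,
            "classes": classes,
            "report": report,
            "histogram": hist,
            "combos": table,
        }
    tick("lmi+combos")

    unc_cfg = {**DEFAULT_UNCERTAINTY, **(config.get("uncertainty") or {})}
    if unc_cfg["enabled"]:
        stratum = strata[0]
        matrix = build_input_matrix(
            raw,
            land.stratum_mask(stratum),
            max_rows=unc_cfg["max_rows"],
            seed=scen_cfg.seed + 1,
        )
        samples = sample_thresholds(
            registry_thresholds(),
            n_sims=unc_cfg["n_sims"],
            sd_fraction=unc_cfg["sd_fraction"],
            seed=scen_cfg.seed + 2,
        )
        labels, freq = simulate_lmi_labels(matrix, samples)
        maps = fit_rf_uncertainty(
            matrix,
            labels,
            n_trees=unc_cfg["n_trees"],
            reps=unc_cfg["reps"],
            seed=scen_cfg.seed + 3,
            target=unc_cfg["target"],
        )
        for k, g in maps.probabilities.items():
            write_raster(outdir / f"prob_class{k}_{stratum}.tif", g)
        write_raster(outdir / f"predicted_class_{stratum}.tif", maps.predicted)
        maps.importances.rename("importance").to_frame().rename_axis("column").to_csv(
            outdir / "rf_importances.csv", float_format="%.10g"
        )
        ranges = class_area_error_ranges(
            matrix, labels, maps, cell_area_km2=(scen_cfg.cell_size_m / 1000.0) ** 2
        )
        ranges.to_csv(outdir / "class_area_ranges.csv", **_CSV_KW)
        results["uncertainty"] = {
            "matrix": matrix,
            "samples": samples,
            "labels": labels,
            "freq": freq,
            "maps": maps,
            "ranges": ranges,
        }
    tick("uncertainty")

    run_manifest = {
        "version": __version__,
        "seed": scen_cfg.seed,
        "thresholds": registry_thresholds(),
        "missing_processes": missing,
        "uncertainty": {k: v for k, v in unc_cfg.items()},
        "strata": list(strata),
        "timings_s": timings,
    }
    if unc_cfg["enabled"]:
        run_manifest["oob_error"] = results["uncertainty"]["maps"].oob_error
    (outdir / "run_manifest.json").write_text(
        json.dumps(run_manifest, indent=2, sort_keys=True, default=str)
    )
    return results
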