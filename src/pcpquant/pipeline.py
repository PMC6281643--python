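"""Run orchestration: stage-by-stage processing of a simulated experiment.

A *run directory* is created by :func:`run_simulate` (fields, ground truth,
manifest, and the run configuration) and then populated stage by stage:
``segment`` -> ``tpcp`` / ``rpcp`` / ``membrane`` / ``docking`` ->
``report``.  Each stage reads only the products of its upstream stages and
writes its own CSV/TIFF/JSON products; a missing upstream product raises
:class:`PipelineError` naming the stage to run first.  All outputs embed
the run config hash and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import docking as dk
from . import membrane as mb
from . import rpcp, spots, tpcp
from .io import config_hash, read_csv, read_field, write_csv
from .segmentation import MembraneMaskParams, regions_to_table, segment_cells
from .simulate import NoiseModel, SimulationConfig, generate_two_genotype_experiment
from .spots import SpotDetectionParams
from .stats import compare_two_groups

__all__ = [
    "PipelineError",
    "default_run_config",
    "run_simulate",
    "run_segment",
    "run_tpcp",
    "run_rpcp",
    "run_membrane",
    "run_docking",
    "run_report",
]

log = logging.getLogger("pcpquant")


class PipelineError(RuntimeError):
    pass


def default_run_config() -> dict:
    """A complete run configuration (two genotypes, WT-like vs KO-like)."""
    return {
        "seed": 0,
        "n_fields": 2,
        "labels": ["WT", "KO"],
        "base": {},
        "genotypes": {
            "WT": {},
            "KO": {
                "displacement_um": 0.3,
                "displacement_coordination_kappa": 0.2,
                "rotation_kappa": 0.5,
                "dot_density_per_um": 0.1,
                "docked_fraction": 0.3,
            },
        },
        "segmentation": {},
        "spots": {},
        "pairing": {"max_pair_dist_um": 0.8},
        "tpcp": {"noise_floor_um": 0.2},
        "rpcp": {"min_bb": 5, "n_permutations": 999, "csd_method": "circular"},
        "membrane": {"markers": ["enriched", "uniform"]},
        "docking": {"delta_z_um": 1.0, "docked_fraction_threshold": 0.8, "min_bb": 10},
    }


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    out.update(override or {})
    return out


def _sim_config(cfg: dict, genotype: str) -> SimulationConfig:
    params = _merge(cfg.get("base", {}), cfg.get("genotypes", {}).get(genotype, {}))
    noise = params.pop("noise", None)
    if noise is not None:
        params["noise"] = NoiseModel(**noise)
    for key in ("field_size_um", "bb_per_cell"):
        if key in params:
            params[key] = tuple(params[key])
    return SimulationConfig(**params)


def _load_run(run_dir) -> tuple:
    run_dir = Path(run_dir)
    cfg_path = run_dir / "config.yaml"
    manifest_path = run_dir / "manifest.csv"
    if not cfg_path.exists() or not manifest_path.exists():
        raise PipelineError(
            f"{run_dir} is not a run directory; run 'simulate' first "
            f"(missing {cfg_path.name} or {manifest_path.name})"
        )
    cfg = yaml.safe_load(cfg_path.read_text())
    manifest = read_csv(manifest_path)
    return run_dir, cfg, manifest


def _provenance(cfg: dict) -> dict:
    return {"config_hash": config_hash(cfg), "seed": cfg.get("seed", 0)}


def _require(path: Path, stage: str):
    if not Path(path).exists():
        raise PipelineError(f"missing {path}; run the '{stage}' stage first")


def _write_json(payload: dict, path: Path, cfg: dict):
    payload = dict(payload)
    payload["provenance"] = _provenance(cfg)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=1, default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


# ---------------------------------------------------------------------------
# stages


def run_simulate(config: dict, run_dir) -> pd.DataFrame:
    """Simulate a two-genotype experiment into ``run_dir``."""
    cfg = _merge(default_run_config(), config or {})
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    labels = tuple(cfg["labels"])
    manifest = generate_two_genotype_experiment(
        _sim_config(cfg, labels[0]),
        _sim_config(cfg, labels[1]),
        n_fields=int(cfg["n_fields"]),
        seed=int(cfg["seed"]),
        out_dir=run_dir,
        labels=labels,
    )
    (run_dir / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=False))
    log.info("simulate: %d fields in %s", len(manifest), run_dir)
    return manifest


def _field_stack(run_dir: Path, row) -> "ImageStack":
    return read_field(run_dir / row["image"])


def run_segment(run_dir) -> pd.DataFrame:
    """Membrane selection and cell segmentation for every field."""
    run_dir, cfg, manifest = _load_run(run_dir)
    params = MembraneMaskParams(**cfg.get("segmentation", {}))
    out = run_dir / "segment"
    out.mkdir(exist_ok=True)
    tables = []
    for _, row in manifest.iterrows():
        stack = _field_stack(run_dir, row)
        plane = stack.plane("membrane")
        labels, regions, skeleton, selection = segment_cells(
            plane, params, stack.pixel_size_um
        )
        stem = row["field_id"]
        tifffile.imwrite(out / f"{stem}_labels.tif", labels.astype(np.uint16))
        tifffile.imwrite(out / f"{stem}_selection.tif", (selection * np.uint8(255)))
        table = regions_to_table(regions, stack.pixel_size_um)
        table.insert(0, "field_id", stem)
        table.insert(1, "genotype", row["genotype"])
        write_csv(table, out / f"{stem}_cells.csv", _provenance(cfg))
        tables.append(table)
    all_cells = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    write_csv(all_cells, out / "cells.csv", _provenance(cfg))
    log.info("segment: %d cells across %d fields", len(all_cells), len(manifest))
    return all_cells


def _segmented_field(run_dir: Path, cfg: dict, row):
    """Re-derive regions for a field (deterministic) plus its label image."""
    params = MembraneMaskParams(**cfg.get("segmentation", {}))
    stack = _field_stack(run_dir, row)
    labels_path = run_dir / "segment" / f"{row['field_id']}_labels.tif"
    _require(labels_path, "segment")
    labels = tifffile.imread(labels_path)
    _, regions, _, selection = segment_cells(
        stack.plane("membrane"), params, stack.pixel_size_um
    )
    return stack, labels, regions, selection


def _detect_assigned(stack, labels, channel: str, cfg: dict):
    det = SpotDetectionParams(**cfg.get("spots", {}))
    found = spots.detect_spots(stack.plane(channel), det, channel_name=channel)
    return spots.assign_spots_to_cells(found, labels, stack.pixel_size_um)


def run_tpcp(run_dir) -> dict:
    """Per-cell displacement vectors and the genotype comparison."""
    run_dir, cfg, manifest = _load_run(run_dir)
    out = run_dir / "tpcp"
    out.mkdir(exist_ok=True)
    noise_floor = float(cfg.get("tpcp", {}).get("noise_floor_um", 0.2))
    per_cell, field_rows = [], []
    for _, row in manifest.iterrows():
        stack, labels, regions, _ = _segmented_field(run_dir, cfg, row)
        gtub = _detect_assigned(stack, labels, "gtub", cfg)
        table = tpcp.measure_field_tpcp(regions, gtub, stack.pixel_size_um, row["field_id"])
        table.insert(1, "genotype", row["genotype"])
        per_cell.append(table)
        vectors = [
            tpcp.PolarityVector((0, 0), (0, 0), m, a, d)
            for m, a, d in zip(table["magnitude_um"], table["angle_deg"], table["degenerate"])
        ]
        try:
            coord = tpcp.displacement_coordination(vectors, noise_floor)
            field_rows.append(
                {
                    "field_id": row["field_id"],
                    "genotype": row["genotype"],
                    "n_cells": len(table),
                    "mean_magnitude_um": table["magnitude_um"].mean(),
                    "direction_mean_deg": coord.mean_angle_deg,
                    "direction_csd_deg": coord.csd_deg,
                }
            )
        except ValueError:
            field_rows.append(
                {
                    "field_id": row["field_id"],
                    "genotype": row["genotype"],
                    "n_cells": len(table),
                    "mean_magnitude_um": table["magnitude_um"].mean(),
                    "direction_mean_deg": np.nan,
                    "direction_csd_deg": np.nan,
                }
            )
    cells = pd.concat(per_cell, ignore_index=True)
    write_csv(cells, out / "percell.csv", _provenance(cfg))
    write_csv(pd.DataFrame(field_rows), out / "fields.csv", _provenance(cfg))

    g1, g2 = cfg["labels"]
    comp = compare_two_groups(
        cells.loc[cells.genotype == g1, "magnitude_um"],
        cells.loc[cells.genotype == g2, "magnitude_um"],
    )
    payload = {
        "comparison": "tpcp_displacement_magnitude_um",
        "groups": {
            g: {
                "n": int((cells.genotype == g).sum()),
                "mean_um": float(cells.loc[cells.genotype == g, "magnitude_um"].mean()),
            }
            for g in (g1, g2)
        },
        "test": dataclasses.asdict(comp),
    }
    _write_json(payload, out / "comparison.json", cfg)
    return payload


def run_rpcp(run_dir) -> dict:
    """Per-cell rotational-angle summaries and the Watson U2 comparison."""
    run_dir, cfg, manifest = _load_run(run_dir)
    out = run_dir / "rpcp"
    out.mkdir(exist_ok=True)
    rcfg = cfg.get("rpcp", {})
    min_bb = int(rcfg.get("min_bb", 5))
    csd_method = rcfg.get("csd_method", "circular")
    max_pair = float(cfg.get("pairing", {}).get("max_pair_dist_um", 0.8))

    per_cell = []
    for _, row in manifest.iterrows():
        stack, labels, regions, _ = _segmented_field(run_dir, cfg, row)
        gtub = _detect_assigned(stack, labels, "gtub", cfg)
        fop = _detect_assigned(stack, labels, "fop", cfg)
        pairs, _, _ = spots.pair_spots(fop, gtub, max_pair, stack.pixel_size_um)
        angles = pd.DataFrame(
            [
                {"cell_id": p.cell_id, "angle_deg": rpcp.rotation_angle(p)}
                for p in pairs
                if p.cell_id is not None and p.separation_um > 0
            ],
            columns=["cell_id", "angle_deg"],
        )
        table, excluded = rpcp.per_cell_rpcp(angles, min_bb=min_bb, csd_method=csd_method)
        if excluded:
            log.info("rpcp %s: %d cells below min_bb=%d", row["field_id"], len(excluded), min_bb)
        table.insert(0, "field_id", row["field_id"])
        table.insert(1, "genotype", row["genotype"])
        per_cell.append(table)
    cells = pd.concat(per_cell, ignore_index=True)
    write_csv(cells, out / "percell.csv", _provenance(cfg))

    g1, g2 = cfg["labels"]
    a = cells.loc[cells.genotype == g1, "mean_angle_deg"].to_numpy()
    b = cells.loc[cells.genotype == g2, "mean_angle_deg"].to_numpy()
    u2 = rpcp.watson_u2(
        a, b, n_permutations=int(rcfg.get("n_permutations", 999)), seed=int(cfg.get("seed", 0))
    )
    csd_comp = compare_two_groups(
        cells.loc[cells.genotype == g1, "csd_deg"],
        cells.loc[cells.genotype == g2, "csd_deg"],
    )
    for g in (g1, g2):
        write_csv(
            rpcp.rose_histogram(cells.loc[cells.genotype == g, "mean_angle_deg"]),
            out / f"rose_{g}.csv",
            _provenance(cfg),
        )
    payload = {
        "comparison": "rpcp_cell_mean_angles_and_csd",
        "groups": {
            g: {
                "n": int((cells.genotype == g).sum()),
                "median_csd_deg": float(cells.loc[cells.genotype == g, "csd_deg"].median()),
            }
            for g in (g1, g2)
        },
        "watson_u2": dataclasses.asdict(u2),
        "csd_test": dataclasses.asdict(csd_comp),
    }
    _write_json(payload, out / "comparison.json", cfg)
    return payload


def run_membrane(run_dir) -> dict:
    """Membrane MFI of diffuse markers and per-cell membrane dot stats."""
    run_dir, cfg, manifest = _load_run(run_dir)
    out = run_dir / "membrane"
    out.mkdir(exist_ok=True)
    markers = cfg.get("membrane", {}).get("markers", ["enriched", "uniform"])
    det = SpotDetectionParams(**cfg.get("spots", {}))
    mfi_rows, dot_rows = [], []
    for _, row in manifest.iterrows():
        stack, labels, regions, selection = _segmented_field(run_dir, cfg, row)
        for marker in markers:
            m = mb.membrane_mfi(
                stack.plane(marker), selection, marker=marker, field_id=row["field_id"]
            )
            mfi_rows.append(
                {
                    "field_id": row["field_id"],
                    "genotype": row["genotype"],
                    "marker": marker,
                    "mfi": m.mfi,
                    "n_pixels": m.n_pixels,
                }
            )
        plane = stack.plane("puncta")
        for region in regions:
            stats_ = mb.membrane_dot_stats(plane, region, det)
            dot_rows.append(
                {
                    "field_id": row["field_id"],
                    "genotype": row["genotype"],
                    "cell_id": region.cell_id,
                    "n_dots": stats_.n_dots,
                    "mean_dot_intensity": stats_.mean_dot_intensity,
                }
            )
    mfi = pd.DataFrame(mfi_rows)
    dots = pd.DataFrame(dot_rows)
    write_csv(mfi, out / "mfi.csv", _provenance(cfg))
    write_csv(dots, out / "dots.csv", _provenance(cfg))

    g1, g2 = cfg["labels"]
    comp = compare_two_groups(
        dots.loc[dots.genotype == g1, "n_dots"], dots.loc[dots.genotype == g2, "n_dots"]
    )
    payload = {
        "comparison": "membrane_dot_count_and_mfi",
        "groups": {
            g: {
                "n_cells": int((dots.genotype == g).sum()),
                "mean_dots": float(dots.loc[dots.genotype == g, "n_dots"].mean()),
                "mfi": {
                    marker: float(
                        mfi.loc[(mfi.genotype == g) & (mfi.marker == marker), "mfi"].mean()
                    )
                    for marker in markers
                },
            }
            for g in (g1, g2)
        },
        "dot_count_test": dataclasses.asdict(comp),
    }
    _write_json(payload, out / "comparison.json", cfg)
    return payload


def run_docking(run_dir) -> dict:
    """Per-cell docking calls from z-stacks plus the Fisher contingency."""
    run_dir, cfg, manifest = _load_run(run_dir)
    out = run_dir / "docking"
    out.mkdir(exist_ok=True)
    dcfg = cfg.get("docking", {})
    call_rows = []
    for _, row in manifest.iterrows():
        stack, labels, regions, _ = _segmented_field(run_dir, cfg, row)
        if not stack.is_stack:
            raise PipelineError(
                f"field {row['field_id']} is single-plane; docking needs z-stacks "
                "(set z_planes > 1 in the simulation config)"
            )
        gtub_spots = _detect_assigned(stack, labels, "gtub", cfg)
        mem = stack.channel("membrane")
        gtub_vol = stack.channel("gtub")
        by_cell = {}
        for s in gtub_spots:
            if s.cell_id is not None:
                by_cell.setdefault(s.cell_id, []).append(s)
        for region in regions:
            cell_spots = by_cell.get(region.cell_id, [])
            if len(cell_spots) < int(dcfg.get("min_bb", 10)):
                continue
            try:
                apical = dk.apical_reference(mem, region.membrane_band, stack.z_step_um)
            except ValueError:
                continue
            zs = [
                dk.bb_z_position(gtub_vol, s.x_px, s.y_px, stack.z_step_um)
                for s in cell_spots
            ]
            call = dk.classify_docking(
                zs,
                apical,
                cell_id=region.cell_id,
                delta_z_um=float(dcfg.get("delta_z_um", 1.0)),
                docked_fraction_threshold=float(dcfg.get("docked_fraction_threshold", 0.8)),
                min_bb=int(dcfg.get("min_bb", 10)),
            )
            call_rows.append(
                {
                    "field_id": row["field_id"],
                    "genotype": row["genotype"],
                    "cell_id": call.cell_id,
                    "n_bb": call.n_bb,
                    "fraction_apical": call.fraction_apical,
                    "call": call.call,
                    "apical_z_um": call.apical_z_um,
                }
            )
    calls = pd.DataFrame(call_rows)
    write_csv(calls, out / "calls.csv", _provenance(cfg))
    g1, g2 = cfg["labels"]
    by_geno = {
        g: [
            dk.DockingCall(r.cell_id, r.n_bb, r.fraction_apical, r.call, r.apical_z_um)
            for r in calls[calls.genotype == g].itertuples()
        ]
        for g in (g1, g2)
    }
    table, fisher = dk.docking_contingency(by_geno)
    payload = {
        "comparison": "docking_contingency",
        "table": {g: table.loc[g].to_dict() for g in (g1, g2)},
        "fisher": dataclasses.asdict(fisher),
        "sidedness": "two-sided",
    }
    _write_json(payload, out / "contingency.json", cfg)
    return payload


def run_report(run_dir) -> dict:
    """Aggregate the four genotype comparisons into one report."""
    run_dir, cfg, _ = _load_run(run_dir)
    blocks = {}
    for block, path, stage in [
        ("tpcp", run_dir / "tpcp" / "comparison.json", "tpcp"),
        ("rpcp", run_dir / "rpcp" / "comparison.json", "rpcp"),
        ("membrane", run_dir / "membrane" / "comparison.json", "membrane"),
        ("docking", run_dir / "docking" / "contingency.json", "docking"),
    ]:
        _require(path, stage)
        blocks[block] = json.loads(path.read_text())
    report = {"blocks": blocks}
    _write_json(report, run_dir / "report.json", cfg)
    lines = ["pcpquant report", "==============="]
    t = blocks["tpcp"]
    for g, v in t["groups"].items():
        lines.append(f"tpcp  {g}: mean displacement {v['mean_um']:.2f} um (n={v['n']})")
    lines.append(f"tpcp  test: {t['test']['test_name']} p={t['test']['p_value']:.3g}")
    r = blocks["rpcp"]
    for g, v in r["groups"].items():
        lines.append(f"rpcp  {g}: median per-cell CSD {v['median_csd_deg']:.1f} deg (n={v['n']})")
    lines.append(f"rpcp  Watson U2={r['watson_u2']['u2']:.3f} p={r['watson_u2']['p_value']:.3g}")
    m = blocks["membrane"]
    for g, v in m["groups"].items():
        lines.append(f"membrane  {g}: mean dots/cell {v['mean_dots']:.1f}")
    d = blocks["docking"]
    for g, v in d["table"].items():
        lines.append(f"docking  {g}: docked {v['docked']} / scattered {v['scattered']}")
    lines.append(f"docking  Fisher p={d['fisher']['p_value']:.3g}")
    (run_dir / "report.txt").write_text("\n".join(lines) + "\n")
    return report
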