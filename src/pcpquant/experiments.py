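"""Ground-truth recovery experiments on the synthetic epithelium.

Each function here runs a complete simulate -> process -> measure loop and
scores the measurements against the generator's ground truth: displacement
recovery for translational polarity, circular-spread recovery for
rotational polarity, spot detection and pairing fidelity, membrane-mask and
MFI fidelity, docking-call accuracy, and the size/power of the permutation
Watson U2 test.  These are the package's benchmark harness; all problem
sizes default to the study conditions of the headline analyses.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from shapely.geometry import Point

from .membrane import membrane_mfi
from .rpcp import circular_summary, per_cell_rpcp, rotation_angle, vonmises_csd_deg, watson_u2
from .segmentation import MembraneMaskParams, segment_cells
from .simulate import SimulationConfig, _membrane_ribbon, generate_sheet
from .spots import SpotDetectionParams, assign_spots_to_cells, detect_spots, pair_spots
from .stats import compare_two_groups, fisher_exact
from .tpcp import measure_field_tpcp

__all__ = [
    "measure_field",
    "tpcp_two_genotype_recovery",
    "rpcp_two_genotype_recovery",
    "spot_detection_performance",
    "pairing_hungarian_agreement",
    "membrane_selection_fidelity",
    "membrane_mfi_ordering",
    "docking_call_accuracy",
    "docking_fisher_power",
    "watson_u2_calibration",
    "vonmises_csd_recovery",
]


def _sub_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def _region_truth_map(regions, gt) -> dict:
    """region cell_id -> ground-truth cell_id via centroid containment."""
    polys = list(zip(gt.cells["cell_id"], gt.polygons()))
    out = {}
    for r in regions:
        pt = Point(r.centroid_px)
        for cid, poly in polys:
            if poly.contains(pt):
                out[r.cell_id] = int(cid)
                break
    return out


@dataclasses.dataclass
class FieldMeasurements:
    """Everything the 2D pipeline measures on one simulated field."""

    stack: object
    gt: object
    labels: np.ndarray
    regions: list
    selection: np.ndarray
    tpcp_table: pd.DataFrame  # + disp truth columns for matched cells
    rpcp_table: pd.DataFrame
    region_to_true: dict


def measure_field(cfg: SimulationConfig, min_bb: int = 5) -> FieldMeasurements:
    """Run the default 2D pipeline on one simulated field."""
    stack, gt = generate_sheet(cfg)
    px = cfg.pixel_size_um
    labels, regions, _, selection = segment_cells(
        stack.plane("membrane"), MembraneMaskParams(), px
    )
    gtub = assign_spots_to_cells(detect_spots(stack.plane("gtub")), labels, px)
    fop = assign_spots_to_cells(detect_spots(stack.plane("fop")), labels, px)
    region_to_true = _region_truth_map(regions, gt)

    tpcp_table = measure_field_tpcp(regions, gtub, px)
    truth = gt.cells.set_index("cell_id")
    tpcp_table["true_cell_id"] = tpcp_table["cell_id"].map(region_to_true)
    matched = tpcp_table["true_cell_id"].notna()
    tpcp_table.loc[matched, "true_magnitude_um"] = truth.loc[
        tpcp_table.loc[matched, "true_cell_id"], "disp_magnitude_um"
    ].to_numpy()

    pairs, _, _ = pair_spots(fop, gtub, 0.8, px)
    angles = pd.DataFrame(
        [
            {"cell_id": p.cell_id, "angle_deg": rotation_angle(p)}
            for p in pairs
            if p.cell_id is not None and p.separation_um > 0
        ],
        columns=["cell_id", "angle_deg"],
    )
    rpcp_table, _ = per_cell_rpcp(angles, min_bb=min_bb)
    return FieldMeasurements(
        stack=stack,
        gt=gt,
        labels=labels,
        regions=regions,
        selection=selection,
        tpcp_table=tpcp_table,
        rpcp_table=rpcp_table,
        region_to_true=region_to_true,
    )


def _collect_cells(cfg: SimulationConfig, n_cells: int, seeds, table: str) -> pd.DataFrame:
    """Measure fields until ``n_cells`` analysed cells are collected."""
    frames = []
    total = 0
    for s in seeds:
        m = measure_field(dataclasses.replace(cfg, seed=int(s)))
        frame = getattr(m, table)
        frames.append(frame)
        total += len(frame)
        if total >= n_cells:
            break
    out = pd.concat(frames, ignore_index=True)
    if len(out) < n_cells:
        raise RuntimeError(f"only {len(out)} cells collected; needed {n_cells}")
    return out.iloc[:n_cells]


def tpcp_two_genotype_recovery(
    displacement_a: float = 2.0,
    displacement_b: float = 0.3,
    n_cells: int = 24,
    seed: int = 0,
) -> dict:
    """Displacement recovery for a strong vs weak translational-polarity pair.

    Mirrors the wild-type vs knockout comparison: per-genotype group means of
    the pipeline-recovered displacement magnitudes are scored against the
    ground-truth means of the same cells, and the two genotypes compared with
    the normality-gated two-group test.
    """
    seeds = _sub_seeds(seed, 24).reshape(2, 12)
    out = {"n_cells": n_cells}
    groups = {}
    for label, disp, row in (("a", displacement_a, 0), ("b", displacement_b, 1)):
        cfg = SimulationConfig(displacement_um=disp)
        cells = _collect_cells(cfg, n_cells, seeds[row], "tpcp_table")
        matched = cells.dropna(subset=["true_magnitude_um"])
        groups[label] = cells["magnitude_um"].to_numpy()
        out[f"recovered_mean_{label}_um"] = float(matched["magnitude_um"].mean())
        out[f"true_mean_{label}_um"] = float(matched["true_magnitude_um"].mean())
        out[f"rel_err_{label}"] = abs(
            out[f"recovered_mean_{label}_um"] - out[f"true_mean_{label}_um"]
        ) / out[f"true_mean_{label}_um"]
    out["p_value"] = compare_two_groups(groups["a"], groups["b"]).p_value
    return out


def rpcp_two_genotype_recovery(
    kappa_a: float = 8.0,
    kappa_b: float = 0.5,
    n_cells: int = 105,
    seed: int = 0,
) -> dict:
    """Circular-spread recovery for concentrated vs dispersed rotation.

    Per-cell circular SDs of the recovered rotational angles are compared
    between the two arms (rank test) and the per-cell mean angles with
    Watson's permutation U2.
    """
    seeds = _sub_seeds(seed, 40).reshape(2, 20)
    tables = {}
    for label, kappa, row in (("a", kappa_a, 0), ("b", kappa_b, 1)):
        cfg = SimulationConfig(rotation_kappa=kappa)
        tables[label] = _collect_cells(cfg, n_cells, seeds[row], "rpcp_table")
    csd_p = compare_two_groups(tables["a"]["csd_deg"], tables["b"]["csd_deg"]).p_value
    watson = watson_u2(
        tables["a"]["mean_angle_deg"].to_numpy(),
        tables["b"]["mean_angle_deg"].to_numpy(),
        n_permutations=999,
        seed=seed,
    )
    return {
        "n_cells": n_cells,
        "median_csd_a_deg": float(tables["a"]["csd_deg"].median()),
        "median_csd_b_deg": float(tables["b"]["csd_deg"].median()),
        "csd_rank_p": float(csd_p),
        "watson_u2": watson.u2,
        "watson_p": watson.p_value,
    }


def spot_detection_performance(seed: int = 0, match_radius_px: float = 2.0) -> dict:
    """Recall/precision of BB detection on large 40-BB cells at SNR 10."""
    cfg = SimulationConfig(
        field_size_um=(30.0, 30.0),
        n_cells=4,
        bb_per_cell=(40, 40),
        bb_patch_radius_um=4.0,
        displacement_um=0.5,
        seed=int(_sub_seeds(seed, 1)[0]),
    )
    stack, gt = generate_sheet(cfg)
    spots = detect_spots(stack.plane("gtub"))
    det = np.array([[s.x_px, s.y_px] for s in spots])
    true = gt.bbs[["gtub_x_px", "gtub_y_px"]].to_numpy()
    d = cdist(true, det)
    ri, ci = linear_sum_assignment(np.minimum(d, 2 * match_radius_px))
    n_match = int((d[ri, ci] <= match_radius_px).sum())
    return {
        "n_true": len(true),
        "n_detected": len(det),
        "recall": n_match / len(true),
        "precision": n_match / len(det),
    }


def pairing_hungarian_agreement(seed: int = 0) -> dict:
    """Agreement of mutual-NN pairing with min-cost bipartite assignment."""
    cfg = SimulationConfig(seed=int(_sub_seeds(seed, 2)[1]))
    stack, _ = generate_sheet(cfg)
    px = cfg.pixel_size_um
    fop = detect_spots(stack.plane("fop"))
    gtub = detect_spots(stack.plane("gtub"))
    pairs, _, _ = pair_spots(fop, gtub, 0.8, px)
    f_xy = np.array([[s.x_px, s.y_px] for s in sorted(fop, key=lambda s: (s.x_px, s.y_px))])
    g_xy = np.array([[s.x_px, s.y_px] for s in sorted(gtub, key=lambda s: (s.x_px, s.y_px))])
    cap = 0.8 / px
    d = cdist(f_xy, g_xy)
    ri, ci = linear_sum_assignment(np.minimum(d, 2 * cap))
    hungarian = {(tuple(f_xy[i]), tuple(g_xy[j])) for i, j in zip(ri, ci) if d[i, j] <= cap}
    ours = {((p.fop.x_px, p.fop.y_px), (p.gtub.x_px, p.gtub.y_px)) for p in pairs}
    return {
        "n_pairs": len(pairs),
        "agreement": len(ours & hungarian) / max(len(hungarian), 1),
    }


def membrane_selection_fidelity(seed: int = 0) -> dict:
    """IoU of the blur/threshold/skeletonize/dilate selection vs ground truth.

    The reference is the true junctional midline dilated to the same band
    width as the recovered selection.
    """
    cfg = SimulationConfig(seed=int(_sub_seeds(seed, 3)[2]))
    m = measure_field(cfg)
    params = MembraneMaskParams()
    true_skel = _membrane_ribbon(m.gt, m.stack.data.shape[-2:], 1)
    true_sel = ndi.binary_dilation(
        true_skel, np.ones((3, 3)), iterations=params.dilate_iterations
    )
    sel = m.selection
    return {"iou": float((sel & true_sel).sum() / (sel | true_sel).sum())}


def membrane_mfi_ordering(n_seeds: int = 20, seed: int = 0) -> dict:
    """How often the membrane-enriched marker out-scores the uniform one."""
    wins = 0
    for s in _sub_seeds(seed, n_seeds):
        cfg = SimulationConfig(field_size_um=(30.0, 30.0), n_cells=9, seed=int(s))
        stack, _ = generate_sheet(cfg)
        _, _, _, sel = segment_cells(
            stack.plane("membrane"), MembraneMaskParams(), cfg.pixel_size_um
        )
        enriched = membrane_mfi(stack.plane("enriched"), sel).mfi
        uniform = membrane_mfi(stack.plane("uniform"), sel).mfi
        wins += enriched > uniform
    return {"n_seeds": n_seeds, "wins": int(wins)}


def docking_call_accuracy(n_fields: int = 2, seed: int = 0, min_bb: int = 8) -> dict:
    """Fraction of docked/scattered calls matching the simulated labels."""
    from .docking import apical_reference, bb_z_position, classify_docking

    correct = total = 0
    for s in _sub_seeds(seed, n_fields):
        cfg = SimulationConfig(z_planes=9, docked_fraction=0.5, seed=int(s))
        stack, gt = generate_sheet(cfg)
        px = cfg.pixel_size_um
        labels, regions, _, _ = segment_cells(stack.plane("membrane"), MembraneMaskParams(), px)
        spots = assign_spots_to_cells(detect_spots(stack.plane("gtub")), labels, px)
        region_to_true = _region_truth_map(regions, gt)
        truth = gt.cells.set_index("cell_id")["docked"]
        mem = stack.channel("membrane")
        gvol = stack.channel("gtub")
        for r in regions:
            cell_spots = [s_ for s_ in spots if s_.cell_id == r.cell_id]
            if len(cell_spots) < min_bb or r.cell_id not in region_to_true:
                continue
            try:
                apical = apical_reference(mem, r.membrane_band, stack.z_step_um)
            except ValueError:
                continue
            zs = [bb_z_position(gvol, s_.x_px, s_.y_px, stack.z_step_um) for s_ in cell_spots]
            call = classify_docking(zs, apical, min_bb=min_bb)
            want = "docked" if truth.loc[region_to_true[r.cell_id]] else "scattered"
            total += 1
            correct += call.call == want
    return {"n_cells": total, "accuracy": correct / total if total else float("nan")}


def docking_fisher_power(
    rate_a: float = 0.9,
    rate_b: float = 0.3,
    n_a: int = 125,
    n_b: int = 140,
    n_rep: int = 100,
    seed: int = 0,
) -> dict:
    """Fisher's exact power for a strong docking-rate contrast.

    Docking calls are drawn binomially at the two rates (the contingency
    analysis operates on call counts, not images).
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_rep):
        da = int(rng.binomial(n_a, rate_a))
        db = int(rng.binomial(n_b, rate_b))
        p = fisher_exact([[da, n_a - da], [db, n_b - db]]).p_value
        hits += p < 0.001
    return {"n_rep": n_rep, "power": hits / n_rep}


def watson_u2_calibration(
    n_null: int = 500,
    n_power: int = 100,
    n_permutations: int = 999,
    seed: int = 0,
) -> dict:
    """Size and power of the permutation Watson U2.

    Null: both samples von Mises(mu=0, kappa=2), n=30 each; alternative:
    means 90 degrees apart at kappa=4, n=50 each.  Rejection at alpha=0.05.
    """
    rng = np.random.default_rng(seed)
    null_rej = 0
    for i in range(n_null):
        a = np.degrees(rng.vonmises(0.0, 2.0, 30)) % 360
        b = np.degrees(rng.vonmises(0.0, 2.0, 30)) % 360
        null_rej += watson_u2(a, b, n_permutations, seed=i).p_value <= 0.05
    power_rej = 0
    for i in range(n_power):
        a = np.degrees(rng.vonmises(0.0, 4.0, 50)) % 360
        b = np.degrees(rng.vonmises(np.pi / 2, 4.0, 50)) % 360
        power_rej += watson_u2(a, b, n_permutations, seed=i).p_value <= 0.05
    return {
        "null_rejection_rate": null_rej / n_null,
        "power": power_rej / n_power,
        "n_null": n_null,
        "n_power": n_power,
    }


def vonmises_csd_recovery(n: int = 500, seed: int = 0) -> dict:
    """Relative CSD error vs the Bessel-function oracle at three kappas."""
    rng = np.random.default_rng(seed)
    out = {}
    for kappa in (0.5, 2.0, 8.0):
        angles = np.degrees(rng.vonmises(0.0, kappa, n)) % 360
        csd = circular_summary(angles).csd_deg
        expected = vonmises_csd_deg(kappa)
        out[f"rel_err_kappa_{kappa:g}"] = abs(csd - expected) / expected
    out["n"] = n
    return out
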