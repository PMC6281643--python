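"""Basal-body docking: apical-surface reference, per-cell calls, contingency.

From a z-stack, the apical surface of each cell is located as the peak of
the membrane channel's z-profile over the cell's membrane band; each basal
body's z-position is the (parabolically refined) peak of the gamma-tubulin
z-profile at its (x, y).  A cell is called ``docked`` when at least
``docked_fraction_threshold`` of its basal bodies lie within ``delta_z_um``
of the apical reference, and ``scattered`` otherwise; genotype proportions
are compared with Fisher's exact test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import FisherResult, fisher_exact

__all__ = [
    "DockingCall",
    "apical_reference",
    "bb_z_position",
    "classify_docking",
    "docking_contingency",
]


@dataclass(frozen=True)
class DockingCall:
    cell_id: int
    n_bb: int
    fraction_apical: float
    call: str  # "docked" | "scattered"
    apical_z_um: float


def _parabolic_peak(profile: np.ndarray, z_step_um: float) -> float:
    """Sub-plane peak position (um) of a 1D z-profile."""
    k = int(np.argmax(profile))
    if 0 < k < len(profile) - 1:
        fm1, f0, fp1 = profile[k - 1], profile[k], profile[k + 1]
        denom = fm1 - 2 * f0 + fp1
        if denom < 0:
            k = k + float(np.clip(0.5 * (fm1 - fp1) / denom, -0.5, 0.5))
    return float(k * z_step_um)


def apical_reference(
    membrane_stack: np.ndarray,
    membrane_band: np.ndarray,
    z_step_um: float,
    min_contrast: float = 0.2,
) -> float:
    """Apical-surface z (um) of one cell from the membrane z-profile.

    The profile is the mean membrane intensity over the cell's membrane band
    per plane; its peak (intensity-weighted, parabolically refined) is the
    apical reference.  A flat profile (relative contrast below
    ``min_contrast``) is an error: no apical surface is resolvable.
    """
    stack = np.asarray(membrane_stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 3:
        raise ValueError("apical_reference needs a (Z, Y, X) stack with >= 3 planes")
    band = np.asarray(membrane_band, dtype=bool)
    if band.shape != stack.shape[1:]:
        raise ValueError("membrane band shape must match stack planes")
    if not band.any():
        raise ValueError("empty membrane band")
    profile = stack[:, band].mean(axis=1)
    baseline = profile.min()
    peak = profile.max()
    if peak <= 0 or (peak - baseline) < min_contrast * peak:
        raise ValueError(
            "membrane z-profile is flat; apical surface cannot be determined"
        )
    return _parabolic_peak(profile - baseline, z_step_um)


def bb_z_position(gtub_stack: np.ndarray, x_px: float, y_px: float, z_step_um: float) -> float:
    """z-position (um) of a basal body: peak of the local gamma-tubulin profile.

    The profile is averaged over a 3x3 pixel window around the spot and the
    peak refined parabolically.
    """
    stack = np.asarray(gtub_stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("bb_z_position needs a (Z, Y, X) stack")
    r, c = int(round(y_px)), int(round(x_px))
    rs = slice(max(0, r - 1), min(stack.shape[1], r + 2))
    cs = slice(max(0, c - 1), min(stack.shape[2], c + 2))
    profile = stack[:, rs, cs].mean(axis=(1, 2))
    return _parabolic_peak(profile - profile.min(), z_step_um)


def classify_docking(
    bb_z_um,
    apical_z_um: float,
    cell_id: int = 0,
    delta_z_um: float = 1.0,
    docked_fraction_threshold: float = 0.8,
    min_bb: int = 10,
) -> DockingCall:
    """Docked/scattered call from basal-body z-positions.

    ``fraction_apical`` is the fraction of basal bodies within
    ``delta_z_um`` of the apical reference; the call is ``docked`` iff it
    reaches ``docked_fraction_threshold``.  Increasing ``delta_z_um`` can
    only increase the fraction, so the call is monotone in the tolerance.
    """
    z = np.asarray(bb_z_um, dtype=float)
    if z.size < min_bb:
        raise ValueError(f"need at least {min_bb} basal bodies with z estimates, got {z.size}")
    frac = float(np.mean(np.abs(z - apical_z_um) <= delta_z_um))
    call = "docked" if frac >= docked_fraction_threshold else "scattered"
    return DockingCall(
        cell_id=cell_id,
        n_bb=int(z.size),
        fraction_apical=frac,
        call=call,
        apical_z_um=float(apical_z_um),
    )


def docking_contingency(calls_by_genotype: dict):
    """2x2 contingency table of docking calls plus two-sided Fisher p.

    ``calls_by_genotype`` maps exactly two genotype labels to lists of
    :class:`DockingCall`.  Returns ``(table, FisherResult)`` where ``table``
    is a DataFrame indexed by genotype with columns ``docked, scattered``.
    """
    if len(calls_by_genotype) != 2:
        raise ValueError("docking contingency compares exactly two genotypes")
    rows = {}
    for genotype, calls in calls_by_genotype.items():
        docked = sum(1 for c in calls if c.call == "docked")
        rows[genotype] = {"docked": docked, "scattered": len(calls) - docked}
    table = pd.DataFrame(rows).T[["docked", "scattered"]]
    result: FisherResult = fisher_exact(table.to_numpy())
    return table, result
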