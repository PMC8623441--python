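"""Evaluation metrics: hard Dice, boundary MAE, topology index, volume.

Boundaries are recovered from hard class masks by first-transition scanning
down each column; the Topology Incorrectness Index (TII) is the percentage
of masks whose labels decrease anywhere down a column; the preretinal volume
converts class-1 pixel counts to mm^3 using the scan voxel dimensions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .losses import EPS, N_CLASSES
from .phantom import VOXEL_UM, BoundarySet

__all__ = [
    "EvalReport",
    "extract_boundaries",
    "hard_dice",
    "mae",
    "mae_report",
    "tii",
    "is_topology_correct",
    "preretinal_volume",
]

BOUNDARY_NAMES = ("PCV", "ILM", "RPE")


def extract_boundaries(mask: np.ndarray):
    """Recover (PCV, ILM, RPE) row coordinates from a class mask.

    Per column: PCV = first row with label >= 1, ILM = first row with
    label >= 2, RPE = last row with label <= 2.  For topologically broken
    columns the first qualifying transition is used.  Columns missing a
    transition fall back to the column extremes and are flagged.

    Returns ``(BoundarySet, flags)`` where ``flags`` marks degenerate
    columns.
    """
    mask = np.asarray(mask)
    h, w = mask.shape
    ge1 = mask >= 1
    ge2 = mask >= 2
    le2 = mask <= 2

    any1 = ge1.any(axis=0)
    any2 = ge2.any(axis=0)
    any_le2 = le2.any(axis=0)

    pcv = np.where(any1, ge1.argmax(axis=0), h - 1).astype(np.float64)
    ilm = np.where(any2, ge2.argmax(axis=0), h - 1).astype(np.float64)
    rpe = np.where(any_le2, h - 1 - le2[::-1].argmax(axis=0), 0).astype(np.float64)

    # flag degenerate columns: a missing transition (including boundaries
    # clipped to the column extremes, e.g. a single-class column) or a
    # topologically broken ordering
    top_clipped = mask[0, :] >= 1
    bottom_clipped = mask[-1, :] <= 2
    flags = ((~any1) | (~any2) | (~any_le2) | (rpe < ilm) | (ilm < pcv)
             | top_clipped | bottom_clipped)
    # clamp so the returned set always satisfies its ordering invariant
    ilm = np.maximum(ilm, pcv)
    rpe = np.maximum(rpe, ilm)
    return BoundarySet(pcv=pcv, ilm=ilm, rpe=rpe), flags


def hard_dice(gt: np.ndarray, pred: np.ndarray,
              n_classes: int = N_CLASSES) -> np.ndarray:
    """Per-class Dice 2|A and B| / (|A| + |B|) on hard label masks.

    A class absent from both masks scores 1 (epsilon convention).
    """
    gt = np.asarray(gt)
    pred = np.asarray(pred)
    if gt.shape != pred.shape:
        raise ValueError("mask shapes differ")
    out = np.empty(n_classes)
    for c in range(n_classes):
        a = gt == c
        b = pred == c
        out[c] = (2.0 * np.logical_and(a, b).sum() + EPS) / (a.sum() + b.sum() + EPS)
    return out


def mae(gt_bounds: BoundarySet, pred_bounds: BoundarySet) -> np.ndarray:
    """Mean absolute vertical distance in px for (PCV, ILM, RPE)."""
    if gt_bounds.width != pred_bounds.width:
        raise ValueError("boundary widths differ")
    return np.array([
        np.abs(np.asarray(getattr(pred_bounds, k)) - np.asarray(getattr(gt_bounds, k))).mean()
        for k in ("pcv", "ilm", "rpe")
    ])


def mae_report(pairs):
    """Aggregate per-scan MAE over (gt, pred) boundary pairs.

    Returns ``(mean, sd, per_scan)`` with SD computed across scans.
    """
    per_scan = np.array([mae(g, p) for g, p in pairs])
    return per_scan.mean(axis=0), per_scan.std(axis=0), per_scan


def is_topology_correct(mask: np.ndarray) -> bool:
    """True iff labels never decrease down any column."""
    return bool(np.all(np.diff(np.asarray(mask), axis=0) >= 0))


def tii(masks) -> float:
    """Topology Incorrectness Index: % of masks with any label inversion."""
    masks = list(masks)
    if not masks:
        raise ValueError("need at least one mask")
    bad = sum(0 if is_topology_correct(m) else 1 for m in masks)
    return 100.0 * bad / len(masks)


def preretinal_volume(masks, voxel_um=VOXEL_UM) -> float:
    """Preretinal-space volume in mm^3 from class-1 pixel counts.

    ``masks`` are the ordered B-scans of one volume; each class-1 pixel
    contributes voxel_y * voxel_x * voxel_z um^3.
    """
    n1 = sum(int((np.asarray(m) == 1).sum()) for m in masks)
    um3 = n1 * voxel_um[0] * voxel_um[1] * voxel_um[2]
    return um3 * 1e-9


@dataclass
class EvalReport:
    """Aggregated evaluation over a set of B-scans."""

    dice_mean: np.ndarray
    dice_sd: np.ndarray
    mae_mean: np.ndarray
    mae_sd: np.ndarray
    tii_pct: float
    preretinal_volume_mm3: float
    n_scans: int = 0
    per_scan_dice: np.ndarray | None = field(default=None, repr=False)
    per_scan_mae: np.ndarray | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        from .phantom import CLASS_NAMES

        return {
            "dice_mean": dict(zip(CLASS_NAMES, map(float, self.dice_mean))),
            "dice_sd": dict(zip(CLASS_NAMES, map(float, self.dice_sd))),
            "mae_px_mean": dict(zip(BOUNDARY_NAMES, map(float, self.mae_mean))),
            "mae_px_sd": dict(zip(BOUNDARY_NAMES, map(float, self.mae_sd))),
            "tii_pct": float(self.tii_pct),
            "preretinal_volume_mm3": float(self.preretinal_volume_mm3),
            "n_scans": int(self.n_scans),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def to_csv(self, path) -> None:
        """Flat CSV: one row per (scan, metric)."""
        import csv

        from .phantom import CLASS_NAMES

        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["scan", "metric", "value"])
            if self.per_scan_dice is not None:
                for z, row in enumerate(self.per_scan_dice):
                    for c, v in enumerate(row):
                        writer.writerow([z, f"dice_{CLASS_NAMES[c]}", f"{v:.6f}"])
            if self.per_scan_mae is not None:
                for z, row in enumerate(self.per_scan_mae):
                    for b, v in enumerate(row):
                        writer.writerow([z, f"mae_{BOUNDARY_NAMES[b]}", f"{v:.6f}"])
            writer.writerow(["all", "tii_pct", f"{self.tii_pct:.4f}"])
            writer.writerow(["all", "preretinal_volume_mm3",
                             f"{self.preretinal_volume_mm3:.6f}"])


def evaluate_masks(gt_masks, pred_masks, gt_bounds=None,
                   voxel_um=VOXEL_UM) -> EvalReport:
    """Full report from aligned lists of ground-truth and predicted masks."""
    gt_masks = list(gt_masks)
    pred_masks = list(pred_masks)
    if len(gt_masks) != len(pred_masks):
        raise ValueError("mask list lengths differ")
    dices = np.array([hard_dice(g, p) for g, p in zip(gt_masks, pred_masks)])
    if gt_bounds is None:
        gt_bounds = [extract_boundaries(g)[0] for g in gt_masks]
    pred_bounds = [extract_boundaries(p)[0] for p in pred_masks]
    mae_mean, mae_sd, per_scan_mae = mae_report(list(zip(gt_bounds, pred_bounds)))
    return EvalReport(
        dice_mean=dices.mean(axis=0),
        dice_sd=dices.std(axis=0),
        mae_mean=mae_mean,
        mae_sd=mae_sd,
        tii_pct=tii(pred_masks),
        preretinal_volume_mm3=preretinal_volume(pred_masks, voxel_um),
        n_scans=len(gt_masks),
        per_scan_dice=dices,
        per_scan_mae=per_scan_mae,
    )
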