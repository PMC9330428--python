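"""Segmentation metrics, success rates and stone-size-stratified reporting.

All metrics derive from per-class one-vs-rest voxel confusion counts:
Dice = 2TP/(2TP+FP+FN), specificity = TN/(TN+FP), sensitivity =
TP/(TP+FN), accuracy = (TP+TN)/total.  Zero-denominator conventions are
chosen so that stone-free cases with correct empty predictions are not
penalized: empty-vs-empty Dice is 1, sensitivity with FN = 0 is 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from renalseg.patchwork import STRUCT_26

#: Stone volume class boundaries in mm^3, half-open: [0, 28) small,
#: [28, 315) medium, [315, inf) large.
SMALL_MAX_MM3 = 28.0
MEDIUM_MAX_MM3 = 315.0

SIZE_CLASSES = ("small", "medium", "large")

KIDNEY = 1
STONE = 2


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class StoneRecord:
    component_id: int
    voxel_count: int
    volume_mm3: float
    size_class: str
    center_voxel: tuple[int, int, int]
    matched_component: int | None = None

    @property
    def equivalent_diameter_mm(self) -> float:
        """Equivalent-sphere diameter, for display only."""
        return float(2.0 * (3.0 * self.volume_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0))


def confusion_counts(pred: np.ndarray, truth: np.ndarray, class_id: int) -> ConfusionCounts:
    """Voxel confusion counts for the one-vs-rest binarization of ``class_id``."""
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    p = pred == class_id
    t = truth == class_id
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = p.size - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def metrics_from_counts(c: ConfusionCounts) -> dict[str, float]:
    return {
        "dice": _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
        "specificity": _ratio(c.tn, c.tn + c.fp),
        "sensitivity": _ratio(c.tp, c.tp + c.fn),
        "accuracy": _ratio(c.tp + c.tn, c.total),
    }


def dice_score(pred: np.ndarray, truth: np.ndarray, class_id: int) -> float:
    return metrics_from_counts(confusion_counts(pred, truth, class_id))["dice"]


def classify_stone_size(volume_mm3: float) -> str:
    if volume_mm3 < 0:
        raise ValueError(f"negative stone volume: {volume_mm3}")
    if volume_mm3 < SMALL_MAX_MM3:
        return "small"
    if volume_mm3 < MEDIUM_MAX_MM3:
        return "medium"
    return "large"


def stone_inventory(label: np.ndarray, spacing: tuple[float, float, float]) -> list[StoneRecord]:
    """26-connected stone components with rasterized volumes and size classes."""
    comp, n = ndimage.label(label == STONE, structure=STRUCT_26)
    voxel_vol = float(np.prod(spacing))
    records = []
    for cid in range(1, n + 1):
        mask = comp == cid
        count = int(np.count_nonzero(mask))
        vol = count * voxel_vol
        center = tuple(int(round(c)) for c in ndimage.center_of_mass(mask))
        records.append(
            StoneRecord(
                component_id=cid,
                voxel_count=count,
                volume_mm3=vol,
                size_class=classify_stone_size(vol),
                center_voxel=center,
            )
        )
    return records


def success_rate(values: list[float] | np.ndarray, threshold: float = 0.5) -> float:
    """Fraction of cases whose per-case metric is >= threshold."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("success_rate needs at least one case")
    return float(np.count_nonzero(values >= threshold) / values.size)


def per_stone_dice(pred: np.ndarray, truth: np.ndarray, spacing: tuple[float, float, float]) -> list[dict]:
    """Per-truth-stone Dice with greedy maximum-overlap instance matching.

    Each truth stone is matched to the unmatched predicted stone component
    with the largest voxel overlap; Dice is computed between the two
    component masks (0 when unmatched).
    """
    t_comp, t_n = ndimage.label(truth == STONE, structure=STRUCT_26)
    p_comp, p_n = ndimage.label(pred == STONE, structure=STRUCT_26)
    voxel_vol = float(np.prod(spacing))

    t_sizes = {cid: int(np.count_nonzero(t_comp == cid)) for cid in range(1, t_n + 1)}
    p_sizes = {cid: int(np.count_nonzero(p_comp == cid)) for cid in range(1, p_n + 1)}

    # overlap table between truth and predicted components
    overlaps: dict[tuple[int, int], int] = {}
    both = (t_comp > 0) & (p_comp > 0)
    if both.any():
        pairs, counts = np.unique(
            np.stack([t_comp[both], p_comp[both]]), axis=1, return_counts=True
        )
        for (tc, pc), cnt in zip(pairs.T, counts):
            overlaps[(int(tc), int(pc))] = int(cnt)

    # greedy: largest overlaps claim their prediction first
    order = sorted(overlaps.items(), key=lambda kv: -kv[1])
    matched_t: dict[int, tuple[int, int]] = {}
    used_p: set[int] = set()
    for (tc, pc), cnt in order:
        if tc in matched_t or pc in used_p:
            continue
        matched_t[tc] = (pc, cnt)
        used_p.add(pc)

    results = []
    for tc in range(1, t_n + 1):
        vol = t_sizes[tc] * voxel_vol
        pc, inter = matched_t.get(tc, (None, 0))
        dice = 0.0
        if pc is not None:
            dice = 2.0 * inter / (t_sizes[tc] + p_sizes[pc])
        results.append(
            {
                "truth_component": tc,
                "matched_pred_component": pc,
                "volume_mm3": vol,
                "size_class": classify_stone_size(vol),
                "dice": dice,
            }
        )
    return results


def size_stratified_dice(
    cases: list[tuple[np.ndarray, np.ndarray, tuple[float, float, float]]],
) -> pd.DataFrame:
    """Mean ± sd per-stone Dice per size class over (pred, truth, spacing) cases.

    Strata with no truth stones are absent from the result.
    """
    rows = []
    for case_idx, (pred, truth, spacing) in enumerate(cases):
        for rec in per_stone_dice(pred, truth, spacing):
            rows.append({"case": case_idx, **rec})
    if not rows:
        return pd.DataFrame(columns=["size_class", "n_stones", "dice_mean", "dice_sd"])
    df = pd.DataFrame(rows)
    agg = (
        df.groupby("size_class")["dice"]
        .agg(n_stones="count", dice_mean="mean", dice_sd="std")
        .reset_index()
    )
    agg["dice_sd"] = agg["dice_sd"].fillna(0.0)
    order = {c: i for i, c in enumerate(SIZE_CLASSES)}
    return agg.sort_values("size_class", key=lambda s: s.map(order)).reset_index(drop=True)


def evaluate_case(pred: np.ndarray, truth: np.ndarray) -> dict[str, dict[str, float]]:
    """All four metrics for kidney and stone classes of one case."""
    return {
        name: metrics_from_counts(confusion_counts(pred, truth, cid))
        for name, cid in (("kidney", KIDNEY), ("stone", STONE))
    }


def evaluate_cohort(
    cases: list[tuple[np.ndarray, np.ndarray]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-case metrics table + cohort mean/sd aggregate."""
    rows = []
    for idx, (pred, truth) in enumerate(cases):
        for cls, metrics in evaluate_case(pred, truth).items():
            rows.append({"case": idx, "class": cls, **metrics})
    per_case = pd.DataFrame(rows)
    summary = (
        per_case.drop(columns="case")
        .groupby("class")
        .agg(["mean", "std"])
    )
    summary.columns = [f"{m}_{s}" for m, s in summary.columns]
    return per_case, summary.reset_index()


def _ratio(num: float, den: float) -> float:
    if den == 0:
        return 1.0  # empty-vs-empty convention
    return float(num / den)
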