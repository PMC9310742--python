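"""ROI placement, ROI statistics and the method-comparison report.

Three regions of interest mirror the study design: two hot ROIs of 27
pixels grown around the two strongest uptake maxima of the *reference*
reconstruction, and one cold ROI of 198 pixels in the trachea, where no
tracer is expected.  Per (ROI, method) the report holds the mean ± SD of
the reconstructed activity concentration and the relative difference of
the mean to the reference method, rounded half-away-from-zero to integer
percent.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import ImageGrid
from .phantom import Label, TissueLabelMap

__all__ = ["RoiSet", "EvaluationReport", "place_rois", "roi_stats",
           "relative_difference", "difference_image",
           "HOT_ROI_SIZE", "COLD_ROI_SIZE"]

HOT_ROI_SIZE = 27
COLD_ROI_SIZE = 198


@dataclass
class RoiSet:
    """Named boolean pixel masks on the PET grid (mutually disjoint)."""

    masks: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        acc = None
        for name, m in self.masks.items():
            m = np.asarray(m, dtype=bool)
            self.masks[name] = m
            if acc is None:
                acc = np.zeros_like(m, dtype=int)
            acc += m
        if acc is not None and acc.max() > 1:
            raise ValueError("ROI masks must be disjoint")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def sizes(self) -> dict[str, int]:
        return {k: int(v.sum()) for k, v in self.masks.items()}


def _grow_region(values: np.ndarray, seed: tuple[int, int],
                 size: int) -> np.ndarray:
    """Greedy connected growth: repeatedly absorb the highest-valued
    8-neighbour of the region, ties broken by (row, column)."""
    ny, nx = values.shape
    mask = np.zeros_like(values, dtype=bool)
    in_heap = np.zeros_like(mask)
    heap: list[tuple[float, int, int]] = []

    def push(r, c):
        if 0 <= r < ny and 0 <= c < nx and not in_heap[r, c]:
            heapq.heappush(heap, (-values[r, c], r, c))
            in_heap[r, c] = True

    push(*seed)
    while heap and mask.sum() < size:
        _, r, c = heapq.heappop(heap)
        if mask[r, c]:
            continue
        mask[r, c] = True
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr or dc:
                    push(r + dr, c + dc)
    if mask.sum() < size:
        raise ValueError("image too small to grow the requested ROI")
    return mask


def _top_two_maxima(values: np.ndarray, min_separation_px: int = 8
                    ) -> list[tuple[int, int]]:
    footprint = np.ones((5, 5), dtype=bool)
    is_max = (values == ndimage.maximum_filter(values, footprint=footprint))
    if values.max() - values.min() <= 1e-12 * max(abs(values.max()), 1.0):
        raise ValueError("activity image is uniform: no two distinct maxima")
    cand = np.argwhere(is_max)
    order = np.lexsort((cand[:, 1], cand[:, 0], -values[cand[:, 0], cand[:, 1]]))
    picked: list[tuple[int, int]] = []
    for idx in order:
        r, c = cand[idx]
        if all(np.hypot(r - pr, c - pc) >= min_separation_px for pr, pc in picked):
            picked.append((int(r), int(c)))
        if len(picked) == 2:
            return picked
    raise ValueError("fewer than two distinct uptake maxima found")


def place_rois(reference_activity: ImageGrid, labels: TissueLabelMap,
               hot_size: int = HOT_ROI_SIZE,
               cold_size: int = COLD_ROI_SIZE) -> RoiSet:
    """Deterministic ROI placement driven by the reference reconstruction.

    Hot ROIs are grown to ``hot_size`` connected pixels around each of the
    two strongest local maxima; the cold ROI takes the ``cold_size`` trachea
    pixels nearest the trachea centroid.  The left/right naming follows the
    x coordinate of the two maxima.
    """
    reference_activity.require_same_grid(labels.grid)
    trachea = labels.mask(Label.AIR_INSIDE)
    if trachea.sum() < cold_size:
        raise ValueError(
            f"trachea has {int(trachea.sum())} px but {cold_size} are needed; "
            "use a larger phantom trachea")

    p1, p2 = _top_two_maxima(reference_activity.values)
    left, right = sorted([p1, p2], key=lambda rc: rc[1])
    hot_left = _grow_region(reference_activity.values, left, hot_size)
    hot_right = _grow_region(reference_activity.values, right, hot_size)

    rr, cc = np.nonzero(trachea)
    cy, cx = rr.mean(), cc.mean()
    dist = np.hypot(rr - cy, cc - cx)
    order = np.lexsort((cc, rr, dist))
    cold = np.zeros_like(trachea)
    cold[rr[order[:cold_size]], cc[order[:cold_size]]] = True

    return RoiSet({"HOT_LEFT": hot_left, "HOT_RIGHT": hot_right, "COLD": cold})


def roi_stats(activity: ImageGrid, mask: np.ndarray) -> tuple[float, float]:
    """Arithmetic mean and population SD of the masked pixels."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty ROI mask")
    vals = activity.values[mask]
    return float(vals.mean()), float(vals.std(ddof=0))


def relative_difference(test_mean: float, reference_mean: float) -> int:
    """Percent difference to the reference, half-away-from-zero to integer."""
    if reference_mean <= 0:
        raise ValueError("reference mean must be > 0")
    pct = 100.0 * (test_mean - reference_mean) / reference_mean
    return int(np.copysign(np.floor(abs(pct) + 0.5), pct))


def difference_image(test: ImageGrid, reference: ImageGrid) -> ImageGrid:
    """Signed voxelwise difference test − reference (same units)."""
    test.require_same_grid(reference)
    if test.unit != reference.unit:
        raise ValueError("units differ")
    return test.with_values(test.values - reference.values)


@dataclass
class EvaluationReport:
    """Per-(ROI, method) activity statistics and differences to the reference."""

    table: pd.DataFrame
    reference_method: str
    rois: RoiSet
    meta: dict = field(default_factory=dict)

    @classmethod
    def from_reconstructions(cls, activities: dict[str, ImageGrid],
                             rois: RoiSet, reference_method: str
                             ) -> "EvaluationReport":
        if reference_method not in activities:
            raise KeyError(f"reference method {reference_method!r} missing")
        # canonical method order so reports are byte-stable regardless of
        # the order reconstructions were produced in
        canon = ("TRUE", "TX", "REF", "CT", "DIXON", "UTE")
        ordered = sorted(activities,
                         key=lambda m: (canon.index(m) if m in canon
                                        else len(canon), m))
        rows = []
        for roi_name, mask in rois.masks.items():
            ref_mean, _ = roi_stats(activities[reference_method], mask)
            for method in ordered:
                act = activities[method]
                mean, sd = roi_stats(act, mask)
                if method == reference_method:
                    rel: float | int = np.nan    # printed as the dash analogue
                else:
                    rel = relative_difference(mean, ref_mean)
                rows.append({"roi": roi_name, "method": method,
                             "mean_kbq_ml": mean, "sd_kbq_ml": sd,
                             "rel_diff_pct": rel})
        return cls(pd.DataFrame(rows), reference_method, rois)

    def rel_diff(self, roi: str, method: str) -> float:
        t = self.table
        row = t[(t.roi == roi) & (t.method == method)]
        if row.empty:
            raise KeyError((roi, method))
        return float(row.rel_diff_pct.iloc[0])

    def to_text(self) -> str:
        lines = [f"Reference method: {self.reference_method}",
                 f"{'ROI':<10} {'Method':<7} {'Activity [kBq/ml]':>20} {'Rel. diff':>10}"]
        for _, r in self.table.iterrows():
            rel = "-" if np.isnan(r.rel_diff_pct) else f"{int(r.rel_diff_pct):+d}%"
            lines.append(f"{r.roi:<10} {r.method:<7} "
                         f"{r.mean_kbq_ml:>10.1f} ± {r.sd_kbq_ml:<7.1f} {rel:>10}")
        return "\n".join(lines)
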