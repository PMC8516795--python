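"""Similarity metrics between density maps and point sets.

Two metrics: pixel-wise Pearson correlation between two smoothed maps, and
a location-based ROC area that scores a map against a set of positive point
locations (thresholds taken at the map values attained at the positives).
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping

import numpy as np
import pandas as pd

from .density_maps import DensityMap, make_density_map
from .gaze_data import ClickTable, ScreenGeometry

__all__ = [
    "pearson_cc",
    "auc_judd",
    "compare_conditions",
    "summarize_scores",
    "permute_recall",
]

log = logging.getLogger(__name__)

#: Map kinds scored against clicking data, in reporting order.
COMPARED_KINDS = ("encoding", "matched_encoding", "recall", "relocated_recall")


def pearson_cc(map_a: DensityMap, map_b: DensityMap) -> float:
    """Pixel-wise Pearson correlation of two equally shaped maps."""
    a = map_a.grid.ravel()
    b = map_b.grid.ravel()
    if a.shape != b.shape:
        raise ValueError(f"map shapes differ: {map_a.grid.shape} vs {map_b.grid.shape}")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("Pearson correlation undefined for a constant map")
    return float(np.corrcoef(a, b)[0, 1])


def auc_judd(dmap: DensityMap, positives) -> float:
    """ROC area of a map against positive point locations.

    The map is thresholded at each distinct value it attains at the positive
    locations; the true-positive rate is the fraction of positives at or
    above threshold, the false-positive rate the fraction of the remaining
    pixels at or above threshold. The area is integrated by the trapezoidal
    rule. Invariant under strictly monotone transforms of the map values.
    A constant map carries no information and scores 0.5 (with a warning).
    """
    positives = np.asarray(positives, dtype=float).reshape(-1, 2)
    if len(positives) == 0:
        raise ValueError("auc_judd requires at least one positive location")
    grid = dmap.grid
    height, width = grid.shape
    ix = np.rint(positives[:, 0]).astype(int)
    iy = np.rint(positives[:, 1]).astype(int)
    if np.any(ix < 0) or np.any(ix >= width) or np.any(iy < 0) or np.any(iy >= height):
        raise ValueError("positive locations must lie inside the map")

    if grid.max() == grid.min():
        warnings.warn("constant map: AUC defined as 0.5 by convention", stacklevel=2)
        return 0.5

    pos_values = grid[iy, ix]
    flat_idx = np.unique(iy * width + ix)
    remaining = np.delete(grid.ravel(), flat_idx)
    if remaining.size == 0:
        raise ValueError("no non-positive pixels left to form false positives")

    thresholds = np.unique(pos_values)[::-1]  # descending
    n_pos = len(pos_values)
    n_rem = remaining.size
    tpr = [0.0]
    fpr = [0.0]
    remaining_sorted = np.sort(remaining)
    pos_sorted = np.sort(pos_values)
    for t in thresholds:
        tpr.append((n_pos - np.searchsorted(pos_sorted, t, side="left")) / n_pos)
        fpr.append((n_rem - np.searchsorted(remaining_sorted, t, side="left")) / n_rem)
    tpr.append(1.0)
    fpr.append(1.0)
    return float(np.trapezoid(tpr, fpr))


def compare_conditions(
    maps_by_image: Mapping[str, Mapping[str, DensityMap]],
    clicks: ClickTable,
    geom: ScreenGeometry,
    click_sigma_deg: float = 2.0,
) -> pd.DataFrame:
    """Score per-image maps against clicking data.

    For every image and every available map kind in :data:`COMPARED_KINDS`,
    computes Pearson CC against the clicking map (built here at
    ``click_sigma_deg``) and ROC area against the raw click positions.
    Images or kinds without data are skipped and logged, not errors.
    Returns a long-format frame (image, map_kind, metric, value).
    """
    rows = []
    for image_id, kind_maps in maps_by_image.items():
        positives = clicks.positions_for(image_id)
        if len(positives) == 0:
            log.warning("no click data for image %s; skipped", image_id)
            continue
        any_map = next(iter(kind_maps.values()))
        clicking = make_density_map(
            positives, any_map.image_size, click_sigma_deg, geom, kind="clicking"
        )
        for kind in COMPARED_KINDS:
            dmap = kind_maps.get(kind)
            if dmap is None:
                log.warning("image %s has no %s map; cell absent", image_id, kind)
                continue
            rows.append(
                {
                    "image": image_id,
                    "map_kind": kind,
                    "metric": "cc",
                    "value": pearson_cc(dmap, clicking),
                }
            )
            rows.append(
                {
                    "image": image_id,
                    "map_kind": kind,
                    "metric": "auc",
                    "value": auc_judd(dmap, positives),
                }
            )
    return pd.DataFrame(rows, columns=["image", "map_kind", "metric", "value"])


def permute_recall(
    recall_by_image: Mapping[str, object],
    rng: np.random.Generator | None = None,
    permutation=None,
) -> dict:
    """Re-pair recall sequences with the wrong images (chance baseline).

    Returns a dict with the same keys but values taken from a permuted key
    order. Provide an explicit ``permutation`` (sequence of positions) for
    reproducibility; the identity permutation returns an equal pairing.
    """
    keys = sorted(recall_by_image)
    if permutation is None:
        if rng is None:
            raise ValueError("provide either rng or an explicit permutation")
        permutation = rng.permutation(len(keys))
    permutation = list(permutation)
    if sorted(permutation) != list(range(len(keys))):
        raise ValueError("permutation must be a rearrangement of range(n)")
    return {keys[i]: recall_by_image[keys[p]] for i, p in enumerate(permutation)}


def summarize_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """Mean score per (map_kind, metric) over images."""
    if scores.empty:
        return pd.DataFrame(columns=["map_kind", "metric", "value"])
    return (
        scores.groupby(["map_kind", "metric"], as_index=False)["value"].mean()
    )
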