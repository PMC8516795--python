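"""Radius matching of relocated recall fixations onto encoding fixations.

An encoding fixation counts as matched when any relocated recall fixation
lies within the matching radius epsilon (inclusive). Matching is
many-to-many: one recall fixation may claim several encoding fixations and
vice versa; there is no one-to-one assignment step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .density_maps import DensityMap, make_density_map
from .gaze_data import FixationSequence, ScreenGeometry, deg_to_px, px_to_deg

__all__ = [
    "MatchResult",
    "match",
    "reduction_rate",
    "matched_maps",
    "jaccard",
    "match_table",
]


@dataclass
class MatchResult:
    """Partition of encoding fixations into matched vs leftover.

    ``correspondences`` lists every (recall index, encoding index, distance
    in pixels) pair within the matching radius.
    """

    matched_encoding: np.ndarray
    leftover_encoding: np.ndarray
    correspondences: list[tuple[int, int, float]]
    epsilon_deg: float

    @property
    def n_encoding(self) -> int:
        return len(self.matched_encoding) + len(self.leftover_encoding)

    @property
    def matched_set(self) -> frozenset:
        return frozenset(int(i) for i in self.matched_encoding)


def match(
    encoding,
    relocated,
    epsilon_deg: float,
    geom: ScreenGeometry,
) -> MatchResult:
    """Partition encoding fixations by proximity to relocated recall fixations.

    Encoding fixation i is matched iff its distance to the nearest relocated
    recall fixation is <= ``deg_to_px(epsilon_deg)`` (boundary inclusive).
    An empty relocated set leaves every encoding fixation unmatched; an
    empty encoding set is an error.
    """
    if epsilon_deg <= 0:
        raise ValueError(f"epsilon_deg must be > 0, got {epsilon_deg}")
    P = encoding.positions if isinstance(encoding, FixationSequence) else np.asarray(
        encoding, dtype=float
    ).reshape(-1, 2)
    D = np.asarray(relocated, dtype=float).reshape(-1, 2)
    n = len(P)
    if n == 0:
        raise ValueError("match requires at least one encoding fixation")
    eps_px = deg_to_px(epsilon_deg, geom)

    if len(D) == 0:
        return MatchResult(
            matched_encoding=np.empty(0, dtype=int),
            leftover_encoding=np.arange(n),
            correspondences=[],
            epsilon_deg=float(epsilon_deg),
        )

    dist = np.linalg.norm(P[:, None, :] - D[None, :, :], axis=2)  # (n_enc, n_rec)
    within = dist <= eps_px
    matched_mask = within.any(axis=1)
    correspondences = [
        (int(j), int(i), float(dist[i, j])) for i, j in zip(*np.nonzero(within))
    ]
    return MatchResult(
        matched_encoding=np.nonzero(matched_mask)[0],
        leftover_encoding=np.nonzero(~matched_mask)[0],
        correspondences=correspondences,
        epsilon_deg=float(epsilon_deg),
    )


def reduction_rate(result: MatchResult) -> float:
    """Leftover encoding fixations divided by all encoding fixations."""
    if result.n_encoding == 0:
        raise ValueError("reduction rate undefined for zero encoding fixations")
    return len(result.leftover_encoding) / result.n_encoding


def matched_maps(
    encoding: FixationSequence,
    result: MatchResult,
    sigma_deg: float,
    geom: ScreenGeometry,
) -> tuple[DensityMap, DensityMap]:
    """Density maps of the matched ('remembered') and leftover ('forgotten')
    encoding fixations; their unsmoothed counts partition the encoding map."""
    positions = encoding.positions
    matched = make_density_map(
        positions[result.matched_encoding],
        encoding.image_size,
        sigma_deg,
        geom,
        kind="matched_encoding",
    )
    leftover = make_density_map(
        positions[result.leftover_encoding],
        encoding.image_size,
        sigma_deg,
        geom,
        kind="leftover",
    )
    return matched, leftover


def jaccard(a, b) -> float:
    """Jaccard overlap of two index sets; 1.0 when both are empty."""
    sa, sb = set(a), set(b)
    if not sa and not sb:
        return 1.0
    return len(sa & sb) / len(sa | sb)


def match_table(
    encoding: FixationSequence,
    relocated,
    result: MatchResult,
    geom: ScreenGeometry,
) -> pd.DataFrame:
    """Per-encoding-fixation table: matched flag, nearest recall fixation
    and its distance in degrees (for the CLI TSV output)."""
    P = encoding.positions
    D = np.asarray(relocated, dtype=float).reshape(-1, 2)
    rows = []
    matched = result.matched_set
    for i, fix in enumerate(encoding):
        if len(D):
            dist = np.linalg.norm(D - P[i], axis=1)
            nearest = int(np.argmin(dist))
            nearest_deg = float(px_to_deg(dist[nearest], geom))
        else:
            nearest, nearest_deg = -1, float("nan")
        rows.append(
            {
                "participant": encoding.participant_id,
                "image": encoding.image_id,
                "encoding_index": fix.index,
                "matched": int(i in matched),
                "nearest_recall_index": nearest,
                "distance_deg": nearest_deg,
            }
        )
    return pd.DataFrame(rows)
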