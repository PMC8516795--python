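"""Gaze density maps (smoothed spatial histograms) and position entropy.

Six map kinds are distinguished: ``encoding``, ``recall``,
``relocated_recall``, ``matched_encoding``, ``leftover`` and ``clicking``.
All share the same representation: a nonnegative grid at stimulus resolution
obtained by binning point positions to their nearest pixel and convolving
with an isotropic Gaussian whose sigma is given in degrees of visual angle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .gaze_data import ScreenGeometry, deg_to_px

__all__ = [
    "DensityMap",
    "MAP_KINDS",
    "make_density_map",
    "normalize_map",
    "peak_location",
    "peak_shifted",
    "fixation_entropy_2d",
    "map_to_tsv",
    "map_from_tsv",
    "map_to_png",
]

MAP_KINDS = (
    "encoding",
    "recall",
    "relocated_recall",
    "matched_encoding",
    "leftover",
    "clicking",
)


@dataclass(frozen=True)
class DensityMap:
    """Smoothed spatial histogram on the stimulus pixel grid.

    ``grid`` is indexed ``[row, col]`` i.e. ``[y, x]``; its shape is
    ``(image_height, image_width)``.
    """

    grid: np.ndarray
    kernel_sigma_deg: float
    kind: str = "encoding"

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        object.__setattr__(self, "grid", grid)
        if grid.ndim != 2:
            raise ValueError("density map grid must be 2-D")
        if not np.all(np.isfinite(grid)) or np.any(grid < 0):
            raise ValueError("density map values must be finite and >= 0")
        if self.kind not in MAP_KINDS:
            raise ValueError(f"unknown map kind {self.kind!r}; expected one of {MAP_KINDS}")

    @property
    def image_size(self) -> tuple[int, int]:
        """(width, height) in pixels."""
        return (self.grid.shape[1], self.grid.shape[0])

    @property
    def total(self) -> float:
        return float(self.grid.sum())


def _bin_points(points: np.ndarray, image_size, weights=None) -> np.ndarray:
    width, height = image_size
    hist = np.zeros((height, width), dtype=float)
    if len(points) == 0:
        return hist
    ix = np.clip(np.rint(points[:, 0]).astype(int), 0, width - 1)
    iy = np.clip(np.rint(points[:, 1]).astype(int), 0, height - 1)
    w = np.ones(len(points)) if weights is None else np.asarray(weights, dtype=float)
    np.add.at(hist, (iy, ix), w)
    return hist


def make_density_map(
    points,
    image_size: tuple[int, int],
    sigma_deg: float,
    geom: ScreenGeometry,
    kind: str = "encoding",
    duration_weights=None,
) -> DensityMap:
    """Bin points to their nearest pixel and smooth with a Gaussian kernel.

    ``sigma_deg`` is converted to pixels through ``geom``. Counts are
    unweighted unless ``duration_weights`` is given. Total mass equals the
    number of points (to 1e-6 relative) whenever all points lie at least four
    sigma away from the image borders; zero points yield an all-zero map.
    """
    if sigma_deg <= 0:
        raise ValueError(f"sigma_deg must be > 0, got {sigma_deg}")
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    hist = _bin_points(points, image_size, duration_weights)
    sigma_px = deg_to_px(sigma_deg, geom)
    grid = gaussian_filter(hist, sigma=sigma_px, mode="constant", truncate=4.0)
    return DensityMap(grid=grid, kernel_sigma_deg=float(sigma_deg), kind=kind)


def normalize_map(dmap: DensityMap, mode: str = "unit_range") -> DensityMap:
    """Rescale a map so its maximum is 1 (``unit_range``) or its sum is 1
    (``unit_sum``). All-zero maps have no defined scale and raise."""
    grid = dmap.grid
    if mode == "unit_range":
        top = grid.max()
        if top <= 0:
            raise ValueError("cannot range-normalize an all-zero map")
        return DensityMap(grid / top, dmap.kernel_sigma_deg, dmap.kind)
    if mode == "unit_sum":
        total = grid.sum()
        if total <= 0:
            raise ValueError("cannot sum-normalize an all-zero map")
        return DensityMap(grid / total, dmap.kernel_sigma_deg, dmap.kind)
    raise ValueError(f"unknown normalization mode {mode!r}")


def peak_location(dmap: DensityMap) -> np.ndarray:
    """Position (x, y) of the map maximum; ties break to the smallest row,
    then the smallest column."""
    grid = dmap.grid
    if grid.max() <= 0:
        raise ValueError("peak of an all-zero map is undefined")
    row, col = np.unravel_index(int(np.argmax(grid)), grid.shape)
    return np.array([col, row], dtype=float)


def peak_shifted(
    map_a: DensityMap,
    map_b: DensityMap,
    geom: ScreenGeometry,
    threshold_deg: float = 4.0,
) -> bool:
    """True iff the two map peaks are strictly more than ``threshold_deg``
    of visual angle apart."""
    if map_a.grid.shape != map_b.grid.shape:
        raise ValueError(
            f"map shapes differ: {map_a.grid.shape} vs {map_b.grid.shape}"
        )
    pa = peak_location(map_a)
    pb = peak_location(map_b)
    return float(np.linalg.norm(pa - pb)) > deg_to_px(threshold_deg, geom)


def fixation_entropy_2d(points, image_size: tuple[int, int], n_bins: int = 16) -> float:
    """Normalized Shannon entropy of the 2-D occupancy histogram.

    The image is divided into ``n_bins x n_bins`` cells; entropy of the cell
    occupancy distribution is divided by ``log(n_bins**2)`` so the result is
    in [0, 1] regardless of logarithm base. Requires at least one point.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(points) == 0:
        raise ValueError("entropy of zero points is undefined")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    width, height = image_size
    hist, _, _ = np.histogram2d(
        np.clip(points[:, 0], 0, width - 1e-9),
        np.clip(points[:, 1], 0, height - 1e-9),
        bins=n_bins,
        range=[[0, width], [0, height]],
    )
    p = hist.ravel() / hist.sum()
    p = p[p > 0]
    entropy = float(-(p * np.log(p)).sum())
    return entropy / float(np.log(n_bins**2))


# ---------------------------------------------------------------------------
# Export helpers (TSV is the round-trip format; PNG is visualization only)


def map_to_tsv(dmap: DensityMap, path) -> None:
    np.savetxt(path, dmap.grid, delimiter="\t")


def map_from_tsv(path, kernel_sigma_deg: float, kind: str = "encoding") -> DensityMap:
    grid = np.atleast_2d(np.loadtxt(path, delimiter="\t"))
    return DensityMap(grid=grid, kernel_sigma_deg=kernel_sigma_deg, kind=kind)


def map_to_png(dmap: DensityMap, path, cmap: str = "inferno") -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6 * dmap.grid.shape[0] / max(dmap.grid.shape[1], 1)))
    ax.imshow(dmap.grid, cmap=cmap, origin="upper")
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight", dpi=150)
    plt.close(fig)
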