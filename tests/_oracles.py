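"""Independent brute-force oracles shared by unit and acceptance tests."""

import numpy as np


def procrustes_objective(src, dst, weights, angle, translation=None):
    """Literal weighted sum of squared residuals for a rotation angle.

    If ``translation`` is None, the closed-form optimal translation for that
    angle (difference of weighted centroids) is used.
    """
    c, s = np.cos(angle), np.sin(angle)
    R = np.array([[c, -s], [s, c]])
    w = np.asarray(weights, float)
    if translation is None:
        total = w.sum()
        translation = (w @ dst) / total - R @ ((w @ src) / total)
    res = src @ R.T + translation - dst
    return float((w * (res**2).sum(axis=1)).sum())


def grid_search_procrustes(src, dst, weights, step=1e-5, chunk=200_000):
    """Minimum objective over a dense rotation-angle grid with closed-form
    translation per angle. Entirely independent of the SVD solver."""
    src = np.asarray(src, float)
    dst = np.asarray(dst, float)
    w = np.asarray(weights, float)
    total = w.sum()
    cs = (w @ src) / total
    cd = (w @ dst) / total
    angles = np.arange(-np.pi, np.pi, step)
    best = np.inf
    for start in range(0, len(angles), chunk):
        th = angles[start : start + chunk]
        c, s = np.cos(th), np.sin(th)
        obj = np.zeros_like(th)
        # translation per angle: t = cd - R cs
        tx = cd[0] - (c * cs[0] - s * cs[1])
        ty = cd[1] - (s * cs[0] + c * cs[1])
        for j in range(len(src)):
            rx = c * src[j, 0] - s * src[j, 1] + tx - dst[j, 0]
            ry = s * src[j, 0] + c * src[j, 1] + ty - dst[j, 1]
            obj += w[j] * (rx**2 + ry**2)
        best = min(best, float(obj.min()))
    return best


def roc_auc_enumeration(grid, positives_xy):
    """Direct ROC enumeration for a map and integer positive pixel locations.

    Thresholds at each distinct map value attained at the positives; rates
    use >= comparisons; trapezoidal area. Written loop-style on purpose.
    """
    height, width = grid.shape
    pos_vals = [grid[int(round(y)), int(round(x))] for x, y in positives_xy]
    pos_pixels = {(int(round(x)), int(round(y))) for x, y in positives_xy}
    rest = [
        grid[r, c]
        for r in range(height)
        for c in range(width)
        if (c, r) not in pos_pixels
    ]
    points = [(0.0, 0.0)]
    for t in sorted(set(pos_vals), reverse=True):
        tpr = sum(v >= t for v in pos_vals) / len(pos_vals)
        fpr = sum(v >= t for v in rest) / len(rest)
        points.append((fpr, tpr))
    points.append((1.0, 1.0))
    area = 0.0
    for (f0, t0), (f1, t1) in zip(points, points[1:]):
        area += (f1 - f0) * (t0 + t1) / 2.0
    return area
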