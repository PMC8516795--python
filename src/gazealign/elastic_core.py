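"""Consensus-based elastic relocation of recall fixations.

The relocation D maps each recall fixation position toward the encoding
configuration. It is a spatially varying rigid transform: at any evaluation
point, a rotation and translation are fitted by weighted orthogonal
Procrustes (moving-least-squares with rigid transforms), with Gaussian
weights that decay with distance from the evaluation point. The targets of
the fit are *consensus locations*: Gaussian-distance-weighted centroids of
the encoding fixations around the current relocated positions. Targets and
transforms depend on each other, so the two steps are alternated from an
identity initialization until the relocated points stop moving.

Three consensus regimes fall out of the weighting without special casing:
an isolated nearby encoding fixation captures the target; a tight group of
encoding fixations pulls the target to its weighted centre; and when every
encoding fixation is far away the target degenerates to the current
relocated position itself (flagged, handled explicitly to avoid 0/0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gaze_data import FixationSequence, ScreenGeometry, deg_to_px

__all__ = [
    "RigidTransform2D",
    "AlgorithmParams",
    "RelocationResult",
    "gaussian_weight",
    "consensus_targets",
    "weighted_rigid_procrustes",
    "mls_rigid_deform",
    "relocate",
]


@dataclass(frozen=True)
class RigidTransform2D:
    """Proper rigid motion of the plane: x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(2, 2)
        t = np.asarray(self.translation, dtype=float).reshape(2)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R.T @ R, np.eye(2), atol=1e-8):
            raise ValueError("rotation must be orthogonal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation must be proper (det +1); reflections are not allowed")

    @classmethod
    def identity(cls) -> "RigidTransform2D":
        return cls(np.eye(2), np.zeros(2))

    @classmethod
    def from_angle(cls, angle_rad: float, translation=(0.0, 0.0)) -> "RigidTransform2D":
        c, s = np.cos(angle_rad), np.sin(angle_rad)
        return cls(np.array([[c, -s], [s, c]]), np.asarray(translation, dtype=float))

    @property
    def angle_rad(self) -> float:
        return float(np.arctan2(self.rotation[1, 0], self.rotation[0, 0]))

    def apply(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        out = np.atleast_2d(pts) @ self.rotation.T + self.translation
        return out[0] if single else out


@dataclass(frozen=True)
class AlgorithmParams:
    """Scales (in degrees of visual angle) and stopping rule of the iteration.

    ``w_p_deg`` controls how far encoding fixations may be and still pull on
    a consensus target; ``w_d_deg`` controls the rigidity of the deformation
    (large = near-global rigid motion, small = independent local motions);
    ``epsilon_deg`` is the downstream matching radius.
    """

    w_p_deg: float = 2.0
    w_d_deg: float = 10.0
    epsilon_deg: float = 1.0
    max_iter: int = 50
    tol_deg: float = 0.01

    def __post_init__(self) -> None:
        for name in ("w_p_deg", "w_d_deg", "epsilon_deg", "tol_deg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"AlgorithmParams.{name} must be > 0")
        if self.max_iter < 1:
            raise ValueError("AlgorithmParams.max_iter must be >= 1")


@dataclass
class RelocationResult:
    """Outcome of the alternating iteration for one encoding/recall pair."""

    relocated: np.ndarray
    per_point_transforms: list[RigidTransform2D]
    iterations_run: int
    converged: bool
    displacement_history: list[float] = field(default_factory=list)


def gaussian_weight(distance, scale):
    """exp(-distance^2 / scale^2); equals 1 at distance 0 and e^-1 at the scale."""
    if np.any(np.asarray(scale) <= 0):
        raise ValueError(f"weight scale must be > 0, got {scale}")
    d = np.asarray(distance, dtype=float)
    out = np.exp(-(d**2) / float(scale) ** 2)
    return out if out.ndim else float(out)


def _positions(obj) -> np.ndarray:
    if isinstance(obj, FixationSequence):
        return obj.positions
    return np.asarray(obj, dtype=float).reshape(-1, 2)


def consensus_targets(
    relocated_recall,
    encoding,
    w_p_px: float,
    return_flags: bool = False,
):
    """Distance-weighted centroids of encoding fixations.

    For each current relocated recall position ``d_j`` the target is
    ``q_j = sum_i w(|d_j - p_i|) p_i / sum_i w(|d_j - p_i|)`` with Gaussian
    weights of scale ``w_p_px``. When the weights underflow to zero (all
    encoding fixations extremely far), the target is ``d_j`` itself and the
    point is flagged.
    """
    D = _positions(relocated_recall)
    P = _positions(encoding)
    if len(P) == 0 or len(D) == 0:
        raise ValueError("consensus_targets requires at least one point on each side")
    dist = np.linalg.norm(D[:, None, :] - P[None, :, :], axis=2)
    W = gaussian_weight(dist, w_p_px)
    denom = W.sum(axis=1)
    far = denom <= 0.0
    safe = np.where(far, 1.0, denom)
    q = (W @ P) / safe[:, None]
    q[far] = D[far]
    if return_flags:
        return q, far
    return q


def weighted_rigid_procrustes(src, dst, weights) -> RigidTransform2D:
    """Best proper rigid transform R, t minimizing sum_j w_j |R r_j + t - q_j|^2.

    Solved via the SVD of the weighted cross-covariance with a sign
    correction that forces det(R) = +1. Degenerate inputs (a single
    effective point, collinear or coincident points) fall back continuously
    to the identity rotation with the weighted-mean translation.
    """
    src = _positions(src)
    dst = _positions(dst)
    w = np.asarray(weights, dtype=float).ravel()
    if src.shape != dst.shape or len(w) != len(src):
        raise ValueError("src, dst and weights must have matching lengths")
    if not np.all(np.isfinite(w)) or np.any(w < 0):
        raise ValueError("weights must be finite and nonnegative")
    total = w.sum()
    if total <= 0:
        raise ValueError("at least one weight must be positive")

    c_src = (w @ src) / total
    c_dst = (w @ dst) / total
    src_c = src - c_src
    dst_c = dst - c_dst
    H = (w[:, None] * src_c).T @ dst_c  # 2x2 weighted cross-covariance

    U, S, Vt = np.linalg.svd(H)
    sign = np.sign(np.linalg.det(Vt.T @ U.T))
    if sign == 0:
        sign = 1.0
    R = Vt.T @ np.diag([1.0, sign]) @ U.T
    if S[0] <= 0:
        R = np.eye(2)  # no spatial extent: rotation indeterminate, use identity
    t = c_dst - R @ c_src
    return RigidTransform2D(R, t)


def mls_rigid_deform(
    x,
    handles_src,
    handles_dst,
    w_d_px: float,
) -> tuple[RigidTransform2D, np.ndarray]:
    """Rigid moving-least-squares deformation evaluated at one point.

    Fits a rigid transform to the handle pairs with Gaussian weights of
    scale ``w_d_px`` centred on ``x`` and applies it to ``x``. Weights are
    rescaled by the nearest-handle distance before exponentiation, which is
    exact (Procrustes is invariant to weight scale) and avoids underflow for
    evaluation points far from every handle.
    """
    x = np.asarray(x, dtype=float).reshape(2)
    src = _positions(handles_src)
    dst = _positions(handles_dst)
    if len(src) == 0:
        raise ValueError("mls_rigid_deform requires at least one handle")
    if w_d_px <= 0:
        raise ValueError(f"w_d_px must be > 0, got {w_d_px}")
    d2 = ((src - x) ** 2).sum(axis=1)
    weights = np.exp(-(d2 - d2.min()) / float(w_d_px) ** 2)
    transform = weighted_rigid_procrustes(src, dst, weights)
    return transform, transform.apply(x)


def relocate(
    encoding,
    recall,
    params: AlgorithmParams | None = None,
    geom: ScreenGeometry | None = None,
) -> RelocationResult:
    """Alternate consensus targeting and rigid-MLS deformation to relocate
    recall fixations onto the encoding configuration.

    Each iteration (a) recomputes consensus targets from the *current*
    relocated positions, then (b) re-evaluates the deformation at the
    *original* recall positions — source handles never move, only their
    targets do — so D stays a single mapping of the original recall
    configuration. Stops when the largest per-point displacement between
    iterations drops below ``tol_deg`` or after ``max_iter`` iterations
    (``converged=False`` in that case).
    """
    from .gaze_data import DEFAULT_GEOMETRY

    params = params or AlgorithmParams()
    geom = geom or DEFAULT_GEOMETRY
    P = _positions(encoding)
    R0 = _positions(recall)
    if len(P) == 0 or len(R0) == 0:
        raise ValueError("relocate requires non-empty encoding and recall sequences")

    w_p_px = deg_to_px(params.w_p_deg, geom)
    w_d_px = deg_to_px(params.w_d_deg, geom)
    tol_px = deg_to_px(params.tol_deg, geom)

    current = R0.copy()
    transforms: list[RigidTransform2D] = [RigidTransform2D.identity()] * len(R0)
    history: list[float] = []
    converged = False
    iterations = 0

    for iterations in range(1, params.max_iter + 1):
        targets = consensus_targets(current, P, w_p_px)
        new = np.empty_like(current)
        new_transforms: list[RigidTransform2D] = []
        for j in range(len(R0)):
            transform, moved = mls_rigid_deform(R0[j], R0, targets, w_d_px)
            new[j] = moved
            new_transforms.append(transform)
        displacement = float(np.linalg.norm(new - current, axis=1).max())
        history.append(displacement)
        current = new
        transforms = new_transforms
        if displacement < tol_px:
            converged = True
            break

    return RelocationResult(
        relocated=current,
        per_point_transforms=transforms,
        iterations_run=iterations,
        converged=converged,
        displacement_history=history,
    )
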