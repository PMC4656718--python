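"""Planar 3-DoF kinematic arm, parametric target shapes, joint-space
target generation, and the NRMSE behavioural error.

The arm is a chain of three segments in the plane, base at the origin,
angles in radians with counter-clockwise positive and cumulative from the
base (the usual planar convention). Read-out activations in [0, 1] map
affinely onto per-joint angle ranges.

Rhythmic target shapes (square, sideways figure-eight, moon) are sampled
in Cartesian space and converted to periodic joint-angle series by damped
least-squares inverse kinematics with a null-space pull toward a rest
posture; the pull resolves the one-dimensional redundancy of a 3-joint
planar arm so the joint series closes on itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ArmModel", "TargetTask", "forward_kinematics", "inverse_kinematics",
    "shape_points", "make_target", "nrmse", "SHAPE_CATALOGUE",
]


@dataclass(frozen=True)
class ArmModel:
    """Segment lengths, joint limits and the read-out-to-angle map."""

    lengths: tuple = (1.0, 1.0, 1.0)
    joint_limits: tuple = ((-np.pi, np.pi),) * 3
    rest_posture: tuple = (0.9, 0.6, 0.4)

    def __post_init__(self) -> None:
        if any(l <= 0 for l in self.lengths):
            raise ValueError("segment lengths must be positive")

    @property
    def reach(self) -> float:
        return float(sum(self.lengths))

    def readout_to_angles(self, o: np.ndarray) -> np.ndarray:
        """Affine map from read-out activations in [0, 1] to joint angles."""
        lims = np.asarray(self.joint_limits, dtype=float)
        return lims[:, 0] + np.asarray(o, dtype=float) * (lims[:, 1] - lims[:, 0])

    def angles_to_readout(self, angles: np.ndarray) -> np.ndarray:
        lims = np.asarray(self.joint_limits, dtype=float)
        return (np.asarray(angles, dtype=float) - lims[:, 0]) / (lims[:, 1] - lims[:, 0])


def forward_kinematics(angles: np.ndarray, arm: ArmModel) -> np.ndarray:
    """Joint and end-effector positions of the planar chain.

    Returns an array of shape (4, 2): base, joint 2, joint 3, end effector.
    Angles are cumulative: segment *i* points along ``sum(angles[:i+1])``.
    """
    angles = np.asarray(angles, dtype=float)
    if not np.all(np.isfinite(angles)):
        raise ValueError("joint angles must be finite")
    pts = np.zeros((4, 2))
    phi = 0.0
    for i, (a, l) in enumerate(zip(angles, arm.lengths)):
        phi += a
        pts[i + 1] = pts[i] + l * np.array([np.cos(phi), np.sin(phi)])
    return pts


def _jacobian(angles: np.ndarray, arm: ArmModel) -> np.ndarray:
    """2x3 Jacobian of the end-effector position."""
    phi = np.cumsum(angles)
    J = np.zeros((2, 3))
    for j in range(3):
        # joint j moves all segments from j on
        for i in range(j, 3):
            J[0, j] += -arm.lengths[i] * np.sin(phi[i])
            J[1, j] += arm.lengths[i] * np.cos(phi[i])
    return J


def inverse_kinematics(
    target: np.ndarray,
    arm: ArmModel,
    seed_angles: np.ndarray,
    damping: float = 0.1,
    null_gain: float = 0.1,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> np.ndarray:
    """Damped least-squares IK for one Cartesian target point.

    Iterates ``dtheta = J^T (J J^T + damping^2 I)^-1 err`` plus a
    null-space pull toward the arm's rest posture, starting from
    ``seed_angles``. The null-space term makes the solution unique, so
    periodic Cartesian curves map to periodic joint series.
    """
    target = np.asarray(target, dtype=float)
    if np.linalg.norm(target) > arm.reach:
        raise ValueError(
            f"target {target} outside arm reach (max {arm.reach:.3f})"
        )
    theta = np.asarray(seed_angles, dtype=float).copy()
    rest = np.asarray(arm.rest_posture, dtype=float)
    eye2 = np.eye(2)
    for _ in range(max_iter):
        err = target - forward_kinematics(theta, arm)[-1]
        if err @ err < tol**2:
            break
        J = _jacobian(theta, arm)
        JJt = J @ J.T + damping**2 * eye2
        dtheta = J.T @ np.linalg.solve(JJt, err)
        # null-space pull toward the rest posture
        Jpinv = J.T @ np.linalg.solve(J @ J.T + 1e-9 * eye2, eye2)
        null = (np.eye(3) - Jpinv @ J) @ (rest - theta)
        theta = theta + dtheta + null_gain * null
    return theta


# ---------------------------------------------------------------------------
# shape catalogue

def _square(t: np.ndarray) -> np.ndarray:
    """Rounded-corner square of side 0.8, traced counter-clockwise."""
    half, r = 0.4, 0.12
    s = half - r
    # perimeter pieces: 4 straights of length 2s and 4 quarter arcs
    straight, arc = 2 * s, 0.5 * np.pi * r
    total = 4 * (straight + arc)
    d = (t / (2 * np.pi)) * total
    pts = np.zeros((len(t), 2))
    seg = np.stack([d % total], axis=-1)[:, 0]
    for i, di in enumerate(seg):
        side, rem = int(di // (straight + arc)), di % (straight + arc)
        if rem < straight:
            u = rem - s
            local = {0: (u, -half), 1: (half, u), 2: (-u, half), 3: (-half, -u)}[side]
        else:
            a = (rem - straight) / r
            base = {0: (s, -s), 1: (s, s), 2: (-s, s), 3: (-s, -s)}[side]
            phi0 = side * 0.5 * np.pi - 0.5 * np.pi
            local = (base[0] + r * np.cos(phi0 + a), base[1] + r * np.sin(phi0 + a))
        pts[i] = local
    return pts


def _figure8(t: np.ndarray) -> np.ndarray:
    """Sideways figure-eight (Lissajous 1:2), lobes left and right."""
    return np.stack([0.5 * np.sin(t), 0.3 * np.sin(2 * t)], axis=-1)


def _moon(t: np.ndarray) -> np.ndarray:
    """Crescent: a 240-degree outer arc and a shallower inner return arc
    through the same two end points (both bulging the same way)."""
    R, theta_out, bulge = 0.45, 2 * np.pi / 3, 0.2
    ex, ey = R * np.cos(theta_out), R * np.sin(theta_out)
    # inner arc: circle with centre (c, 0) through the outer end points,
    # rightmost point at x = bulge
    c = (bulge**2 - ex**2 - ey**2) / (2 * (bulge - ex))
    r = bulge - c
    theta_in = np.arctan2(ey, ex - c)
    t = np.mod(t, 2 * np.pi)
    pts = np.zeros((len(t), 2))
    out = t < np.pi
    a = -theta_out + (t[out] / np.pi) * (2 * theta_out)
    pts[out] = R * np.stack([np.cos(a), np.sin(a)], axis=-1)
    b = theta_in - ((t[~out] - np.pi) / np.pi) * (2 * theta_in)
    pts[~out] = np.stack([c + r * np.cos(b), r * np.sin(b)], axis=-1)
    return pts


def _circle(t: np.ndarray) -> np.ndarray:
    return np.stack([0.3 * np.cos(t), 0.3 * np.sin(t)], axis=-1)


SHAPE_CATALOGUE = {
    "square": _square,
    "figure8": _figure8,
    "moon": _moon,
    "circle": _circle,
}

DEFAULT_SHAPE_CENTRE = np.array([1.5, 0.9])


@dataclass
class TargetTask:
    """A motor task: a joint-angle series over one task window.

    ``kind`` is "rhythmic" (periodic joint series, one shape cycle per
    ``period`` samples) or "endpoint" (constant posture). ``cartesian``
    stores the Cartesian curve the joint series realises (for rhythmic
    tasks).
    """

    kind: str
    joint_target: np.ndarray
    shape_id: str = "custom"
    cartesian: np.ndarray | None = None


def shape_points(shape_id: str, n: int, translate=(0.0, 0.0), scale: float = 1.0,
                 centre=DEFAULT_SHAPE_CENTRE) -> np.ndarray:
    """Sample ``n`` points of a catalogue shape, uniformly in phase, after
    scaling about the shape centre and translating."""
    if shape_id not in SHAPE_CATALOGUE:
        raise KeyError(
            f"unknown shape {shape_id!r}; catalogue: {sorted(SHAPE_CATALOGUE)}"
        )
    t = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    pts = SHAPE_CATALOGUE[shape_id](t) * scale
    return pts + np.asarray(centre) + np.asarray(translate, dtype=float)


def make_target(
    shape_id: str,
    n_samples: int,
    arm: ArmModel | None = None,
    translate=(0.0, 0.0),
    scale: float = 1.0,
    endpoint: bool = False,
    max_cycles: int = 12,
) -> TargetTask:
    """Build a joint-space target for a catalogue shape.

    Rhythmic targets: the Cartesian curve is sampled uniformly in phase and
    converted point-by-point with IK seeded from the previous sample; the
    conversion is iterated over repeated cycles until the series closes on
    itself, so the joint target is periodic. Endpoint targets use the first
    curve point only and return a constant posture.
    """
    arm = arm or ArmModel()
    pts = shape_points(shape_id, n_samples, translate, scale)
    if np.any(np.linalg.norm(pts, axis=1) > arm.reach):
        raise ValueError(
            f"shape {shape_id!r} leaves the arm's reach ({arm.reach:.2f})"
        )
    if endpoint:
        theta = inverse_kinematics(pts[0], arm, np.asarray(arm.rest_posture))
        return TargetTask(
            kind="endpoint",
            joint_target=np.tile(theta, (n_samples, 1)),
            shape_id=shape_id, cartesian=np.tile(pts[0], (n_samples, 1)),
        )
    theta = np.asarray(arm.rest_posture, dtype=float)
    series = np.zeros((n_samples, 3))
    for _ in range(max_cycles):
        start = theta.copy()
        for i in range(n_samples):
            theta = inverse_kinematics(pts[i], arm, theta)
            series[i] = theta
        if np.max(np.abs(theta - start)) < 1e-7:
            break
    return TargetTask(kind="rhythmic", joint_target=series,
                      shape_id=shape_id, cartesian=pts)


def nrmse(pred: np.ndarray, target: np.ndarray) -> float:
    """Normalized root-mean-square error between two (T, D) series.

    Per dimension, RMSE divided by the target's range (max - min), then
    averaged over dimensions. The target must vary in every dimension.
    """
    pred = np.atleast_2d(np.asarray(pred, dtype=float))
    target = np.atleast_2d(np.asarray(target, dtype=float))
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {target.shape}")
    rng = target.max(axis=0) - target.min(axis=0)
    if np.any(rng <= 0):
        raise ValueError("target has zero range in some dimension; "
                         "NRMSE is undefined for constant targets")
    rmse = np.sqrt(np.mean((pred - target) ** 2, axis=0))
    return float(np.mean(rmse / rng))
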