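"""Least-squares rigid registration of matched fiducial sets.

Fits the rigid transform T* = [R* t*; 0 1] minimizing
sum_i || R C_i + t - P_i ||^2 over rotations R (det +1, no scale, no
reflection) and translations t, where C is the ground-truth centroid set and
P the perceived physical set, matched by marker label.  This is the classic
Kabsch/Umeyama solution: demean both sets, take the SVD of the
cross-covariance, and correct the sign of the smallest singular direction so
the solution is a proper rotation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frames import FiducialSet, Frame, FrameTransform, Unit

__all__ = ["RigidFit", "fit_rigid"]


@dataclass(frozen=True)
class RigidFit:
    """A fitted rigid transform C -> P with its per-marker residuals.

    ``residuals[i] = R @ C_i + t - P_i`` — the fiducial-registration-error
    vector of marker i before taking norms.
    """

    rotation: np.ndarray
    translation: np.ndarray
    residuals: np.ndarray
    labels: tuple[int, ...]

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        res = np.atleast_2d(np.asarray(self.residuals, dtype=float))
        if r.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-9):
            raise ValueError("rotation matrix is not orthogonal")
        if np.linalg.det(r) < 0:
            raise ValueError("rotation has negative determinant (reflection)")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)
        object.__setattr__(self, "residuals", res)

    @property
    def matrix(self) -> np.ndarray:
        """The 4x4 homogeneous T*."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    @property
    def rms_residual(self) -> float:
        """Root-mean-square residual magnitude over markers, mm."""
        return float(np.sqrt(np.mean(np.sum(self.residuals**2, axis=1))))

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return pts @ self.rotation.T + self.translation

    def as_frame_transform(self) -> FrameTransform:
        """Package as a tagged RICS->RICS transform for serialization."""
        return FrameTransform(
            matrix=self.matrix,
            source_frame=Frame.RICS,
            target_frame=Frame.RICS,
            unit_in=Unit.MM,
            unit_out=Unit.MM,
            name="T*CP",
        )

    @classmethod
    def identity(cls, labels: tuple[int, ...] = ()) -> "RigidFit":
        n = max(len(labels), 1)
        return cls(np.eye(3), np.zeros(3), np.zeros((n, 3)), tuple(labels) or (1,))


def fit_rigid(c: FiducialSet, p: FiducialSet) -> RigidFit:
    """Fit the optimal rigid transform mapping set ``c`` onto set ``p``.

    Both sets must be in the analysis frame (RAS, mm), contain at least
    three markers, be matched label-for-label in order, and not be
    collinear.  Scaling and reflection are excluded: the linear part is a
    proper rotation (det +1) by construction.
    """
    c.check_matched(p)
    n = len(c)
    if n < 3:
        raise ValueError(f"rigid registration needs >= 3 fiducials, got {n}")

    cp = np.asarray(c.points, dtype=float)
    pp = np.asarray(p.points, dtype=float)
    c_mean = cp.mean(axis=0)
    p_mean = pp.mean(axis=0)
    cd = cp - c_mean
    pd = pp - p_mean

    # Collinear markers leave the rotation about their common axis
    # unconstrained; refuse rather than return an arbitrary solution.
    if np.linalg.matrix_rank(cd, tol=1e-8 * max(1.0, np.abs(cd).max())) < 2:
        raise ValueError(
            "degenerate fiducial configuration: markers are collinear, "
            "rigid rotation is not identifiable"
        )

    h = cd.T @ pd  # cross-covariance
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    correction = np.diag([1.0, 1.0, d])
    rotation = vt.T @ correction @ u.T
    translation = p_mean - rotation @ c_mean
    residuals = cp @ rotation.T + translation - pp
    return RigidFit(rotation, translation, residuals, c.labels)
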