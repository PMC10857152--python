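"""Landmark-based accuracy metrics: FLE, TRE, FRE and the Frobenius norm.

All four metrics live in the analysis frame (RAS, mm) and are computed from
the three ordered fiducial sets of a case:

* ``C`` — marker centroids segmented from the reference image (ground truth);
* ``V`` — the perceived *virtual* marker centers, probed on the hologram;
* ``P`` — the perceived *physical* marker centers, probed on the phantom.

The interpolated metrics are per-marker displacement vectors:
``FLE_i = V_i - C_i`` (localization/perception error — how well the user can
place the probe) and ``TRE_i = P_i - C_i`` (the virtual-to-physical alignment
error at the marker).  The extrapolated metrics derive from the optimal rigid
fit T* of C onto P: ``FRE_i = R* C_i + t* - P_i`` (geometric shape
consistency of the two sets) and ``FN = ||T* - I||_F``, the Frobenius norm of
the fitted transform minus the identity, a single scalar "size" of the
misregistration.  FN mixes dimensionless rotation residuals with millimetre
translation entries by construction; an optional decomposition into the two
parts is provided for interpretability.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .frames import FiducialSet, SurgicalPosition
from .registration import RigidFit

__all__ = [
    "MetricKind",
    "DisplacementVectors",
    "CaseLandmarkSummary",
    "compute_fle",
    "compute_tre",
    "compute_fre",
    "compute_fn",
    "decompose_fn",
    "summarize_landmarks",
]


class MetricKind(str, enum.Enum):
    FLE = "FLE"
    TRE = "TRE"
    FRE = "FRE"


@dataclass(frozen=True)
class DisplacementVectors:
    """Per-marker displacement vectors of one metric kind, with magnitudes."""

    kind: MetricKind
    labels: tuple[int, ...]
    vectors: np.ndarray  # (N, 3), mm

    def __post_init__(self) -> None:
        v = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        if v.shape != (len(self.labels), 3):
            raise ValueError(
                f"expected {(len(self.labels), 3)} vectors, got {v.shape}"
            )
        object.__setattr__(self, "vectors", v)

    @property
    def magnitudes(self) -> np.ndarray:
        """Euclidean norms, mm, one per marker."""
        return np.linalg.norm(self.vectors, axis=1)

    @property
    def mean(self) -> float:
        return float(self.magnitudes.mean())

    @property
    def sd(self) -> float:
        """Sample standard deviation (n-1) of the magnitudes."""
        m = self.magnitudes
        return float(m.std(ddof=1)) if len(m) > 1 else float("nan")


def _difference(a: FiducialSet, b: FiducialSet, kind: MetricKind) -> DisplacementVectors:
    b.check_matched(a)
    return DisplacementVectors(kind, a.labels, a.points - b.points)


def compute_fle(v: FiducialSet, c: FiducialSet) -> DisplacementVectors:
    """Fiducial localization error: per-marker vector V_i - C_i."""
    return _difference(v, c, MetricKind.FLE)


def compute_tre(p: FiducialSet, c: FiducialSet) -> DisplacementVectors:
    """Target registration error: per-marker vector P_i - C_i."""
    return _difference(p, c, MetricKind.TRE)


def compute_fre(
    c: FiducialSet, p: FiducialSet, fit: RigidFit
) -> DisplacementVectors:
    """Fiducial registration error: R* C_i + t* - P_i under the fitted T*.

    The fit must have been produced from these sets (labels must agree).
    """
    c.check_matched(p)
    if fit.labels != c.labels:
        raise ValueError(
            f"fit was computed on labels {fit.labels}, sets have {c.labels}"
        )
    vectors = c.points @ fit.rotation.T + fit.translation - p.points
    return DisplacementVectors(MetricKind.FRE, c.labels, vectors)


def compute_fn(fit: RigidFit) -> float:
    """Frobenius norm of (T* - I) over all 16 entries of the 4x4 matrix."""
    return float(np.linalg.norm(fit.matrix - np.eye(4), ord="fro"))


def decompose_fn(fit: RigidFit) -> dict[str, float]:
    """Split FN into its rotation-block and translation-column norms.

    Off-by-default interpretive extension: ``fn**2 == rotation_part**2 +
    translation_part**2`` exactly, since the two blocks are disjoint.
    """
    rot = float(np.linalg.norm(fit.rotation - np.eye(3), ord="fro"))
    trans = float(np.linalg.norm(fit.translation))
    return {
        "fn": compute_fn(fit),
        "rotation_part": rot,
        "translation_part": trans,
    }


@dataclass(frozen=True)
class CaseLandmarkSummary:
    """Per-case mean +/- SD of the landmark metric magnitudes, plus FN.

    SDs are sample standard deviations (n-1) over that case's markers.  The
    acquisition-order note records that the virtual set V was probed before
    the physical set P, so FLE serves as an uncontaminated quality-control
    baseline for the later TRE measurements.
    """

    case_id: str
    position: SurgicalPosition
    n_markers: int
    mean_fle: float
    sd_fle: float
    mean_tre: float
    sd_tre: float
    mean_fre: float
    sd_fre: float
    fn: float
    acquisition_order: tuple[str, ...] = ("V", "P")

    def as_dict(self) -> dict:
        return {
            "case_id": self.case_id,
            "position": self.position.value,
            "n_markers": self.n_markers,
            "mean_fle": self.mean_fle,
            "sd_fle": self.sd_fle,
            "mean_tre": self.mean_tre,
            "sd_tre": self.sd_tre,
            "mean_fre": self.mean_fre,
            "sd_fre": self.sd_fre,
            "fn": self.fn,
        }


def summarize_landmarks(
    case_id: str,
    position: SurgicalPosition,
    c: FiducialSet,
    v: FiducialSet,
    p: FiducialSet,
    fit: RigidFit,
) -> CaseLandmarkSummary:
    """Summarize one case's landmark metrics (means and SDs in mm, plus FN)."""
    fle = compute_fle(v, c)
    tre = compute_tre(p, c)
    fre = compute_fre(c, p, fit)
    return CaseLandmarkSummary(
        case_id=case_id,
        position=SurgicalPosition.coerce(position),
        n_markers=len(c),
        mean_fle=fle.mean,
        sd_fle=fle.sd,
        mean_tre=tre.mean,
        sd_tre=tre.sd,
        mean_fre=fre.mean,
        sd_fre=fre.sd,
        fn=compute_fn(fit),
    )
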