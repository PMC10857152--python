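"""Coordinate frames of the navigation workflow and the transforms linking them.

Four frames are involved when holographic content prepared from a reference
scan is displayed on, and measured against, a physical head:

* ``RICS`` — the reference image coordinate system of the preoperative scan:
  right-handed RAS (right-anterior-superior), millimetres.
* ``IVCS`` — an intermediate virtual frame: RICS re-oriented for the surgical
  position and rescaled to centimetres (the holographic platform's unit), but
  still right-handed.
* ``VCS`` — the virtual frame proper, left-handed (third axis flipped).
* ``ACS`` — the analysis frame in which all accuracy metrics are computed;
  identified with RICS (right-handed RAS, mm).

The forward engineering matrix (FEM) maps RICS to IVCS: a rotation about the
superior (cranio-caudal) axis that depends on the surgical position — 0 deg
supine, 180 deg prone, +/-90 deg lateral — composed with a uniform 0.1 scale
(mm to cm).  The handedness conversion matrix (HCM) negates the third axis,
taking IVCS to the left-handed VCS.  The reverse engineering matrix (REM) is
the exact inverse of the FEM and brings platform-reported coordinates back
into the analysis frame.

All transforms carry explicit source/target frame and unit tags, and
:func:`apply_transform` refuses a point set whose tags do not match — silent
unit coercion is how millimetre/centimetre bugs are born.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

__all__ = [
    "SurgicalPosition",
    "Frame",
    "Unit",
    "FiducialRole",
    "FrameTransform",
    "FiducialSet",
    "make_fem",
    "make_hcm",
    "make_rem",
    "apply_transform",
]

MM_PER_CM = 10.0


class SurgicalPosition(str, enum.Enum):
    """Patient position during navigation; selects the FEM/REM rotation."""

    SUPINE = "supine"
    PRONE = "prone"
    LEFT_LATERAL = "left_lateral"
    RIGHT_LATERAL = "right_lateral"

    @classmethod
    def coerce(cls, value: "SurgicalPosition | str") -> "SurgicalPosition":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).lower().replace("-", "_"))
        except ValueError as exc:
            raise ValueError(
                f"unknown surgical position {value!r}; expected one of "
                f"{[p.value for p in cls]}"
            ) from exc


#: Rotation (degrees, about the superior axis) applied by the FEM for each
#: position.  The lateral signs follow the default convention (left = +90);
#: ``make_fem`` accepts ``lateral_sign=-1`` to swap them.
POSITION_ANGLES_DEG = {
    SurgicalPosition.SUPINE: 0.0,
    SurgicalPosition.PRONE: 180.0,
    SurgicalPosition.LEFT_LATERAL: 90.0,
    SurgicalPosition.RIGHT_LATERAL: -90.0,
}


class Frame(str, enum.Enum):
    RICS = "RICS"
    IVCS = "IVCS"
    VCS = "VCS"
    ACS = "ACS"


class Unit(str, enum.Enum):
    MM = "mm"
    CM = "cm"


class FiducialRole(str, enum.Enum):
    """Which of the study's three ordered point sets a fiducial set plays."""

    C_GROUNDTRUTH = "C_groundtruth"
    V_VIRTUAL = "V_virtual"
    P_PHYSICAL = "P_physical"


@dataclass(frozen=True)
class FrameTransform:
    """A 4x4 homogeneous transform tagged with frames and units.

    The matrix may include a uniform scale (the FEM folds the mm->cm factor
    into the linear part), so the linear block is not necessarily orthogonal.
    """

    matrix: np.ndarray
    source_frame: Frame
    target_frame: Frame
    unit_in: Unit
    unit_out: Unit
    position: SurgicalPosition | None = None
    name: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError(f"transform matrix must be 4x4, got {m.shape}")
        if not np.allclose(m[3], [0.0, 0.0, 0.0, 1.0], atol=1e-12):
            raise ValueError("bottom row of a homogeneous transform must be (0,0,0,1)")
        if abs(np.linalg.det(m)) < 1e-12:
            raise ValueError("transform matrix is singular")
        object.__setattr__(self, "matrix", m)

    @property
    def linear(self) -> np.ndarray:
        """The 3x3 linear block (rotation, possibly scaled)."""
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def inverse(self) -> "FrameTransform":
        """Exact inverse with frame/unit tags swapped."""
        return FrameTransform(
            matrix=np.linalg.inv(self.matrix),
            source_frame=self.target_frame,
            target_frame=self.source_frame,
            unit_in=self.unit_out,
            unit_out=self.unit_in,
            position=self.position,
            name=f"inv({self.name})" if self.name else "",
        )

    def compose(self, first: "FrameTransform") -> "FrameTransform":
        """Return self o first (apply ``first``, then ``self``)."""
        if first.target_frame != self.source_frame or first.unit_out != self.unit_in:
            raise ValueError(
                f"cannot compose: inner transform produces "
                f"{first.target_frame.value}/{first.unit_out.value}, outer expects "
                f"{self.source_frame.value}/{self.unit_in.value}"
            )
        return FrameTransform(
            matrix=self.matrix @ first.matrix,
            source_frame=first.source_frame,
            target_frame=self.target_frame,
            unit_in=first.unit_in,
            unit_out=self.unit_out,
            position=self.position or first.position,
            name=f"{self.name}∘{first.name}" if (self.name and first.name) else "",
        )

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        """Apply to an (N, 3) array of coordinates (no tag checking)."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        homo = np.hstack([pts, np.ones((len(pts), 1))])
        return (self.matrix @ homo.T).T[:, :3]

    # -- plain-text serialization (row-major matrix + JSON sidecar) --------

    def write(self, path: str | Path) -> None:
        path = Path(path)
        np.savetxt(path, self.matrix, fmt="%.17g")
        sidecar = {
            "source_frame": self.source_frame.value,
            "target_frame": self.target_frame.value,
            "unit_in": self.unit_in.value,
            "unit_out": self.unit_out.value,
            "position": self.position.value if self.position else None,
            "name": self.name,
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2) + "\n"
        )

    @classmethod
    def read(cls, path: str | Path) -> "FrameTransform":
        path = Path(path)
        matrix = np.loadtxt(path).reshape(4, 4)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(
            matrix=matrix,
            source_frame=Frame(meta["source_frame"]),
            target_frame=Frame(meta["target_frame"]),
            unit_in=Unit(meta["unit_in"]),
            unit_out=Unit(meta["unit_out"]),
            position=SurgicalPosition(meta["position"]) if meta.get("position") else None,
            name=meta.get("name", ""),
        )


@dataclass(frozen=True)
class FiducialSet:
    """An ordered, labelled set of 3-D points in a named frame with units.

    The order (and the integer marker labels) carries the correspondence
    between the ground-truth set C and the measured sets V and P; every
    pairwise operation checks the labels match one-to-one.
    """

    points: np.ndarray
    labels: tuple[int, ...]
    frame: Frame = Frame.RICS
    units: Unit = Unit.MM
    role: FiducialRole | None = None

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"points must be (N, 3), got {pts.shape}")
        labels = tuple(int(l) for l in self.labels)
        if len(labels) != len(pts):
            raise ValueError(
                f"{len(pts)} points but {len(labels)} labels"
            )
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate fiducial labels in {labels}")
        if len(pts) < 1:
            raise ValueError("a fiducial set needs at least one point")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return len(self.labels)

    def check_matched(self, other: "FiducialSet") -> None:
        """Raise unless labels correspond one-to-one, in order."""
        if self.labels != other.labels:
            raise ValueError(
                f"fiducial label mismatch: {self.labels} vs {other.labels}"
            )
        analysis = {Frame.RICS, Frame.ACS}  # same physical frame
        frames_ok = self.frame == other.frame or (
            {self.frame, other.frame} <= analysis
        )
        if not frames_ok or self.units != other.units:
            raise ValueError(
                f"fiducial sets live in different frames/units: "
                f"{self.frame.value}/{self.units.value} vs "
                f"{other.frame.value}/{other.units.value}"
            )

    def with_points(self, points: np.ndarray, **changes) -> "FiducialSet":
        return replace(self, points=points, **changes)


def make_fem(
    position: SurgicalPosition | str, *, lateral_sign: int = +1
) -> FrameTransform:
    """Forward engineering matrix: RICS (mm, RAS) -> IVCS (cm).

    A rotation about the superior axis (0 supine, 180 prone, +/-90 lateral)
    composed with a uniform 0.1 scale.  ``lateral_sign=-1`` swaps the sign
    convention of the two lateral positions.
    """
    position = SurgicalPosition.coerce(position)
    if lateral_sign not in (+1, -1):
        raise ValueError("lateral_sign must be +1 or -1")
    angle = POSITION_ANGLES_DEG[position]
    if position in (SurgicalPosition.LEFT_LATERAL, SurgicalPosition.RIGHT_LATERAL):
        angle *= lateral_sign
    theta = np.deg2rad(angle)
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    m = np.eye(4)
    m[:3, :3] = (1.0 / MM_PER_CM) * rot
    return FrameTransform(
        matrix=m,
        source_frame=Frame.RICS,
        target_frame=Frame.IVCS,
        unit_in=Unit.MM,
        unit_out=Unit.CM,
        position=position,
        name=f"FEM[{position.value}]",
    )


def make_hcm() -> FrameTransform:
    """Handedness conversion matrix: IVCS -> VCS, negating the third axis."""
    return FrameTransform(
        matrix=np.diag([1.0, 1.0, -1.0, 1.0]),
        source_frame=Frame.IVCS,
        target_frame=Frame.VCS,
        unit_in=Unit.CM,
        unit_out=Unit.CM,
        name="HCM",
    )


def make_rem(
    position: SurgicalPosition | str, *, lateral_sign: int = +1
) -> FrameTransform:
    """Reverse engineering matrix: exact inverse of the FEM, IVCS (cm) -> ACS (mm)."""
    position = SurgicalPosition.coerce(position)
    fem = make_fem(position, lateral_sign=lateral_sign)
    inv = np.linalg.inv(fem.matrix)
    return FrameTransform(
        matrix=inv,
        source_frame=Frame.IVCS,
        target_frame=Frame.ACS,
        unit_in=Unit.CM,
        unit_out=Unit.MM,
        position=position,
        name=f"REM[{position.value}]",
    )


def apply_transform(t: FrameTransform, pts: FiducialSet) -> FiducialSet:
    """Apply a tagged transform to a fiducial set, checking frames and units.

    ACS and RICS are the same physical frame (both RAS mm); a set tagged with
    either is accepted where the other is expected.
    """
    equivalent = {Frame.RICS, Frame.ACS}

    def frames_match(a: Frame, b: Frame) -> bool:
        return a == b or ({a, b} <= equivalent)

    if not frames_match(pts.frame, t.source_frame) or pts.units != t.unit_in:
        raise ValueError(
            f"transform expects {t.source_frame.value} [{t.unit_in.value}] but "
            f"point set is in {pts.frame.value} [{pts.units.value}]"
        )
    return pts.with_points(
        t.apply_points(pts.points), frame=t.target_frame, units=t.unit_out
    )
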