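"""Readers and writers for the formats the pipeline touches.

Fiducials travel as plain CSV (``label,x,y,z``) or as the 3D Slicer markups
fiducial dialect (FCSV); lesion masks as NRRD or NIfTI; skin meshes as STL
or OBJ; transforms as plain-text 4x4 matrices with a JSON sidecar (see
:mod:`navphantom.frames`).

Coordinate policy, applied centrally here: point coordinates are physical
RAS millimetres, voxel indices are 0-based, and files declaring LPS (FCSV
headers; all ITK-read images) are converted on read by negating the first
two axes.  Round-trips are lossless to 1e-9 (masks: exact).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .frames import FiducialRole, FiducialSet, Frame, Unit

__all__ = [
    "RunConfig",
    "read_fiducials",
    "write_fiducials_csv",
    "write_fiducials_fcsv",
    "read_mask",
    "write_mask",
    "read_mesh",
    "write_mesh",
]

_RAS_FROM_LPS = np.diag([-1.0, -1.0, 1.0])


@dataclass
class RunConfig:
    """Fully-resolved configuration of one pipeline run.

    Written next to every run's outputs; re-running with the same config
    reproduces deterministic stages bit-for-bit.
    """

    seed: int = 0
    n_cases: int = 19
    position_mix: tuple[int, int, int] = (8, 6, 5)
    sigma_probe: float = 1.2
    rot_sigma_deg: float = 1.5
    trans_sigma: float = 1.0
    lateral_sign: int = +1
    symmetric_hd95: bool = False
    outdir: str = "navphantom_run"
    verbosity: str = "info"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["position_mix"] = list(self.position_mix)
        return d

    def config_hash(self) -> str:
        """Hash of the scientific configuration (paths/verbosity excluded)."""
        d = self.to_dict()
        d.pop("outdir", None)
        d.pop("verbosity", None)
        payload = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def write(self, path: str | Path) -> None:
        import yaml

        doc = self.to_dict()
        doc["config_hash"] = self.config_hash()
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))

    @classmethod
    def read(cls, path: str | Path) -> "RunConfig":
        import yaml

        doc = yaml.safe_load(Path(path).read_text())
        doc.pop("config_hash", None)
        doc["position_mix"] = tuple(doc.get("position_mix", (8, 6, 5)))
        return cls(**doc)


# --------------------------------------------------------------------------
# fiducials


def _parse_label(token: str, fallback: int) -> int:
    digits = "".join(ch for ch in token if ch.isdigit())
    return int(digits) if digits else fallback


def read_fiducials(
    path: str | Path,
    dialect: str | None = None,
    role: FiducialRole | None = None,
) -> FiducialSet:
    """Read an ordered fiducial set from CSV or Slicer FCSV.

    The dialect is inferred from the suffix unless given explicitly.  FCSV
    files declaring an LPS coordinate system are converted to RAS on read
    (x and y negated).  Malformed rows raise with their line number;
    duplicate labels raise.
    """
    path = Path(path)
    dialect = dialect or ("fcsv" if path.suffix.lower() == ".fcsv" else "csv")
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path}: empty fiducial file")
    if dialect == "csv":
        return _read_plain_csv(path, text, role)
    if dialect == "fcsv":
        return _read_fcsv(path, text, role)
    raise ValueError(f"unknown fiducial dialect {dialect!r}")


def _read_plain_csv(path: Path, text: str, role) -> FiducialSet:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    start = 1 if lines and lines[0].lower().startswith("label") else 0
    labels, points = [], []
    for lineno, line in enumerate(lines[start:], start=start + 1):
        parts = [p.strip() for p in line.split(",")]
        if len(parts) != 4:
            raise ValueError(
                f"{path}:{lineno}: expected 'label,x,y,z', got {line!r}"
            )
        try:
            labels.append(int(parts[0]))
            points.append([float(v) for v in parts[1:]])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed row {line!r}") from exc
    return FiducialSet(np.array(points), tuple(labels), Frame.RICS, Unit.MM, role)


def _read_fcsv(path: Path, text: str, role) -> FiducialSet:
    lps = False
    labels, points = [], []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith("#"):
            if "CoordinateSystem" in line:
                system = line.split("=")[-1].strip()
                lps = system.upper() in ("LPS", "0")
            continue
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) < 4:
            raise ValueError(f"{path}:{lineno}: malformed FCSV row {line!r}")
        try:
            xyz = [float(v) for v in parts[1:4]]
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed FCSV row {line!r}") from exc
        label_token = parts[11] if len(parts) > 11 else ""
        labels.append(_parse_label(label_token, fallback=len(labels) + 1))
        points.append(xyz)
    pts = np.array(points)
    if lps:
        pts = pts @ _RAS_FROM_LPS  # negate x and y
    return FiducialSet(pts, tuple(labels), Frame.RICS, Unit.MM, role)


def write_fiducials_csv(fs: FiducialSet, path: str | Path) -> None:
    lines = ["label,x,y,z"]
    for label, (x, y, z) in zip(fs.labels, fs.points):
        lines.append(f"{label},{x:.17g},{y:.17g},{z:.17g}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_fiducials_fcsv(fs: FiducialSet, path: str | Path) -> None:
    """Write the Slicer markups dialect (RAS declared explicitly)."""
    lines = [
        "# Markups fiducial file version = 4.11",
        "# CoordinateSystem = RAS",
        "# columns = id,x,y,z,ow,ox,oy,oz,vis,sel,lock,label,desc,associatedNodeID",
    ]
    for i, (label, (x, y, z)) in enumerate(zip(fs.labels, fs.points), start=1):
        lines.append(
            f"vtkMRMLMarkupsFiducialNode_{i},{x:.17g},{y:.17g},{z:.17g},"
            f"0,0,0,1,1,1,0,F-{label},,"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# masks


def read_mask(path: str | Path):
    """Read a binary mask (NRRD or NIfTI) into a LesionModel, RAS mm."""
    from .lesions import LesionModel

    path = Path(path)
    suffix = "".join(path.suffixes).lower()
    if suffix.endswith((".nii", ".nii.gz")):
        return _read_nifti(path, LesionModel)
    if suffix.endswith(".nrrd"):
        return _read_nrrd(path, LesionModel)
    raise ValueError(f"unsupported mask format: {path}")


def _read_nifti(path: Path, cls):
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    affine = img.affine  # nibabel affines are RAS already
    linear = affine[:3, :3]
    spacing = np.linalg.norm(linear, axis=0)
    direction = linear / spacing
    return cls(
        mask=data > 0,
        spacing=tuple(spacing),
        origin=tuple(affine[:3, 3]),
        direction=direction,
    )


def _read_nrrd(path: Path, cls):
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)  # (z,y,x) -> (x,y,z)
    direction_lps = np.array(img.GetDirection()).reshape(3, 3)
    origin_lps = np.array(img.GetOrigin())
    return cls(
        mask=data > 0,
        spacing=tuple(img.GetSpacing()),
        origin=tuple(_RAS_FROM_LPS @ origin_lps),
        direction=_RAS_FROM_LPS @ direction_lps,
    )


def write_mask(lesion, path: str | Path) -> None:
    """Write a LesionModel as NRRD or NIfTI (exact round-trip of the mask)."""
    path = Path(path)
    suffix = "".join(path.suffixes).lower()
    if suffix.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        nib.save(
            nib.Nifti1Image(lesion.mask.astype(np.uint8), lesion.affine),
            str(path),
        )
        return
    if suffix.endswith(".nrrd"):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(
            lesion.mask.astype(np.uint8).transpose(2, 1, 0)
        )
        img.SetSpacing(lesion.spacing)
        img.SetOrigin(tuple(_RAS_FROM_LPS @ np.asarray(lesion.origin)))
        img.SetDirection(tuple((_RAS_FROM_LPS @ lesion.direction).ravel()))
        sitk.WriteImage(img, str(path), useCompression=False)
        return
    raise ValueError(f"unsupported mask format: {path}")


# --------------------------------------------------------------------------
# meshes


def read_mesh(path: str | Path):
    """Load a surface mesh (STL/OBJ) as a trimesh.Trimesh."""
    import trimesh

    mesh = trimesh.load(str(path), force="mesh")
    if mesh.is_empty:
        raise ValueError(f"{path}: empty mesh")
    return mesh


def write_mesh(mesh, path: str | Path) -> None:
    mesh.export(str(path))
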