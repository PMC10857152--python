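"""Synthetic head-phantom cases with the statistical structure of the study.

Each case emulates one phantom experiment: a head (smooth triangulated
ellipsoid standing in for a 3D-printed scalp), 6–7 scalp fiducial markers,
one or two intracranial lesions as binary voxel masks, and the three ordered
point sets the navigation platform would report:

* ``C`` — ground-truth marker centroids (exact, on the skin surface);
* ``V`` — perceived virtual markers: C plus isotropic Gaussian probe noise;
* ``P`` — perceived physical markers: a small rigid misregistration T_err
  applied to C, plus independent probe noise.

The misregistration is a small random rotation (uniform random axis,
Gaussian angle) about the head center, composed with a Gaussian translation.
Because the head center is deliberately offset from the image origin (as it
is in real reference scans, where lesion centroids sit ~8 cm from the RAS
origin), expressing T_err about the origin mixes the rotation into the
translation column exactly as the fitted transform does in practice.

Default noise magnitudes are calibrated to the study's scales: probe noise
sigma = 1.2 mm per coordinate puts the Maxwell-distribution mean of the FLE
magnitude at 2*sigma*sqrt(2/pi) = 1.91 mm (reported FLE 1.9 +/- 0.4 mm), and
rot_sigma = 1.5 deg with trans_sigma = 1.0 mm/axis puts the simulated TRE
near the reported 3.0 +/- 0.5 mm.  These are calibrations of an assumed
noise family, not a claim about the platform's actual error model.

Identical seeds reproduce identical cases bit-for-bit; cohort generation
derives per-case seeds from the master seed with fixed arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import trimesh

from .frames import FiducialRole, FiducialSet, Frame, SurgicalPosition, Unit
from .lesions import LesionModel
from .registration import RigidFit

__all__ = [
    "NoiseModel",
    "PhantomParams",
    "CaseRecord",
    "generate_case",
    "generate_cohort",
    "simulate_fle_magnitudes",
    "dsc_volume_simulation",
]

_PATHOLOGIES = (
    "Metastasis",
    "Meningioma",
    "Hematoma",
    "Diffused astrocytoma",
    "Cavernous malformation",
    "Diffuse large B-cell lymphoma",
    "Aneurysm",
    "High grade glioma",
)
# empirical pathology frequencies in the 19-case cohort
_PATHOLOGY_P = np.array([7, 3, 4, 1, 1, 1, 1, 1], dtype=float) / 19.0


@dataclass(frozen=True)
class NoiseModel:
    """Noise family for one synthetic case.

    ``sigma_probe`` — isotropic Gaussian per-coordinate localization noise of
    the virtual probe (mm); applied independently to V and P.
    ``rot_sigma_deg`` — SD of the misregistration rotation angle (degrees),
    about a uniformly random axis through the head center.
    ``trans_sigma`` — SD of the misregistration translation per axis (mm).
    """

    sigma_probe: float = 1.2
    rot_sigma_deg: float = 1.5
    trans_sigma: float = 1.0

    def __post_init__(self) -> None:
        if min(self.sigma_probe, self.rot_sigma_deg, self.trans_sigma) < 0:
            raise ValueError("noise sigmas must be non-negative")


@dataclass(frozen=True)
class PhantomParams:
    """Geometry and sampling parameters of a synthetic head phantom."""

    head_axes: tuple[float, float, float] = (80.0, 95.0, 85.0)  # mm semi-axes
    head_center: tuple[float, float, float] = (10.0, 25.0, 70.0)  # mm, RAS
    n_markers: int = 7
    n_lesions: int = 1
    lesion_volume_range: tuple[float, float] = (8.0, 38.0)  # cm^3
    min_marker_separation: float = 25.0  # mm
    position: SurgicalPosition = SurgicalPosition.SUPINE
    mask_spacing: float = 1.0  # mm, isotropic
    mask_margin: float = 12.0  # mm of background around each lesion

    def __post_init__(self) -> None:
        if not 6 <= self.n_markers <= 7:
            raise ValueError("marker count must be 6 or 7")
        if not 1 <= self.n_lesions <= 2:
            raise ValueError("lesion count must be 1 or 2")
        lo, hi = self.lesion_volume_range
        if not 0 < lo <= hi:
            raise ValueError("invalid lesion volume range")
        object.__setattr__(
            self, "position", SurgicalPosition.coerce(self.position)
        )


@dataclass(frozen=True)
class CaseRecord:
    """One synthetic phantom case with its generator-internal ground truth."""

    case_id: str
    sex: str
    age: float
    pathology: str
    position: SurgicalPosition
    fiducials_C: FiducialSet
    fiducials_V: FiducialSet
    fiducials_P: FiducialSet
    lesions: tuple[LesionModel, ...]
    skin: trimesh.Trimesh
    true_misregistration: RigidFit
    params: PhantomParams
    noise: NoiseModel
    seed: int
    #: V was probed before P, so FLE is an uncontaminated QC baseline.
    acquisition_order: tuple[str, ...] = ("V", "P")


def _ellipsoid_point(direction: np.ndarray, axes: np.ndarray) -> np.ndarray:
    """Scale a unit direction onto the ellipsoid surface (exact)."""
    d = direction / np.linalg.norm(direction)
    scale = 1.0 / np.sqrt(np.sum((d / axes) ** 2))
    return scale * d


def _sample_markers(
    rng: np.random.Generator, params: PhantomParams
) -> np.ndarray:
    """Markers on the anterior/superior skin with minimum pairwise spacing."""
    axes = np.asarray(params.head_axes)
    center = np.asarray(params.head_center)
    pts: list[np.ndarray] = []
    for _ in range(20000):
        if len(pts) == params.n_markers:
            break
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        # restrict to the anterior/superior aspect, where adhesive markers go
        if u[1] < 0.1 and u[2] < 0.2:
            continue
        cand = center + _ellipsoid_point(u, axes)
        if all(
            np.linalg.norm(cand - q) >= params.min_marker_separation for q in pts
        ):
            pts.append(cand)
    if len(pts) < params.n_markers:
        raise RuntimeError(
            "could not place markers with the requested separation"
        )
    return np.array(pts)


def _sample_misregistration(
    rng: np.random.Generator, noise: NoiseModel, head_center: np.ndarray
) -> RigidFit:
    """Small rigid error: rotation about the head center + translation.

    Returned expressed about the image origin (rotation R, translation
    t + (I - R) @ head_center), the frame in which T* is fitted.
    """
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.normal(0.0, noise.rot_sigma_deg))
    k = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    rotation = (
        np.eye(3) + np.sin(angle) * k + (1.0 - np.cos(angle)) * (k @ k)
    )
    translation = rng.normal(0.0, noise.trans_sigma, size=3)
    t_origin = translation + head_center - rotation @ head_center
    return RigidFit(rotation, t_origin, np.zeros((1, 3)), (1,))


def _lesion_mask(
    rng: np.random.Generator,
    params: PhantomParams,
    volume_cm3: float,
) -> LesionModel:
    """An ellipsoidal binary mask of the requested volume on a 1-mm grid."""
    axes_head = np.asarray(params.head_axes)
    center_head = np.asarray(params.head_center)
    # mildly anisotropic semi-axes with the requested volume
    anis = rng.uniform(0.75, 1.3, size=3)
    anis /= np.prod(anis) ** (1.0 / 3.0)
    r_eq = (3.0 * volume_cm3 * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    semi = r_eq * anis
    if np.any(semi >= 0.8 * axes_head):
        raise ValueError(
            f"lesion of {volume_cm3:.1f} cm^3 does not fit inside the head"
        )
    # centroid strictly inside the skin, with room for the lesion body
    room = axes_head - semi.max() - 5.0
    if np.any(room <= 0):
        raise ValueError("lesion too large for the head interior")
    for _ in range(1000):
        frac = rng.uniform(-0.6, 0.6, size=3)
        centroid = center_head + frac * room
        if np.sum(((centroid - center_head) / (axes_head - semi.max())) ** 2) < 1.0:
            break
    else:  # pragma: no cover - geometrically unreachable with defaults
        raise ValueError("could not place lesion inside the head")

    sp = params.mask_spacing
    half = semi + params.mask_margin
    shape = tuple(int(np.ceil(2 * h / sp)) + 1 for h in half)
    origin = centroid - (np.array(shape) - 1) / 2.0 * sp
    idx = np.indices(shape).reshape(3, -1).T
    world = origin + idx * sp
    inside = np.sum(((world - centroid) / semi) ** 2, axis=1) <= 1.0
    mask = inside.reshape(shape)
    return LesionModel(mask, (sp, sp, sp), tuple(origin))


def _skin_mesh(params: PhantomParams, subdivisions: int = 3) -> trimesh.Trimesh:
    mesh = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    mesh.apply_scale(list(params.head_axes))
    mesh.apply_translation(list(params.head_center))
    return mesh


def _fiducial_set(points: np.ndarray, role: FiducialRole) -> FiducialSet:
    return FiducialSet(
        points=points,
        labels=tuple(range(1, len(points) + 1)),
        frame=Frame.RICS,
        units=Unit.MM,
        role=role,
    )


def generate_case(
    params: PhantomParams | None = None,
    noise: NoiseModel | None = None,
    seed: int = 0,
    *,
    case_id: str = "case_01",
    skin: trimesh.Trimesh | None = None,
) -> CaseRecord:
    """Generate one deterministic synthetic phantom case.

    ``skin`` accepts any user-supplied watertight mesh in place of the
    default ellipsoid (markers and lesions are still placed on/in the
    analytic ellipsoid, so a custom mesh should enclose it).
    """
    params = params or PhantomParams()
    noise = noise or NoiseModel()
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    c_points = _sample_markers(rng, params)
    t_err = _sample_misregistration(
        rng, noise, np.asarray(params.head_center)
    )
    v_points = c_points + rng.normal(0.0, noise.sigma_probe, size=c_points.shape)
    p_points = t_err.apply(c_points) + rng.normal(
        0.0, noise.sigma_probe, size=c_points.shape
    )

    volumes = sorted(
        rng.uniform(*params.lesion_volume_range, size=params.n_lesions),
        reverse=True,
    )
    lesions = tuple(_lesion_mask(rng, params, v) for v in volumes)

    sex = "M" if rng.random() < 12.0 / 19.0 else "F"
    age = float(np.clip(rng.normal(54.4, 18.5), 5.0, 90.0))
    pathology = str(rng.choice(_PATHOLOGIES, p=_PATHOLOGY_P))

    return CaseRecord(
        case_id=case_id,
        sex=sex,
        age=age,
        pathology=pathology,
        position=params.position,
        fiducials_C=_fiducial_set(c_points, FiducialRole.C_GROUNDTRUTH),
        fiducials_V=_fiducial_set(v_points, FiducialRole.V_VIRTUAL),
        fiducials_P=_fiducial_set(p_points, FiducialRole.P_PHYSICAL),
        lesions=lesions,
        skin=skin if skin is not None else _skin_mesh(params),
        true_misregistration=t_err,
        params=params,
        noise=noise,
        seed=seed,
    )


def _case_seed(master_seed: int, index: int) -> int:
    """Fixed arithmetic deriving per-case seeds from the master seed."""
    return int((master_seed * 1_000_003 + 7919 * (index + 1)) % (2**31 - 1))


def generate_cohort(
    n_cases: int = 19,
    position_mix: tuple[int, int, int] = (8, 6, 5),
    noise: NoiseModel | None = None,
    seed: int = 0,
    params: PhantomParams | None = None,
    two_lesion_cases: tuple[int, ...] = (8, 14),
) -> list[CaseRecord]:
    """Generate a deterministic cohort of synthetic phantom cases.

    ``position_mix`` gives (supine, prone, lateral) counts and must sum to
    ``n_cases``; lateral cases alternate left/right starting left (so the
    default 19-case cohort has 8 supine, 6 prone, 3 left- and 2
    right-lateral).  Cases whose 1-based index is in ``two_lesion_cases``
    carry two lesions, so the default cohort holds 21 lesions in 19 cases.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    if len(position_mix) != 3 or min(position_mix) < 0:
        raise ValueError("position_mix must be three non-negative counts")
    if sum(position_mix) != n_cases:
        raise ValueError(
            f"position_mix {position_mix} does not sum to n_cases={n_cases}"
        )
    params = params or PhantomParams()
    noise = noise or NoiseModel()

    positions: list[SurgicalPosition] = (
        [SurgicalPosition.SUPINE] * position_mix[0]
        + [SurgicalPosition.PRONE] * position_mix[1]
        + [
            SurgicalPosition.LEFT_LATERAL
            if i % 2 == 0
            else SurgicalPosition.RIGHT_LATERAL
            for i in range(position_mix[2])
        ]
    )

    cases = []
    for i, position in enumerate(positions):
        idx1 = i + 1
        n_markers = 7 if idx1 % 3 != 0 else 6  # mix of 6- and 7-marker cases
        case_params = replace(
            params,
            position=position,
            n_markers=n_markers,
            n_lesions=2 if idx1 in two_lesion_cases else 1,
        )
        cases.append(
            generate_case(
                case_params,
                noise,
                seed=_case_seed(seed, i),
                case_id=f"case_{idx1:02d}",
            )
        )
    return cases


def simulate_fle_magnitudes(
    n_draws: int = 10_000,
    sigma_probe: float = 1.2,
    n_markers: int = 7,
    seed: int = 0,
) -> np.ndarray:
    """Per-marker FLE magnitudes from repeated virtual-probe measurements.

    Places one marker configuration, then repeatedly probes it with the
    isotropic Gaussian probe-noise model and computes FLE through the metric
    path.  Under this model the magnitudes follow a Maxwell distribution
    with mean 2 * sigma * sqrt(2/pi) — the closed form used to calibrate
    ``sigma_probe`` against the reported FLE scale.
    """
    from .landmarks import compute_fle

    params = PhantomParams(n_markers=n_markers)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    c_points = _sample_markers(rng, params)
    c = _fiducial_set(c_points, FiducialRole.C_GROUNDTRUTH)
    mags = []
    while len(mags) * n_markers < n_draws:
        v = _fiducial_set(
            c_points + rng.normal(0.0, sigma_probe, size=c_points.shape),
            FiducialRole.V_VIRTUAL,
        )
        mags.append(compute_fle(v, c).magnitudes)
    return np.concatenate(mags)[:n_draws]


def dsc_volume_simulation(
    n_lesions: int = 21,
    translation_mm: float = 3.0,
    volume_range: tuple[float, float] = (2.0, 60.0),
    seed: int = 0,
) -> "pd.DataFrame":
    """Similar-shaped lesions of graded volume under one fixed translation.

    Applies a rigid misregistration of fixed translation magnitude (random
    direction per lesion) to a family of scaled ellipsoidal lesions and
    computes DSC for each — the construction behind the volume–DSC
    association: at fixed boundary displacement, larger lesions lose a
    smaller fraction of their volume overlap.
    """
    import pandas as pd

    from .lesions import dsc as _dsc
    from .lesions import transform_lesion

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    params = PhantomParams()
    volumes = np.linspace(*volume_range, n_lesions)
    rows = []
    for vol in volumes:
        # one fixed shape, scaled: anisotropy fixed across the family
        anis = np.array([1.0, 1.15, 0.9])
        anis /= np.prod(anis) ** (1.0 / 3.0)
        r_eq = (3.0 * vol * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
        semi = r_eq * anis
        sp = params.mask_spacing
        half = semi + params.mask_margin
        shape = tuple(int(np.ceil(2 * h / sp)) + 1 for h in half)
        centroid = np.zeros(3)
        origin = centroid - (np.array(shape) - 1) / 2.0 * sp
        idx = np.indices(shape).reshape(3, -1).T
        world = origin + idx * sp
        mask = (np.sum(((world - centroid) / semi) ** 2, axis=1) <= 1.0).reshape(
            shape
        )
        gt = LesionModel(mask, (sp, sp, sp), tuple(origin))
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        fit = RigidFit(
            np.eye(3), translation_mm * direction, np.zeros((1, 3)), (1,)
        )
        tm = transform_lesion(gt, fit)
        rows.append({"volume_cm3": gt.volume_cm3, "dsc": _dsc(gt, tm)})
    return pd.DataFrame(rows)
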