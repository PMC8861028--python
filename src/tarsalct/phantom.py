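"""Synthetic tarsal phantoms with exact ground truth.

The phantom emulates an already-reconstructed in vivo µCT of the mouse
tarsal region at 18 µm isotropic voxels: a stack of five ellipsoidal bone
bodies (a navicular analogue, three cuneiform analogues side by side, and
a cuboid analogue) inside an ellipsoidal soft-tissue envelope, on an air
background.  Intensities follow the scanner's HU-like arbitrary-unit (AU)
scale: air ≪ soft tissue < 1500 AU < gap < bone > 3500 AU, so a
noiseless phantom is exactly separable by the fixed thresholds used for
segmentation.

Default intensities are air -900 AU, soft tissue 300 AU and bone 6700 AU.
These place each segmentation boundary at the midpoint of the intensity
step it cuts: 3500 AU is the midpoint of soft (300) to bone (6700), so
under trilinear resampling (reorientation) the implied bone surface stays
put instead of creeping ~0.2 voxel inward; likewise -300 AU is the
midpoint of air (-900) to soft (300), so the 0.1 mm Gaussian used for the
soft channel does not systematically shift the air boundary.  Off-midpoint
choices bias the recovered volumes by several percent for bodies of this
size.

Rasterization is by voxel-centre membership (a voxel belongs to an
ellipsoid iff its centre satisfies the ellipsoid inequality after undoing
the scene rotation), which makes a brute-force point-in-solid count an
exact independent oracle.  Ground-truth masks are the noiseless,
pre-threshold rasterizations; recorded volumes are exactly
``mask voxel count x voxel volume``.

Disease effects are modelled as surface erosion pits (spheres carved from
bone down to soft-tissue intensity, calibrated to remove a requested
fraction of ground-truth bone volume) and soft-tissue swelling (isotropic
scaling of the envelope).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation as _R

from .errors import GeometryError, RangeError
from .image_io import VoxelVolume

__all__ = [
    "Ellipsoid",
    "RigidRotation",
    "ErosionPits",
    "PhantomSpec",
    "GroundTruth",
    "make_phantom",
    "default_tarsal_spec",
    "small_tarsal_spec",
    "tarsal_spec",
    "rotated_spec",
    "apply_disease",
    "rotation_matrix",
]

#: The fixed thresholds the AU regime must respect (strict bone cut at 3500).
BONE_MIN_AU = 3500.0
SOFT_LOW_AU = -300.0
SOFT_HIGH_AU = 1500.0


def rotation_matrix(axis, angle_deg: float) -> np.ndarray:
    """Right-handed rotation matrix about ``axis`` by ``angle_deg`` degrees."""
    axis = np.asarray(axis, dtype=float)
    nrm = np.linalg.norm(axis)
    if nrm == 0:
        raise RangeError("rotation axis must be non-zero")
    return _R.from_rotvec(axis / nrm * math.radians(angle_deg)).as_matrix()


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid: centre (mm), semi-axes (mm), intensity (AU)."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    intensity: float

    def __post_init__(self):
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))
        object.__setattr__(self, "semi_axes", tuple(float(s) for s in self.semi_axes))
        if any(s <= 0 for s in self.semi_axes):
            raise RangeError("ellipsoid semi-axes must be positive")

    @property
    def volume_mm3(self) -> float:
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * math.pi * a * b * c

    def translated(self, shift) -> "Ellipsoid":
        c = tuple(ci + si for ci, si in zip(self.center, shift))
        return dataclasses.replace(self, center=c)


@dataclass(frozen=True)
class RigidRotation:
    """Rigid rotation of the whole scene: axis + angle about ``center`` (mm)."""

    axis: tuple[float, float, float]
    angle_deg: float
    center: tuple[float, float, float]

    @property
    def matrix(self) -> np.ndarray:
        return rotation_matrix(self.axis, self.angle_deg)

    def translated(self, shift) -> "RigidRotation":
        c = tuple(ci + si for ci, si in zip(self.center, shift))
        return dataclasses.replace(self, center=c)


@dataclass(frozen=True)
class ErosionPits:
    """Explicit erosion-pit spheres (centres in the unrotated scene frame)."""

    radius_mm: float
    centers: tuple[tuple[float, float, float], ...]

    def translated(self, shift) -> "ErosionPits":
        cs = tuple(tuple(ci + si for ci, si in zip(c, shift)) for c in self.centers)
        return dataclasses.replace(self, centers=cs)


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of a synthetic tarsal scene.

    Invariants (checked by :meth:`validate`): bone intensities > 3500 AU,
    soft intensity inside (-300, 1500) AU, air < -300 AU, noise_sd >= 0,
    and every ellipsoid inside the grid after the scene rotation.
    """

    grid_shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (0.018, 0.018, 0.018)
    bones: tuple[Ellipsoid, ...] = ()
    soft_envelope: Ellipsoid | None = None
    air_intensity: float = -1000.0
    noise_sd: float = 50.0
    rotation: RigidRotation | None = None
    erosion: ErosionPits | None = None

    def validate(self) -> None:
        if len(self.grid_shape) != 3 or any(int(n) < 1 for n in self.grid_shape):
            raise RangeError("grid_shape must be three positive integers")
        if any(s <= 0 for s in self.spacing):
            raise RangeError("spacing must be positive")
        if self.noise_sd < 0:
            raise RangeError("noise_sd must be >= 0")
        for b in self.bones:
            if b.intensity <= BONE_MIN_AU:
                raise RangeError(
                    f"bone intensity {b.intensity} AU must exceed {BONE_MIN_AU} AU"
                )
        if self.soft_envelope is not None:
            s = self.soft_envelope.intensity
            if not (SOFT_LOW_AU < s < SOFT_HIGH_AU):
                raise RangeError(
                    f"soft intensity {s} AU must lie inside ({SOFT_LOW_AU}, {SOFT_HIGH_AU}) AU"
                )
        if self.air_intensity >= SOFT_LOW_AU:
            raise RangeError(f"air intensity {self.air_intensity} AU must be < {SOFT_LOW_AU} AU")
        R, r0 = self._frame()
        extent = np.asarray(self.grid_shape) * np.asarray(self.spacing)
        for ell in self._all_ellipsoids():
            lo, hi = _rotated_bbox(ell, R, r0)
            if np.any(lo < -1e-9) or np.any(hi > extent + 1e-9):
                raise GeometryError(
                    f"ellipsoid at {ell.center} escapes the grid after rotation "
                    f"(bbox {lo}..{hi}, grid extent {extent})"
                )

    def _all_ellipsoids(self):
        out = list(self.bones)
        if self.soft_envelope is not None:
            out.append(self.soft_envelope)
        return out

    def _frame(self):
        """(rotation matrix, rotation centre) of the scene, identity if none."""
        if self.rotation is None:
            return np.eye(3), np.zeros(3)
        return self.rotation.matrix, np.asarray(self.rotation.center, dtype=float)

    @property
    def scene_center(self) -> tuple[float, float, float]:
        if self.soft_envelope is not None:
            return self.soft_envelope.center
        ext = np.asarray(self.grid_shape) * np.asarray(self.spacing) / 2.0
        return tuple(ext)


@dataclass(frozen=True)
class GroundTruth:
    """Exact masks and volumes of the noiseless, pre-threshold scene."""

    bone_mask: np.ndarray
    soft_mask: np.ndarray
    bone_volume_mm3: float
    soft_volume_mm3: float
    applied_rotation: RigidRotation | None
    landmark_slice: int | None  # first slice (scanning +z) containing bone


def _rotated_bbox(ell: Ellipsoid, R: np.ndarray, r0: np.ndarray):
    """Axis-aligned bounds (mm) of an ellipsoid after rotating about r0."""
    c = np.asarray(ell.center, dtype=float)
    c_rot = R @ (c - r0) + r0
    # extent along axis k of R @ diag(s) @ unit-ball = ||row_k(R diag(s))||
    half = np.sqrt(((R * np.asarray(ell.semi_axes)[None, :]) ** 2).sum(axis=1))
    return c_rot - half, c_rot + half


def _bbox_to_slices(lo, hi, shape, spacing):
    idx_lo = np.maximum(np.floor(lo / np.asarray(spacing) - 0.5).astype(int), 0)
    idx_hi = np.minimum(
        np.ceil(hi / np.asarray(spacing) - 0.5).astype(int) + 1, np.asarray(shape)
    )
    if np.any(idx_hi <= idx_lo):
        return None
    return tuple(slice(int(a), int(b)) for a, b in zip(idx_lo, idx_hi))


def _voxel_centers(slices, spacing):
    axes = []
    for sl, h in zip(slices, spacing):
        axes.append((np.arange(sl.start, sl.stop, dtype=np.float64) + 0.5) * h)
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def _rasterize_ellipsoid(ell: Ellipsoid, spec: PhantomSpec, R, r0):
    """Sub-box slices + boolean sub-mask of the rotated ellipsoid."""
    lo, hi = _rotated_bbox(ell, R, r0)
    slices = _bbox_to_slices(lo, hi, spec.grid_shape, spec.spacing)
    if slices is None:
        return None, None
    xs, ys, zs = _voxel_centers(slices, spec.spacing)
    # undo the scene rotation, then test the axis-aligned inequality
    px = xs - r0[0]
    py = ys - r0[1]
    pz = zs - r0[2]
    Rt = R.T
    qx = Rt[0, 0] * px + Rt[0, 1] * py + Rt[0, 2] * pz + r0[0] - ell.center[0]
    qy = Rt[1, 0] * px + Rt[1, 1] * py + Rt[1, 2] * pz + r0[1] - ell.center[1]
    qz = Rt[2, 0] * px + Rt[2, 1] * py + Rt[2, 2] * pz + r0[2] - ell.center[2]
    a, b, c = ell.semi_axes
    inside = (qx / a) ** 2 + (qy / b) ** 2 + (qz / c) ** 2 <= 1.0
    return slices, inside


def _carve_sphere(mask: np.ndarray, center, radius, spacing, R=None, r0=None):
    """Clear mask voxels whose centres lie inside the (rotated) sphere.

    Returns the number of voxels removed.  Spheres map to spheres under
    rotation, so only the centre needs transforming.
    """
    c = np.asarray(center, dtype=float)
    if R is not None:
        c = R @ (c - r0) + r0
    lo, hi = c - radius, c + radius
    slices = _bbox_to_slices(lo, hi, mask.shape, spacing)
    if slices is None:
        return 0
    xs, ys, zs = _voxel_centers(slices, spacing)
    inside = (xs - c[0]) ** 2 + (ys - c[1]) ** 2 + (zs - c[2]) ** 2 <= radius**2
    sub = mask[slices]
    removed = int(np.count_nonzero(sub & inside))
    sub[inside] = False
    return removed


def make_phantom(spec: PhantomSpec, seed: int = 0) -> tuple[VoxelVolume, GroundTruth]:
    """Rasterize a phantom and its exact ground truth.

    Compositing is by overwrite precedence bone > soft > air; erosion pits
    carve bone voxels down to soft-tissue intensity; seeded Gaussian noise
    is added last.  Ground-truth masks are taken before noise.
    """
    spec.validate()
    R, r0 = spec._frame()
    shape = tuple(int(n) for n in spec.grid_shape)
    vol = np.full(shape, spec.air_intensity, dtype=np.float32)

    soft_mask = np.zeros(shape, dtype=bool)
    if spec.soft_envelope is not None:
        slices, inside = _rasterize_ellipsoid(spec.soft_envelope, spec, R, r0)
        if slices is not None:
            soft_mask[slices] |= inside
        vol[soft_mask] = spec.soft_envelope.intensity

    bone_mask = np.zeros(shape, dtype=bool)
    for bone in spec.bones:
        slices, inside = _rasterize_ellipsoid(bone, spec, R, r0)
        if slices is None:
            continue
        bone_mask[slices] |= inside
        sub = vol[slices]
        sub[inside] = bone.intensity
        vol[slices] = sub

    if spec.erosion is not None and spec.erosion.centers:
        soft_val = (
            spec.soft_envelope.intensity if spec.soft_envelope is not None else 300.0
        )
        for c in spec.erosion.centers:
            _carve_sphere(
                bone_mask, c, spec.erosion.radius_mm, spec.spacing,
                R if spec.rotation is not None else None, r0,
            )
        # carved bone voxels revert to soft tissue
        carved = (vol > BONE_MIN_AU) & ~bone_mask
        vol[carved] = soft_val

    soft_mask &= ~bone_mask

    from .volumetry import mask_volume

    bone_slices = np.flatnonzero(bone_mask.any(axis=(0, 1)))
    truth = GroundTruth(
        bone_mask=bone_mask,
        soft_mask=soft_mask,
        bone_volume_mm3=mask_volume(bone_mask, spec.spacing),
        soft_volume_mm3=mask_volume(soft_mask, spec.spacing),
        applied_rotation=spec.rotation,
        landmark_slice=int(bone_slices[0]) if bone_slices.size else None,
    )

    if spec.noise_sd > 0:
        rng = np.random.default_rng(seed)
        vol = vol + rng.standard_normal(shape, dtype=np.float32) * np.float32(spec.noise_sd)

    return VoxelVolume(vol, spec.spacing), truth


# ---------------------------------------------------------------------------
# the default tarsal scene
# ---------------------------------------------------------------------------

_REF_SPAN_MM = 1.798  # reference axial bone span of the full-size scene
_EDGE_EPS_MM = 0.008  # how far the extreme bone surfaces poke past the
# extreme covered slice centres; < spacing/2, so the bone stack occupies
# exactly `n_slices` slices by construction


def tarsal_spec(
    n_slices: int = 100,
    spacing_mm: float = 0.018,
    envelope_pad_z_mm: float = 1.3,
    margin_mm: float = 0.15,
    noise_sd: float = 50.0,
) -> PhantomSpec:
    """Build a tarsal-like scene whose bones span exactly ``n_slices`` slices.

    Five bone bodies sit on the grid's central axis (the three cuneiform
    analogues are offset laterally but balanced, keeping the principal
    axis of the bone cloud exactly +z), inside a soft envelope that extends
    ``envelope_pad_z_mm`` beyond the bone stack at both ends.
    """
    h = float(spacing_mm)
    eps = _EDGE_EPS_MM * h / 0.018
    L = (n_slices - 1) * h + 2 * eps
    f = L / _REF_SPAN_MM

    # z origin: anchor the proximal bone surface just below a slice centre
    s0 = int(round((margin_mm + envelope_pad_z_mm + eps) / h - 0.5))
    z_lo = (s0 + 0.5) * h - eps
    z_mid = z_lo + L / 2.0

    r_t = 1.30 * f  # transverse envelope semi-axis
    nx = int(math.ceil(2.0 * (r_t + margin_mm) / h))
    cx = nx * h / 2.0
    nz = int(math.ceil((z_mid + L / 2.0 + envelope_pad_z_mm + margin_mm) / h))

    bone_au = 6700.0
    c_nav, c_tri, c_cub = 0.30 * f, 0.25 * f, 0.28 * f
    bones = (
        # navicular analogue: the single largest body, proximal end
        Ellipsoid((cx, cx, z_lo + c_nav), (0.26 * f, 0.24 * f, c_nav), bone_au),
        # three cuneiform analogues, side by side, laterally balanced
        Ellipsoid((cx - 0.30 * f, cx, z_lo + 0.40 * L), (0.16 * f, 0.16 * f, c_tri), bone_au),
        Ellipsoid((cx, cx, z_lo + 0.40 * L), (0.16 * f, 0.16 * f, c_tri), bone_au),
        Ellipsoid((cx + 0.30 * f, cx, z_lo + 0.40 * L), (0.16 * f, 0.16 * f, c_tri), bone_au),
        # cuboid analogue, distal end
        Ellipsoid((cx, cx, z_lo + L - c_cub), (0.22 * f, 0.21 * f, c_cub), bone_au),
    )
    envelope = Ellipsoid((cx, cx, z_mid), (r_t, r_t, L / 2.0 + envelope_pad_z_mm), 300.0)
    return PhantomSpec(
        grid_shape=(nx, nx, nz),
        spacing=(h, h, h),
        bones=bones,
        soft_envelope=envelope,
        air_intensity=-900.0,
        noise_sd=noise_sd,
    )


def default_tarsal_spec() -> PhantomSpec:
    """The study-scale scene: 18 µm voxels, bones spanning 100 slices (1.8 mm)."""
    return tarsal_spec(n_slices=100)


def small_tarsal_spec() -> PhantomSpec:
    """A reduced scene (60-slice bone span) for demos and fast checks."""
    return tarsal_spec(n_slices=60, envelope_pad_z_mm=0.30)


def rotated_spec(
    spec: PhantomSpec, axis, angle_deg: float, margin_mm: float = 0.12
) -> PhantomSpec:
    """Apply a rigid scene rotation, enlarging the grid so nothing escapes.

    The rotation is about the scene centre (soft-envelope centre); the grid
    is re-sized to the rotated scene's bounding box plus ``margin_mm`` and
    all descriptors are translated accordingly.
    """
    r0 = np.asarray(spec.scene_center, dtype=float)
    rot = RigidRotation(tuple(float(a) for a in np.asarray(axis, float)), float(angle_deg), tuple(r0))
    R = rot.matrix
    los, his = [], []
    for ell in spec._all_ellipsoids():
        lo, hi = _rotated_bbox(ell, R, r0)
        los.append(lo)
        his.append(hi)
    lo = np.min(los, axis=0) - margin_mm
    hi = np.max(his, axis=0) + margin_mm
    shift = -lo
    shape = tuple(int(math.ceil(e / h)) for e, h in zip(hi - lo, spec.spacing))
    bones = tuple(b.translated(shift) for b in spec.bones)
    env = spec.soft_envelope.translated(shift) if spec.soft_envelope else None
    ero = spec.erosion.translated(shift) if spec.erosion else None
    return dataclasses.replace(
        spec,
        grid_shape=shape,
        bones=bones,
        soft_envelope=env,
        erosion=ero,
        rotation=rot.translated(shift),
    )


def _pad_to_fit(spec: PhantomSpec, margin_mm: float = 0.12) -> PhantomSpec:
    """Grow the grid (translating the scene) until every ellipsoid fits."""
    R, r0 = spec._frame()
    los, his = [], []
    for ell in spec._all_ellipsoids():
        lo, hi = _rotated_bbox(ell, R, r0)
        los.append(lo)
        his.append(hi)
    lo = np.min(los, axis=0)
    hi = np.max(his, axis=0)
    extent = np.asarray(spec.grid_shape) * np.asarray(spec.spacing)
    if np.all(lo >= 0) and np.all(hi <= extent):
        return spec
    new_lo = np.minimum(lo - margin_mm, 0.0)
    new_hi = np.maximum(hi + margin_mm, extent)
    shift = -new_lo
    shape = tuple(int(math.ceil(e / h)) for e, h in zip(new_hi - new_lo, spec.spacing))
    return dataclasses.replace(
        spec,
        grid_shape=shape,
        bones=tuple(b.translated(shift) for b in spec.bones),
        soft_envelope=spec.soft_envelope.translated(shift) if spec.soft_envelope else None,
        erosion=spec.erosion.translated(shift) if spec.erosion else None,
        rotation=spec.rotation.translated(shift) if spec.rotation else None,
    )


def apply_disease(
    spec: PhantomSpec,
    erosion_fraction: float = 0.0,
    swelling_factor: float = 1.0,
    seed: int = 0,
    pit_radius_mm: float = 0.05,
) -> PhantomSpec:
    """Add disease effects to a scene description.

    Erosion pits (spheres of ``pit_radius_mm`` centred on seeded random
    points of the bone surfaces) are added one by one, carving the
    rasterized ground-truth bone mask, until the ground-truth bone volume
    drops by ``erosion_fraction`` of the original (stopping within 0.5%,
    well inside the contracted +/-2% absolute band).  Soft-tissue swelling
    scales the envelope semi-axes isotropically so its volume grows by
    ``swelling_factor``; the grid is enlarged if the swollen envelope
    would escape it.

    The calibrated pit centres are recorded on the returned spec (in the
    unrotated scene frame), so :func:`make_phantom` reproduces the carved
    scene deterministically; with the same seed, a larger fraction extends
    the same pit sequence, making erosion monotone.
    """
    if not 0.0 <= erosion_fraction < 1.0:
        raise RangeError("erosion_fraction must be in [0, 1)")
    if swelling_factor < 1.0:
        raise RangeError("swelling_factor must be >= 1")

    out = spec
    if swelling_factor > 1.0:
        env = spec.soft_envelope
        if env is None:
            raise RangeError("cannot swell a scene with no soft envelope")
        s = swelling_factor ** (1.0 / 3.0)
        out = dataclasses.replace(
            out,
            soft_envelope=dataclasses.replace(
                env, semi_axes=tuple(a * s for a in env.semi_axes)
            ),
        )
        out = _pad_to_fit(out)

    if erosion_fraction > 0.0:
        if not out.bones:
            raise RangeError("cannot erode a scene with no bones")
        # calibrate in the unrotated frame; pits are stored unrotated too
        base = dataclasses.replace(out, rotation=None)
        I3, z3 = np.eye(3), np.zeros(3)
        mask = np.zeros(tuple(int(n) for n in base.grid_shape), dtype=bool)
        for bone in base.bones:
            slices, inside = _rasterize_ellipsoid(bone, base, I3, z3)
            if slices is not None:
                mask[slices] |= inside
        if base.erosion is not None:
            for c in base.erosion.centers:
                _carve_sphere(mask, c, base.erosion.radius_mm, base.spacing)
        v0 = int(np.count_nonzero(mask))
        if v0 == 0:
            raise RangeError("bone rasterizes to zero voxels; nothing to erode")
        target = erosion_fraction * v0
        rng = np.random.default_rng(seed)
        weights = np.array([b.volume_mm3 for b in base.bones])
        weights /= weights.sum()
        removed = 0
        centers: list[tuple[float, float, float]] = []
        stagnant = 0
        while removed < target - 0.005 * v0:
            k = rng.choice(len(base.bones), p=weights)
            bone = base.bones[k]
            u = rng.standard_normal(3)
            u /= np.linalg.norm(u)
            point = tuple(
                c + a * ui for c, a, ui in zip(bone.center, bone.semi_axes, u)
            )
            got = _carve_sphere(mask, point, pit_radius_mm, base.spacing)
            centers.append(point)
            removed += got
            stagnant = stagnant + 1 if got == 0 else 0
            if stagnant > 5000 or len(centers) > 200000:
                raise GeometryError(
                    "erosion calibration stalled before reaching the target "
                    f"fraction {erosion_fraction} (removed {removed}/{v0} voxels)"
                )
        prev = out.erosion.centers if out.erosion is not None else ()
        out = dataclasses.replace(
            out, erosion=ErosionPits(pit_radius_mm, tuple(prev) + tuple(centers))
        )
    return out
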