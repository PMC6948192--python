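"""Low-resolution volume rendering, projection, and 2D class matching.

Bead models are rendered as sums of isotropic Gaussian blobs whose width is
set by a target resolution (FWHM of the rendered blob equals half the
nominal resolution).  Because the projection of a 3-D Gaussian is a 2-D
Gaussian of the same width, projections of a rendered volume can be
computed either by rotating + line-integrating the voxel grid (the generic
path, used for externally supplied volumes) or analytically by rotating the
bead coordinates and splatting 2-D Gaussians (the fast path used for
projection matching) — the two agree to interpolation error.

Matching scores are Pearson correlations after mean subtraction, maximized
over a spherical orientation grid, exhaustive in-plane rotation at the same
angular step, and integer-pixel translations within a small search radius.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .conformers import BeadModel, ModelPool

__all__ = [
    "VolumeGrid",
    "ClassImage",
    "MatchResult",
    "render_volume",
    "project",
    "project_model",
    "match_classes",
    "euler_matrix",
]

DEFAULT_VOXEL = 6.5  # Angstrom, the calibrated pixel size of the micrographs
DEFAULT_RESOLUTION = 40.0  # Angstrom


@dataclass
class VolumeGrid:
    """Cubic-voxel 3-D density grid; origin at the box corner, so the
    physical position of voxel (i, j, k) is origin + voxel * (i, j, k)
    in (z, y, x) index order."""

    voxel: float
    data: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3-D")
        if self.voxel <= 0:
            raise ValueError("voxel size must be positive")
        if np.any(self.data < -1e-9):
            raise ValueError("rendered density must be non-negative")


@dataclass
class ClassImage:
    """A 2-D class average (or projection) with its pixel size."""

    pixel: float
    data: np.ndarray
    particle_count: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("class image must be 2-D")
        if self.pixel <= 0:
            raise ValueError("pixel size must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("class image must be finite")


@dataclass
class MatchResult:
    """Score matrix (classes x models) with best orientations/assignments."""

    scores: np.ndarray
    best_orientation: np.ndarray  # (classes, models, 3) Euler angles, deg
    best_model: np.ndarray  # per class argmax over models

    def best_score(self, class_i: int) -> float:
        return float(self.scores[class_i].max())


def _sigma_from_resolution(resolution: float) -> float:
    # FWHM of the rendered blob = resolution / 2
    return resolution / (2.0 * np.sqrt(2.0 * np.log(2.0))) * 0.5


def euler_matrix(phi: float, theta: float, psi: float) -> np.ndarray:
    """ZYZ Euler rotation matrix, angles in degrees."""
    a, b, c = np.deg2rad([phi, theta, psi])

    def rz(t):
        return np.array([[np.cos(t), -np.sin(t), 0],
                         [np.sin(t), np.cos(t), 0],
                         [0, 0, 1.0]])

    def ry(t):
        return np.array([[np.cos(t), 0, np.sin(t)],
                         [0, 1.0, 0],
                         [-np.sin(t), 0, np.cos(t)]])

    return rz(c) @ ry(b) @ rz(a)


def render_volume(
    m: BeadModel,
    voxel: float = DEFAULT_VOXEL,
    resolution: float = DEFAULT_RESOLUTION,
    box: int | None = None,
) -> VolumeGrid:
    """Render a bead model as a Gaussian-blob density on a cubic grid.

    Each bead contributes a unit-integral Gaussian, so the integrated
    density is proportional to the bead count.  The box is sized to hold
    the model plus 3 blob widths of padding unless ``box`` is given.
    """
    if resolution < 2.0 * voxel:
        raise ValueError("resolution must be at least twice the voxel size")
    sig = _sigma_from_resolution(resolution)
    coords = m.coords - m.coords.mean(axis=0)
    extent = np.abs(coords).max() if len(coords) else 0.0
    need = 2.0 * (extent + 3.0 * sig)
    if box is None:
        box = int(np.ceil(need / voxel)) + 1
    elif box * voxel < need:
        raise ValueError(
            f"model needs a box of {need / voxel:.0f} voxels, got {box}")
    half = (box - 1) / 2.0
    axis = (np.arange(box) - half) * voxel
    vol = np.zeros((box, box, box))
    norm = 1.0 / ((2.0 * np.pi) ** 1.5 * sig**3) * voxel**3
    cut = 4.0 * sig
    for x, y, z in coords:
        iz = np.searchsorted(axis, [z - cut, z + cut])
        iy = np.searchsorted(axis, [y - cut, y + cut])
        ix = np.searchsorted(axis, [x - cut, x + cut])
        az = axis[iz[0]:iz[1]] - z
        ay = axis[iy[0]:iy[1]] - y
        ax_ = axis[ix[0]:ix[1]] - x
        g = np.exp(-(az[:, None, None] ** 2 + ay[None, :, None] ** 2
                     + ax_[None, None, :] ** 2) / (2.0 * sig**2))
        vol[iz[0]:iz[1], iy[0]:iy[1], ix[0]:ix[1]] += norm * g
    return VolumeGrid(voxel=voxel, data=vol,
                      origin=np.array([axis[0]] * 3))


def project(v: VolumeGrid, phi: float = 0.0, theta: float = 0.0,
            psi: float = 0.0) -> ClassImage:
    """Line-integral projection of a volume after ZYZ Euler rotation.

    The volume is rotated about its center with linear interpolation and
    summed along the first (z) axis; projection sums are conserved to
    interpolation error as long as the density stays inside the box.
    """
    R = euler_matrix(phi, theta, psi)
    center = (np.array(v.data.shape) - 1) / 2.0
    # index order is (z, y, x): conjugate the coordinate rotation
    P = R[::-1, ::-1].T
    rotated = ndimage.affine_transform(
        v.data, P, offset=center - P @ center, order=1, mode="constant")
    img = rotated.sum(axis=0) * v.voxel
    return ClassImage(pixel=v.voxel, data=img)


def project_model(
    m: BeadModel,
    phi: float,
    theta: float,
    psi: float,
    box: int,
    pixel: float = DEFAULT_VOXEL,
    resolution: float = DEFAULT_RESOLUTION,
) -> np.ndarray:
    """Analytic projection: rotate beads, splat 2-D Gaussians.

    Equivalent to ``project(render_volume(m), ...)`` because the line
    integral of an isotropic 3-D Gaussian is a 2-D Gaussian of the same
    sigma; exact up to pixel sampling.
    """
    sig = _sigma_from_resolution(resolution)
    coords = m.coords - m.coords.mean(axis=0)
    rot = coords @ euler_matrix(phi, theta, psi).T
    half = (box - 1) / 2.0
    axis = (np.arange(box) - half) * pixel
    img = np.zeros((box, box))
    norm = 1.0 / (2.0 * np.pi * sig**2) * pixel**2
    # image row = y, column = x after projecting along z
    dy = axis[:, None] - rot[:, 1][None, :]
    dx = axis[:, None] - rot[:, 0][None, :]
    gy = np.exp(-dy**2 / (2 * sig**2))
    gx = np.exp(-dx**2 / (2 * sig**2))
    img = norm * (gy @ gx.T)
    return img


def _orientation_grid(step: float) -> list[tuple[float, float]]:
    """(phi, theta) spherical grid at the given angular step in degrees."""
    out = []
    for theta in np.arange(0.0, 180.0 + step / 2, step):
        if theta in (0.0, 180.0):
            out.append((0.0, float(theta)))
            continue
        for phi in np.arange(0.0, 360.0, step):
            out.append((float(phi), float(theta)))
    return out


def _normalize_rows(X: np.ndarray) -> np.ndarray:
    X = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return X / norms


def _shifted_stack(img: np.ndarray, max_shift: int) -> np.ndarray:
    """All integer-pixel translations of an image within +/- max_shift."""
    shifts = range(-max_shift, max_shift + 1)
    out = []
    for dy in shifts:
        for dx in shifts:
            out.append(np.roll(np.roll(img, dy, axis=0), dx, axis=1))
    return np.stack(out)


def match_classes(
    classes: list[ClassImage],
    models: ModelPool | list[BeadModel],
    angular_step: float = 10.0,
    resolution: float = DEFAULT_RESOLUTION,
    max_shift: int = 3,
) -> MatchResult:
    """Score every (class, model) pair over orientations, in-plane rotations
    and small translations; assign each class to its best-scoring model.

    Scores are Pearson correlations in [-1, 1].  The orientation grid
    covers (phi, theta) at ``angular_step`` with exhaustive in-plane
    rotation at the same step (in-plane rotation of a projection equals the
    third Euler angle) and translation search within ``max_shift`` pixels.
    """
    if not classes:
        raise ValueError("no class images supplied")
    model_list = models.models if isinstance(models, ModelPool) else list(models)
    if not model_list:
        raise ValueError("no models supplied")
    if 360.0 % angular_step != 0:
        raise ValueError("angular_step must divide 360")
    pixel = classes[0].pixel
    box = classes[0].data.shape[0]
    for c in classes:
        if c.pixel != pixel or c.data.shape != (box, box):
            raise ValueError("class images must share pixel size and box")

    views = _orientation_grid(angular_step)
    inplane = np.arange(0.0, 360.0, angular_step)

    # classes x in-plane rotations x shifts, rows normalized once
    stack_rows = []
    meta = []
    for ci, cl in enumerate(classes):
        # center by centroid of the absolute signal before the shift search
        for rot in inplane:
            rot_img = ndimage.rotate(cl.data, rot, reshape=False, order=1)
            for si, shifted in enumerate(_shifted_stack(rot_img, max_shift)):
                stack_rows.append(shifted.ravel())
                meta.append((ci, float(rot), si))
    C = _normalize_rows(np.asarray(stack_rows, dtype=np.float32))

    n_cls, n_mod = len(classes), len(model_list)
    scores = np.full((n_cls, n_mod), -1.0)
    best_orient = np.zeros((n_cls, n_mod, 3))
    for mi, m in enumerate(model_list):
        P = np.asarray([
            project_model(m, phi, theta, 0.0, box, pixel, resolution).ravel()
            for phi, theta in views], dtype=np.float32)
        Pn = _normalize_rows(P)
        S = C @ Pn.T  # (rows, views)
        for row in range(S.shape[0]):
            ci, rot, _si = meta[row]
            vbest = int(np.argmax(S[row]))
            val = float(S[row, vbest])
            if val > scores[ci, mi]:
                scores[ci, mi] = val
                phi, theta = views[vbest]
                best_orient[ci, mi] = (phi, theta, rot)
    return MatchResult(
        scores=scores,
        best_orientation=best_orient,
        best_model=np.argmax(scores, axis=1),
    )
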