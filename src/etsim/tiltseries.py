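"""Forward projection of volumes into single- and dual-axis tilt series.

The acquisition geometry mirrors a dual-axis room-temperature ET session:
the holder tilts about the image y axis from +60 deg to -60 deg in 1 deg
steps (axis A); for the second axis the specimen itself is rotated by 90
deg in the x-y plane and swept again (axis B).

Projection model: parallel beam along +z at zero tilt.  Tilting the
specimen by ``theta`` about +y moves a point at centred physical
coordinates ``(x, z)`` to detector coordinate::

    x' = x * cos(theta) - z * sin(theta)

and the image value is the line integral (voxel sum) along the beam.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .phantom import DensityVolume, GridSpec

logger = logging.getLogger(__name__)

DEFAULT_TILT_MAX_DEG = 60.0
DEFAULT_TILT_STEP_DEG = 1.0


def default_schedule(axis_id: str = "A",
                     tilt_max: float = DEFAULT_TILT_MAX_DEG,
                     step: float = DEFAULT_TILT_STEP_DEG) -> "TiltSchedule":
    """The +60..-60 deg, 1 deg sweep used throughout."""
    n = int(round(2 * tilt_max / step)) + 1
    angles = tuple(np.linspace(tilt_max, -tilt_max, n))
    return TiltSchedule(angles_deg=angles, axis_id=axis_id)


@dataclass(frozen=True)
class TiltSchedule:
    """Ordered tilt angles about a fixed in-plane axis.

    ``tilt_axis`` is the in-plane image axis about which the holder tilts;
    axis A tilts about the image y axis.  Axis B is realized physically by
    rotating the specimen 90 deg in-plane, so its images also tilt about
    their own y axis, but in the specimen frame the effective axis is x.
    """

    angles_deg: tuple[float, ...]
    axis_id: str = "A"
    tilt_axis: str = "y"

    def __post_init__(self):
        a = np.asarray(self.angles_deg, float)
        if a.size == 0:
            raise ValueError("schedule needs at least one angle")
        if np.any(np.abs(a) > 90):
            raise ValueError("|tilt angle| must be <= 90 deg")
        d = np.diff(a)
        if a.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("angles must be strictly monotonic")
        if self.axis_id not in ("A", "B"):
            raise ValueError("axis_id must be 'A' or 'B'")
        object.__setattr__(self, "angles_deg", tuple(float(x) for x in a))

    @property
    def half_angle_deg(self) -> float:
        return float(np.max(np.abs(self.angles_deg)))

    def __len__(self) -> int:
        return len(self.angles_deg)


@dataclass(frozen=True)
class PerturbationSpec:
    """Per-image geometric perturbations emulating beam-induced drift.

    shift_sigma_nm : std of the iid Gaussian per-image translation (nm)
    shift_max_nm : hard clip on each shift component (nm)
    rotation_sigma_deg : std of the iid in-plane rotation (deg)
    shrinkage_rate : cumulative isotropic shrinkage per image (fraction)
    """

    shift_sigma_nm: float = 0.0
    shift_max_nm: float | None = None
    rotation_sigma_deg: float = 0.0
    shrinkage_rate: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.shrinkage_rate <= 0.01):
            raise ValueError("shrinkage_rate must be in [0, 0.01]")
        if self.shift_sigma_nm < 0 or self.rotation_sigma_deg < 0:
            raise ValueError("perturbation magnitudes must be >= 0")


@dataclass
class TiltSeries:
    """Ordered stack of 2D projections plus acquisition metadata.

    ``images`` is ``(n_angles, ny, nx)``.  ``shifts_px`` / ``rotations_deg``
    / ``scales`` log the perturbations actually applied (ground truth for
    alignment), in the convention *observed = transform(projected)*.
    """

    images: np.ndarray
    schedule: TiltSchedule
    pixel_nm: float
    shifts_px: np.ndarray | None = None
    rotations_deg: np.ndarray | None = None
    scales: np.ndarray | None = None
    noise_log: dict = field(default_factory=dict)

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=np.float32)
        if self.images.ndim != 3:
            raise ValueError("images must be (n, ny, nx)")
        if self.images.shape[0] != len(self.schedule):
            raise ValueError("image count must equal angle count")
        n = self.images.shape[0]
        if self.shifts_px is None:
            self.shifts_px = np.zeros((n, 2))
        if self.rotations_deg is None:
            self.rotations_deg = np.zeros(n)
        if self.scales is None:
            self.scales = np.ones(n)

    def __len__(self) -> int:
        return self.images.shape[0]

    def copy(self) -> "TiltSeries":
        return TiltSeries(
            self.images.copy(), self.schedule, self.pixel_nm,
            self.shifts_px.copy(), self.rotations_deg.copy(), self.scales.copy(),
            dict(self.noise_log),
        )


def rotate_volume_zx(values: np.ndarray, theta_deg: float) -> np.ndarray:
    """Rotate a ``[z, y, x]`` volume by ``theta`` about the +y axis.

    Positive ``theta`` carries +x toward +z (right-handed about +y with the
    (z, x) plane conventions used here).  Bilinear interpolation in the
    z-x plane, zero outside the volume; rotation centre is the volume
    centre in the voxel-centre convention.
    """
    nz, ny, nx = values.shape
    t = np.deg2rad(theta_deg)
    c, s = np.cos(t), np.sin(t)
    cz, cx = (nz - 1) / 2.0, (nx - 1) / 2.0
    zz, xx = np.meshgrid(np.arange(nz) - cz, np.arange(nx) - cx, indexing="ij")
    # source coordinates: inverse rotation of the target grid
    z_src = c * zz - s * xx + cz
    x_src = s * zz + c * xx + cx
    z0 = np.floor(z_src).astype(np.int64)
    x0 = np.floor(x_src).astype(np.int64)
    fz = z_src - z0
    fx = x_src - x0
    out = np.zeros((nz, ny, nx), dtype=np.float64)
    vals = values.astype(np.float64, copy=False)
    for dz in (0, 1):
        for dx in (0, 1):
            zi = z0 + dz
            xi = x0 + dx
            w = (fz if dz else 1 - fz) * (fx if dx else 1 - fx)
            ok = (zi >= 0) & (zi < nz) & (xi >= 0) & (xi < nx) & (w > 0)
            if not np.any(ok):
                continue
            contrib = np.zeros((nz, nx, ny))
            contrib[ok] = vals[zi[ok], :, xi[ok]] * w[ok, None]
            out += contrib.transpose(0, 2, 1)
    return out


def project(volume: DensityVolume, schedule: TiltSchedule) -> TiltSeries:
    """Parallel-beam projection of a volume over a tilt schedule.

    Each image is the voxel sum along the beam after rotating the volume by
    the tilt angle about the tilt axis (image y), with zero padding outside
    the volume.  Image shape is ``(ny, nx)``.
    """
    vals = np.asarray(volume.values, np.float64)
    if not np.all(np.isfinite(vals)):
        raise ValueError("volume must be finite")
    images = np.empty((len(schedule), vals.shape[1], vals.shape[2]), dtype=np.float32)
    for i, ang in enumerate(schedule.angles_deg):
        if ang == 0.0:
            images[i] = vals.sum(axis=0)
        else:
            images[i] = rotate_volume_zx(vals, ang).sum(axis=0)
    return TiltSeries(images=images, schedule=schedule, pixel_nm=volume.voxel_nm)


def projected_position(point_nm, volume: DensityVolume, tilt_deg: float) -> tuple[float, float]:
    """Closed-form detector position (x_px, y_px) of a 3D point at a tilt.

    Implements x' = x*cos(theta) - z*sin(theta) about the volume centre, and
    converts physical nm to pixel indices of the projection image.
    """
    p = np.asarray(point_nm, float)
    c = volume.center_nm()
    t = np.deg2rad(tilt_deg)
    xc = (p[0] - c[0]) * np.cos(t) - (p[2] - c[2]) * np.sin(t)
    nx, ny, _ = volume.grid.shape
    x_px = xc / volume.voxel_nm + (nx - 1) / 2.0
    y_px = (p[1] - c[1]) / volume.voxel_nm + (ny - 1) / 2.0
    return float(x_px), float(y_px)


def make_second_axis(volume: DensityVolume, crop: bool = False) -> DensityVolume:
    """Rotate the specimen by 90 deg in the x-y plane (axis-B geometry).

    The rotation is an exact array quarter-turn, so four applications
    restore the input bit-exactly.  Requires a square x-y footprint unless
    ``crop=True`` centre-crops to the smaller dimension first.
    """
    vals = volume.values
    nz, ny, nx = vals.shape
    if ny != nx:
        if not crop:
            raise ValueError(
                f"x-y footprint is {nx}x{ny}; pass crop=True to centre-crop to square"
            )
        n = min(nx, ny)
        y0 = (ny - n) // 2
        x0 = (nx - n) // 2
        vals = vals[:, y0:y0 + n, x0:x0 + n]
        nx = ny = n
    rot = np.ascontiguousarray(np.rot90(vals, k=1, axes=(1, 2)))
    grid = GridSpec(voxel_nm=volume.voxel_nm, shape=(nx, ny, nz))
    return DensityVolume(rot, grid, volume.origin_nm)


def undo_second_axis(volume: DensityVolume) -> DensityVolume:
    """Inverse of :func:`make_second_axis` (exact quarter-turn back)."""
    rot = np.ascontiguousarray(np.rot90(volume.values, k=-1, axes=(1, 2)))
    nz, ny, nx = rot.shape
    return DensityVolume(rot, GridSpec(volume.voxel_nm, (nx, ny, nz)), volume.origin_nm)


def _similarity_resample(image: np.ndarray, shift_px, rotation_deg: float,
                         scale: float, inverse: bool = False) -> np.ndarray:
    """Apply (or invert) *content = scale * R(rot) about centre + shift*.

    Forward: a feature at p appears at ``scale*R*(p-c) + c + shift``.
    Cubic B-spline resampling (zero fill): perturb-then-align passes every
    image through two warps, and bilinear would blur sharp features twice.
    """
    ny, nx = image.shape
    if rotation_deg == 0.0 and scale == 1.0:
        # pure translation: exact band-limited (Fourier) shift, zero-padded
        # against wrap-around — no interpolation loss at all
        dy, dx = float(shift_px[1]), float(shift_px[0])
        if inverse:
            dy, dx = -dy, -dx
        pad = int(np.ceil(max(abs(dy), abs(dx)))) + 4
        padded = np.zeros((ny + 2 * pad, nx + 2 * pad))
        padded[pad:pad + ny, pad:pad + nx] = image
        shifted = np.fft.ifftn(
            ndimage.fourier_shift(np.fft.fftn(padded), (dy, dx))).real
        return shifted[pad:pad + ny, pad:pad + nx].astype(np.float32)
    c = np.array([(ny - 1) / 2.0, (nx - 1) / 2.0])
    t = np.deg2rad(rotation_deg)
    # rows are y, cols are x; rotation acts on (y, x)
    R = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
    s = np.array([shift_px[1], shift_px[0]])  # (dy, dx) -> row/col order
    if inverse:
        # out[u] = in(scale*R*(u-c) + c + s): inverse warp
        A = scale * R
        off = c + s - A @ c
    else:
        A = R.T / scale
        off = c - A @ (c + s)
    return ndimage.affine_transform(
        image, A, offset=off, order=3, mode="constant", cval=0.0,
        output=np.float64,
    ).astype(np.float32)


def perturb(series: TiltSeries, spec: PerturbationSpec, seed: int | None = None) -> TiltSeries:
    """Apply seeded per-image shift/rotation/shrinkage perturbations.

    The transforms actually drawn are recorded in the output's perturbation
    log (``shifts_px``, ``rotations_deg``, ``scales``) as ground truth for
    alignment; a zero-magnitude spec returns the images unchanged.
    """
    rng = np.random.default_rng(seed)
    n = len(series)
    shifts_nm = rng.normal(0.0, spec.shift_sigma_nm, size=(n, 2)) if spec.shift_sigma_nm else np.zeros((n, 2))
    if spec.shift_max_nm is not None:
        shifts_nm = np.clip(shifts_nm, -spec.shift_max_nm, spec.shift_max_nm)
    rots = rng.normal(0.0, spec.rotation_sigma_deg, size=n) if spec.rotation_sigma_deg else np.zeros(n)
    scales = (1.0 - spec.shrinkage_rate) ** np.arange(n)
    shifts_px = shifts_nm / series.pixel_nm

    out = series.copy()
    for i in range(n):
        identity = (
            shifts_px[i, 0] == 0 and shifts_px[i, 1] == 0
            and rots[i] == 0 and scales[i] == 1.0
        )
        if not identity:
            out.images[i] = _similarity_resample(
                series.images[i].astype(np.float64), shifts_px[i], rots[i], scales[i]
            )
    out.shifts_px = series.shifts_px + shifts_px
    out.rotations_deg = series.rotations_deg + rots
    out.scales = series.scales * scales
    return out


def add_noise(series: TiltSeries, dose: float, seed: int | None = None) -> TiltSeries:
    """Poisson counting noise at a mean of ``dose`` counts per pixel.

    Image values are scaled so the series mean maps to ``dose`` expected
    counts, Poisson sampled, and scaled back; the noise model and seed are
    recorded in ``noise_log``.  As dose grows the output converges to the
    input (relative RMS ~ 1/sqrt(dose)).
    """
    if dose <= 0:
        raise ValueError("dose must be > 0")
    rng = np.random.default_rng(seed)
    out = series.copy()
    mean = float(series.images.mean())
    if mean > 0:
        k = dose / mean
        lam = np.clip(series.images.astype(np.float64) * k, 0, None)
        out.images = (rng.poisson(lam) / k).astype(np.float32)
    out.noise_log = dict(series.noise_log, model="poisson", dose=dose, seed=seed)
    return out


def render_bead_series(bead_positions_px: np.ndarray,
                       schedule: TiltSchedule,
                       image_shape: tuple[int, int],
                       shifts_px: np.ndarray | None = None,
                       rotations_deg: np.ndarray | None = None,
                       spot_sigma_px: float = 2.0,
                       amplitude: float = 100.0,
                       pixel_nm: float = 1.0) -> TiltSeries:
    """Render an ideal fiducial tilt series directly from the closed form.

    Each 3D bead at centred pixel coordinates (X, Y, Z) is drawn as a
    Gaussian spot at ``x' = X cos(t) - Z sin(t), y' = Y`` (transformed by
    the optional per-image shift/rotation, which is recorded in the
    perturbation log).  Because the spots are rendered analytically rather
    than projected from a voxel grid, the series is an exact oracle for
    alignment-recovery experiments.
    """
    beads = np.asarray(bead_positions_px, float)
    n = len(schedule)
    ny, nx = image_shape
    c = np.array([(nx - 1) / 2.0, (ny - 1) / 2.0])
    if shifts_px is None:
        shifts_px = np.zeros((n, 2))
    if rotations_deg is None:
        rotations_deg = np.zeros(n)
    yy, xx = np.mgrid[0:ny, 0:nx]
    images = np.zeros((n, ny, nx), dtype=np.float32)
    t_rad = np.deg2rad(np.asarray(schedule.angles_deg))
    for i in range(n):
        px = beads[:, 0] * np.cos(t_rad[i]) - beads[:, 2] * np.sin(t_rad[i])
        py = beads[:, 1]
        tt = np.deg2rad(rotations_deg[i])
        R = np.array([[np.cos(tt), -np.sin(tt)], [np.sin(tt), np.cos(tt)]])
        pos = (np.stack([px, py], axis=1) @ R.T) + shifts_px[i] + c
        for bx, by in pos:
            images[i] += amplitude * np.exp(
                -((xx - bx) ** 2 + (yy - by) ** 2) / (2 * spot_sigma_px**2))
    return TiltSeries(images=images, schedule=schedule, pixel_nm=pixel_nm,
                      shifts_px=np.array(shifts_px, float),
                      rotations_deg=np.array(rotations_deg, float))


def path_length_factor(tilt_deg: float) -> float:
    """Relative beam path length through a flat section at a tilt.

    Returns 1/cos(tilt): 1.0 at zero tilt, 2.0 at 60 deg, ~2.92 at 70 deg —
    the geometric reason tilt ranges stop near +-60..70 deg.
    """
    if abs(tilt_deg) >= 90:
        raise ValueError("|tilt| must be < 90 deg")
    return 1.0 / float(np.cos(np.deg2rad(tilt_deg)))
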