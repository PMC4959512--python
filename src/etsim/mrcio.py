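"""MRC2014 volume/stack I/O and plain-text tilt-angle files.

Implements the subset of the MRC2014 format the toolkit needs: mode 2
(32-bit float) volumes and image stacks with the voxel size recorded in
the cell dimensions (Angstrom, per the format convention; this package
works in nm and converts at the boundary).  Reading modes 0 (int8) and 1
(int16) is supported for interoperability; writing is always mode 2, and a
mode-2 round trip is bit-exact.

Tilt angles use the one-angle-per-line ".tlt" convention.

All writes are atomic: data goes to a temporary file in the target
directory which is then renamed into place.
"""

from __future__ import annotations

import os
import struct
import tempfile

import numpy as np

from .phantom import DensityVolume, GridSpec
from .tiltseries import TiltSeries, TiltSchedule

_HEADER_SIZE = 1024
_MODE_DTYPES = {0: np.int8, 1: np.int16, 2: np.float32}


def _build_header(nz: int, ny: int, nx: int, voxel_nm: float,
                  data: np.ndarray, origin_nm=(0.0, 0.0, 0.0),
                  ispg: int = 1) -> bytes:
    ang = voxel_nm * 10.0  # nm -> Angstrom
    h = bytearray(_HEADER_SIZE)
    struct.pack_into("<3i", h, 0, nx, ny, nz)            # nx, ny, nz
    struct.pack_into("<i", h, 12, 2)                     # mode 2
    struct.pack_into("<3i", h, 16, 0, 0, 0)              # nxstart..
    struct.pack_into("<3i", h, 28, nx, ny, nz)           # mx, my, mz
    struct.pack_into("<3f", h, 40, nx * ang, ny * ang, nz * ang)   # cella
    struct.pack_into("<3f", h, 52, 90.0, 90.0, 90.0)     # cellb
    struct.pack_into("<3i", h, 64, 1, 2, 3)              # mapc, mapr, maps
    struct.pack_into("<3f", h, 76, float(data.min()), float(data.max()),
                     float(data.mean()))                 # dmin, dmax, dmean
    struct.pack_into("<i", h, 88, ispg)                  # ispg (0 for stacks)
    struct.pack_into("<i", h, 92, 0)                     # nsymbt
    ox, oy, oz = (float(v) * 10.0 for v in origin_nm)    # origin in Angstrom
    struct.pack_into("<3f", h, 196, ox, oy, oz)
    h[208:212] = b"MAP "
    h[212:216] = bytes([0x44, 0x44, 0x00, 0x00])         # little-endian machine stamp
    struct.pack_into("<f", h, 216, float(data.std()))    # rms
    struct.pack_into("<i", h, 220, 1)                    # nlabl
    label = b"etsim: MRC2014 mode 2"
    h[224:224 + len(label)] = label
    return bytes(h)


def _atomic_write(path: str, payload: bytes) -> None:
    d = os.path.dirname(os.path.abspath(path)) or "."
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    try:
        with os.fdopen(fd, "wb") as f:
            f.write(payload)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_mrc(obj, path: str) -> None:
    """Write a DensityVolume, TiltSeries, or raw (nz, ny, nx) array as
    mode-2 MRC.  TiltSeries are written as image stacks (ispg 0); pair
    them with :func:`write_tlt` for the angles."""
    if isinstance(obj, DensityVolume):
        data = obj.values.astype("<f4")
        voxel, origin, ispg = obj.voxel_nm, obj.origin_nm, 1
    elif isinstance(obj, TiltSeries):
        data = obj.images.astype("<f4")
        voxel, origin, ispg = obj.pixel_nm, (0.0, 0.0, 0.0), 0
    else:
        data = np.asarray(obj, dtype="<f4")
        if data.ndim != 3:
            raise ValueError("raw arrays must be 3D (nz, ny, nx)")
        voxel, origin, ispg = 1.0, (0.0, 0.0, 0.0), 1
    nz, ny, nx = data.shape
    header = _build_header(nz, ny, nx, voxel, data, origin, ispg)
    _atomic_write(path, header + np.ascontiguousarray(data).tobytes())


def read_mrc(path: str) -> DensityVolume:
    """Read an MRC file (modes 0, 1, 2) as a DensityVolume.

    Voxel size is reconstructed from cella/mx (Angstrom -> nm); the header
    origin is honoured.  Unsupported modes and truncated files fail with a
    diagnostic naming the problem.
    """
    with open(path, "rb") as f:
        header = f.read(_HEADER_SIZE)
        if len(header) < _HEADER_SIZE:
            raise ValueError(f"{path}: corrupt header (only {len(header)} bytes)")
        nx, ny, nz = struct.unpack_from("<3i", header, 0)
        mode, = struct.unpack_from("<i", header, 12)
        mx, my, mz = struct.unpack_from("<3i", header, 28)
        cella = struct.unpack_from("<3f", header, 40)
        origin_ang = struct.unpack_from("<3f", header, 196)
        if header[208:212] not in (b"MAP ", b"\x00\x00\x00\x00"):
            raise ValueError(f"{path}: not an MRC2014 file (missing MAP stamp)")
        if mode not in _MODE_DTYPES:
            raise ValueError(f"{path}: unsupported MRC mode {mode} (modes 0, 1, 2 supported)")
        if min(nx, ny, nz) < 1 or max(nx, ny, nz) > 100_000:
            raise ValueError(f"{path}: corrupt header (shape {nx}x{ny}x{nz})")
        dtype = np.dtype(_MODE_DTYPES[mode]).newbyteorder("<")
        count = nx * ny * nz
        data = np.frombuffer(f.read(count * dtype.itemsize), dtype=dtype)
        if data.size != count:
            raise ValueError(f"{path}: truncated data ({data.size} of {count} values)")
    voxel_nm = (cella[0] / mx) / 10.0 if mx > 0 and cella[0] > 0 else 1.0
    values = data.reshape(nz, ny, nx).astype(np.float32)
    origin_nm = tuple(v / 10.0 for v in origin_ang)
    return DensityVolume(values, GridSpec(voxel_nm=voxel_nm, shape=(nx, ny, nz)), origin_nm)


def write_tlt(angles_deg, path: str) -> None:
    """Write tilt angles, one per line (".tlt" convention)."""
    text = "".join(f"{float(a):.2f}\n" for a in angles_deg)
    _atomic_write(path, text.encode())


def read_tlt(path: str) -> list[float]:
    with open(path) as f:
        return [float(line) for line in f if line.strip()]


def read_tiltseries(mrc_path: str, tlt_path: str, axis_id: str = "A") -> TiltSeries:
    """Read an image stack plus its angle file as a TiltSeries.

    The stack's z count must equal the number of angles.
    """
    vol = read_mrc(mrc_path)
    angles = read_tlt(tlt_path)
    n = vol.values.shape[0]
    if n != len(angles):
        raise ValueError(
            f"{mrc_path} has {n} images but {tlt_path} lists {len(angles)} angles")
    schedule = TiltSchedule(angles_deg=tuple(angles), axis_id=axis_id)
    return TiltSeries(images=vol.values, schedule=schedule, pixel_nm=vol.voxel_nm)


def write_tiltseries(series: TiltSeries, mrc_path: str, tlt_path: str) -> None:
    write_mrc(series, mrc_path)
    write_tlt(series.schedule.angles_deg, tlt_path)


def write_tracks(tracks, path: str) -> None:
    """Serialize fiducial tracks as a plain-text table: bead, image, x, y."""
    lines = ["# bead\timage\tx_px\ty_px\n"]
    for j, tr in enumerate(tracks.tracks):
        for i in sorted(tr):
            x, y = tr[i]
            lines.append(f"{j}\t{i}\t{x:.4f}\t{y:.4f}\n")
    _atomic_write(path, "".join(lines).encode())


def write_alignment(model, path: str) -> None:
    """Serialize an alignment model: image, dx, dy, rotation, scale."""
    lines = ["# image\tdx_px\tdy_px\trot_deg\tscale\n"]
    for i in range(len(model.shifts_px)):
        lines.append(
            f"{i}\t{model.shifts_px[i, 0]:.4f}\t{model.shifts_px[i, 1]:.4f}"
            f"\t{model.rotations_deg[i]:.4f}\t{model.scales[i]:.6f}\n")
    lines.append(f"# residual_rms_px\t{model.residual_rms_px:.4f}\n")
    _atomic_write(path, "".join(lines).encode())
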