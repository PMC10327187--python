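"""Image-format I/O: MRC2014 in/out, SMV (ADSC) and TIFF out, gain maps in.

Conventions: frames are 0-based, row-major, with the slowest axis being
the frame index; SMV headers follow the de facto ADSC key=value dialect
with BEAM_CENTER given in mm.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Optional, Union

import mrcfile
import numpy as np
import tifffile

from .processing import GainMap

__all__ = [
    "FrameMetadata",
    "read_mrc",
    "write_mrc",
    "write_smv",
    "read_smv",
    "write_tiff",
    "read_gain",
]

# MRC2014 modes supported for read/write
_MODE_DTYPES = {
    0: np.int8,
    1: np.int16,
    2: np.float32,
    6: np.uint16,
}


@dataclass(frozen=True)
class FrameMetadata:
    """Geometry header fields required by downstream reduction software.

    Units follow the ADSC/SMV convention: distances in mm, wavelength in
    Angstrom, angles in degrees.  ``exposure_scale`` is the multiplier
    applied before integer output (default 32, preserving five fractional
    bits).
    """

    pixel_size: Optional[float] = None       # mm
    detector_distance: Optional[float] = None  # mm
    wavelength: Optional[float] = None       # Angstrom
    oscillation_start: float = 0.0           # degrees
    oscillation_range: float = 0.0           # degrees
    beam_center: tuple[float, float] = (0.0, 0.0)  # (x, y), mm
    exposure_scale: float = 32.0

    def __post_init__(self) -> None:
        if self.wavelength is not None and self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if self.oscillation_range < 0:
            raise ValueError("oscillation_range must be >= 0")

    def require_geometry(self) -> None:
        missing = [n for n in ("pixel_size", "detector_distance",
                               "wavelength") if getattr(self, n) is None]
        if missing:
            raise ValueError(
                f"metadata field(s) {', '.join(missing)} must be set"
            )


def read_mrc(path: Union[str, os.PathLike]) -> tuple[np.ndarray, tuple]:
    """Read an MRC2014 stack.

    Returns ``(stack, voxel_size)`` with the stack always 3-D
    (frame, row, column), 0-based, row-major; a single image is promoted
    to a 1-frame stack.  Byte order is detected from the header's machine
    stamp by the underlying reader.
    """
    try:
        with mrcfile.open(path, mode="r", permissive=False) as mrc:
            data = np.asarray(mrc.data).copy()
            vx = mrc.voxel_size
            voxel = (float(vx.x), float(vx.y), float(vx.z))
            mode = int(mrc.header.mode)
    except ValueError as exc:
        raise ValueError(f"invalid MRC file {path}: {exc}") from exc
    if mode not in _MODE_DTYPES:
        raise ValueError(
            f"unsupported MRC mode {mode} in {path}; "
            f"supported modes: {sorted(_MODE_DTYPES)}"
        )
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"expected a 2-D image or 3-D stack in {path}, "
                         f"got {data.ndim} dimensions")
    return data, voxel


def write_mrc(
    stack: np.ndarray,
    path: Union[str, os.PathLike],
    mode: int = 2,
    voxel_size: Optional[float] = None,
) -> None:
    """Write an MRC2014 stack in the given mode.

    Integer modes check that all values are representable after rounding
    and raise (never silently clamp) otherwise.  The header carries the
    "MAP " tag, a machine stamp, and filled MIN/MAX/MEAN statistics.
    """
    if mode not in _MODE_DTYPES:
        raise ValueError(f"unsupported MRC mode {mode}; "
                         f"supported modes: {sorted(_MODE_DTYPES)}")
    dtype = _MODE_DTYPES[mode]
    arr = np.asarray(stack)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError("stack must be a 2-D image or 3-D stack")
    if mode != 2:
        info = np.iinfo(dtype)
        rounded = np.rint(arr)
        bad = int(((rounded < info.min) | (rounded > info.max)).sum())
        if bad:
            raise ValueError(
                f"{bad} value(s) not representable in MRC mode {mode} "
                f"({np.dtype(dtype).name})"
            )
        if not np.issubdtype(arr.dtype, np.integer):
            arr = rounded
    out = arr.astype(dtype)
    with mrcfile.new(path, overwrite=True) as mrc:
        mrc.set_data(out)
        if voxel_size is not None:
            mrc.voxel_size = voxel_size
        mrc.update_header_from_data()
        mrc.update_header_stats()


def write_smv(
    frame: np.ndarray,
    meta: FrameMetadata,
    path: Union[str, os.PathLike],
) -> None:
    """Write one frame as an SMV/ADSC image.

    512-byte ASCII key=value header (null-padded, starting with "{")
    followed by little-endian unsigned 16-bit pixel data, row-major.
    The frame must already be integer in [0, 65535]; run
    :func:`edframes.processing.scale_for_integer_output` first.
    """
    arr = np.asarray(frame)
    if arr.ndim != 2:
        raise ValueError("SMV frames are 2-D")
    if not np.issubdtype(arr.dtype, np.integer):
        raise TypeError("SMV frames must be integer; scale and round first")
    if arr.size and (arr.min() < 0 or arr.max() > 65535):
        raise ValueError("SMV pixel values must lie in [0, 65535]")
    meta.require_geometry()
    h, w = arr.shape
    bx, by = meta.beam_center
    fields = [
        ("HEADER_BYTES", " 512"),
        ("DIM", "2"),
        ("BYTE_ORDER", "little_endian"),
        ("TYPE", "unsigned_short"),
        ("SIZE1", str(w)),
        ("SIZE2", str(h)),
        ("PIXEL_SIZE", f"{meta.pixel_size:.6f}"),
        ("DISTANCE", f"{meta.detector_distance:.6f}"),
        ("WAVELENGTH", f"{meta.wavelength:.6f}"),
        ("OSC_START", f"{meta.oscillation_start:.6f}"),
        ("OSC_RANGE", f"{meta.oscillation_range:.6f}"),
        ("PHI", f"{meta.oscillation_start:.6f}"),
        ("BEAM_CENTER_X", f"{bx:.6f}"),
        ("BEAM_CENTER_Y", f"{by:.6f}"),
    ]
    header = "{\n" + "".join(f"{k}={v};\n" for k, v in fields) + "}\n"
    encoded = header.encode("ascii")
    if len(encoded) > 512:
        raise ValueError("SMV header exceeds 512 bytes")
    with open(path, "wb") as fh:
        fh.write(encoded.ljust(512, b"\x00"))
        fh.write(np.ascontiguousarray(arr, dtype="<u2").tobytes())


def read_smv(path: Union[str, os.PathLike]) -> tuple[np.ndarray, dict]:
    """Read an SMV image written by :func:`write_smv`.

    Returns ``(frame, header)`` where header maps the key=value pairs as
    strings.  A line-oriented scan, sufficient for round-trip checks and
    ADSC-style files.
    """
    with open(path, "rb") as fh:
        raw_header = fh.read(512)
        header: dict[str, str] = {}
        for line in raw_header.rstrip(b"\x00").decode("ascii").splitlines():
            line = line.strip().rstrip(";")
            if "=" in line:
                k, v = line.split("=", 1)
                header[k.strip()] = v.strip()
        hb = int(header.get("HEADER_BYTES", "512"))
        if hb != 512:
            fh.seek(hb)
        w = int(header["SIZE1"])
        h = int(header["SIZE2"])
        data = np.frombuffer(fh.read(2 * w * h), dtype="<u2")
    return data.reshape(h, w), header


def write_tiff(
    frame: np.ndarray,
    path: Union[str, os.PathLike],
    compress: bool = False,
) -> None:
    """Write one frame as a lossless single-image grayscale TIFF.

    Values are preserved exactly for 16-bit integer input; deflate
    compression is optional and decodes identically.
    """
    arr = np.asarray(frame)
    if arr.ndim != 2:
        raise ValueError("TIFF frames are 2-D")
    allowed = (np.uint8, np.int8, np.uint16, np.int16, np.uint32,
               np.int32, np.float32, np.float64)
    if arr.dtype.type not in allowed:
        raise TypeError(f"unsupported TIFF bit depth: {arr.dtype}")
    tifffile.imwrite(path, arr, photometric="minisblack",
                     compression="zlib" if compress else None)


def read_gain(
    path: Union[str, os.PathLike],
    shape: Optional[tuple[int, int]] = None,
) -> GainMap:
    """Read a gain reference map.

    Accepts a single-frame float MRC, or a raw little-endian float32 dump
    (``shape`` required).  Normalization is *not* applied at read time —
    that is an explicit step (``GainMap.normalize``).  Nonpositive pixels
    raise with their count and first offending index.
    """
    path = os.fspath(path)
    with open(path, "rb") as fh:
        head = fh.read(212)
    is_mrc = len(head) >= 212 and head[208:212] == b"MAP "
    if is_mrc:
        stack, _ = read_mrc(path)
        if stack.shape[0] != 1:
            raise ValueError("gain reference must be a single frame")
        values = stack[0].astype(float)
    else:
        if shape is None:
            raise ValueError("shape is required for raw float32 gain files")
        h, w = shape
        expected = h * w * 4
        size = os.path.getsize(path)
        if size != expected:
            raise ValueError(
                f"raw gain file size {size} does not match "
                f"{h}x{w} float32 ({expected} bytes)"
            )
        values = np.fromfile(path, dtype="<f4").reshape(h, w).astype(float)
    return GainMap(values, normalized=False)
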