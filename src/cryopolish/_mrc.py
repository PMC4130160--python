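"""Minimal MRC2014 reader/writer.

Supports the subset of the format this package needs: modes 0/1/2/6 on read
(converted to float32), mode 2 on write, pixel size carried in the cell
parameters.  Volumes use ispg=1, image stacks ispg=0 (MRCS convention).
"""

from __future__ import annotations

import struct

import numpy as np

from .errors import FormatError

HEADER_BYTES = 1024

_MODE_DTYPES = {
    0: np.dtype("<i1"),
    1: np.dtype("<i2"),
    2: np.dtype("<f4"),
    6: np.dtype("<u2"),
}


def read_mrc_header(path: str) -> dict:
    """Parse the fixed 1024-byte MRC header into a dict."""
    with open(path, "rb") as fh:
        raw = fh.read(HEADER_BYTES)
    if len(raw) < HEADER_BYTES:
        raise FormatError(f"{path}: truncated MRC header ({len(raw)} bytes)")
    nx, ny, nz, mode = struct.unpack("<4i", raw[0:16])
    mx, my, mz = struct.unpack("<3i", raw[28:40])
    cella = struct.unpack("<3f", raw[40:52])
    ispg = struct.unpack("<i", raw[88:92])[0]
    nsymbt = struct.unpack("<i", raw[92:96])[0]
    if mode not in _MODE_DTYPES:
        raise FormatError(f"{path}: unsupported MRC mode {mode}")
    pixel = float(cella[0]) / mx if mx > 0 and cella[0] > 0 else 1.0
    return {
        "nx": nx,
        "ny": ny,
        "nz": nz,
        "mode": mode,
        "pixel_size": pixel,
        "ispg": ispg,
        "nsymbt": nsymbt,
    }


def read_mrc(path: str) -> tuple[np.ndarray, float]:
    """Read an MRC/MRCS file.

    Returns
    -------
    data : float32 array of shape (nz, ny, nx)
    pixel_size : float, Angstrom per pixel
    """
    hdr = read_mrc_header(path)
    dtype = _MODE_DTYPES[hdr["mode"]]
    count = hdr["nx"] * hdr["ny"] * hdr["nz"]
    offset = HEADER_BYTES + hdr["nsymbt"]
    data = np.fromfile(path, dtype=dtype, count=count, offset=offset)
    if data.size != count:
        raise FormatError(
            f"{path}: expected {count} voxels, file holds {data.size}"
        )
    data = data.reshape(hdr["nz"], hdr["ny"], hdr["nx"]).astype(np.float32)
    return data, hdr["pixel_size"]


def write_mrc(path: str, data: np.ndarray, pixel_size: float, is_stack: bool = False) -> None:
    """Write float32 (mode 2) MRC.  ``data`` must be 3-D (nz, ny, nx)."""
    data = np.ascontiguousarray(data, dtype="<f4")
    if data.ndim != 3:
        raise FormatError(f"MRC data must be 3-D, got ndim={data.ndim}")
    nz, ny, nx = data.shape
    header = bytearray(HEADER_BYTES)
    struct.pack_into("<4i", header, 0, nx, ny, nz, 2)
    # nxstart/nystart/nzstart left at 0
    struct.pack_into("<3i", header, 28, nx, ny, nz)  # mx, my, mz
    struct.pack_into(
        "<3f", header, 40, nx * pixel_size, ny * pixel_size, nz * pixel_size
    )
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)  # cell angles
    struct.pack_into("<3i", header, 64, 1, 2, 3)  # axis order
    struct.pack_into(
        "<3f", header, 76, float(data.min()), float(data.max()), float(data.mean())
    )
    struct.pack_into("<i", header, 88, 0 if is_stack else 1)  # ispg
    header[208:212] = b"MAP "
    header[212:216] = bytes([0x44, 0x44, 0x00, 0x00])  # little-endian stamp
    struct.pack_into("<f", header, 216, float(data.std()))
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(data.tobytes())
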