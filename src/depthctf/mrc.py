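"""Minimal MRC2014 volume/stack I/O.

Reads modes 0 (int8), 1 (int16), 2 (float32) and 6 (uint16); writes mode 2
for floating-point data and mode 1 for integer data, always little-endian,
with the pixel size recorded in the cell dimensions.  Data are returned and
accepted in (nz, ny, nx) order (x fastest, as stored on disk).
"""

from __future__ import annotations

import struct

import numpy as np

_HEADER_SIZE = 1024
_MODE_DTYPES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}


def write_mrc(path, data, pixel_size: float) -> None:
    """Write a 2D image or (nz, ny, nx) array as an MRC2014 file."""
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError("data must be 2D or 3D")
    if np.issubdtype(data.dtype, np.integer):
        payload = data.astype("<i2")
        mode = 1
    else:
        payload = data.astype("<f4")
        mode = 2
    nz, ny, nx = payload.shape
    stats = payload.astype(np.float64)
    header = bytearray(_HEADER_SIZE)
    struct.pack_into("<10i", header, 0, nx, ny, nz, mode, 0, 0, 0, nx, ny, nz)
    struct.pack_into("<6f", header, 40,
                     nx * pixel_size, ny * pixel_size, nz * pixel_size,
                     90.0, 90.0, 90.0)
    struct.pack_into("<3i", header, 64, 1, 2, 3)  # mapc, mapr, maps
    struct.pack_into("<3f", header, 76, float(stats.min()), float(stats.max()),
                     float(stats.mean()))
    struct.pack_into("<2i", header, 88, 1, 0)  # ispg (volume), nsymbt
    header[208:212] = b"MAP "
    header[212:216] = b"\x44\x44\x00\x00"  # little-endian machine stamp
    struct.pack_into("<f", header, 216, float(stats.std()))
    struct.pack_into("<i", header, 220, 1)  # nlabl
    header[224:224 + 9] = b"depthctf "
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(np.ascontiguousarray(payload).tobytes())


def read_mrc(path):
    """Read an MRC file; returns (data (nz, ny, nx), pixel_size in A)."""
    with open(path, "rb") as fh:
        header = fh.read(_HEADER_SIZE)
        if len(header) < _HEADER_SIZE:
            raise ValueError(f"{path}: truncated MRC header")
        nx, ny, nz, mode = struct.unpack_from("<4i", header, 0)
        mx = struct.unpack_from("<i", header, 28)[0]
        cella_x = struct.unpack_from("<f", header, 40)[0]
        nsymbt = struct.unpack_from("<i", header, 92)[0]
        if header[208:211] not in (b"MAP", b"\x00\x00\x00"):
            raise ValueError(f"{path}: missing MAP magic; not an MRC2014 file")
        if mode not in _MODE_DTYPES:
            raise ValueError(f"{path}: unsupported MRC mode {mode}")
        fh.seek(_HEADER_SIZE + nsymbt)
        dtype = np.dtype(_MODE_DTYPES[mode]).newbyteorder("<")
        count = nx * ny * nz
        data = np.frombuffer(fh.read(count * dtype.itemsize), dtype=dtype)
        if data.size != count:
            raise ValueError(f"{path}: truncated MRC data block")
    pixel = cella_x / (mx if mx else nx) if cella_x else 1.0
    return data.reshape(nz, ny, nx).copy(), float(pixel)
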