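"""Minimal MRC2014 reader/writer.

Only what this package needs: 3D volumes and 2D image stacks, mode 0/1/2/6
on read, mode 2 (float32) on write.  Axis convention: the returned array is
indexed ``grid[ix, iy, iz]`` with x the fastest-varying axis on disk, i.e.
the transpose of the on-disk ``(nz, ny, nx)`` section order.

Voxel centers sit at ``origin + (i + 0.5) * spacing`` along each axis.
"""

from __future__ import annotations

import numpy as np

from shapesearch.errors import MapFormatError

HEADER_BYTES = 1024

_MODE_DTYPES = {
    0: np.dtype(np.int8),
    1: np.dtype(np.int16),
    2: np.dtype(np.float32),
    6: np.dtype(np.uint16),
}


def read_mrc(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read an MRC file.

    Returns
    -------
    grid : ndarray, shape (nx, ny, nz)
        Voxel data as float64 (a 2D image stack comes back as (nx, ny, nz)
        with nz the number of sections).
    spacing : ndarray, shape (3,)
        Voxel spacing in Angstrom per axis (cella / m).
    origin : ndarray, shape (3,)
        Physical origin in Angstrom.

    Raises
    ------
    MapFormatError
        If the file is truncated or a header field is invalid; the message
        names the offending field.
    """
    with open(path, "rb") as fh:
        raw = fh.read(HEADER_BYTES)
        if len(raw) < HEADER_BYTES:
            raise MapFormatError(
                f"{path}: truncated header ({len(raw)} < {HEADER_BYTES} bytes)"
            )
        ints = np.frombuffer(raw, dtype="<i4")
        floats = np.frombuffer(raw, dtype="<f4")

        nx, ny, nz = (int(v) for v in ints[0:3])
        mode = int(ints[3])
        mx, my, mz = (int(v) for v in ints[7:10])
        cella = floats[10:13].astype(np.float64)
        origin = floats[49:52].astype(np.float64)

        if min(nx, ny, nz) <= 0:
            raise MapFormatError(f"{path}: invalid dimensions nx/ny/nz = {nx},{ny},{nz}")
        if mode not in _MODE_DTYPES:
            raise MapFormatError(f"{path}: unsupported mode = {mode}")
        for label, m in (("mx", mx), ("my", my), ("mz", mz)):
            if m <= 0:
                raise MapFormatError(f"{path}: invalid sampling {label} = {m}")

        dtype = _MODE_DTYPES[mode]
        n_vox = nx * ny * nz
        data = np.fromfile(fh, dtype=dtype, count=n_vox)
        if data.size < n_vox:
            raise MapFormatError(
                f"{path}: truncated data section ({data.size} of {n_vox} voxels)"
            )

    spacing = cella / np.array([mx, my, mz], dtype=np.float64)
    if np.any(spacing <= 0):
        # Some writers leave cella zeroed; default to 1 A like most tools.
        spacing = np.where(spacing > 0, spacing, 1.0)
    grid = data.reshape(nz, ny, nx).transpose(2, 1, 0).astype(np.float64)
    return grid, spacing, origin


def write_mrc(path, grid: np.ndarray, spacing, origin=(0.0, 0.0, 0.0)) -> None:
    """Write ``grid[ix, iy, iz]`` as an MRC2014 mode-2 (float32) file."""
    grid = np.asarray(grid, dtype=np.float32)
    if grid.ndim == 2:
        grid = grid[:, :, None]
    if grid.ndim != 3:
        raise ValueError(f"expected a 2D or 3D array, got ndim={grid.ndim}")
    spacing = np.broadcast_to(np.asarray(spacing, dtype=np.float64), (3,))
    origin = np.asarray(origin, dtype=np.float64)
    nx, ny, nz = grid.shape

    header_i = np.zeros(256, dtype="<i4")
    header_f = header_i.view("<f4")
    header_i[0:3] = (nx, ny, nz)
    header_i[3] = 2  # mode 2: float32
    header_i[7:10] = (nx, ny, nz)  # mx, my, mz
    header_f[10:13] = spacing * np.array([nx, ny, nz])  # cella
    header_f[13:16] = 90.0  # cellb
    header_i[16:19] = (1, 2, 3)  # mapc, mapr, maps
    header_f[19] = float(grid.min())
    header_f[20] = float(grid.max())
    header_f[21] = float(grid.mean())
    header_i[22] = 1  # ispg: volume
    header_i[27] = 20140  # nversion
    header_f[49:52] = origin
    header_i[52] = int.from_bytes(b"MAP ", "little")
    header_i[53] = int.from_bytes(bytes([0x44, 0x44, 0, 0]), "little")  # little-endian stamp
    header_f[54] = float(grid.std())

    with open(path, "wb") as fh:
        fh.write(header_i.tobytes())
        grid.transpose(2, 1, 0).astype("<f4").tofile(fh)
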