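"""Header + raw binary array archives and NIfTI map export.

Arrays are stored as a pair of files: ``<stem>.hdr`` — a JSON text header
with the dimension list (documented order x, y, z, time, coil), dtype,
domain flags and free-form metadata — and ``<stem>.bin`` — the raw
little-endian binary payload in C order. The round trip is lossless and
bit-identical for the supported dtypes.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

_DTYPES = {
    "complex64": np.complex64,
    "complex128": np.complex128,
    "float32": np.float32,
    "float64": np.float64,
}


class ArchiveError(RuntimeError):
    pass


def write_archive(array: np.ndarray, stem: str | Path, metadata: dict | None = None) -> None:
    """Write ``<stem>.hdr`` / ``<stem>.bin``. dtype must be a supported
    complex/float type; byte order is forced little-endian."""
    stem = Path(stem)
    array = np.ascontiguousarray(array)
    name = array.dtype.name
    if name not in _DTYPES:
        raise ArchiveError(f"unsupported dtype {name!r}")
    header = {
        "dims": list(array.shape),
        "dtype": name,
        "order": "x,y,z,time,coil (C order)",
        "metadata": metadata or {},
    }
    stem.with_suffix(".hdr").write_text(json.dumps(header, indent=1))
    stem.with_suffix(".bin").write_bytes(
        array.astype(array.dtype.newbyteorder("<"), copy=False).tobytes()
    )


def read_archive(stem: str | Path) -> tuple[np.ndarray, dict]:
    """Read an archive pair; returns (array, metadata).

    Distinct errors for an unparseable header, an unknown dtype, and a
    payload whose length disagrees with the header dims.
    """
    stem = Path(stem)
    try:
        header = json.loads(stem.with_suffix(".hdr").read_text())
        dims = [int(d) for d in header["dims"]]
        dtype_name = header["dtype"]
    except (OSError, ValueError, KeyError) as exc:
        raise ArchiveError(f"unparseable header for {stem}: {exc}") from exc
    if dtype_name not in _DTYPES:
        raise ArchiveError(f"unknown dtype {dtype_name!r} in header")
    dtype = np.dtype(_DTYPES[dtype_name]).newbyteorder("<")
    payload = stem.with_suffix(".bin").read_bytes()
    expected = int(np.prod(dims)) * dtype.itemsize
    if len(payload) != expected:
        raise ArchiveError(
            f"payload length {len(payload)} does not match header dims {dims} "
            f"({expected} bytes expected)"
        )
    array = np.frombuffer(payload, dtype=dtype).reshape(dims)
    return array, header.get("metadata", {})


def export_nifti(
    volume: np.ndarray, path: str | Path, voxel_mm: float = 25.0
) -> None:
    """Write a real-valued 3D map as NIfTI with isotropic voxel size."""
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError("export_nifti expects a 3D volume")
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    img = nib.Nifti1Image(volume.astype(np.float32), affine)
    nib.save(img, str(path))
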