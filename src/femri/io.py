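"""Raster and table I/O shared by all pipeline stages.

Supported raster containers: multi-page TIFF (echo stacks, maps), NIfTI
volumes (``.nii``/``.nii.gz``), and PNG for histology rasters.  Scalar
metadata (pixel size, echo times, ...) rides along as JSON — in the TIFF
image description, in a sidecar ``<path>.json`` for NIfTI and PNG — so a
round trip is lossless for both pixel data and metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .exceptions import RasterIOError

__all__ = ["read_raster", "write_raster"]

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def _is_nifti(path: Path) -> bool:
    return path.name.endswith(_NIFTI_SUFFIXES)


def _jsonify(metadata: dict) -> dict:
    out = {}
    for key, value in metadata.items():
        if isinstance(value, np.ndarray):
            out[key] = value.tolist()
        elif isinstance(value, (np.floating, np.integer)):
            out[key] = value.item()
        else:
            out[key] = value
    return out


def write_raster(path, array: np.ndarray, metadata: dict | None = None) -> None:
    """Write a raster (2-D image or 3-D stack) with optional metadata."""
    path = Path(path)
    metadata = _jsonify(metadata or {})
    array = np.asarray(array)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            import tifffile

            tifffile.imwrite(path, array, metadata=metadata)
        elif _is_nifti(path):
            import nibabel as nib

            nib.save(nib.Nifti1Image(np.asarray(array, dtype=np.float32),
                                     affine=np.eye(4)), path)
            path.with_name(path.name + ".json").write_text(json.dumps(metadata))
        elif path.suffix.lower() == ".png":
            import imageio.v3 as iio

            if array.dtype not in (np.uint8, np.uint16):
                raise RasterIOError(f"PNG requires uint8/uint16 data: {path}")
            iio.imwrite(path, array)
            path.with_name(path.name + ".json").write_text(json.dumps(metadata))
        else:
            raise RasterIOError(f"unsupported raster container: {path}")
    except RasterIOError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-raise with path context
        raise RasterIOError(f"failed to write raster {path}: {exc}") from exc


def read_raster(path) -> tuple[np.ndarray, dict]:
    """Read a raster and its metadata; raises with the path on failure."""
    path = Path(path)
    if not path.exists():
        raise RasterIOError(f"raster file not found: {path}")
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            import tifffile

            with tifffile.TiffFile(path) as tif:
                array = tif.asarray()
                meta = {}
                if tif.shaped_metadata:
                    meta = dict(tif.shaped_metadata[0])
                meta.pop("shape", None)
                return array, meta
        if _is_nifti(path):
            import nibabel as nib

            img = nib.load(path)
            array = np.asarray(img.dataobj)
            sidecar = path.with_name(path.name + ".json")
            meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
            return array, meta
        if path.suffix.lower() == ".png":
            import imageio.v3 as iio

            array = iio.imread(path)
            sidecar = path.with_name(path.name + ".json")
            meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
            return array, meta
        raise RasterIOError(f"unsupported raster container: {path}")
    except RasterIOError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise RasterIOError(f"failed to read raster {path}: {exc}") from exc
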