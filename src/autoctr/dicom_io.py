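"""DICOM ingestion, photometric normalization, and the overlapping mask store.

Radiographs arrive as single-frame grayscale DICOM.  Two conventions must
be normalized before any model sees the pixels:

* the modality rescale transform (``pixels × RescaleSlope +
  RescaleIntercept``), and
* grayscale polarity — MONOCHROME1 displays the minimum value as white, so
  such images are inverted about their per-image maximum to the
  MONOCHROME2 convention the rest of the pipeline assumes.

Masks are stored as two independent binary channels, "heart" and "lungs",
in a zarr group per source image; the channels may overlap (the cardiac
silhouette overlies the lung fields), which a single label plane could not
encode.  By annotation convention both lungs are a single channel, so a
dataset of N masked images counts N hearts and 2N lungs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .core import Projection, SegmentationMask

__all__ = [
    "Photometric",
    "RadiographImage",
    "DatasetManifest",
    "UnsupportedFormatError",
    "MaskNotFoundError",
    "read_radiograph",
    "write_radiograph",
    "apply_rescale",
    "normalize_photometric",
    "write_masks",
    "read_masks",
    "list_mask_ids",
    "manifest_from_ids",
    "build_manifest",
    "manifest_to_csv",
]


class UnsupportedFormatError(ValueError):
    """Multi-frame, color, or otherwise unsupported DICOM content."""


class MaskNotFoundError(KeyError):
    """No masks stored under the requested source id."""


# enum kept as plain strings to mirror the DICOM attribute values
class Photometric:
    MONOCHROME1 = "MONOCHROME1"
    MONOCHROME2 = "MONOCHROME2"


@dataclass
class RadiographImage:
    pixels: np.ndarray
    photometric: str = Photometric.MONOCHROME2
    rescale_slope: float = 1.0
    rescale_intercept: float = 0.0
    projection: Projection = Projection.UNKNOWN
    source_id: str = ""
    original_shape: tuple = ()

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D matrix")
        if self.pixels.shape[0] < 8 or self.pixels.shape[1] < 8:
            raise ValueError("image smaller than 8x8")
        if not np.isfinite(self.pixels).all():
            raise ValueError("pixels must be finite")
        if self.photometric not in (Photometric.MONOCHROME1, Photometric.MONOCHROME2):
            raise ValueError(f"unsupported photometric {self.photometric!r}")
        if not self.original_shape:
            self.original_shape = self.pixels.shape
        self.projection = Projection.parse(self.projection)


def read_radiograph(path, projection=None) -> RadiographImage:
    """Read a single-frame grayscale DICOM radiograph.

    ``projection`` overrides DICOM ViewPosition (projection was assigned by
    readers in the source protocol and is often missing from metadata);
    missing or unparseable values map to UNKNOWN.  Missing rescale terms
    default to slope 1 / intercept 0.
    """
    path = Path(path)
    try:
        ds = pydicom.dcmread(path)
        pixels = ds.pixel_array
    except FileNotFoundError:
        raise
    except Exception as exc:  # unreadable / undecodable file
        raise IOError(f"cannot read DICOM file {path}: {exc}") from exc
    if int(getattr(ds, "NumberOfFrames", 1) or 1) > 1:
        raise UnsupportedFormatError("multi-frame DICOM not supported")
    if int(getattr(ds, "SamplesPerPixel", 1) or 1) != 1 or pixels.ndim != 2:
        raise UnsupportedFormatError("color DICOM not supported")
    if projection is None:
        projection = getattr(ds, "ViewPosition", "") or Projection.UNKNOWN
    return RadiographImage(
        pixels=pixels.astype(np.float64),
        photometric=str(getattr(ds, "PhotometricInterpretation",
                                Photometric.MONOCHROME2)),
        rescale_slope=float(getattr(ds, "RescaleSlope", 1.0) or 1.0),
        rescale_intercept=float(getattr(ds, "RescaleIntercept", 0.0) or 0.0),
        projection=Projection.parse(projection),
        source_id=path.stem,
        original_shape=pixels.shape,
    )


def write_radiograph(path, pixels: np.ndarray,
                     photometric: str = Photometric.MONOCHROME2,
                     rescale_slope: float | None = None,
                     rescale_intercept: float | None = None,
                     projection: Projection | None = None) -> None:
    """Write a 16-bit grayscale DICOM file (phantom export / fixtures)."""
    pixels = np.asarray(pixels)
    if pixels.dtype != np.uint16:
        if pixels.min() < 0 or pixels.max() > 65535:
            raise ValueError("pixels must fit uint16")
        pixels = pixels.astype(np.uint16)
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = pydicom.Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "CR"
    ds.PhotometricInterpretation = photometric
    ds.SamplesPerPixel = 1
    ds.Rows, ds.Columns = pixels.shape
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    if rescale_slope is not None:
        ds.RescaleSlope = rescale_slope
    if rescale_intercept is not None:
        ds.RescaleIntercept = rescale_intercept
    if projection is not None and Projection.parse(projection) is not Projection.UNKNOWN:
        ds.ViewPosition = Projection.parse(projection).value
    ds.PixelData = pixels.tobytes()
    ds.save_as(path, enforce_file_format=True)


def apply_rescale(img: RadiographImage) -> RadiographImage:
    """Apply the modality rescale transform; resets slope/intercept to 1/0."""
    pixels = img.pixels * img.rescale_slope + img.rescale_intercept
    return dataclasses.replace(img, pixels=pixels,
                               rescale_slope=1.0, rescale_intercept=0.0)


def normalize_photometric(img: RadiographImage) -> RadiographImage:
    """Invert MONOCHROME1 pixels about the per-image maximum.

    The per-image maximum (rather than 2^BitsStored − 1) makes the
    inversion robust to incorrect bit-depth metadata; downstream
    standardization removes the affine difference.  Idempotent.
    """
    if img.photometric == Photometric.MONOCHROME2:
        return img
    pixels = img.pixels.max() - img.pixels
    return dataclasses.replace(img, pixels=pixels,
                               photometric=Photometric.MONOCHROME2)


# -- mask store -------------------------------------------------------------


def _open_store(store, mode):
    import zarr

    return zarr.open_group(str(store), mode=mode)


def write_masks(mask: SegmentationMask, store, source_id: str,
                projection: Projection = Projection.UNKNOWN) -> None:
    """Store both channels under a group named by ``source_id``."""
    root = _open_store(store, "a")
    grp = root.require_group(source_id)
    for name, channel in (("heart", mask.heart), ("lungs", mask.lungs)):
        arr = grp.create_array(name, shape=channel.shape, dtype="uint8",
                               overwrite=True)
        arr[:] = channel
    grp.attrs["projection"] = Projection.parse(projection).value


def read_masks(store, source_id: str) -> SegmentationMask:
    root = _open_store(store, "r")
    try:
        grp = root[source_id]
        return SegmentationMask(heart=grp["heart"][:], lungs=grp["lungs"][:])
    except KeyError:
        raise MaskNotFoundError(source_id) from None


def read_projection(store, source_id: str) -> Projection:
    root = _open_store(store, "r")
    try:
        return Projection.parse(root[source_id].attrs.get("projection", "UNKNOWN"))
    except KeyError:
        raise MaskNotFoundError(source_id) from None


def list_mask_ids(store) -> list[str]:
    try:
        root = _open_store(store, "r")
    except FileNotFoundError:
        return []
    return sorted(root.group_keys())


@dataclass
class DatasetManifest:
    """Dataset inventory; lungs count twice per masked image by convention
    (both lung fields are annotated as one channel)."""

    entries: list = field(default_factory=list)  # (source_id, has_mask, projection)
    n_images: int = 0
    n_hearts: int = 0
    n_lungs: int = 0


def manifest_from_ids(masked_ids, projections: dict | None = None) -> DatasetManifest:
    """Manifest arithmetic: one heart and two lungs per masked image."""
    projections = projections or {}
    entries = [(sid, True, Projection.parse(projections.get(sid, "UNKNOWN")))
               for sid in masked_ids]
    n = len(entries)
    return DatasetManifest(entries=entries, n_images=n,
                           n_hearts=n, n_lungs=2 * n)


def build_manifest(store) -> DatasetManifest:
    ids = list_mask_ids(store)
    return manifest_from_ids(ids, {sid: read_projection(store, sid)
                                   for sid in ids})


def manifest_to_csv(manifest: DatasetManifest, path) -> None:
    import pandas as pd

    df = pd.DataFrame(
        [(sid, has, Projection.parse(p).value) for sid, has, p in manifest.entries],
        columns=["source_id", "has_mask", "projection"],
    )
    df.to_csv(path, index=False)
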