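"""Radiograph and mask I/O plus resampling to model inputs.

Chest radiographs arrive as single-frame 8-bit grayscale DICOM (or PNG
equivalents) at 1024x1024.  For the networks they are replicated to three
identical channels, resized with bilinear interpolation and rescaled to
[0, 1]; masks are resized with nearest-neighbor so they stay binary.
Probability maps are upscaled bilinearly back to native resolution before
thresholding so removal thresholds count native-resolution pixels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid
from PIL import Image
from skimage.transform import resize

__all__ = [
    "ImageRecord",
    "ModelInput",
    "read_dicom",
    "read_png",
    "read_image",
    "write_dicom",
    "to_model_input",
    "resize_mask",
    "upscale_probability",
    "write_mask_png",
    "read_mask_png",
    "write_probability_png",
    "read_probability_png",
]


@dataclass
class ImageRecord:
    """A grayscale radiograph as stored on disk, before any resampling."""

    image_id: str
    pixels: np.ndarray  # (H, W) uint8
    source_kind: str  # "dicom" | "png"
    native_size: tuple[int, int]  # (height, width)


@dataclass
class ModelInput:
    """Network-ready image tensor with an optional aligned binary mask."""

    tensor: np.ndarray  # (H, W, 3) float32 in [0, 1], all channels equal
    mask: np.ndarray | None = None  # (H, W) uint8 in {0, 1}


def read_dicom(path) -> ImageRecord:
    """Read a single-frame 8-bit grayscale DICOM radiograph.

    MONOCHROME1 (inverted polarity) data is flipped to MONOCHROME2 so that
    air is dark everywhere downstream.  No windowing is applied to 8-bit
    data.
    """
    path = Path(path)
    try:
        ds = pydicom.dcmread(path)
        pixels = ds.pixel_array
    except Exception as exc:
        raise IOError(f"unreadable DICOM file {path}: {exc}") from exc
    if pixels.ndim != 2:
        raise IOError(f"{path}: expected a single-frame grayscale image, got shape {pixels.shape}")
    pixels = pixels.astype(np.uint8)
    if getattr(ds, "PhotometricInterpretation", "MONOCHROME2") == "MONOCHROME1":
        pixels = 255 - pixels
    # file stems carry the image identifier in both the challenge layout and
    # the phantom corpus; the SOP instance UID is only a fallback
    image_id = path.stem or str(getattr(ds, "SOPInstanceUID", ""))
    return ImageRecord(image_id=image_id, pixels=pixels, source_kind="dicom", native_size=pixels.shape)


def read_png(path, image_id: str | None = None) -> ImageRecord:
    path = Path(path)
    arr = np.asarray(Image.open(path).convert("L"), dtype=np.uint8)
    return ImageRecord(
        image_id=image_id or path.stem, pixels=arr, source_kind="png", native_size=arr.shape
    )


def read_image(path) -> ImageRecord:
    """Dispatch on extension: .dcm -> DICOM, anything else -> PNG."""
    path = Path(path)
    return read_dicom(path) if path.suffix.lower() in {".dcm", ".dicom"} else read_png(path)


def write_dicom(path, pixels: np.ndarray, image_id: str) -> None:
    """Write a minimal single-frame 8-bit MONOCHROME2 secondary-capture DICOM."""
    pixels = np.asarray(pixels, dtype=np.uint8)
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.SeriesDescription = image_id
    ds.Modality = "CR"
    ds.PatientName = ds.PatientID = "PHANTOM"
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.SamplesPerPixel = 1
    ds.Rows, ds.Columns = pixels.shape
    ds.BitsAllocated = ds.BitsStored = 8
    ds.HighBit = 7
    ds.PixelRepresentation = 0
    ds.PixelData = pixels.tobytes()
    pydicom.dcmwrite(path, ds, enforce_file_format=True)


def _resize_bilinear(arr: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    return resize(
        arr.astype(np.float64), target, order=1, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )


def resize_mask(mask: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbor mask resize; the value set {0, 1} is preserved."""
    out = resize(
        np.asarray(mask, dtype=np.uint8), target, order=0, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )
    return (out > 0).astype(np.uint8)


def to_model_input(
    rec: ImageRecord,
    mask: np.ndarray | None = None,
    target_size: int | tuple[int, int] = 512,
) -> ModelInput:
    """Resize, rescale to [0, 1] and replicate grayscale to three channels."""
    if isinstance(target_size, int):
        target_size = (target_size, target_size)
    if target_size[0] <= 0 or target_size[1] <= 0:
        raise ValueError(f"target_size must be positive, got {target_size}")
    if mask is not None and np.asarray(mask).shape != rec.pixels.shape:
        raise ValueError(
            f"mask shape {np.asarray(mask).shape} does not match image {rec.pixels.shape}"
        )
    img = _resize_bilinear(rec.pixels, target_size) / 255.0
    tensor = np.repeat(img[:, :, None], 3, axis=2).astype(np.float32)
    out_mask = resize_mask(mask, target_size) if mask is not None else None
    return ModelInput(tensor=tensor, mask=out_mask)


def upscale_probability(prob: np.ndarray, target_size: int | tuple[int, int]) -> np.ndarray:
    """Bilinear upscaling of a probability map; output stays within [0, 1]."""
    if isinstance(target_size, int):
        target_size = (target_size, target_size)
    out = _resize_bilinear(np.asarray(prob, dtype=np.float64), target_size)
    return np.clip(out, 0.0, 1.0)


def write_mask_png(path, mask: np.ndarray) -> None:
    """8-bit mask PNG: foreground 255, background 0."""
    Image.fromarray((np.asarray(mask) != 0).astype(np.uint8) * 255, mode="L").save(path)


def read_mask_png(path) -> np.ndarray:
    return (np.asarray(Image.open(path).convert("L")) > 127).astype(np.uint8)


def write_probability_png(path, prob: np.ndarray) -> None:
    """Probability map as 16-bit grayscale PNG (quantised to 1/65535)."""
    q = np.round(np.clip(np.asarray(prob, dtype=np.float64), 0, 1) * 65535).astype(np.uint16)
    Image.fromarray(q).save(path)


def read_probability_png(path) -> np.ndarray:
    arr = np.asarray(Image.open(path), dtype=np.uint16)
    return arr.astype(np.float64) / 65535.0
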