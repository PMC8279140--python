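"""Relative run-length codec for binary pneumothorax masks.

The SIIM-ACR challenge stores masks as *relative* RLE strings: the first
token of each run pair is an offset from the end of the previous run (the
very first token is an absolute flat pixel index), the second token is the
run length.  ``"247981 1 1022 2 1021 3"`` therefore means: take 1 pixel at
247981, then skip 1022 pixels and take 2 (249004, 249005), then skip 1021
and take 3 (250027-250029).  ``"-1"`` marks an image with no pneumothorax.

Flat pixel indices are column-major and 0-based by default, matching the
challenge's reference encoder; both choices are configurable because a
single worked example cannot disambiguate them (row- and column-major
decodes of a square mask differ only by a transpose).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EncodedMask",
    "RleError",
    "decode_rle",
    "encode_rle",
    "merge_masks",
    "index_to_rowcol",
    "rowcol_to_index",
    "load_annotations",
    "EMPTY_RLE",
]

EMPTY_RLE = "-1"


class RleError(ValueError):
    """Malformed or out-of-bounds run-length string."""


@dataclass
class EncodedMask:
    """An image identifier with its RLE annotation strings.

    Images may carry several RLE strings (multi-lesion annotations); they
    are merged by pixelwise OR when the mask is materialised.
    """

    image_id: str
    rle_strings: list[str] = field(default_factory=list)
    width: int = 1024
    height: int = 1024

    def to_mask(self, order: str = "F") -> np.ndarray:
        if not self.rle_strings:
            return np.zeros((self.height, self.width), dtype=np.uint8)
        return merge_masks(
            [
                decode_rle(s, self.width, self.height, order=order, image_id=self.image_id)
                for s in self.rle_strings
            ]
        )


def _parse_tokens(rle: str, image_id: str | None) -> np.ndarray | None:
    """Return the integer tokens, or None for the empty-mask sentinel."""
    tokens = rle.split()
    if tokens == [EMPTY_RLE]:
        return None
    ident = f" (image {image_id})" if image_id else ""
    try:
        values = np.asarray([int(t) for t in tokens], dtype=np.int64)
    except ValueError as exc:
        raise RleError(f"non-integer RLE token in {rle!r}{ident}") from exc
    if values.size == 0 or values.size % 2:
        raise RleError(f"RLE token count must be even and positive, got {values.size}{ident}")
    if (values < 0).any():
        raise RleError(f"negative RLE token in {rle!r}{ident}")
    return values


def decode_rle(
    rle: str,
    width: int,
    height: int,
    *,
    order: str = "F",
    one_based: bool = False,
    image_id: str | None = None,
) -> np.ndarray:
    """Decode a relative RLE string to a ``(height, width)`` uint8 mask.

    Parameters
    ----------
    order:
        Flattening order of pixel indices: ``"F"`` (column-major, the
        challenge dialect) or ``"C"`` (row-major).
    one_based:
        If true, the first pixel of the image has flat index 1.
    """
    values = _parse_tokens(rle, image_id)
    flat = np.zeros(height * width, dtype=np.uint8)
    if values is not None:
        offsets, lengths = values[0::2], values[1::2]
        starts = np.cumsum(offsets + np.concatenate(([0], lengths[:-1])))
        if one_based:
            starts = starts - 1
        ends = starts + lengths
        n_pix = height * width
        bad = np.nonzero((starts < 0) | (ends > n_pix))[0]
        if bad.size:
            k = int(bad[0])
            ident = f" (image {image_id})" if image_id else ""
            raise RleError(
                f"run {k + 1} (start {int(starts[k])}, length {int(lengths[k])}) exceeds "
                f"the {height}x{width} mask bounds{ident}"
            )
        for s, e in zip(starts, ends):
            flat[s:e] = 1
    return flat.reshape((height, width), order=order)


def encode_rle(mask: np.ndarray, *, order: str = "F", one_based: bool = False) -> str:
    """Encode a binary mask as a relative RLE string; empty masks give ``"-1"``."""
    mask = np.asarray(mask)
    flat = (mask != 0).astype(np.int8).ravel(order=order)
    if not flat.any():
        return EMPTY_RLE
    # run boundaries of the foreground stretches in the flattened mask
    diff = np.diff(np.concatenate(([0], flat, [0])))
    starts = np.nonzero(diff == 1)[0]
    ends = np.nonzero(diff == -1)[0]
    lengths = ends - starts
    offsets = np.empty_like(starts)
    offsets[0] = starts[0] + (1 if one_based else 0)
    offsets[1:] = starts[1:] - ends[:-1]
    out = np.empty(starts.size * 2, dtype=np.int64)
    out[0::2], out[1::2] = offsets, lengths
    return " ".join(map(str, out.tolist()))


def merge_masks(masks: list[np.ndarray]) -> np.ndarray:
    """Pixelwise OR of same-shaped binary masks."""
    if not masks:
        raise ValueError("merge_masks needs at least one mask")
    shape = masks[0].shape
    for m in masks[1:]:
        if m.shape != shape:
            raise ValueError(f"mask shape mismatch: {m.shape} vs {shape}")
    out = np.zeros(shape, dtype=np.uint8)
    for m in masks:
        out |= np.asarray(m, dtype=np.uint8)
    return (out != 0).astype(np.uint8)


def index_to_rowcol(flat_index: int, width: int, height: int, *, order: str = "F") -> tuple[int, int]:
    """Map a flat pixel index to (row, col) under the configured flattening order."""
    if not 0 <= flat_index < width * height:
        raise IndexError(f"flat index {flat_index} out of range for {height}x{width}")
    if order == "F":
        return flat_index % height, flat_index // height
    if order == "C":
        return flat_index // width, flat_index % width
    raise ValueError(f"order must be 'F' or 'C', got {order!r}")


def rowcol_to_index(row: int, col: int, width: int, height: int, *, order: str = "F") -> int:
    if not (0 <= row < height and 0 <= col < width):
        raise IndexError(f"({row}, {col}) out of range for {height}x{width}")
    return col * height + row if order == "F" else row * width + col


def load_annotations(csv_path, width: int = 1024, height: int = 1024) -> dict[str, EncodedMask]:
    """Read an ``ImageId,EncodedPixels`` annotation CSV into EncodedMask records.

    Multiple rows per image accumulate RLE strings; the challenge CSV's
    leading-space ``" -1"`` variant is tolerated.  Malformed strings raise
    :class:`RleError` naming the image.
    """
    df = pd.read_csv(csv_path, dtype=str)
    cols = {c.strip(): c for c in df.columns}
    try:
        id_col, px_col = cols["ImageId"], cols["EncodedPixels"]
    except KeyError as exc:
        raise ValueError(f"annotation CSV must have ImageId and EncodedPixels columns, got {list(df.columns)}") from exc
    records: dict[str, EncodedMask] = {}
    for image_id, rle in zip(df[id_col], df[px_col]):
        image_id = str(image_id).strip()
        rec = records.setdefault(EncodedMask(image_id, [], width, height).image_id, EncodedMask(image_id, [], width, height))
        rle = str(rle).strip()
        if rle != EMPTY_RLE:
            _parse_tokens(rle, image_id)  # validate eagerly, fail loudly
            rec.rle_strings.append(rle)
    return records
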