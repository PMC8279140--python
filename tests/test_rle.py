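"""Relative RLE codec: worked example, inverses, dialects, errors."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from pneumoseg.rle import (
    EMPTY_RLE,
    EncodedMask,
    RleError,
    decode_rle,
    encode_rle,
    index_to_rowcol,
    load_annotations,
    merge_masks,
    rowcol_to_index,
)

WORKED_EXAMPLE = "247981 1 1022 2 1021 3"
WORKED_PIXELS = {247981, 249004, 249005, 250027, 250028, 250029}


def brute_force_decode(rle: str, n_pixels: int) -> set[int]:
    """Token-by-token walk of the relative encoding."""
    if rle.strip() == EMPTY_RLE:
        return set()
    tokens = [int(t) for t in rle.split()]
    pixels, cursor = set(), 0
    for offset, length in zip(tokens[0::2], tokens[1::2]):
        cursor += offset
        for i in range(length):
            assert 0 <= cursor + i < n_pixels
            pixels.add(cursor + i)
        cursor += length
    return pixels


def brute_force_encode(mask: np.ndarray) -> str:
    """Run extraction by scanning the column-major flattened mask."""
    flat = (np.asarray(mask) != 0).astype(int).ravel(order="F").tolist()
    runs = []
    pos = 0
    for value, group in itertools.groupby(flat):
        n = len(list(group))
        if value:
            runs.append((pos, n))
        pos += n
    if not runs:
        return EMPTY_RLE
    tokens, prev_end = [], 0
    for start, length in runs:
        tokens += [start - prev_end, length]
        prev_end = start + length
    return " ".join(map(str, tokens))


def test_worked_example_pixel_set():
    mask = decode_rle(WORKED_EXAMPLE, 1024, 1024)
    flat = np.flatnonzero(mask.ravel(order="F"))
    assert set(flat.tolist()) == WORKED_PIXELS


def test_worked_example_matches_brute_force():
    mask = decode_rle(WORKED_EXAMPLE, 1024, 1024)
    assert set(np.flatnonzero(mask.ravel(order="F")).tolist()) == brute_force_decode(
        WORKED_EXAMPLE, 1024 * 1024
    )


@pytest.mark.parametrize(
    "rle,size,expected",
    [
        (EMPTY_RLE, (1024, 1024), set()),
        ("0 3", (4, 4), {0, 1, 2}),
        ("2 2 3 1", (4, 4), {2, 3, 7}),
    ],
)
def test_decode_small_cases(rle, size, expected):
    mask = decode_rle(rle, size[1], size[0])
    assert set(np.flatnonzero(mask.ravel(order="F")).tolist()) == expected


def test_decode_foreground_equals_length_sum(rng):
    for _ in range(20):
        mask = (rng.random((16, 16)) < 0.2).astype(np.uint8)
        rle = encode_rle(mask)
        if rle == EMPTY_RLE:
            continue
        lengths = [int(t) for t in rle.split()][1::2]
        assert decode_rle(rle, 16, 16).sum() == sum(lengths)


def test_encode_empty_and_simple():
    assert encode_rle(np.zeros((4, 4))) == EMPTY_RLE
    mask = np.zeros((4, 4), dtype=np.uint8)
    mask[0:3, 0] = 1  # flat column-major indices 0, 1, 2
    assert encode_rle(mask) == "0 3"


@pytest.mark.parametrize("side", [16, 64, 1024])
def test_roundtrip_against_oracle(side, rng):
    """encode∘decode and decode∘encode are identities; encoder matches the
    brute-force run-extraction oracle.  500 random masks across sizes."""
    n_cases = {16: 240, 64: 240, 1024: 20}[side]
    density = 0.3 if side < 1024 else 0.001
    for _ in range(n_cases):
        mask = (rng.random((side, side)) < density).astype(np.uint8)
        rle = encode_rle(mask)
        assert rle == brute_force_encode(mask)
        np.testing.assert_array_equal(decode_rle(rle, side, side), mask)
        # decode∘encode identity from the string side
        assert encode_rle(decode_rle(rle, side, side)) == rle


@settings(max_examples=60, deadline=None, derandomize=True)
@given(hnp.arrays(np.uint8, (16, 16), elements=st.integers(0, 1)))
def test_roundtrip_property(mask):
    """decode(encode(m)) == m for arbitrary binary masks, both dialects."""
    for order in ("F", "C"):
        rle = encode_rle(mask, order=order)
        np.testing.assert_array_equal(decode_rle(rle, 16, 16, order=order), mask)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(0, 16 * 16 - 1), st.sampled_from(["F", "C"]))
def test_index_rowcol_inverse_property(idx, order):
    r, c = index_to_rowcol(idx, 16, 16, order=order)
    assert 0 <= r < 16 and 0 <= c < 16
    assert rowcol_to_index(r, c, 16, 16, order=order) == idx


def test_dialect_is_transpose_conjugation(rng):
    mask = (rng.random((32, 32)) < 0.2).astype(np.uint8)
    rle = encode_rle(mask, order="F")
    np.testing.assert_array_equal(
        decode_rle(rle, 32, 32, order="C"), decode_rle(rle, 32, 32, order="F").T
    )


def test_one_based_dialect_shifts_by_one():
    m0 = decode_rle("1 3", 4, 4, one_based=True)
    m1 = decode_rle("0 3", 4, 4, one_based=False)
    np.testing.assert_array_equal(m0, m1)
    assert encode_rle(m0, one_based=True) == "1 3"


@pytest.mark.parametrize(
    "bad", ["247981 1 1022", "a 3", "-5 3", "1048570 100"]
)
def test_malformed_rle_raises(bad):
    with pytest.raises(RleError):
        decode_rle(bad, 1024, 1024, image_id="img42")


def test_out_of_bounds_error_names_run():
    with pytest.raises(RleError, match="run 2"):
        decode_rle("0 3 1048570 10", 1024, 1024)


def test_merge_masks():
    m = (np.arange(16).reshape(4, 4) % 3 == 0).astype(np.uint8)
    zero = np.zeros_like(m)
    np.testing.assert_array_equal(merge_masks([m, zero]), m)
    np.testing.assert_array_equal(merge_masks([m, m]), m)
    a, b = zero.copy(), zero.copy()
    a.flat[:3] = 1
    b.flat[4:8] = 1
    assert merge_masks([a, b]).sum() == 7
    with pytest.raises(ValueError):
        merge_masks([m, np.zeros((3, 3))])


def test_index_rowcol_bijection():
    assert index_to_rowcol(0, 1024, 1024) == (0, 0)
    assert index_to_rowcol(1024 * 1024 - 1, 1024, 1024) == (1023, 1023)
    assert index_to_rowcol(1024, 1024, 1024, order="F") == (0, 1)  # second column
    assert index_to_rowcol(1024, 1024, 1024, order="C") == (1, 0)
    for order in ("F", "C"):
        for idx in [0, 5, 1023, 4095]:
            r, c = index_to_rowcol(idx, 64, 64, order=order)
            assert rowcol_to_index(r, c, 64, 64, order=order) == idx
    with pytest.raises(IndexError):
        index_to_rowcol(64 * 64, 64, 64)


def test_load_annotations_merges_and_validates(tmp_path):
    df = pd.DataFrame(
        {
            "ImageId": ["a", "a", "b"],
            "EncodedPixels": ["0 2", "5 1", " -1"],  # leading-space -1 tolerated
        }
    )
    path = tmp_path / "ann.csv"
    df.to_csv(path, index=False)
    recs = load_annotations(path, 4, 4)
    assert recs["a"].to_mask().sum() == 3
    assert recs["b"].to_mask().sum() == 0
    bad = pd.DataFrame({"ImageId": ["c"], "EncodedPixels": ["1 2 3"]})
    bad.to_csv(path, index=False)
    with pytest.raises(RleError, match="c"):
        load_annotations(path, 4, 4)


def test_encoded_mask_multi_rle_or():
    rec = EncodedMask("x", ["0 2", "1 2"], 4, 4)
    assert rec.to_mask().sum() == 3  # overlap at index 1
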