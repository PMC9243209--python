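"""ULBPEZ: uniform local binary patterns with zero-run encoding.

The enhanced 512x512 green-channel image is tiled into a grid of small
blocks whose side equals the LBP neighbourhood diameter (2R+1).  Each block
that lies entirely inside the retinal field of view contributes a uniform-LBP
histogram; because the block is exactly as large as the neighbourhood, only
its centre pixel has a complete circular neighbourhood, so each histogram is
one-hot.  The per-block histograms are stacked into one long, extremely
sparse vector, whose zero runs are then replaced by run-length tokens —
reducing the feature size to a few percent of the stacked length.  The token
stream, right-padded to a fixed capacity, is the classifier input; reshaped
row-major into the smallest enclosing square, normalised and CLAHE-enhanced,
it becomes the "feature image" consumed by the small CNN.

Conventions (fixed for reproducibility): neighbour 0 sits at angle 0 (east)
and neighbours advance counter-clockwise; samples at non-integer coordinates
are bilinearly interpolated; a neighbour >= centre yields bit 1; bit 0 is
the least significant.  Uniform codes (at most two circular 0<->1 bit
transitions) occupy bins 0..P(P-1)+1 in ascending raw-code order and all
non-uniform codes share the final catch-all bin, for P(P-1)+3 bins total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .preprocessing import clahe as _clahe

__all__ = [
    "SUPPORTED_P",
    "SUPPORTED_R",
    "TABLE_CAPACITIES",
    "LBPConfig",
    "UniformMapping",
    "StackedFeatures",
    "EncodedFeatureVector",
    "block_size_for",
    "divisions_for",
    "n_bins_for",
    "circular_transitions",
    "build_uniform_mapping",
    "lbp_code",
    "block_histogram",
    "stack_features",
    "encode_zeros",
    "decode_zeros",
    "pad_to_capacity",
    "feature_image_side",
    "to_feature_image",
    "extract",
]

SUPPORTED_P = (8, 12, 16, 20, 24)
SUPPORTED_R = (2, 3, 4, 5)

#: Maximum encoded feature length per radius, as established empirically on
#: full-scale fundus data (keyed by R; independent of P).
TABLE_CAPACITIES = {2: 16150, 3: 8200, 4: 4950, 5: 3300}


def block_size_for(R: int) -> int:
    """Block side in pixels: just enclosing the radius-R circular neighbourhood."""
    if R < 1:
        raise ValueError("radius must be >= 1")
    return 2 * R + 1


def divisions_for(image_side: int, R: int) -> int:
    """Blocks per axis for a square image: 5 * floor(side / (5 * block_size))."""
    bs = block_size_for(R)
    if image_side < 5 * bs:
        raise ValueError(
            f"image side {image_side} too small for 5 blocks of size {bs}"
        )
    return 5 * (image_side // (5 * bs))


def n_bins_for(P: int) -> int:
    """Histogram length per block: P(P-1)+2 uniform bins plus one catch-all."""
    if P < 4:
        raise ValueError("neighbour count must be >= 4")
    return P * (P - 1) + 3


@dataclass
class LBPConfig:
    """The (P, R) operating point with its derived grid and capacity.

    P : number of circular neighbours (8, 12, 16, 20 or 24).
    R : sampling radius in pixels (2..5 for the tabulated capacities).
    capacity : fixed classifier input length; defaults to the tabulated
        per-radius maximum and must be given explicitly for other radii.
    """

    P: int = 8
    R: int = 3
    image_side: int = 512
    capacity: Optional[int] = None
    block_size: int = field(init=False)
    divisions: int = field(init=False)
    n_bins: int = field(init=False)

    def __post_init__(self) -> None:
        if self.P < 4:
            raise ValueError("neighbour count P must be >= 4")
        if self.R < 1:
            raise ValueError("radius R must be >= 1")
        self.block_size = block_size_for(self.R)
        self.divisions = divisions_for(self.image_side, self.R)
        self.n_bins = n_bins_for(self.P)
        if self.capacity is None:
            if self.R not in TABLE_CAPACITIES:
                raise ValueError(
                    f"no tabulated capacity for R={self.R}; pass capacity explicitly"
                )
            self.capacity = TABLE_CAPACITIES[self.R]
        if self.capacity <= 0:
            raise ValueError("capacity must be positive")
        assert self.block_size % 2 == 1 and self.block_size > 2 * self.R
        assert self.divisions * self.block_size <= self.image_side


def circular_transitions(code: int, P: int) -> int:
    """Number of 0<->1 changes scanning the P bits of ``code`` circularly."""
    rotated = ((code >> 1) | ((code & 1) << (P - 1))) & ((1 << P) - 1)
    return bin(code ^ rotated).count("1")


def _uniform_codes(P: int) -> np.ndarray:
    """All 2 + P(P-1) codes with at most two circular transitions, sorted.

    They are exactly the all-zeros code, the all-ones code, and every
    circular rotation of a single run of 1..P-1 ones.
    """
    full = (1 << P) - 1
    codes = {0, full}
    for ones in range(1, P):
        run = (1 << ones) - 1
        for rot in range(P):
            codes.add(((run << rot) | (run >> (P - rot))) & full)
    out = np.array(sorted(codes), dtype=np.int64)
    assert out.size == P * (P - 1) + 2
    return out


class UniformMapping:
    """Raw LBP code -> histogram bin.

    Uniform codes get bins 0..P(P-1)+1 in ascending raw-code order; every
    non-uniform code maps to the single catch-all bin P(P-1)+2.  Stored as
    the sorted uniform-code array so it stays cheap even at P=24 (2^24 raw
    codes); lookups vectorise via binary search.
    """

    def __init__(self, P: int):
        self.P = P
        self.n_bins = n_bins_for(P)
        self.uniform_codes = _uniform_codes(P)
        self.nonuniform_bin = self.n_bins - 1

    def lookup(self, codes: np.ndarray | int) -> np.ndarray | int:
        codes = np.asarray(codes, dtype=np.int64)
        idx = np.searchsorted(self.uniform_codes, codes)
        idx = np.minimum(idx, self.uniform_codes.size - 1)
        hit = self.uniform_codes[idx] == codes
        bins = np.where(hit, idx, self.nonuniform_bin)
        return int(bins) if bins.ndim == 0 else bins

    def __getitem__(self, code: int) -> int:
        return int(self.lookup(code))


def build_uniform_mapping(P: int) -> UniformMapping:
    return UniformMapping(P)


# Sample offsets within this distance of a lattice point (per axis) snap to
# it.  This makes P = 8 the classic 8-neighbour operator at every radius
# (diagonals at R*cos(45°) = 0.707R snap to the corner pixels), while
# genuinely between-pixel angles (larger P) keep bilinear interpolation.
_SNAP = 0.3


def _neighbour_offsets(P: int, R: float) -> tuple[np.ndarray, np.ndarray]:
    """(drow, dcol) offsets of the P neighbours; neighbour 0 east, CCW.

    Offsets are snapped to 9 decimals so axis-aligned neighbours land on
    exact integer coordinates, and to the nearest lattice point when within
    ``_SNAP`` of it per axis.
    """
    k = np.arange(P)
    theta = 2.0 * np.pi * k / P
    dcol = np.round(R * np.cos(theta), 9)
    drow = np.round(-R * np.sin(theta), 9)
    for arr in (dcol, drow):
        near = np.abs(arr - np.round(arr)) <= _SNAP
        arr[near] = np.round(arr[near])
    return drow, dcol


def _bilinear(img: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Sample float coordinates from an image by bilinear interpolation."""
    r0 = np.floor(rows).astype(np.intp)
    c0 = np.floor(cols).astype(np.intp)
    tr = rows - r0
    tc = cols - c0
    r1 = np.minimum(r0 + 1, img.shape[0] - 1)
    c1 = np.minimum(c0 + 1, img.shape[1] - 1)
    f = img.astype(np.float64)
    return (
        f[r0, c0] * (1 - tr) * (1 - tc)
        + f[r0, c1] * (1 - tr) * tc
        + f[r1, c0] * tr * (1 - tc)
        + f[r1, c1] * tr * tc
    )


# Interpolated ties within this tolerance of the centre count as "not below";
# keeps exact ties (constant patches) deterministic despite float rounding.
_TIE_EPS = 1e-6


def _codes_at(img: np.ndarray, rows: np.ndarray, cols: np.ndarray, P: int, R: float) -> np.ndarray:
    """Vectorised LBP codes for many centre pixels at integer (rows, cols)."""
    drow, dcol = _neighbour_offsets(P, R)
    centre = img[rows, cols].astype(np.float64)
    codes = np.zeros(rows.shape, dtype=np.int64)
    for k in range(P):
        sample = _bilinear(img, rows + drow[k], cols + dcol[k])
        bit = sample >= centre - _TIE_EPS
        codes |= bit.astype(np.int64) << k
    return codes


def lbp_code(img: np.ndarray, row: int, col: int, cfg: LBPConfig) -> int:
    """Raw LBP code at one pixel: bit k set iff neighbour k >= centre."""
    img = np.asarray(img)
    if (
        row - cfg.R < 0
        or col - cfg.R < 0
        or row + cfg.R > img.shape[0] - 1
        or col + cfg.R > img.shape[1] - 1
    ):
        raise ValueError(
            f"radius-{cfg.R} neighbourhood of ({row}, {col}) leaves the image"
        )
    return int(
        _codes_at(img, np.array([row]), np.array([col]), cfg.P, cfg.R)[0]
    )


def block_histogram(
    img: np.ndarray,
    block_origin: tuple[int, int],
    cfg: LBPConfig,
    mapping: UniformMapping,
) -> np.ndarray:
    """Uniform-LBP histogram of one block.

    Only pixels whose circular neighbourhood lies fully inside the block
    contribute; with the default block size 2R+1 that is the centre pixel
    alone, so the histogram is one-hot.
    """
    r0, c0 = block_origin
    bs = cfg.block_size
    if r0 < 0 or c0 < 0 or r0 + bs > img.shape[0] or c0 + bs > img.shape[1]:
        raise ValueError("block leaves the image")
    lo, hi = cfg.R, bs - cfg.R  # interior pixel range within the block
    rows, cols = np.mgrid[r0 + lo : r0 + hi, c0 + lo : c0 + hi]
    codes = _codes_at(img, rows.ravel(), cols.ravel(), cfg.P, cfg.R)
    bins = mapping.lookup(codes)
    return np.bincount(bins, minlength=cfg.n_bins).astype(np.int64)


@dataclass
class StackedFeatures:
    """Concatenated per-block histograms (row-major block order)."""

    values: np.ndarray
    n_blocks_used: int
    n_bins: int

    def __len__(self) -> int:
        return int(self.values.size)


def stack_features(
    img: np.ndarray,
    mask: np.ndarray,
    cfg: LBPConfig,
    mapping: Optional[UniformMapping] = None,
) -> StackedFeatures:
    """Stack histograms of all fully-foreground blocks, row-major.

    The divisions x divisions grid starts at the image's top-left corner;
    any block containing at least one background pixel is skipped entirely,
    so corner background contributes nothing.  Raises if no block survives.
    """
    img = np.asarray(img)
    mask = np.asarray(mask, dtype=bool)
    if img.shape != mask.shape:
        raise ValueError("image and mask dimensions differ")
    if img.shape[0] < cfg.image_side or img.shape[1] < cfg.image_side:
        raise ValueError(
            f"image smaller than configured side {cfg.image_side}"
        )
    mapping = mapping or build_uniform_mapping(cfg.P)
    d, bs = cfg.divisions, cfg.block_size
    side = d * bs
    blocks_ok = (
        mask[:side, :side].reshape(d, bs, d, bs).all(axis=(1, 3))
    )  # (d, d) True where the block is fully foreground
    n_used = int(blocks_ok.sum())
    if n_used == 0:
        raise ValueError("every block touches background; nothing to extract")

    br, bc = np.nonzero(blocks_ok)  # row-major order guaranteed by nonzero
    if bs == 2 * cfg.R + 1:
        # Fast path: single contributing (centre) pixel per block.
        rows = br * bs + cfg.R
        cols = bc * bs + cfg.R
        codes = _codes_at(img, rows, cols, cfg.P, cfg.R)
        bins = mapping.lookup(codes)
        values = np.zeros(n_used * cfg.n_bins, dtype=np.int64)
        values[np.arange(n_used) * cfg.n_bins + bins] = 1
    else:
        hists = [
            block_histogram(img, (r * bs, c * bs), cfg, mapping)
            for r, c in zip(br, bc)
        ]
        values = np.concatenate(hists)
    return StackedFeatures(values=values, n_blocks_used=n_used, n_bins=cfg.n_bins)


@dataclass
class EncodedFeatureVector:
    """Zero-run encoding of a stacked feature vector.

    ``tokens`` alternates (zero-run length, nonzero value) pairs and ends
    with a (trailing zero-run length, 0) terminator, so decoding is exact.
    """

    tokens: np.ndarray
    original_length: int
    capacity: int


def encode_zeros(
    stacked: StackedFeatures | np.ndarray, capacity: Optional[int] = None
) -> EncodedFeatureVector:
    """Replace zero runs with run-length tokens.

    Each nonzero value v preceded by z zeros becomes the pair (z, v); a
    final (trailing-zero-count, 0) pair terminates the stream.  Raises when
    the token stream would not fit in ``capacity``.
    """
    values = stacked.values if isinstance(stacked, StackedFeatures) else np.asarray(stacked)
    values = np.asarray(values, dtype=np.int64)
    if values.ndim != 1 or values.size == 0:
        raise ValueError("expected a nonempty 1-D feature vector")
    if (values < 0).any():
        raise ValueError("feature values must be non-negative")
    nz = np.flatnonzero(values)
    starts = np.concatenate(([-1], nz))
    run_lengths = np.diff(starts) - 1  # zeros before each nonzero
    pairs = np.column_stack((run_lengths, values[nz]))
    trailing = values.size - (int(nz[-1]) + 1 if nz.size else 0)
    tokens = np.concatenate((pairs.ravel(), [trailing, 0])).astype(np.int64)
    cap = capacity if capacity is not None else tokens.size
    if tokens.size > cap:
        raise ValueError(
            f"encoded length {tokens.size} exceeds capacity {cap}"
        )
    return EncodedFeatureVector(
        tokens=tokens, original_length=int(values.size), capacity=int(cap)
    )


def decode_zeros(enc: EncodedFeatureVector) -> np.ndarray:
    """Exact inverse of :func:`encode_zeros`."""
    out = np.zeros(enc.original_length, dtype=np.int64)
    pos = 0
    pairs = enc.tokens.reshape(-1, 2)
    for run, value in pairs[:-1]:
        pos += int(run)
        out[pos] = value
        pos += 1
    run, value = pairs[-1]
    if value != 0 or pos + int(run) != enc.original_length:
        raise ValueError("malformed token stream")
    return out


def pad_to_capacity(enc: EncodedFeatureVector) -> np.ndarray:
    """Token stream right-padded with zeros to exactly ``capacity`` entries."""
    if enc.tokens.size > enc.capacity:
        raise ValueError("token stream exceeds capacity")
    out = np.zeros(enc.capacity, dtype=np.int64)
    out[: enc.tokens.size] = enc.tokens
    return out


def feature_image_side(capacity: int) -> int:
    """Side of the smallest square holding ``capacity`` values."""
    return math.isqrt(capacity - 1) + 1 if capacity > 0 else 0


def to_feature_image(padded: np.ndarray, capacity: int) -> np.ndarray:
    """Render a padded token vector as an 8-bit square image.

    Row-major fill of the ceil(sqrt(capacity))-sided square (tail cells 0),
    min-max normalisation to [0, 255] (an all-constant vector maps to all
    zeros), then CLAHE with the preprocessing defaults to spread the token
    dynamic range.
    """
    padded = np.asarray(padded)
    if padded.size != capacity:
        raise ValueError(f"expected a vector of length {capacity}")
    side = feature_image_side(capacity)
    grid = np.zeros(side * side, dtype=np.float64)
    grid[:capacity] = padded.astype(np.float64)
    lo, hi = grid.min(), grid.max()
    if hi == lo:
        return np.zeros((side, side), dtype=np.uint8)
    img = np.rint((grid - lo) / (hi - lo) * 255).astype(np.uint8).reshape(side, side)
    return _clahe(img)


def extract(
    img: np.ndarray,
    mask: np.ndarray,
    cfg: LBPConfig,
    mapping: Optional[UniformMapping] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Enhanced image + mask -> (padded ULBPEZ vector, feature image)."""
    mapping = mapping or build_uniform_mapping(cfg.P)
    stacked = stack_features(img, mask, cfg, mapping)
    padded = pad_to_capacity(encode_zeros(stacked, cfg.capacity))
    return padded, to_feature_image(padded, cfg.capacity)
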