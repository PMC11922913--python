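"""Contrast-enhancement operators for grayscale mammograms.

Implements the multi-fusion enhancement stage: global histogram equalization
(HE), contrast-limited adaptive histogram equalization (CLAHE), intensity
inversion, Gaussian low-pass / high-pass filtering, and high-boost sharpening,
plus their composition into an ordered fusion pipeline.

All operators work on :class:`GrayImage`, a 2-D integer intensity grid with an
explicit number of levels (256 for 8-bit input).  HE remaps intensities through
the image's cumulative distribution function:

    N(k)   = H(k) / (n * m)                 (normalized histogram)
    CDF(j) = sum_{k<=j} N(k)                (cumulative distribution)
    P(x)   = round((L - 1) * CDF(x))        (transfer map, round-half-up)

CLAHE applies the same construction per tile after clipping each tile histogram
at ``clip_factor`` times the mean bin height and redistributing the clipped
mass evenly, then blends adjacent tile maps bilinearly to avoid block seams.
High-boost sharpening amplifies the high-frequency residual of a Gaussian
blur:  A*f - lowpass(f)  ==  (A-1)*f + highpass(f).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import InvalidConfigError, InvalidInputError

__all__ = [
    "GrayImage",
    "IntensityHistogram",
    "TransferMap",
    "ClaheConfig",
    "ClaheStep",
    "InvertStep",
    "HighBoostStep",
    "FusionConfig",
    "compute_histogram",
    "equalization_map",
    "equalize",
    "clip_redistribute",
    "clahe",
    "invert",
    "low_pass",
    "high_pass",
    "high_boost",
    "apply_fusion",
    "to_grayscale",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GrayImage:
    """A 2-D grid of integer intensities with an explicit level count.

    Parameters
    ----------
    pixels
        Integer array of shape ``(n_rows, n_cols)`` with values in
        ``[0, levels - 1]``.
    levels
        Number of representable intensity levels (256 for 8-bit images).
    """

    pixels: np.ndarray
    levels: int = 256

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise InvalidInputError(
                f"expected a non-empty 2-D intensity grid, got shape {px.shape}"
            )
        if not np.issubdtype(px.dtype, np.integer):
            if not np.all(px == np.round(px)):
                raise InvalidInputError("pixel values must be integers")
            px = px.astype(np.int64)
        if self.levels < 2:
            raise InvalidInputError(f"levels must be >= 2, got {self.levels}")
        if px.min() < 0 or px.max() > self.levels - 1:
            raise InvalidInputError(
                f"pixel values must lie in [0, {self.levels - 1}], "
                f"got range [{px.min()}, {px.max()}]"
            )
        object.__setattr__(self, "pixels", px.astype(np.int64))

    @property
    def n_rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_cols(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple:
        return self.pixels.shape


@dataclass(frozen=True)
class IntensityHistogram:
    """Per-level counts H(k), frequencies N(k) and cumulative CDF(j)."""

    counts: np.ndarray
    normalized: np.ndarray
    cumulative: np.ndarray


@dataclass(frozen=True)
class TransferMap:
    """Monotone lookup table mapping each input level to an output level."""

    lut: np.ndarray

    def __post_init__(self) -> None:
        lut = np.asarray(self.lut, dtype=np.int64)
        if np.any(np.diff(lut) < 0):
            raise InvalidInputError("transfer map must be monotone non-decreasing")
        object.__setattr__(self, "lut", lut)


@dataclass(frozen=True)
class ClaheConfig:
    """CLAHE parameters.

    ``clip_factor`` is a multiple of the mean tile bin height; the absolute
    clip limit is ``clip_factor * tile_pixel_count / levels``.  The default
    of 2.0 is the common convention.  ``interpolation='none'`` applies each
    tile's map to its own pixels without blending (block artifacts; intended
    for reference checks).
    """

    tile_grid: tuple = (8, 8)
    clip_factor: float = 2.0
    interpolation: str = "bilinear"

    def __post_init__(self) -> None:
        rows, cols = self.tile_grid
        if rows < 1 or cols < 1:
            raise InvalidConfigError(f"tile grid must be >= 1x1, got {self.tile_grid}")
        if self.clip_factor <= 0:
            raise InvalidConfigError(f"clip_factor must be > 0, got {self.clip_factor}")
        if self.interpolation not in ("bilinear", "none"):
            raise InvalidConfigError(
                f"interpolation must be 'bilinear' or 'none', got {self.interpolation!r}"
            )


@dataclass(frozen=True)
class ClaheStep:
    config: ClaheConfig = field(default_factory=ClaheConfig)


@dataclass(frozen=True)
class InvertStep:
    pass


@dataclass(frozen=True)
class HighBoostStep:
    """High-boost sharpening step with amplification ``A`` and blur width ``sigma``."""

    A: float = 1.5
    sigma: float = 2.0

    def __post_init__(self) -> None:
        if self.A <= 0:
            raise InvalidConfigError(f"amplification factor A must be > 0, got {self.A}")
        if self.sigma <= 0:
            raise InvalidConfigError(f"sigma must be > 0, got {self.sigma}")


FusionStep = Union[ClaheStep, InvertStep, HighBoostStep]


@dataclass(frozen=True)
class FusionConfig:
    """Ordered enhancement recipe applied left-to-right.

    The default recipe is CLAHE followed by high-boost sharpening; inversion
    is available as an optional step.  An empty step list is the identity.
    """

    steps: Sequence[FusionStep] = ()

    @staticmethod
    def default() -> "FusionConfig":
        return FusionConfig(steps=(ClaheStep(), HighBoostStep()))

    @staticmethod
    def from_names(
        names: Sequence[str],
        clahe_config: ClaheConfig = None,
        boost_A: float = 1.5,
        sigma: float = 2.0,
    ) -> "FusionConfig":
        """Build a recipe from step names: 'clahe', 'invert', 'highboost'."""
        steps = []
        for name in names:
            key = name.strip().lower().replace("_", "").replace("-", "")
            if key == "clahe":
                steps.append(ClaheStep(clahe_config or ClaheConfig()))
            elif key in ("invert", "inverted"):
                steps.append(InvertStep())
            elif key in ("highboost", "boost"):
                steps.append(HighBoostStep(A=boost_A, sigma=sigma))
            elif key == "":
                continue
            else:
                raise InvalidConfigError(f"unknown fusion step {name!r}")
        return FusionConfig(steps=tuple(steps))


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _as_gray(img) -> GrayImage:
    if isinstance(img, GrayImage):
        return img
    return GrayImage(np.asarray(img))


def _round_half_up(x: np.ndarray) -> np.ndarray:
    # np.round ties to even; the transfer-map contract is round-half-up
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(np.int64)


def to_grayscale(arr: np.ndarray) -> np.ndarray:
    """Collapse an (H, W, 3) RGB array to single-channel luminance (uint8).

    Uses the ITU-R BT.601 weights.  2-D input is returned unchanged.
    """
    a = np.asarray(arr)
    if a.ndim == 2:
        return a
    if a.ndim == 3 and a.shape[2] in (3, 4):
        rgb = a[..., :3].astype(float)
        lum = rgb @ np.array([0.299, 0.587, 0.114])
        return np.clip(_round_half_up(lum), 0, 255).astype(np.uint8)
    raise InvalidInputError(f"cannot interpret array of shape {a.shape} as an image")


# ---------------------------------------------------------------------------
# histogram equalization
# ---------------------------------------------------------------------------


def compute_histogram(img: GrayImage) -> IntensityHistogram:
    """Per-level counts, normalized frequencies and CDF of an image.

    ``counts[k]`` is the number of pixels at level ``k``; ``normalized`` sums
    to 1; ``cumulative`` is non-decreasing and ends at 1.
    """
    img = _as_gray(img)
    counts = np.bincount(img.pixels.ravel(), minlength=img.levels).astype(np.int64)
    n_pixels = img.pixels.size
    normalized = counts / n_pixels
    # divide the integer cumulative counts once so CDF(j) is the correctly
    # rounded value of (sum of counts)/n, keeping round-half-up ties exact
    cumulative = np.cumsum(counts) / n_pixels
    return IntensityHistogram(counts=counts, normalized=normalized, cumulative=cumulative)


def equalization_map(hist: IntensityHistogram, levels: int) -> TransferMap:
    """Transfer map P(x) = round((L-1) * CDF(x)), round-half-up."""
    lut = _round_half_up((levels - 1) * np.asarray(hist.cumulative))
    return TransferMap(lut=np.clip(lut, 0, levels - 1))


def equalize(img: GrayImage) -> GrayImage:
    """Global histogram equalization of an image."""
    img = _as_gray(img)
    lut = equalization_map(compute_histogram(img), img.levels).lut
    return GrayImage(lut[img.pixels], levels=img.levels)


# ---------------------------------------------------------------------------
# CLAHE
# ---------------------------------------------------------------------------


def clip_redistribute(counts: np.ndarray, clip_limit: float) -> np.ndarray:
    """Clip histogram bins at ``clip_limit`` and spread the excess evenly.

    The integer cap is ``max(floor(clip_limit), 1)``.  The total clipped mass
    is divided evenly across all bins; any integer remainder is assigned one
    unit per bin starting at bin 0.  The result conserves the total count
    exactly.  A single pass is used: redistribution may push bins slightly
    above the cap, which bounds contrast amplification all the same.
    """
    counts = np.asarray(counts, dtype=np.int64)
    cap = max(int(np.floor(clip_limit)), 1)
    clipped = np.minimum(counts, cap)
    excess = int(counts.sum() - clipped.sum())
    n_bins = counts.size
    clipped = clipped + excess // n_bins
    remainder = excess % n_bins
    if remainder:
        clipped[:remainder] += 1
    return clipped


def _tile_edges(extent: int, n_tiles: int) -> np.ndarray:
    """Tile boundaries [e_0..e_T] covering ``extent`` in near-equal chunks."""
    return np.round(np.linspace(0, extent, n_tiles + 1)).astype(int)


def clahe(img: GrayImage, cfg: ClaheConfig = None) -> GrayImage:
    """Contrast-limited adaptive histogram equalization.

    The image is split into a ``tile_grid`` of near-equal tiles.  Each tile's
    histogram is clipped (see :func:`clip_redistribute`) at
    ``clip_factor * tile_pixel_count / levels`` and turned into an
    equalization map; pixel values are then blended bilinearly between the
    four surrounding tile maps (edge and corner pixels use the available
    maps).  With one tile and a non-binding clip this reduces exactly to
    global histogram equalization.
    """
    img = _as_gray(img)
    cfg = cfg or ClaheConfig()
    g_rows, g_cols = cfg.tile_grid
    H, W = img.shape
    if g_rows > H or g_cols > W:
        raise InvalidConfigError(
            f"tile grid {cfg.tile_grid} larger than image of shape {(H, W)}"
        )

    row_edges = _tile_edges(H, g_rows)
    col_edges = _tile_edges(W, g_cols)
    L = img.levels

    maps = np.empty((g_rows, g_cols, L), dtype=np.int64)
    centers_r = np.empty(g_rows)
    centers_c = np.empty(g_cols)
    for ti in range(g_rows):
        r0, r1 = row_edges[ti], row_edges[ti + 1]
        centers_r[ti] = (r0 + r1 - 1) / 2.0
        for tj in range(g_cols):
            c0, c1 = col_edges[tj], col_edges[tj + 1]
            centers_c[tj] = (c0 + c1 - 1) / 2.0
            tile = img.pixels[r0:r1, c0:c1]
            counts = np.bincount(tile.ravel(), minlength=L).astype(np.int64)
            clip_limit = cfg.clip_factor * tile.size / L
            counts = clip_redistribute(counts, clip_limit)
            cdf = np.cumsum(counts) / tile.size
            maps[ti, tj] = np.clip(_round_half_up((L - 1) * cdf), 0, L - 1)

    if cfg.interpolation == "none":
        tile_of_row = np.searchsorted(row_edges[1:-1], np.arange(H), side="right")
        tile_of_col = np.searchsorted(col_edges[1:-1], np.arange(W), side="right")
        out = maps[tile_of_row[:, None], tile_of_col[None, :], img.pixels]
        return GrayImage(out, levels=L)

    # bilinear blend between the four nearest tile centers, clamped at edges
    def _bracket(coords: np.ndarray, centers: np.ndarray):
        hi = np.clip(np.searchsorted(centers, coords), 0, centers.size - 1)
        lo = np.clip(hi - 1, 0, centers.size - 1)
        span = centers[hi] - centers[lo]
        with np.errstate(invalid="ignore", divide="ignore"):
            w = np.where(span > 0, (coords - centers[lo]) / np.where(span > 0, span, 1), 0.0)
        return lo, hi, np.clip(w, 0.0, 1.0)

    r_lo, r_hi, wr = _bracket(np.arange(H, dtype=float), centers_r)
    c_lo, c_hi, wc = _bracket(np.arange(W, dtype=float), centers_c)

    px = img.pixels
    m00 = maps[r_lo[:, None], c_lo[None, :], px]
    m01 = maps[r_lo[:, None], c_hi[None, :], px]
    m10 = maps[r_hi[:, None], c_lo[None, :], px]
    m11 = maps[r_hi[:, None], c_hi[None, :], px]
    wr_ = wr[:, None]
    wc_ = wc[None, :]
    blended = (
        (1 - wr_) * (1 - wc_) * m00
        + (1 - wr_) * wc_ * m01
        + wr_ * (1 - wc_) * m10
        + wr_ * wc_ * m11
    )
    out = np.clip(_round_half_up(blended), 0, L - 1)
    return GrayImage(out, levels=L)


# ---------------------------------------------------------------------------
# inversion and high-boost sharpening
# ---------------------------------------------------------------------------


def invert(img: GrayImage) -> GrayImage:
    """Intensity inversion: out(x, y) = (L - 1) - in(x, y)."""
    img = _as_gray(img)
    return GrayImage((img.levels - 1) - img.pixels, levels=img.levels)


def low_pass(img, sigma: float) -> np.ndarray:
    """Gaussian blur with reflect boundary handling; returns a float array."""
    if sigma <= 0:
        raise InvalidConfigError(f"sigma must be > 0, got {sigma}")
    arr = img.pixels if isinstance(img, GrayImage) else np.asarray(img)
    return gaussian_filter(arr.astype(float), sigma=sigma, mode="reflect")


def high_pass(img, sigma: float) -> np.ndarray:
    """High-frequency residual: img - low_pass(img, sigma).  May be negative."""
    arr = img.pixels if isinstance(img, GrayImage) else np.asarray(img)
    return arr.astype(float) - low_pass(arr, sigma)


def high_boost(img: GrayImage, A: float = 1.5, sigma: float = 2.0) -> GrayImage:
    """High-boost sharpening: A*f - lowpass(f), clipped to range and rounded.

    Computed in real arithmetic; the equivalent form (A-1)*f + highpass(f)
    agrees before clipping.  With A = 1 this is the clipped high-pass filter.
    """
    img = _as_gray(img)
    if A <= 0:
        raise InvalidConfigError(f"amplification factor A must be > 0, got {A}")
    boosted = A * img.pixels.astype(float) - low_pass(img, sigma)
    out = np.clip(_round_half_up(boosted), 0, img.levels - 1)
    return GrayImage(out, levels=img.levels)


def apply_fusion(img: GrayImage, cfg: FusionConfig) -> GrayImage:
    """Apply an ordered multi-fusion enhancement recipe to an image."""
    img = _as_gray(img)
    out = img
    for step in cfg.steps:
        if isinstance(step, ClaheStep):
            out = clahe(out, step.config)
        elif isinstance(step, InvertStep):
            out = invert(out)
        elif isinstance(step, HighBoostStep):
            out = high_boost(out, A=step.A, sigma=step.sigma)
        else:
            raise InvalidConfigError(f"unknown fusion step {step!r}")
    return out
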