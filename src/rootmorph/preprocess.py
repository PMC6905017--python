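"""Convert a plate photograph into a clean binary root mask.

The stages mirror the acquisition workflow for excavated roots photographed
on a white background plate: crop to the plate, convert to grayscale (the
blue channel gives the strongest root/plate contrast for dark roots on a
white board), threshold the gray histogram (valley between the two modes if
the histogram is clearly bimodal, otherwise an iterative class-mean
fixed-point threshold), remove impulse noise with a median filter, and
clean the binary mask with morphological closing and opening.

Images are plain numpy arrays throughout: H×W×3 uint8 for color, H×W uint8
for gray, H×W bool for binary masks.  Coordinates are row-major, 0-based,
origin top-left; crop rectangles are half-open.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from scipy import ndimage

from .errors import EmptyInputError, ParameterError, PipelineError

__all__ = [
    "CropRect",
    "ThresholdResult",
    "PipelineConfig",
    "box",
    "reflect_se",
    "crop_to_plate",
    "to_gray",
    "compute_histogram",
    "valley_threshold",
    "iterative_threshold",
    "apply_threshold",
    "median_filter",
    "dilate",
    "erode",
    "binary_open",
    "binary_close",
    "preprocess_pipeline",
]

N_GRAY_LEVELS = 256

# Eq.-style luma weights for the optional weighted grayscale mode.
_LUMA_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass(frozen=True)
class CropRect:
    """Half-open pixel rectangle: rows [top, bottom), cols [left, right)."""

    top: int
    bottom: int
    left: int
    right: int

    @property
    def height(self) -> int:
        return self.bottom - self.top

    @property
    def width(self) -> int:
        return self.right - self.left


@dataclass(frozen=True)
class ThresholdResult:
    """A segmentation threshold and how it was obtained."""

    threshold: int
    method: Literal["valley", "iterative", "manual"]
    iterations: int = 0

    def __post_init__(self):
        if not (0 <= self.threshold < N_GRAY_LEVELS):
            raise ParameterError(f"threshold {self.threshold} outside [0, 255]")
        if self.iterations < 0:
            raise ParameterError("iterations must be >= 0")


def box(size: int = 3) -> np.ndarray:
    """All-ones square structuring element with odd side length."""
    if size < 1 or size % 2 == 0:
        raise ParameterError("structuring element side must be odd and >= 1")
    return np.ones((size, size), dtype=bool)


def reflect_se(se: np.ndarray) -> np.ndarray:
    """Reflection B̂ of a structuring element about its origin (center)."""
    return se[::-1, ::-1]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def crop_to_plate(img: np.ndarray, rect: CropRect | tuple[int, int, int, int]) -> np.ndarray:
    """Crop to the background plate. ``rect`` is (top, bottom, left, right), half-open.

    The caller records the cropped pixel dimensions for plate-based
    calibration; pixels are copied unchanged.
    """
    if not isinstance(rect, CropRect):
        rect = CropRect(*rect)
    h, w = img.shape[:2]
    if not (0 <= rect.top < rect.bottom <= h and 0 <= rect.left < rect.right <= w):
        raise ParameterError(
            f"crop rect {rect} outside image bounds {h}x{w} or empty"
        )
    return img[rect.top : rect.bottom, rect.left : rect.right].copy()


def to_gray(img: np.ndarray, mode: str = "blue_channel") -> np.ndarray:
    """Color → 8-bit grayscale.

    ``blue_channel`` (the pipeline default) extracts the B plane unchanged:
    for dark roots on a white plate the red and green planes separate
    root from background poorly, while blue gives the strongest contrast.
    ``weighted`` applies the standard luma combination
    0.299 R + 0.587 G + 0.114 B, rounded half-up.
    """
    if img.ndim != 3 or img.shape[2] != 3:
        raise ParameterError("expected an H×W×3 color image")
    if mode == "blue_channel":
        return np.ascontiguousarray(img[:, :, 2], dtype=np.uint8)
    if mode == "weighted":
        wr, wg, wb = _LUMA_WEIGHTS
        gray = img[:, :, 0] * wr + img[:, :, 1] * wg + img[:, :, 2] * wb
        return np.floor(gray + 0.5).astype(np.uint8)
    raise ParameterError(f"unknown gray mode {mode!r}")


def compute_histogram(img: np.ndarray) -> np.ndarray:
    """256-bin gray-level histogram; counts sum to H×W."""
    if img.dtype != np.uint8:
        raise ParameterError("histogram expects an 8-bit gray image")
    return np.bincount(img.ravel(), minlength=N_GRAY_LEVELS).astype(np.int64)


def _smooth_histogram(counts: np.ndarray, width: int = 5) -> np.ndarray:
    return ndimage.uniform_filter1d(counts.astype(float), size=width, mode="nearest")


def valley_threshold(
    counts: np.ndarray, *, smooth_width: int = 5, min_mode_mass: float = 0.05
) -> Optional[ThresholdResult]:
    """Valley threshold for clearly bimodal histograms, or None.

    The histogram is smoothed with a small moving average, and a threshold
    is returned only when there are exactly two dominant modes (each peak
    holding at least ``min_mode_mass`` of the total pixel mass) separated
    by a unique interior minimum.  Unimodal histograms, histograms with a
    broad flat valley, and anything else ambiguous return None so that the
    caller falls back to the iterative threshold.
    """
    counts = np.asarray(counts)
    total = counts.sum()
    if total == 0:
        raise EmptyInputError("all-zero histogram")
    sm = _smooth_histogram(counts, smooth_width)

    # Local maxima of the smoothed histogram (plateaus count once, at their
    # midpoint); ripples below 1% of the tallest peak are not modes.
    from scipy.signal import find_peaks

    peaks, _ = find_peaks(sm, prominence=0.01 * sm.max())
    # Endpoints can be modes too (e.g. mass piled at 0 or 255).
    if sm[0] > sm[1]:
        peaks = np.concatenate(([0], peaks))
    if sm[-1] > sm[-2]:
        peaks = np.concatenate((peaks, [len(sm) - 1]))
    if len(peaks) != 2:
        return None
    lo, hi = int(peaks[0]), int(peaks[1])
    if hi - lo < 2:
        return None
    interior = sm[lo + 1 : hi]
    vmin = interior.min()
    argmins = np.flatnonzero(interior == vmin)
    if len(argmins) != 1:
        return None  # flat or broad valley: ambiguous
    t = int(lo + 1 + argmins[0])
    # Each mode must hold a non-trivial share of the pixels.
    mass_low = counts[: t + 1].sum() / total
    if min(mass_low, 1.0 - mass_low) < min_mode_mass:
        return None
    return ThresholdResult(threshold=t, method="valley")


def iterative_threshold(
    counts: np.ndarray, t0: Optional[int] = None, *, max_iter: int = N_GRAY_LEVELS
) -> ThresholdResult:
    """Iterative (ISODATA-style) optimal threshold.

    Repeatedly sets the threshold to the midpoint of the mean gray levels of
    the two classes it induces (pixels ≤ T and pixels > T), rounding half-up
    to an integer gray level, until the threshold is a fixed point.  The
    initial threshold defaults to the midpoint of the occupied gray range.
    """
    counts = np.asarray(counts, dtype=np.float64)
    if counts.sum() == 0:
        raise EmptyInputError("all-zero histogram")
    nz = np.flatnonzero(counts)
    lo, hi = int(nz[0]), int(nz[-1])
    if lo == hi:
        return ThresholdResult(threshold=lo, method="iterative", iterations=0)

    levels = np.arange(len(counts), dtype=np.float64)

    def clamp(t: int) -> int:
        # keep both classes non-empty: lo <= t < hi
        return min(max(t, lo), hi - 1)

    t = clamp(_round_half_up((lo + hi) / 2.0) if t0 is None else int(t0))
    for i in range(1, max_iter + 1):
        low_mass = counts[: t + 1]
        high_mass = counts[t + 1 :]
        mean_low = (low_mass * levels[: t + 1]).sum() / low_mass.sum()
        mean_high = (high_mass * levels[t + 1 :]).sum() / high_mass.sum()
        t_next = clamp(_round_half_up(0.5 * (mean_low + mean_high)))
        if t_next == t:
            return ThresholdResult(threshold=t, method="iterative", iterations=i)
        t = t_next
    raise RuntimeError("iterative threshold failed to converge (cap reached)")


def apply_threshold(
    img: np.ndarray, t: int, polarity: str = "dark_foreground"
) -> np.ndarray:
    """Threshold a gray image to a boolean mask.

    ``bright_foreground`` labels pixels with value strictly greater than
    ``t`` as foreground.  ``dark_foreground`` (the pipeline default — roots
    are darker than the white plate) labels pixels ≤ t instead.
    """
    if not (0 <= t < N_GRAY_LEVELS):
        raise ParameterError(f"threshold {t} outside [0, 255]")
    if polarity == "bright_foreground":
        return img > t
    if polarity == "dark_foreground":
        return img <= t
    raise ParameterError(f"unknown polarity {polarity!r}")


def median_filter(img: np.ndarray, window: tuple[int, int] = (3, 3)) -> np.ndarray:
    """Windowed median; removes isolated impulse (salt-and-pepper) noise.

    Border pixels use the truncated window (only in-image cells); for the
    resulting even-count windows the lower median is taken, so the output
    stays integral and deterministic.
    """
    wh, ww = window
    if wh < 1 or ww < 1 or wh % 2 == 0 or ww % 2 == 0:
        raise ParameterError("median window dims must be odd and >= 1")
    h, w = img.shape
    if wh > h or ww > w:
        raise ParameterError("median window larger than image")
    is_bool = img.dtype == bool
    work = img.astype(np.uint8) if is_bool else img

    out = ndimage.median_filter(work, size=(wh, ww), mode="nearest")
    # Recompute the border frame with truncated windows.
    rh, rw = wh // 2, ww // 2
    border_rows = list(range(min(rh, h))) + list(range(max(h - rh, 0), h))
    border_cols = list(range(min(rw, w))) + list(range(max(w - rw, 0), w))

    def trunc_median(r: int, c: int):
        win = work[max(0, r - rh) : r + rh + 1, max(0, c - rw) : c + rw + 1]
        flat = np.sort(win, axis=None)
        return flat[(flat.size - 1) // 2]  # lower median

    for r in border_rows:
        for c in range(w):
            out[r, c] = trunc_median(r, c)
    inner_rows = range(rh, h - rh)
    for c in border_cols:
        for r in inner_rows:
            out[r, c] = trunc_median(r, c)
    return out.astype(bool) if is_bool else out


def _se_offsets(se: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    se = np.asarray(se, dtype=bool)
    if se.ndim != 2 or se.shape[0] % 2 == 0 or se.shape[1] % 2 == 0:
        raise ParameterError("structuring element must be 2-D with odd sides")
    orow, ocol = se.shape[0] // 2, se.shape[1] // 2
    rr, cc = np.nonzero(se)
    margin = int(max(se.shape)) // 2
    return rr - orow, cc - ocol, margin


def dilate(a: np.ndarray, se: np.ndarray, border_value: int = 0) -> np.ndarray:
    """Binary dilation (Minkowski sum) of mask ``a`` by structuring element ``se``.

    Fills small cavities / grows the foreground.  ``border_value`` is the
    assumed value of pixels outside the image.
    """
    drs, dcs, m = _se_offsets(se)
    a = np.asarray(a, dtype=bool)
    h, w = a.shape
    pad = np.pad(a, m, constant_values=bool(border_value))
    out = np.zeros_like(a)
    for dr, dc in zip(drs, dcs):
        out |= pad[m + dr : m + dr + h, m + dc : m + dc + w]
    return out


def erode(a: np.ndarray, se: np.ndarray, border_value: int = 0) -> np.ndarray:
    """Binary erosion: keeps pixels where every cell of ``se`` fits inside the
    foreground.  Removes tiny debris objects.

    Dual to dilation: ``~erode(a, se, bv) == dilate(~a, reflect_se(se), 1 - bv)``
    holds bit-exactly for every mask.
    """
    drs, dcs, m = _se_offsets(se)
    a = np.asarray(a, dtype=bool)
    h, w = a.shape
    pad = np.pad(a, m, constant_values=bool(border_value))
    out = np.ones_like(a)
    for dr, dc in zip(drs, dcs):
        out &= pad[m + dr : m + dr + h, m + dc : m + dc + w]
    return out


def binary_open(a: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Opening: erosion then dilation. Removes specks smaller than ``se``."""
    return dilate(erode(a, se), se)


def binary_close(a: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Closing: dilation then erosion. Fills cavities smaller than ``se``.

    The erosion step treats out-of-image pixels as foreground so that
    closing is extensive (never removes foreground) up to the image edge.
    """
    return erode(dilate(a, se), se, border_value=1)


def _class_separation(counts: np.ndarray, t: int) -> float:
    """Distance between the mean gray levels of the two classes split at t."""
    counts = np.asarray(counts, dtype=np.float64)
    levels = np.arange(len(counts), dtype=np.float64)
    low, high = counts[: t + 1], counts[t + 1 :]
    if low.sum() == 0 or high.sum() == 0:
        return 0.0
    mean_low = (low * levels[: t + 1]).sum() / low.sum()
    mean_high = (high * levels[t + 1 :]).sum() / high.sum()
    return float(mean_high - mean_low)


@dataclass
class PipelineConfig:
    """Configuration for :func:`preprocess_pipeline`."""

    crop: Optional[CropRect | tuple[int, int, int, int]] = None
    gray_mode: str = "blue_channel"
    median_window: tuple[int, int] = (3, 3)
    se_size: int = 3
    polarity: str = "dark_foreground"
    threshold_method: str = "auto"  # auto | valley | iterative
    threshold_override: Optional[int] = None
    # Minimum separation (gray levels) between the two class means for the
    # image to be considered to contain a root at all.  A rootless plate has
    # a single gray population; any threshold inside it would label a big
    # chunk of the plate as foreground, so below this contrast the pipeline
    # returns an empty mask instead.
    min_contrast: float = 10.0


def preprocess_pipeline(
    img: np.ndarray, cfg: PipelineConfig | None = None
) -> tuple[np.ndarray, ThresholdResult]:
    """Full preprocessing flow: crop → gray → histogram → threshold →
    median filter → close → open.

    Closing runs before opening: cavities inside the root are filled first,
    then debris specks are removed.  Deterministic for fixed input + config.
    Returns the boolean root mask and the threshold provenance.
    """
    cfg = cfg or PipelineConfig()

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as e:  # noqa: BLE001 - stage identity must be attached
            raise PipelineError(name, str(e)) from e

    if cfg.crop is not None:
        img = stage("crop", crop_to_plate, img, cfg.crop)
    gray = stage("gray", to_gray, img, cfg.gray_mode)
    hist = stage("histogram", compute_histogram, gray)

    if cfg.threshold_override is not None:
        tres = ThresholdResult(int(cfg.threshold_override), "manual")
    elif cfg.threshold_method == "iterative":
        tres = stage("threshold", iterative_threshold, hist)
    else:
        tres = stage("threshold", valley_threshold, hist)
        if tres is None:
            if cfg.threshold_method == "valley":
                raise PipelineError("threshold", "histogram is not clearly bimodal")
            tres = stage("threshold", iterative_threshold, hist)

    if cfg.threshold_override is None and _class_separation(hist, tres.threshold) < cfg.min_contrast:
        return np.zeros(gray.shape, dtype=bool), tres

    mask = stage("segment", apply_threshold, gray, tres.threshold, cfg.polarity)
    mask = stage("median", median_filter, mask, cfg.median_window)
    se = box(cfg.se_size)
    mask = stage("close", binary_close, mask, se)
    mask = stage("open", binary_open, mask, se)
    return mask, tres
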