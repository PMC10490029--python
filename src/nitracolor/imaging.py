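"""Image processing chain for colorimetric cuvette photographs.

A photograph of a chromotropic-acid-treated soil extract is reduced to a
single scalar — the mean Value (V) component of the HSV color model over a
region of interest — which is the raw measurement of the device.  The chain
is: load → EXIF orientation correction → downscale to a 1080-px longest
edge → ROI crop → V-channel histogram equalization → mean V.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
from PIL import Image, UnidentifiedImageError

__all__ = [
    "PixelGrid",
    "ROISpec",
    "HSVTriplet",
    "load_image",
    "correct_orientation",
    "resize_longest_edge",
    "crop_roi",
    "equalize_histogram",
    "rgb_to_hsv",
    "rgb_array_to_hsv",
    "mean_v",
    "process_sample",
    "SampleResult",
]

#: EXIF tag id for orientation.
_EXIF_ORIENTATION_TAG = 0x0112


@dataclass(frozen=True)
class PixelGrid:
    """An 8-bit RGB image as an (H, W, 3) uint8 array.

    Pixel addressing is 0-based, row-major, origin at the top-left.
    ``exif_orientation`` carries the EXIF orientation code (1..8) when the
    source file had one; ``None`` means absent.
    """

    pixels: np.ndarray
    exif_orientation: int | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected an (H, W, 3) array, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must be at least 1x1")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("channel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


@dataclass(frozen=True)
class ROISpec:
    """Half-open rectangle [x0, x1) × [y0, y1) or a centered fraction.

    In ``centered-fraction`` mode the rectangle covering the central
    ``fraction`` × ``fraction`` portion of the image is computed at crop
    time and the explicit coordinates are ignored.
    """

    mode: Literal["manual", "centered-fraction"] = "centered-fraction"
    x0: int = 0
    y0: int = 0
    x1: int = 0
    y1: int = 0
    fraction: float = 0.5

    @classmethod
    def from_dict(cls, d: dict) -> "ROISpec":
        return cls(
            mode=d.get("mode", "centered-fraction"),
            x0=int(d.get("x0", 0)),
            y0=int(d.get("y0", 0)),
            x1=int(d.get("x1", 0)),
            y1=int(d.get("y1", 0)),
            fraction=float(d.get("fraction", 0.5)),
        )

    def resolve(self, width: int, height: int) -> tuple[int, int, int, int]:
        """Concrete (x0, y0, x1, y1) for an image of the given size."""
        if self.mode == "centered-fraction":
            f = self.fraction
            if not 0 < f <= 1:
                raise ValueError(f"fraction must be in (0, 1], got {f}")
            w, h = round(width * f), round(height * f)
            w, h = max(w, 1), max(h, 1)
            x0 = (width - w) // 2
            y0 = (height - h) // 2
            return x0, y0, x0 + w, y0 + h
        return self.x0, self.y0, self.x1, self.y1


@dataclass(frozen=True)
class HSVTriplet:
    """Hue in degrees [0, 360), saturation and value as fractions in [0, 1].

    For achromatic inputs (max = min) hue is undefined; it is reported as
    0.0 with ``achromatic=True``.
    """

    h: float
    s: float
    v: float
    achromatic: bool = False


def load_image(path: str | Path) -> PixelGrid:
    """Read a JPEG or PNG into a :class:`PixelGrid`, keeping the EXIF
    orientation code when one is present.

    Raises ``FileNotFoundError`` for a missing path, ``ValueError`` for an
    unreadable or unsupported file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    try:
        with Image.open(path) as im:
            orientation = None
            try:
                exif = im.getexif()
                code = exif.get(_EXIF_ORIENTATION_TAG)
                if code is not None:
                    orientation = int(code)
            except Exception:
                orientation = None
            rgb = im.convert("RGB")
            arr = np.asarray(rgb, dtype=np.uint8)
    except UnidentifiedImageError as exc:
        raise ValueError(f"cannot decode image file: {path}") from exc
    return PixelGrid(arr, exif_orientation=orientation)


def correct_orientation(img: PixelGrid) -> PixelGrid:
    """Rotate/mirror the pixel grid to upright display orientation.

    Standard EXIF semantics: 1 no-op, 2 mirror horizontal, 3 rotate 180°,
    4 mirror vertical, 5 mirror horizontal + rotate 270° CW, 6 rotate
    90° CW, 7 mirror horizontal + rotate 90° CW, 8 rotate 90° CCW.  Codes
    outside 1..8 (or absent) are treated as 1 with a warning.
    """
    code = img.exif_orientation
    if code is None:
        return replace(img, exif_orientation=1)
    if code not in range(1, 9):
        warnings.warn(
            f"unknown EXIF orientation code {code}; treating as 1", stacklevel=2
        )
        code = 1
    px = img.pixels
    if code == 2:
        px = px[:, ::-1]
    elif code == 3:
        px = px[::-1, ::-1]
    elif code == 4:
        px = px[::-1, :]
    elif code == 5:
        px = np.rot90(px[:, ::-1], k=1)
    elif code == 6:
        # stored image must be rotated 90° CW to display upright
        px = np.rot90(px, k=-1)
    elif code == 7:
        px = np.rot90(px[:, ::-1], k=-1)
    elif code == 8:
        px = np.rot90(px, k=1)
    return PixelGrid(np.ascontiguousarray(px), exif_orientation=1)


def resize_longest_edge(img: PixelGrid, target: int = 1080) -> PixelGrid:
    """Downscale with bilinear interpolation so the longest edge equals
    ``target``; aspect ratio preserved to the nearest pixel.  Images whose
    longest edge is already ≤ target pass through unchanged (no upscaling).
    """
    if target < 1:
        raise ValueError(f"target must be >= 1, got {target}")
    w, h = img.width, img.height
    longest = max(w, h)
    if longest <= target:
        return img
    scale = target / longest
    new_w = target if w == longest else max(1, round(w * scale))
    new_h = target if h == longest else max(1, round(h * scale))
    pil = Image.fromarray(img.pixels)
    resized = pil.resize((new_w, new_h), resample=Image.BILINEAR)
    return PixelGrid(np.asarray(resized, dtype=np.uint8), img.exif_orientation)


def crop_roi(img: PixelGrid, roi: ROISpec) -> PixelGrid:
    """Extract the ROI rectangle (half-open on both axes)."""
    x0, y0, x1, y1 = roi.resolve(img.width, img.height)
    if not (0 <= x0 < x1 <= img.width and 0 <= y0 < y1 <= img.height):
        raise ValueError(
            f"ROI ({x0},{y0})-({x1},{y1}) out of bounds for "
            f"{img.width}x{img.height} image"
        )
    return PixelGrid(
        np.ascontiguousarray(img.pixels[y0:y1, x0:x1]), img.exif_orientation
    )


def rgb_to_hsv(r: int, g: int, b: int) -> HSVTriplet:
    """Convert one 8-bit RGB triplet to HSV.

    Channels are normalized to [0, 1]; V is the maximum of the normalized
    channels, S = (max − min)/max (0 when max = 0), and H follows the
    three-case sector rule with +360° wrap so H ∈ [0, 360).  Achromatic
    inputs (max = min) have undefined hue, reported as H = 0 with the
    achromatic flag set.
    """
    for name, c in (("r", r), ("g", g), ("b", b)):
        if not 0 <= c <= 255:
            raise ValueError(f"channel {name}={c} outside [0, 255]")
    rp, gp, bp = r / 255.0, g / 255.0, b / 255.0
    mx = max(rp, gp, bp)
    mn = min(rp, gp, bp)
    v = mx
    if mx == mn:
        return HSVTriplet(0.0, 0.0, v, achromatic=True)
    d = mx - mn
    if mx == rp:
        h = 60.0 * (gp - bp) / d
        if h < 0:
            h += 360.0
    elif mx == gp:
        h = 60.0 * (2.0 + (bp - rp) / d)
    else:
        h = 60.0 * (4.0 + (rp - gp) / d)
    s = 0.0 if mx == 0 else d / mx
    return HSVTriplet(h % 360.0, s, v)


def rgb_array_to_hsv(px: np.ndarray) -> np.ndarray:
    """Vectorized form of :func:`rgb_to_hsv` for an (..., 3) uint8 array.

    Returns a float array of the same leading shape with H in degrees,
    S and V as fractions.  Achromatic pixels get H = 0.
    """
    arr = np.asarray(px, dtype=np.float64) / 255.0
    r, g, b = arr[..., 0], arr[..., 1], arr[..., 2]
    mx = arr.max(axis=-1)
    mn = arr.min(axis=-1)
    d = mx - mn
    safe_d = np.where(d == 0, 1.0, d)
    h = np.zeros_like(mx)
    is_r = (mx == r) & (d > 0)
    is_g = (mx == g) & (d > 0) & ~is_r
    is_b = (d > 0) & ~is_r & ~is_g
    h = np.where(is_r, 60.0 * (g - b) / safe_d, h)
    h = np.where(is_g, 60.0 * (2.0 + (b - r) / safe_d), h)
    h = np.where(is_b, 60.0 * (4.0 + (r - g) / safe_d), h)
    h = np.where(h < 0, h + 360.0, h) % 360.0
    s = np.where(mx == 0, 0.0, d / np.where(mx == 0, 1.0, mx))
    return np.stack([h, s, mx], axis=-1)


def equalize_histogram(img: PixelGrid) -> PixelGrid:
    """Histogram-equalize the V channel, leaving hue and saturation intact.

    V is quantized to 256 levels and remapped through the cumulative
    distribution of the ROI's own V histogram (v → CDF(v)), a monotone
    non-decreasing map.  An image whose V channel occupies a single level
    carries no contrast to redistribute and is returned unchanged.  The
    remap is applied by scaling the RGB triplet, which preserves H and S
    exactly (both depend only on channel ratios).
    """
    px = img.pixels
    if px.size == 0:
        raise ValueError("cannot equalize an empty image")
    v255 = px.max(axis=-1)  # V on the 0..255 integer scale
    hist = np.bincount(v255.ravel(), minlength=256)
    occupied = np.flatnonzero(hist)
    if occupied.size <= 1:
        return img
    cdf = np.cumsum(hist) / v255.size
    new_v255 = np.round(cdf[v255] * 255.0).astype(np.float64)
    old = v255.astype(np.float64)
    scale = np.where(old == 0, 0.0, new_v255 / np.where(old == 0, 1.0, old))
    out = np.round(px.astype(np.float64) * scale[..., None])
    # pixels that were pure black stay achromatic at the new level
    black = old == 0
    if black.any():
        out[black] = new_v255[black, None]
    return PixelGrid(np.clip(out, 0, 255).astype(np.uint8), img.exif_orientation)


def mean_v(img: PixelGrid, scale: Literal["unit", "percent"] = "percent") -> float:
    """Arithmetic mean of per-pixel V over all pixels.

    Reported in [0, 1] (``unit``) or [0, 100] (``percent``, the scale the
    calibration law is expressed in).
    """
    if img.pixels.size == 0:
        raise ValueError("empty ROI")
    v = img.pixels.max(axis=-1).astype(np.float64) / 255.0
    m = float(v.mean())
    if scale == "percent":
        return m * 100.0
    if scale == "unit":
        return m
    raise ValueError(f"unknown scale {scale!r}")


@dataclass(frozen=True)
class SampleResult:
    """Outcome of the full photo → concentration pipeline, with the
    intermediate mean V retained for audit logging."""

    concentration: float
    mean_v: float
    raw_concentration: float
    below_range: bool
    extrapolated: bool
    stages: dict = field(default_factory=dict)


def process_sample(
    path: str | Path,
    roi: ROISpec,
    model,
    *,
    resize_target: int = 1080,
    equalize: bool = True,
) -> SampleResult:
    """Run the full chain on one photograph and predict NO3⁻ (mg L⁻¹).

    ``model`` is a fitted :class:`~nitracolor.calibration.LinearCalibration`
    (or any object with a ``predict_one`` method on percent-scale V).
    """
    img = load_image(path)
    img = correct_orientation(img)
    img = resize_longest_edge(img, resize_target)
    img = crop_roi(img, roi)
    if equalize:
        img = equalize_histogram(img)
    v = mean_v(img, scale="percent")
    pred = model.predict_one(v)
    return SampleResult(
        concentration=pred.concentration,
        mean_v=v,
        raw_concentration=pred.raw,
        below_range=pred.below_range,
        extrapolated=pred.extrapolated,
        stages={"roi_shape": (img.height, img.width)},
    )
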