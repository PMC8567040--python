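"""Contrast normalization: rolling-ball background subtraction + FFT bandpass.

The mask-building protocol first harmonizes the slowly varying fundus
background (illumination gradient, vignetting, choroidal glow) with a
rolling-ball subtraction at radius 500 px, then band-limits the result with
a frequency-domain bandpass passing structures between 3 px and 30 px —
the size range of microglial somata.

The rolling ball is implemented as a grayscale opening with a ball-top
(hemispherical) structuring element: the background at each pixel is the
highest position of a ball of the given radius rolled under the intensity
surface. For large radii the image is opened at a downsampled scale and
the background is upsampled back — the standard large-radius optimization.
Bit-exact agreement with any particular GUI binary is a non-goal; the
morphological contract (opening ≤ image, additive-constant invariance,
idempotence) is the specification.

The bandpass is a difference-of-Gaussians transfer function: for a length
scale L pixels the low-pass gain at radial spatial frequency f (cycles/px)
is exp(-(f*L)^2 / 2), and the band gain is G(small) - G(large). DC gain is
exactly zero, so the output is zero-mean up to boundary effects. Stripe
suppression and post-filter autoscaling/saturation are deliberately absent;
the filter is linear and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import scipy.fft
import scipy.ndimage as ndi
from skimage.transform import resize

from .imgio import FundusImage

#: radius at or above which the opening runs on a downsampled image
DOWNSAMPLE_RADIUS = 100.0
#: downsampled pixels per original pixel grow with radius: shrink = ceil(r / 32)
_SHRINK_DIVISOR = 32.0


@dataclass(frozen=True)
class PreprocessConfig:
    """Stage-1 parameters; defaults are the published protocol settings."""

    rolling_ball_radius_px: float = 500.0
    bandpass_large_px: float = 30.0
    bandpass_small_px: float = 3.0

    def __post_init__(self) -> None:
        if self.rolling_ball_radius_px < 1:
            raise ValueError("rolling_ball_radius_px must be >= 1")
        if self.bandpass_small_px <= 0 or self.bandpass_large_px <= 0:
            raise ValueError("bandpass length scales must be positive")
        if self.bandpass_small_px >= self.bandpass_large_px:
            raise ValueError(
                "bandpass_small_px must be < bandpass_large_px "
                f"(got {self.bandpass_small_px} >= {self.bandpass_large_px})"
            )


def ball_structuring_element(radius: float) -> tuple[np.ndarray, np.ndarray]:
    """Heights and footprint of a ball-top structuring element.

    Heights are sqrt(r^2 - d^2) on the disc d <= r; the constant offset is
    immaterial for an opening (erosion subtracts it, dilation adds it back).
    """
    r = int(np.ceil(radius))
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    d2 = (yy * yy + xx * xx).astype(np.float64)
    footprint = d2 <= radius * radius
    heights = np.zeros_like(d2)
    heights[footprint] = np.sqrt(radius * radius - d2[footprint])
    return heights, footprint


def _ball_opening(arr: np.ndarray, radius: float) -> np.ndarray:
    heights, footprint = ball_structuring_element(radius)
    return ndi.grey_opening(arr, structure=heights, footprint=footprint,
                            mode="reflect")


def rolling_ball_background(arr: np.ndarray, radius: float) -> np.ndarray:
    """Smooth background estimate; never exceeds the image anywhere."""
    arr = np.asarray(arr, dtype=np.float64)
    if radius < DOWNSAMPLE_RADIUS:
        return _ball_opening(arr, radius)
    shrink = int(np.ceil(radius / _SHRINK_DIVISOR))
    shrink = max(1, min(shrink, min(arr.shape) // 8))
    # block-minimum downsampling: bright cells must not bleed into the
    # background estimate, and the background has to stay under the surface
    small_shape = (max(8, int(np.ceil(arr.shape[0] / shrink))),
                   max(8, int(np.ceil(arr.shape[1] / shrink))))
    small = resize(arr, small_shape, order=1, anti_aliasing=True,
                   preserve_range=True)
    # the structuring element must not dwarf the downsampled image
    r_eff = min(radius / shrink, float(min(small.shape) - 1))
    bg_small = _ball_opening(small, r_eff)
    bg = resize(bg_small, arr.shape, order=1, anti_aliasing=False,
                preserve_range=True)
    return np.minimum(bg, arr)


def subtract_background(img: FundusImage, radius: float) -> FundusImage:
    """Subtract a rolling-ball background estimate (output >= 0, <= input)."""
    if radius < 1:
        raise ValueError(f"rolling-ball radius must be >= 1, got {radius}")
    arr = img.as_float()
    out = np.clip(arr - rolling_ball_background(arr, radius), 0.0, None)
    return img.with_pixels(
        out, bit_depth=None,
        record={"stage": "subtract_background", "rolling_ball_radius_px": radius},
    )


def bandpass_gain(freq: np.ndarray | float, large_px: float,
                  small_px: float) -> np.ndarray | float:
    """Difference-of-Gaussians transfer function at frequency f (cycles/px)."""
    f = np.asarray(freq, dtype=np.float64)
    return np.exp(-0.5 * (f * small_px) ** 2) - np.exp(-0.5 * (f * large_px) ** 2)


def bandpass_filter(img: FundusImage, large_px: float,
                    small_px: float) -> FundusImage:
    """Frequency-domain bandpass between two structure sizes.

    The image is mirror-padded to the next efficient transform size (to
    avoid wrap-around halos around the bright optic disc), filtered with
    the difference-of-Gaussians transfer function, and cropped back.
    """
    if small_px <= 0 or large_px <= 0 or small_px >= large_px:
        raise ValueError(
            f"need 0 < small_px < large_px, got small={small_px}, large={large_px}"
        )
    arr = img.as_float()
    h, w = arr.shape
    h2 = scipy.fft.next_fast_len(2 * h)
    w2 = scipy.fft.next_fast_len(2 * w)
    pt, pl = (h2 - h) // 2, (w2 - w) // 2
    padded = np.pad(arr, ((pt, h2 - h - pt), (pl, w2 - w - pl)), mode="symmetric")
    fy = scipy.fft.fftfreq(h2)[:, None]
    fx = scipy.fft.rfftfreq(w2)[None, :]
    gain = bandpass_gain(np.sqrt(fy * fy + fx * fx), large_px, small_px)
    filtered = scipy.fft.irfft2(scipy.fft.rfft2(padded) * gain, s=(h2, w2))
    out = filtered[pt:pt + h, pl:pl + w]
    return img.with_pixels(
        out, bit_depth=None,
        record={"stage": "bandpass_filter", "bandpass_large_px": large_px,
                "bandpass_small_px": small_px},
    )


def preprocess(img: FundusImage, cfg: PreprocessConfig | None = None) -> FundusImage:
    """Full stage 1: background subtraction, then bandpass (in that order).

    The order matters — the opening is nonlinear — and both parameter sets
    are recorded in the image's provenance.
    """
    cfg = cfg or PreprocessConfig()
    out = subtract_background(img, cfg.rolling_ball_radius_px)
    out = bandpass_filter(out, cfg.bandpass_large_px, cfg.bandpass_small_px)
    return out.with_pixels(
        out.pixels, bit_depth=None,
        record={"stage": "preprocess", "config": asdict(cfg)},
    )
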