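"""Channel normalization and conditioning before segmentation.

Two operations: histogram matching of whole frames to a per-experiment
reference (so one intensity threshold is transferable across samples), and
the four-step conditioning chain applied to surface and synaptic channels
before masking — rolling-ball background subtraction, Gaussian blur, mean
smoothing, and a saturated percentile rescale to the full bit range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import exposure, morphology

from .io import CalibratedImage


@dataclass
class PreprocParams:
    """Conditioning parameters (pixel units).

    background_radius_px : rolling-ball radius; must exceed the largest
        foreground structure for the background estimate to pass under it.
    blur_sigma_px : Gaussian blur sigma.
    smooth_kernel_px : side of the mean-filter box.
    contrast_saturation_frac : fraction of pixels saturated at *each* tail
        during the final rescale (ImageJ "Enhance Contrast" convention).
    """

    background_radius_px: float = 50.0
    blur_sigma_px: float = 1.0
    smooth_kernel_px: int = 3
    contrast_saturation_frac: float = 0.003

    def __post_init__(self) -> None:
        if self.background_radius_px <= 0 or self.blur_sigma_px <= 0:
            raise ValueError("radius and sigma must be > 0")
        if self.smooth_kernel_px <= 0:
            raise ValueError("smooth_kernel_px must be > 0")
        if not (0.0 <= self.contrast_saturation_frac < 0.5):
            raise ValueError("contrast_saturation_frac must lie in [0, 0.5)")


def match_histogram(
    image: CalibratedImage, reference: CalibratedImage
) -> CalibratedImage:
    """Map image intensities so their empirical CDF matches the reference's.

    The mapping is the exact monotone quantile transform: a pixel at
    empirical CDF position q is replaced by the reference's q-quantile
    (inverted-CDF convention), so the output takes only intensity values
    present in the reference.  Matching an image to itself is the
    identity, and the operation is idempotent for a fixed reference.
    """
    if image.bit_depth != reference.bit_depth:
        raise ValueError("image and reference must share a bit depth")
    ref = np.asarray(reference.pixels, dtype=np.float64).ravel()
    if ref.min() == ref.max():
        raise ValueError("reference image is constant; histogram matching undefined")
    px = np.asarray(image.pixels, dtype=np.float64)
    src_sorted = np.sort(px.ravel())
    cdf = np.searchsorted(src_sorted, px.ravel(), side="right") / px.size
    matched = np.quantile(ref, cdf, method="inverted_cdf").reshape(px.shape)
    matched = np.clip(matched, 0, image.max_intensity)
    return image.with_pixels(matched.astype(np.float64))


def _background_subtract(pixels: np.ndarray, radius: float) -> np.ndarray:
    """Rolling-ball-style background removal via grayscale disk opening.

    The flat-disk opening is the standard flat approximation of the
    rolling ball: the background is the largest signal a disk of the
    given radius can fit under, so structures smaller than the disk
    survive subtraction while plateaus and slow gradients are removed.
    Unlike the curved ball, it commutes with intensity scaling.
    """
    footprint = morphology.disk(int(round(radius)), decomposition="sequence")
    background = morphology.opening(pixels, footprint)
    return pixels - background


def _rescale_saturated(
    pixels: np.ndarray, saturation_frac: float, max_intensity: int
) -> np.ndarray:
    lo = np.quantile(pixels, saturation_frac)
    hi = np.quantile(pixels, 1.0 - saturation_frac)
    if hi <= lo:
        return np.zeros_like(pixels)
    out = (pixels - lo) / (hi - lo) * max_intensity
    return np.clip(out, 0, max_intensity)


def condition_channel(
    image: CalibratedImage,
    params: PreprocParams | None = None,
    rescale: bool = True,
) -> CalibratedImage:
    """Background-subtract, blur, smooth, and contrast-rescale one channel.

    Steps run in that fixed order on a float copy; the result is clipped to
    [0, 2**bit_depth − 1].  ``rescale=False`` stops before the contrast
    step, leaving an output that scales linearly with input intensity.
    """
    params = params or PreprocParams()
    h, w = image.shape
    if params.smooth_kernel_px > min(h, w):
        raise ValueError("smoothing kernel larger than image")
    px = image.pixels.astype(np.float64)
    px = _background_subtract(px, params.background_radius_px)
    px = ndi.gaussian_filter(px, sigma=params.blur_sigma_px)
    px = ndi.uniform_filter(px, size=params.smooth_kernel_px)
    if rescale:
        px = _rescale_saturated(px, params.contrast_saturation_frac, image.max_intensity)
    px = np.clip(px, 0, image.max_intensity)
    return image.with_pixels(px)


def equalize_channel(image: CalibratedImage) -> CalibratedImage:
    """Histogram equalization, the alternative contrast step behind a flag."""
    eq = exposure.equalize_hist(image.pixels) * image.max_intensity
    return image.with_pixels(eq)
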