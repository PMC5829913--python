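"""À trous wavelet multiscale-product segmentation of membrane compartments.

The compartment mask (ER network, PM sheet, induced contact sites) is built
by the classic undecimated isotropic wavelet scheme: the image is smoothed
with a separable B3-spline approximation of a Gaussian,
``[1/16, 1/4, 3/8, 1/4, 1/16]``, at S progressively larger dyadic scales
(the kernel dilated with 2^{s-1}-1 interleaved zeros — "à trous"), the
wavelet planes are the differences between consecutive smoothing levels,
negative coefficients are clipped, and the product of the clipped planes
yields a filtered image in which only structures supported across all
scales survive. Thresholding the filtered image at k standard deviations
(default k = 3) gives the binary mask.

Two sign conventions are provided. ``standard`` (the default) takes
W_s = I_{s-1} − I_s, so bright structures produce positive coefficients and
survive clipping — this is the convention of the à trous spot-detection
literature. ``literal`` takes W_s = I_s − I_{s-1}, under which clipping
removes bright structures entirely; it is retained purely so the behaviour
can be audited (see docs/methods.md).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

B3_KERNEL = (1 / 16, 1 / 4, 3 / 8, 1 / 4, 1 / 16)

_BOUNDARY_MODES = ("mirror", "reflect", "wrap", "nearest")


class EmptyRoiError(ValueError):
    """A cell ROI is empty or has a non-positive mean intensity."""


@dataclass(frozen=True)
class WaveletParams:
    """Parameters of the multiscale-product mask.

    threshold_population selects which pixels enter the SD used for
    thresholding: the whole per-cell sub-image (``image``, the literal
    reading of "standard deviation of the filtered image") or only in-ROI
    pixels (``roi``), which matters when cells are cropped tightly.
    """

    kernel: tuple[float, ...] = B3_KERNEL
    n_scales: int = 3
    k: float = 3.0
    sign_convention: str = "standard"  # or "literal"
    boundary: str = "mirror"
    threshold_population: str = "image"  # or "roi"

    def __post_init__(self) -> None:
        kern = np.asarray(self.kernel, dtype=float)
        if kern.ndim != 1 or len(kern) % 2 != 1:
            raise ValueError("kernel must be 1-D with odd length")
        if not np.allclose(kern, kern[::-1]):
            raise ValueError("kernel must be symmetric")
        if not np.isclose(kern.sum(), 1.0):
            raise ValueError("kernel must sum to 1")
        if self.n_scales < 1:
            raise ValueError("n_scales must be >= 1")
        if self.k <= 0:
            raise ValueError("threshold multiplier k must be > 0")
        if self.sign_convention not in ("standard", "literal"):
            raise ValueError(f"unknown sign convention {self.sign_convention!r}")
        if self.boundary not in _BOUNDARY_MODES:
            raise ValueError(f"boundary must be one of {_BOUNDARY_MODES}")
        if self.threshold_population not in ("image", "roi"):
            raise ValueError("threshold_population must be 'image' or 'roi'")


@dataclass(frozen=True)
class WaveletStack:
    """Intermediate images of one decomposition: I_0..I_S, W_1..W_S, product."""

    smoothed: tuple[np.ndarray, ...]  # I_0 .. I_S
    planes: tuple[np.ndarray, ...]  # W_1 .. W_S, pre-clipping
    clipped: tuple[np.ndarray, ...]  # max(W_s, 0)
    filtered: np.ndarray  # product of clipped planes
    params: WaveletParams


@dataclass(frozen=True)
class CompartmentMask:
    """Binary compartment mask plus the parameters that produced it."""

    mask: np.ndarray
    params: WaveletParams
    threshold: float
    channel: str | None = None
    cell_id: int | None = None


def normalize_to_cell_mean(image: np.ndarray, roi: np.ndarray) -> np.ndarray:
    """Divide an image by its mean over the cell ROI (expression correction).

    The output's in-ROI mean is exactly 1, so downstream compartment means
    are automatically ratios to total cell intensity.
    """
    image = np.asarray(image, dtype=float)
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != image.shape:
        raise ValueError(f"ROI shape {roi.shape} does not match image {image.shape}")
    if not roi.any():
        raise EmptyRoiError("cell ROI is empty")
    mean = float(image[roi].mean())
    if mean <= 0:
        raise EmptyRoiError(f"cell ROI mean must be positive, got {mean}")
    return image / mean


def _dilated_kernel(kernel: tuple[float, ...], scale: int) -> np.ndarray:
    """Base kernel with 2^{s-1}-1 zeros interleaved between taps."""
    kern = np.asarray(kernel, dtype=float)
    step = 2 ** (scale - 1)
    out = np.zeros((len(kern) - 1) * step + 1)
    out[::step] = kern
    return out


def atrous_decompose(image: np.ndarray, params: WaveletParams | None = None) -> WaveletStack:
    """Undecimated wavelet decomposition by separable dilated smoothing."""
    if params is None:
        params = WaveletParams()
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("atrous_decompose expects a 2-D image")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    smoothed = [image]
    planes = []
    for s in range(1, params.n_scales + 1):
        kern = _dilated_kernel(params.kernel, s)
        if params.boundary != "wrap" and len(kern) > min(image.shape):
            raise ValueError(
                f"scale {s} kernel support ({len(kern)} px) exceeds the image "
                f"({min(image.shape)} px) with boundary {params.boundary!r}"
            )
        prev = smoothed[-1]
        sm = ndi.convolve1d(prev, kern, axis=0, mode=params.boundary)
        sm = ndi.convolve1d(sm, kern, axis=1, mode=params.boundary)
        smoothed.append(sm)
        if params.sign_convention == "standard":
            planes.append(prev - sm)
        else:  # literal
            planes.append(sm - prev)
    clipped = [np.maximum(w, 0.0) for w in planes]
    filtered = clipped[0].copy()
    for c in clipped[1:]:
        filtered *= c
    return WaveletStack(
        smoothed=tuple(smoothed),
        planes=tuple(planes),
        clipped=tuple(clipped),
        filtered=filtered,
        params=params,
    )


def compute_mask(
    stack: WaveletStack,
    roi: np.ndarray | None = None,
    channel: str | None = None,
    cell_id: int | None = None,
) -> CompartmentMask:
    """Threshold the multiscale product at k·SD of the filtered image.

    A zero-variance filtered image (e.g. a constant input) yields an empty
    mask with a warning rather than a failure.
    """
    params = stack.params
    filtered = stack.filtered
    if params.threshold_population == "roi":
        if roi is None:
            raise ValueError("threshold_population='roi' requires a ROI")
        population = filtered[np.asarray(roi, dtype=bool)]
    else:
        population = filtered.ravel()
    sd = float(population.std())
    threshold = params.k * sd
    if sd == 0:
        warnings.warn("filtered image has zero variance; mask is empty", stacklevel=2)
        mask = np.zeros_like(filtered, dtype=bool)
    else:
        mask = filtered > threshold
    if params.threshold_population == "roi" and roi is not None:
        mask = mask & np.asarray(roi, dtype=bool)
    return CompartmentMask(
        mask=mask, params=params, threshold=threshold, channel=channel, cell_id=cell_id
    )


def segment_compartment(
    image: np.ndarray,
    roi: np.ndarray,
    params: WaveletParams | None = None,
    channel: str | None = None,
    cell_id: int | None = None,
) -> CompartmentMask:
    """Normalize to the cell mean, decompose, and threshold in one call."""
    normalized = normalize_to_cell_mean(image, roi)
    stack = atrous_decompose(normalized, params)
    return compute_mask(stack, roi=roi, channel=channel, cell_id=cell_id)
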