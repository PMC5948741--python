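"""Image-based leaf-area quantification.

The ground-truth leaf-area procedure photographs detached leaves on a
white sheet with a 100 cm^2 black reference square.  Vegetation is
segmented by a linear combination of the RGB planes — by default the
genetic-algorithm-optimised coefficients R = -0.884, G = 1.262,
B = -0.311, with Excess Green (2G - R - B) available as a preset —
followed by Otsu's threshold on the resulting index.  Plants appear
bright in this index, so foreground is the above-threshold class.  The
reference square converts foreground pixel counts to cm^2.

The index image is kept real-valued (no 8-bit clipping): coefficients
with negative entries produce negative values whose clipping would
destroy the bimodality Otsu relies on.  The square is detected in the
raw image by darkness and squareness rather than through the vegetation
index, because the square is not green.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .errors import DegenerateInputError, DetectionError, ParameterError

__all__ = [
    "SegmentationCoefficients",
    "GA2018",
    "EXG",
    "PRESETS",
    "BinaryMask",
    "ReferenceSquare",
    "linear_index",
    "otsu_threshold",
    "binarize",
    "detect_reference_square",
    "leaf_area_from_image",
]


@dataclass(frozen=True)
class SegmentationCoefficients:
    """Coefficients of the linear RGB vegetation index."""

    cR: float
    cG: float
    cB: float

    def __post_init__(self):
        if self.cR == 0 and self.cG == 0 and self.cB == 0:
            raise ParameterError("coefficients must not all be zero")


#: Genetic-algorithm-optimised segmentation coefficients.
GA2018 = SegmentationCoefficients(-0.884, 1.262, -0.311)
#: Excess Green index, 2G - R - B.
EXG = SegmentationCoefficients(-1.0, 2.0, -1.0)

PRESETS = {"ga2018": GA2018, "exg": EXG}


@dataclass
class BinaryMask:
    """Foreground (plant) mask plus the threshold that produced it."""

    mask: np.ndarray
    threshold_used: float


@dataclass
class ReferenceSquare:
    """Detected reference square and the pixel scale it implies."""

    px_count: int
    px_per_cm2: float
    mask: np.ndarray
    bbox: tuple


def _check_image(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ParameterError("expected an (H, W, 3) RGB image")
    return img


def linear_index(
    image: np.ndarray, coeffs: SegmentationCoefficients = GA2018
) -> np.ndarray:
    """Real-valued index ``cR*R + cG*G + cB*B`` per pixel, unclipped."""
    img = _check_image(image).astype(np.float64)
    return coeffs.cR * img[..., 0] + coeffs.cG * img[..., 1] + coeffs.cB * img[..., 2]


def otsu_threshold(index_image: np.ndarray, n_bins: int = 256) -> float:
    """Otsu's threshold on an equal-width histogram of the index.

    The index range [min, max] is split into ``n_bins`` bins; the
    returned threshold is the interior bin edge maximising the
    between-class variance ``w0 * w1 * (mu0 - mu1)^2`` of the binned
    distribution, with ties broken toward the smallest edge.
    """
    vals = np.asarray(index_image, dtype=np.float64).ravel()
    if vals.size == 0:
        raise DegenerateInputError("empty index image")
    vmin, vmax = vals.min(), vals.max()
    if vmin == vmax:
        raise DegenerateInputError("constant image has no threshold")
    if n_bins < 2:
        raise ParameterError("n_bins must be >= 2")
    counts, edges = np.histogram(vals, bins=n_bins, range=(vmin, vmax))
    centers = 0.5 * (edges[:-1] + edges[1:])

    w = counts / counts.sum()
    cum_w = np.cumsum(w)
    cum_mu = np.cumsum(w * centers)
    mu_total = cum_mu[-1]

    # candidate thresholds: interior edges e_1 .. e_{n-1}; class 0 is
    # bins strictly below the edge
    w0 = cum_w[:-1]
    w1 = 1.0 - w0
    mu0_sum = cum_mu[:-1]
    valid = (w0 > 0) & (w1 > 0)
    sigma_b = np.full(n_bins - 1, -np.inf)
    mu0 = mu0_sum[valid] / w0[valid]
    mu1 = (mu_total - mu0_sum[valid]) / w1[valid]
    sigma_b[valid] = w0[valid] * w1[valid] * (mu0 - mu1) ** 2
    if not np.isfinite(sigma_b).any():
        raise DegenerateInputError("all mass in a single bin")
    best = int(np.argmax(sigma_b))  # argmax takes the first = smallest edge
    # edges separated only by empty bins score identically in exact
    # arithmetic (moving the edge past a zero-count bin changes no class
    # moment); walk to the smallest edge of such a plateau so the
    # smallest-threshold tie rule is honoured despite float roundoff
    while best > 0 and counts[best] == 0:
        best -= 1
    return float(edges[1 + best])


def binarize(index_image: np.ndarray, threshold: float) -> BinaryMask:
    """Foreground = pixels whose index exceeds the threshold."""
    idx = np.asarray(index_image, dtype=np.float64)
    return BinaryMask(mask=idx > threshold, threshold_used=float(threshold))


def detect_reference_square(
    image: np.ndarray,
    darkness_max: float = 40.0,
    squareness_min: float = 0.9,
    square_area_cm2: float = 100.0,
) -> ReferenceSquare:
    """Find the black reference square and derive pixels per cm^2.

    Pixels whose maximum channel is at most ``darkness_max`` are
    candidates; among their 4-connected components, the largest one
    whose bounding-box fill ratio reaches ``squareness_min`` is the
    square (ties: higher fill ratio, then top-left position).  Thin
    dark objects such as scale bars fail the fill-ratio test.
    """
    img = _check_image(image)
    dark = img.max(axis=2) <= darkness_max
    labels = cc_label(dark, connectivity=1)
    regions = regionprops(labels)
    candidates = []
    for r in regions:
        fill = r.area / ((r.bbox[2] - r.bbox[0]) * (r.bbox[3] - r.bbox[1]))
        if fill >= squareness_min:
            candidates.append((-r.area, -fill, r.bbox[0], r.bbox[1], r))
    if not candidates:
        raise DetectionError("no dark, square-like component found")
    candidates.sort(key=lambda t: t[:4])
    region = candidates[0][4]
    mask = labels == region.label
    return ReferenceSquare(
        px_count=int(region.area),
        px_per_cm2=float(region.area / square_area_cm2),
        mask=mask,
        bbox=tuple(region.bbox),
    )


def leaf_area_from_image(
    image: np.ndarray,
    coeffs: SegmentationCoefficients = GA2018,
    exclude_square: bool = True,
    *,
    n_bins: int = 256,
    darkness_max: float = 40.0,
    squareness_min: float = 0.9,
    square_area_cm2: float = 100.0,
    details: bool = False,
):
    """Leaf area (cm^2) of a detached-leaf layout photograph.

    Pipeline: detect the reference square, compute the vegetation index,
    threshold it with Otsu (the square's pixels are withheld from the
    histogram — the square is a calibration object, not scene content),
    and divide the foreground pixel count by the square-derived pixel
    scale.  A layout with no vegetation leaves the withheld index
    constant (plain background), which reads as zero leaf area.
    """
    img = _check_image(image)
    square = detect_reference_square(
        img, darkness_max=darkness_max, squareness_min=squareness_min,
        square_area_cm2=square_area_cm2,
    )
    idx = linear_index(img, coeffs)
    sample = idx[~square.mask] if exclude_square else idx
    try:
        threshold = otsu_threshold(sample, n_bins=n_bins)
    except DegenerateInputError:
        # uniform background and no vegetation
        result = (0.0, None, square)
        return result if details else 0.0
    fg = binarize(idx, threshold)
    count = np.count_nonzero(fg.mask & ~square.mask)
    area = count / square.px_per_cm2
    if details:
        return float(area), fg, square
    return float(area)
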