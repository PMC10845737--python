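"""RGB histogram construction and distance analysis.

Images from different laboratories and slide scanners differ in stain hue,
contrast and color rendering before any algorithm sees them. A compact way
to quantify that domain shift is the per-channel distribution of 8-bit
pixel values: each image yields three 256-bin histograms (R, G, B), each
normalized to sum to 1 so that bin v holds the fraction of pixels with
value v. Case-level histograms average the per-image histograms
(image-unweighted). Two histograms are compared with the squared Euclidean
(L2) distance summed over all 768 bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Optional, Sequence, Tuple

import numpy as np

from .records import ValidationError

N_BINS = 256
_NORM_ATOL = 1e-8


@dataclass(frozen=True)
class RGBHistogram:
    """Per-channel 256-bin pixel-value distribution.

    ``bins`` has shape (3, 256) in R, G, B order; after normalization each
    row sums to 1. ``source_count`` tracks how many images were aggregated
    into this histogram.
    """

    bins: np.ndarray
    source_count: int = 1

    def __post_init__(self) -> None:
        bins = np.asarray(self.bins, dtype=np.float64)
        if bins.shape != (3, N_BINS):
            raise ValidationError(f"histogram bins must be (3, {N_BINS}), got {bins.shape}")
        if (bins < 0).any():
            raise ValidationError("histogram bins must be non-negative")
        if self.source_count < 1:
            raise ValidationError("source_count must be >= 1")
        object.__setattr__(self, "bins", bins)

    @property
    def is_normalized(self) -> bool:
        return bool(np.allclose(self.bins.sum(axis=1), 1.0, atol=_NORM_ATOL))


class HistogramDistance(NamedTuple):
    """Squared L2 distance, total and split by channel (R, G, B)."""

    value: float
    per_channel: Tuple[float, float, float]


class ChannelSpread(NamedTuple):
    """Concentration summary of one channel's pixel-value distribution."""

    peak_height: float
    occupied_bins: int
    std_of_values: float


def _check_rgb8(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValidationError(f"expected an H x W x 3 RGB image, got shape {image.shape}")
    if image.dtype != np.uint8:
        raise ValidationError(f"expected 8-bit (uint8) pixels, got dtype {image.dtype}")
    return image


def compute_histogram(
    image: np.ndarray, mask: Optional[np.ndarray] = None
) -> RGBHistogram:
    """Normalized per-channel histogram of an 8-bit RGB image.

    ``mask``, if given, is a boolean H x W raster selecting the pixels to
    count (it must select at least one).
    """
    image = _check_rgb8(image)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != image.shape[:2]:
            raise ValidationError(
                f"mask shape {mask.shape} does not match image {image.shape[:2]}"
            )
        if not mask.any():
            raise ValidationError("mask selects no pixels")
        pixels = image[mask]
    else:
        pixels = image.reshape(-1, 3)
    bins = np.stack(
        [np.bincount(pixels[:, c], minlength=N_BINS) for c in range(3)]
    ).astype(np.float64)
    return RGBHistogram(bins=bins / pixels.shape[0], source_count=1)


def background_mask(image: np.ndarray, luminance_threshold: int = 240) -> np.ndarray:
    """Boolean mask excluding near-white background pixels.

    Tissue-free glass scans as near-white; pixels whose mean channel value
    reaches ``luminance_threshold`` are masked out. Off by default in all
    pipelines -- histograms include background unless explicitly masked.
    """
    image = _check_rgb8(image)
    return image.mean(axis=2) < luminance_threshold


def aggregate_histograms(histograms: Sequence[RGBHistogram]) -> RGBHistogram:
    """Unweighted per-bin mean of normalized histograms.

    Each input image (or prior aggregate) contributes equally regardless
    of pixel count; the result remains normalized.
    """
    histograms = list(histograms)
    if not histograms:
        raise ValidationError("cannot aggregate an empty histogram collection")
    for h in histograms:
        if not h.is_normalized:
            raise ValidationError("all histograms must be normalized before aggregation")
    bins = np.mean([h.bins for h in histograms], axis=0)
    return RGBHistogram(bins=bins, source_count=sum(h.source_count for h in histograms))


def histogram_distance(h1: RGBHistogram, h2: RGBHistogram) -> HistogramDistance:
    """Squared Euclidean distance between two normalized histograms.

    Computed per channel as ``sum_v (h1[c, v] - h2[c, v])^2`` and summed
    over the three channels (768 bins total, no channel averaging).
    Symmetric, non-negative, and zero iff the histograms are identical.
    """
    for h in (h1, h2):
        if not h.is_normalized:
            raise ValidationError("histogram_distance requires normalized histograms")
    per_channel = ((h1.bins - h2.bins) ** 2).sum(axis=1)
    return HistogramDistance(
        value=float(per_channel.sum()),
        per_channel=tuple(float(x) for x in per_channel),
    )


def percent_increase(reference: float, comparison: float) -> float:
    """Percent change of ``comparison`` relative to ``reference`` (> 0)."""
    if reference <= 0:
        raise ValidationError(f"reference must be > 0, got {reference!r}")
    return 100.0 * (comparison - reference) / reference


def spread_summary(h: RGBHistogram) -> Tuple[ChannelSpread, ChannelSpread, ChannelSpread]:
    """Quantify how concentrated each channel's distribution is.

    A narrow-rendering scanner produces high peaks over few occupied bins
    and a small value standard deviation; a scanner that spreads color
    values produces the opposite pattern. ``std_of_values`` is the standard
    deviation of the pixel-value random variable the histogram encodes,
    i.e. sqrt(sum v^2 p(v) - (sum v p(v))^2).
    """
    if not h.is_normalized:
        raise ValidationError("spread_summary requires a normalized histogram")
    values = np.arange(N_BINS, dtype=np.float64)
    out = []
    for c in range(3):
        p = h.bins[c]
        mean = float(p @ values)
        var = max(float(p @ values**2) - mean**2, 0.0)
        out.append(
            ChannelSpread(
                peak_height=float(p.max()),
                occupied_bins=int((p > 0).sum()),
                std_of_values=float(np.sqrt(var)),
            )
        )
    return tuple(out)
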