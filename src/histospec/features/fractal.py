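"""Segmentation-based fractal texture analysis (mSFTA) and box counting.

The masked grayscale region is decomposed with a 4-threshold multi-level
Otsu into two families of binary images — the upper sets {I > t_i} and the
contiguous band sets {t_i < I <= t_{i+1}} (the last band is capped by the
maximum gray value), 8 images in total.  From each binary image the boundary
(region minus its 4-connected erosion) and the skeleton (medial-axis
thinning) are extracted; every one of the 16 derived images contributes its
box-counting fractal dimension and pixel count, and the corresponding
grayscale-masked image its mean intensity and Shannon entropy: 64 features.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_multiotsu
from skimage.morphology import skeletonize

from ..config import TextureParams
from .base import FeatureBlock, shannon_entropy

__all__ = ["fractal_dimension", "msfta_binary_images", "msfta_features",
           "MSFTA_FEATURE_COUNT"]

DEFAULT_PARAMS = TextureParams()
MSFTA_FEATURE_COUNT = 64

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def _box_sizes(limit: int) -> list[int]:
    """Log-spaced box sizes {1, 2, 4} x 3^k up to ``limit``.

    A ladder mixing small powers of 2 with powers of 3 stays dense in log
    scale while sampling triadic self-similar patterns at their natural
    scales, which plain dyadic ladders systematically miss.
    """
    sizes = set()
    for a in (1, 2, 4):
        b = a
        while b <= limit:
            sizes.add(b)
            b *= 3
    return sorted(sizes)


def fractal_dimension(binary: np.ndarray) -> tuple[float, bool]:
    """Box-counting fractal dimension of a binary pattern.

    The pattern is cropped to its bounding box; N(s) counts occupied boxes
    on an s x s grid for a log-spaced ladder of box sizes, and the estimate
    is the least-squares slope of log N(s) against log(1/s).  An empty
    image yields (0, invalid).
    """
    binary = np.asarray(binary, dtype=bool)
    if not binary.any():
        return 0.0, False
    ys, xs = np.nonzero(binary)
    sub = binary[ys.min() : ys.max() + 1, xs.min() : xs.max() + 1]
    h, w = sub.shape
    sizes = []
    counts = []
    for s in _box_sizes(max(2, max(h, w) // 3)):
        nh, nw = -(-h // s), -(-w // s)
        padded = np.zeros((nh * s, nw * s), dtype=bool)
        padded[:h, :w] = sub
        n = int(padded.reshape(nh, s, nw, s).any(axis=(1, 3)).sum())
        sizes.append(s)
        counts.append(n)
    if len(sizes) < 2:
        return 0.0, False
    slope = np.polyfit(np.log(1.0 / np.asarray(sizes, float)), np.log(counts), 1)[0]
    return float(slope), True


def msfta_binary_images(
    gray: np.ndarray, mask: np.ndarray, params: TextureParams = DEFAULT_PARAMS
) -> list[np.ndarray]:
    """The 2 * n_t threshold decomposition of the masked region.

    With fewer distinct gray levels than thresholds, duplicate thresholds
    collapse and the affected images come back empty.
    """
    gray = np.asarray(gray, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    vals = gray[mask]
    n_t = params.n_thresholds
    distinct = np.unique(vals)
    if distinct.size < 2:
        raise ValueError("need at least 2 gray levels for multi-level Otsu")
    classes = min(n_t + 1, distinct.size)
    thresholds = list(
        threshold_multiotsu(vals, classes=classes, nbins=params.otsu_bins)
    )
    while len(thresholds) < n_t:  # degenerate input: collapse duplicates
        thresholds.append(thresholds[-1])
    upper = [mask & (gray > t) for t in thresholds]
    bounds = thresholds + [float(vals.max())]
    bands = [
        mask & (gray > bounds[i]) & (gray <= bounds[i + 1]) for i in range(n_t)
    ]
    return upper + bands


def _boundary(binary: np.ndarray) -> np.ndarray:
    return binary & ~ndi.binary_erosion(binary, structure=_CROSS)


def msfta_features(
    gray: np.ndarray, mask: np.ndarray, params: TextureParams = DEFAULT_PARAMS
) -> FeatureBlock:
    gray = np.asarray(gray, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    n_t = params.n_thresholds
    names = [
        f"msfta.b{i}.{derived}.{feat}"
        for i in range(2 * n_t)
        for derived in ("edge", "skeleton")
        for feat in ("fractal_dimension", "pixel_count", "mean_intensity", "entropy")
    ]
    if mask.sum() == 0 or np.unique(gray[mask]).size < 2:
        return FeatureBlock.invalid(names)
    binaries = msfta_binary_images(gray, mask, params)
    values = np.zeros(len(names))
    valid = np.zeros(len(names), dtype=bool)
    pos = 0
    for binary in binaries:
        for derived_img in (_boundary(binary), skeletonize(binary)):
            fd, fd_ok = fractal_dimension(derived_img)
            npix = int(derived_img.sum())
            values[pos], valid[pos] = fd, fd_ok
            values[pos + 1], valid[pos + 1] = float(npix), True
            if npix:
                region = gray[derived_img]
                values[pos + 2], valid[pos + 2] = float(region.mean()), True
                values[pos + 3] = shannon_entropy(
                    region, bins=params.entropy_bins, value_range=(0.0, 256.0)
                )
                valid[pos + 3] = True
            pos += 4
    block = FeatureBlock(names, values, valid)
    assert len(block) == MSFTA_FEATURE_COUNT
    return block
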