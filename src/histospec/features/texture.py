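"""Texture features of a masked grayscale compartment: GLCM (19), Gabor
filter bank (56) and rotation-invariant local binary patterns (10).

GLCM: the region is min-max scaled to 64 gray levels; 16 co-occurrence
matrices (4 directions x distances 1-4, symmetric counts, pairs straddling
the mask dropped) are normalized to probabilities and averaged; 13 Haralick
statistics plus autocorrelation, cluster prominence, cluster shade,
dissimilarity, inverse difference and maximum probability are read off the
averaged matrix.

Gabor: 28 complex filters (orientations {0, pi/4, pi/2, 3pi/4} x radial
frequencies 2*sqrt(2) .. 128*sqrt(2) cycles per image width, doubling, with
a ~1-octave Gaussian envelope); entropy and energy of each magnitude
response over the mask.

LBP: uniform rotation-invariant patterns, P=8 / R=1, as a 10-bin proportion
histogram over interior mask pixels.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.fft import fft2, ifft2, next_fast_len
from skimage.feature import local_binary_pattern
from skimage.filters import gabor_kernel
from skimage.morphology import disk, erosion

from ..config import TextureParams
from .base import FeatureBlock, shannon_entropy

__all__ = [
    "quantize",
    "cooccurrence_matrix",
    "averaged_glcm",
    "glcm_features",
    "gabor_features",
    "lbp_features",
    "GLCM_FEATURE_COUNT",
    "GABOR_FEATURE_COUNT",
    "LBP_FEATURE_COUNT",
]

DEFAULT_PARAMS = TextureParams()

GLCM_FEATURE_COUNT = 19
GABOR_FEATURE_COUNT = 56
LBP_FEATURE_COUNT = 10

#: horizontal, vertical, right diagonal, left diagonal (row, col) unit offsets
_DIRECTIONS = ((0, 1), (1, 0), (1, 1), (1, -1))

_GLCM_NAMES = [
    "glcm.asm",
    "glcm.contrast",
    "glcm.correlation",
    "glcm.variance",
    "glcm.idm",
    "glcm.sum_average",
    "glcm.sum_variance",
    "glcm.sum_entropy",
    "glcm.entropy",
    "glcm.difference_variance",
    "glcm.difference_entropy",
    "glcm.imc1",
    "glcm.imc2",
    "glcm.autocorrelation",
    "glcm.cluster_prominence",
    "glcm.cluster_shade",
    "glcm.dissimilarity",
    "glcm.inverse_difference",
    "glcm.max_probability",
]


def quantize(gray: np.ndarray, mask: np.ndarray, levels: int) -> np.ndarray:
    """Min-max scale masked pixels into ``levels`` integer gray levels."""
    gray = np.asarray(gray, dtype=float)
    q = np.zeros(gray.shape, dtype=np.int64)
    vals = gray[mask]
    lo, hi = vals.min(), vals.max()
    if hi > lo:
        q[mask] = np.minimum(
            ((gray[mask] - lo) / (hi - lo) * levels).astype(np.int64), levels - 1
        )
    return q


def cooccurrence_matrix(
    quantized: np.ndarray, mask: np.ndarray, offset: tuple[int, int], levels: int
) -> np.ndarray:
    """Symmetric co-occurrence counts at one offset; masked pairs dropped."""
    dr, dc = offset
    h, w = quantized.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    a = quantized[r0:r1, c0:c1]
    b = quantized[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    ok = mask[r0:r1, c0:c1] & mask[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    counts = np.bincount(
        (a[ok] * levels + b[ok]).ravel(), minlength=levels * levels
    ).reshape(levels, levels)
    return (counts + counts.T).astype(float)


def averaged_glcm(
    gray: np.ndarray, mask: np.ndarray, params: TextureParams = DEFAULT_PARAMS
) -> np.ndarray:
    """Average of the 16 probability-normalized co-occurrence matrices."""
    q = quantize(gray, mask, params.glcm_levels)
    mats = []
    for d in params.glcm_distances:
        for dr, dc in _DIRECTIONS:
            m = cooccurrence_matrix(q, mask, (dr * d, dc * d), params.glcm_levels)
            total = m.sum()
            if total > 0:
                mats.append(m / total)
    if not mats:
        raise ValueError("no valid pixel pairs under the mask")
    return np.mean(mats, axis=0)


def glcm_features(
    gray: np.ndarray, mask: np.ndarray, params: TextureParams = DEFAULT_PARAMS
) -> FeatureBlock:
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 2:
        return FeatureBlock.invalid(list(_GLCM_NAMES))
    try:
        p = averaged_glcm(gray, mask, params)
    except ValueError:
        return FeatureBlock.invalid(list(_GLCM_NAMES))
    levels = p.shape[0]
    i = np.arange(levels)[:, None].astype(float)
    j = np.arange(levels)[None, :].astype(float)
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((np.arange(levels) * px).sum())
    mu_y = float((np.arange(levels) * py).sum())
    sd_x = float(np.sqrt(((np.arange(levels) - mu_x) ** 2 * px).sum()))
    sd_y = float(np.sqrt(((np.arange(levels) - mu_y) ** 2 * py).sum()))

    # distributions of i+j and |i-j|
    k_sum = np.arange(2 * levels - 1)
    p_sum = np.zeros(2 * levels - 1)
    np.add.at(p_sum, (i + j).astype(int).ravel(), p.ravel())
    k_diff = np.arange(levels)
    p_diff = np.zeros(levels)
    np.add.at(p_diff, np.abs(i - j).astype(int).ravel(), p.ravel())

    def _ent(q: np.ndarray) -> float:
        q = q[q > 0]
        return float(-(q * np.log2(q)).sum())

    values = np.zeros(GLCM_FEATURE_COUNT)
    valid = np.ones(GLCM_FEATURE_COUNT, dtype=bool)
    values[0] = float((p**2).sum())                               # ASM / energy
    values[1] = float(((i - j) ** 2 * p).sum())                   # contrast
    if sd_x > 0 and sd_y > 0:
        values[2] = float(((i * j * p).sum() - mu_x * mu_y) / (sd_x * sd_y))
    else:
        valid[2] = False                                          # correlation
    values[3] = float(((i - mu_x) ** 2 * p).sum())                # variance
    values[4] = float((p / (1.0 + (i - j) ** 2)).sum())           # IDM
    values[5] = float((k_sum * p_sum).sum())                      # sum average
    values[6] = float(((k_sum - values[5]) ** 2 * p_sum).sum())   # sum variance
    values[7] = _ent(p_sum)                                       # sum entropy
    values[8] = _ent(p.ravel())                                   # entropy
    mu_diff = float((k_diff * p_diff).sum())
    values[9] = float(((k_diff - mu_diff) ** 2 * p_diff).sum())   # diff variance
    values[10] = _ent(p_diff)                                     # diff entropy
    hx, hy, hxy = _ent(px), _ent(py), values[8]
    pij = px[:, None] * py[None, :]
    nz = (p > 0) & (pij > 0)
    hxy1 = float(-(p[nz] * np.log2(pij[nz])).sum())
    nz2 = pij > 0
    hxy2 = float(-(pij[nz2] * np.log2(pij[nz2])).sum())
    if max(hx, hy) > 0:
        values[11] = (hxy - hxy1) / max(hx, hy)                   # IMC1
    else:
        valid[11] = False
    values[12] = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))  # IMC2
    values[13] = float((i * j * p).sum())                         # autocorrelation
    values[14] = float(((i + j - mu_x - mu_y) ** 4 * p).sum())    # cluster prominence
    values[15] = float(((i + j - mu_x - mu_y) ** 3 * p).sum())    # cluster shade
    values[16] = float((np.abs(i - j) * p).sum())                 # dissimilarity
    values[17] = float((p / (1.0 + np.abs(i - j))).sum())         # inverse difference
    values[18] = float(p.max())                                   # max probability
    return FeatureBlock(list(_GLCM_NAMES), values, valid)


@lru_cache(maxsize=64)
def _cached_kernel(frequency: float, theta: float, bandwidth: float) -> np.ndarray:
    return gabor_kernel(frequency=frequency, theta=theta, bandwidth=bandwidth)


def gabor_filter_bank(
    image_width: int, params: TextureParams = DEFAULT_PARAMS
) -> list[tuple[str, np.ndarray]]:
    """The 28 complex kernels; radial frequencies are cycles per image width."""
    bank = []
    for o in range(params.gabor_orientations):
        theta = o * np.pi / params.gabor_orientations
        for k in range(params.gabor_n_frequencies):
            u0 = params.gabor_base_frequency * 2.0**k
            freq = u0 / image_width
            kern = _cached_kernel(round(freq, 10), round(theta, 10), params.gabor_bandwidth)
            bank.append((f"o{o}_f{k}", kern))
    return bank


_KERNEL_FFT_CACHE: dict = {}


def _kernel_fft(kern_key: tuple, kern: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    key = (kern_key, shape)
    if key not in _KERNEL_FFT_CACHE:
        kh, kw = kern.shape
        padded = np.zeros(shape, dtype=complex)
        padded[:kh, :kw] = kern
        _KERNEL_FFT_CACHE[key] = fft2(padded)
    return _KERNEL_FFT_CACHE[key]


def gabor_features(
    gray: np.ndarray, mask: np.ndarray, params: TextureParams = DEFAULT_PARAMS
) -> FeatureBlock:
    gray = np.asarray(gray, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    bank = gabor_filter_bank(gray.shape[1], params)
    names = [f"gabor.{tag}.{stat}" for tag, _ in bank for stat in ("entropy", "energy")]
    if not mask.any():
        return FeatureBlock.invalid(names)
    # masked-out pixels take the region mean, and the DC level is removed so
    # border padding cannot leak energy into the responses (a constant region
    # then has exactly zero magnitude everywhere)
    fill = gray[mask].mean()
    img = np.where(mask, gray, fill) - fill
    h, w = img.shape
    kmax_h = max(k.shape[0] for _, k in bank)
    kmax_w = max(k.shape[1] for _, k in bank)
    shape = (next_fast_len(h + kmax_h - 1), next_fast_len(w + kmax_w - 1))
    img_fft = fft2(img, s=shape)
    values = np.zeros(len(names))
    valid = np.ones(len(names), dtype=bool)
    for idx, (tag, kern) in enumerate(bank):
        resp = ifft2(img_fft * _kernel_fft((tag, gray.shape[1]), kern, shape))
        # crop the 'same'-convolution window
        kh, kw = kern.shape
        r0, c0 = (kh - 1) // 2, (kw - 1) // 2
        mag = np.abs(resp[r0 : r0 + h, c0 : c0 + w])[mask]
        values[2 * idx] = shannon_entropy(mag, bins=params.entropy_bins)
        values[2 * idx + 1] = float(np.mean(mag**2))
    return FeatureBlock(names, values, valid)


def lbp_features(
    gray: np.ndarray, mask: np.ndarray, params: TextureParams = DEFAULT_PARAMS
) -> FeatureBlock:
    """10-bin uniform rotation-invariant LBP histogram over interior pixels."""
    gray = np.asarray(gray, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    n_bins = params.lbp_points + 2
    names = [f"lbp.bin{i:02d}" for i in range(n_bins)]
    interior = erosion(mask, disk(params.lbp_radius))
    interior[: params.lbp_radius, :] = False
    interior[-params.lbp_radius :, :] = False
    interior[:, : params.lbp_radius] = False
    interior[:, -params.lbp_radius :] = False
    if not interior.any():
        return FeatureBlock.invalid(names)
    codes = local_binary_pattern(
        np.clip(np.round(gray), 0, 255).astype(np.uint8),
        P=params.lbp_points,
        R=params.lbp_radius,
        method="uniform",
    )
    hist = np.bincount(codes[interior].astype(int), minlength=n_bins).astype(float)
    return FeatureBlock(names, hist / hist.sum(), np.ones(n_bins, dtype=bool))
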