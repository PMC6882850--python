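"""Color features of a masked H&E compartment (71 scalars).

White pixels (luminance Y > 180 on the 8-bit YCbCr scale) are removed
first.  The remaining pixels yield:

* transformed-RGB histograms — each channel standardized to
  (X - mu_X) / sigma_X over the region, which makes the block scale- and
  shift-invariant with respect to light intensity, then binned into 16
  proportions per channel (48 features);
* the red-blue intensity difference — a 16-bin proportion histogram plus
  7 statistical measures (23 features).
"""

from __future__ import annotations

import numpy as np

from ..config import ColorParams
from .base import STAT_NAMES, FeatureBlock, concat_blocks, seven_stats

__all__ = ["color_features", "COLOR_FEATURE_COUNT"]

COLOR_FEATURE_COUNT = 71
DEFAULT_PARAMS = ColorParams()

_CHANNELS = ("r", "g", "b")


def _names(params: ColorParams) -> list[str]:
    names = [
        f"color.trgb_{ch}.bin{i:02d}" for ch in _CHANNELS for i in range(params.n_bins)
    ]
    names += [f"color.rbdiff.bin{i:02d}" for i in range(params.n_bins)]
    names += [f"color.rbdiff.{s}" for s in STAT_NAMES]
    return names


def _luma(rgb: np.ndarray) -> np.ndarray:
    # 8-bit YCbCr luminance (BT.601 studio swing): Y in [16, 235]
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    return 16.0 + (65.481 * r + 128.553 * g + 24.966 * b) / 255.0


def color_features(
    rgb: np.ndarray, mask: np.ndarray, params: ColorParams = DEFAULT_PARAMS
) -> FeatureBlock:
    rgb = np.asarray(rgb, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    names = _names(params)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB image")
    keep = mask & (_luma(rgb) <= params.y_cutoff)
    pixels = rgb[keep]
    if pixels.shape[0] == 0:
        return FeatureBlock.invalid(names)

    blocks: list[FeatureBlock] = []
    edges = np.linspace(-params.clip, params.clip, params.n_bins + 1)
    for c, ch in enumerate(_CHANNELS):
        x = pixels[:, c]
        mu, sigma = x.mean(), x.std()
        bin_names = [f"color.trgb_{ch}.bin{i:02d}" for i in range(params.n_bins)]
        if sigma == 0:
            # all mass lands in the central bin, flagged as degenerate
            hist = np.zeros(params.n_bins)
            hist[params.n_bins // 2] = 1.0
            blocks.append(FeatureBlock(bin_names, hist, np.zeros(params.n_bins, bool)))
            continue
        z = np.clip((x - mu) / sigma, -params.clip, np.nextafter(params.clip, -np.inf))
        hist, _ = np.histogram(z, bins=edges)
        blocks.append(
            FeatureBlock(bin_names, hist / x.size, np.ones(params.n_bins, bool))
        )

    diff = pixels[:, 0] - pixels[:, 2]
    lo, hi = params.rb_range
    hist, _ = np.histogram(
        np.clip(diff, lo, np.nextafter(hi, lo)), bins=params.n_bins, range=(lo, hi)
    )
    blocks.append(
        FeatureBlock(
            [f"color.rbdiff.bin{i:02d}" for i in range(params.n_bins)],
            hist / diff.size,
            np.ones(params.n_bins, bool),
        )
    )
    stats, stats_valid = seven_stats(diff)
    blocks.append(
        FeatureBlock([f"color.rbdiff.{s}" for s in STAT_NAMES], stats, stats_valid)
    )
    out = concat_blocks(blocks)
    assert len(out) == COLOR_FEATURE_COUNT
    return out
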