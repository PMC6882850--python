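"""The 712-feature bank extracted from one H&E crop.

Each of the three compartments — epithelium, cytoplasm, nuclei — yields 71
color and 149 texture features (GLCM 19, Gabor 56, LBP 10, mSFTA 64); the
nuclei compartment additionally yields 44 morphometric and 8 topology
features: 220 + 220 + 272 = 712.  Names follow
``{compartment}.{family}.{feature}`` and keep a stable order across runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..config import ColorParams, TextureParams
from ..segmentation import TissueMasks
from .base import FeatureBlock, concat_blocks
from .color import COLOR_FEATURE_COUNT, color_features
from .fractal import MSFTA_FEATURE_COUNT, fractal_dimension, msfta_features
from .morphometry import (
    MORPHOMETRY_FEATURE_COUNT,
    TOPOLOGY_FEATURE_COUNT,
    morphometric_features,
    topology_features,
)
from .texture import (
    GABOR_FEATURE_COUNT,
    GLCM_FEATURE_COUNT,
    LBP_FEATURE_COUNT,
    gabor_features,
    glcm_features,
    lbp_features,
)

__all__ = [
    "FeatureVector",
    "assemble_features",
    "texture_features",
    "luminance",
    "color_features",
    "glcm_features",
    "gabor_features",
    "lbp_features",
    "msfta_features",
    "fractal_dimension",
    "morphometric_features",
    "topology_features",
    "TOTAL_FEATURE_COUNT",
    "TEXTURE_FEATURE_COUNT",
    "COLOR_FEATURE_COUNT",
]

TEXTURE_FEATURE_COUNT = (
    GLCM_FEATURE_COUNT + GABOR_FEATURE_COUNT + LBP_FEATURE_COUNT + MSFTA_FEATURE_COUNT
)
COMPARTMENT_COUNTS = {
    "epithelium": COLOR_FEATURE_COUNT + TEXTURE_FEATURE_COUNT,
    "cytoplasm": COLOR_FEATURE_COUNT + TEXTURE_FEATURE_COUNT,
    "nuclei": COLOR_FEATURE_COUNT
    + TEXTURE_FEATURE_COUNT
    + MORPHOMETRY_FEATURE_COUNT
    + TOPOLOGY_FEATURE_COUNT,
}
TOTAL_FEATURE_COUNT = sum(COMPARTMENT_COUNTS.values())


@dataclass
class FeatureVector:
    """712 named, compartment-tagged scalars with per-feature validity."""

    names: list[str]
    values: np.ndarray
    valid: np.ndarray

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"value": self.values, "valid": self.valid}, index=self.names
        )

    def __len__(self) -> int:
        return self.values.size


def luminance(rgb: np.ndarray) -> np.ndarray:
    """ITU BT.601 luminance of an RGB image, on the 8-bit scale."""
    rgb = np.asarray(rgb, dtype=float)
    return 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]


def texture_features(
    gray: np.ndarray,
    mask: np.ndarray,
    params: TextureParams | None = None,
) -> FeatureBlock:
    """The 149-feature texture block on a masked grayscale image."""
    params = params or TextureParams()
    block = concat_blocks(
        [
            glcm_features(gray, mask, params),
            gabor_features(gray, mask, params),
            lbp_features(gray, mask, params),
            msfta_features(gray, mask, params),
        ]
    )
    if len(block) != TEXTURE_FEATURE_COUNT:
        raise AssertionError(
            f"texture block has {len(block)} features, expected {TEXTURE_FEATURE_COUNT}"
        )
    return block


def assemble_features(
    rgb: np.ndarray,
    masks: TissueMasks,
    color_params: ColorParams | None = None,
    texture_params: TextureParams | None = None,
) -> FeatureVector:
    """Extract the full 712-feature bank for one crop.

    Block lengths are asserted at runtime; a wrong length is a contract
    violation, not a degradable condition.
    """
    color_params = color_params or ColorParams()
    texture_params = texture_params or TextureParams()
    gray = luminance(rgb)
    compartments = {
        "epithelium": np.asarray(masks.epithelium, dtype=bool),
        "cytoplasm": np.asarray(masks.cytoplasm, dtype=bool),
        "nuclei": masks.nuclei_labels > 0,
    }
    blocks: list[FeatureBlock] = []
    for comp, mask in compartments.items():
        comp_blocks = [
            color_features(rgb, mask, color_params).prefixed(f"{comp}."),
            texture_features(gray, mask, texture_params).prefixed(f"{comp}."),
        ]
        if comp == "nuclei":
            comp_blocks.append(
                morphometric_features(masks.nuclei_labels, masks.cytoplasm).prefixed(
                    "nuclei."
                )
            )
            import skimage.measure as _measure

            centroids = np.array(
                [r.centroid for r in _measure.regionprops(masks.nuclei_labels)]
            ).reshape(-1, 2)
            comp_blocks.append(topology_features(centroids).prefixed("nuclei."))
        comp_block = concat_blocks(comp_blocks)
        if len(comp_block) != COMPARTMENT_COUNTS[comp]:
            raise AssertionError(
                f"{comp} block has {len(comp_block)} features, "
                f"expected {COMPARTMENT_COUNTS[comp]}"
            )
        blocks.append(comp_block)
    full = concat_blocks(blocks)
    if len(full) != TOTAL_FEATURE_COUNT:
        raise AssertionError(
            f"feature vector has {len(full)} entries, expected {TOTAL_FEATURE_COUNT}"
        )
    return FeatureVector(full.names, full.values, full.valid)
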