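"""Central configuration for the tongue-neoplasia image-analysis pipeline.

Every numeric constant of the analysis (pixel-size survival thresholds,
solidity cutoffs, red/blue color-ratio cutpoints, gray-level counts, filter
bank sizes, hyperparameter grids, significance level) lives here exactly
once.  Stage functions take a parameter object defaulting to these values,
so a single :class:`RunConfig` plus a seed fully determines every artifact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
import yaml

__all__ = [
    "SegmentationParams",
    "ColorParams",
    "TextureParams",
    "GridConfig",
    "AssociationParams",
    "RunConfig",
    "load_config",
    "save_config",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Thresholds of the epithelium / nuclei / cytoplasm segmentation."""

    #: disk radius of the edge-preserving (closing + median) red-channel smoother
    median_radius: int = 13
    #: disk radius of the morphological opening that removes spurious regions
    epithelium_open_radius: int = 5
    #: dilation radius applied to the hole-filled raw nuclei mask
    dilate_radius: int = 2
    #: opening radius applied after dilation
    open_radius: int = 4
    #: components smaller than this are dropped after the morphological cleanup
    min_area_refine: int = 50
    #: area above which a low-solidity component is a "large" nuclear cluster
    large_cluster_area: int = 500
    #: area above which a low-solidity component is a "small" nuclear cluster
    small_cluster_area: int = 150
    #: solidity below which a component is considered a cluster of nuclei
    solidity_threshold: float = 0.9
    #: mean red/blue ratio above which a candidate is a false detection
    rb_ratio_false: float = 1.2
    #: mean red/blue ratio above which a final nucleus is removed
    rb_ratio_final: float = 1.0
    #: survival threshold after the large-cluster splitting stage
    min_area_large_stage: int = 25
    #: survival threshold after each pass of the small-cluster stage
    min_area_small_stage: int = 50
    #: number of repetitions of the watershed-based small-cluster procedure
    small_stage_repeats: int = 2
    #: hard cap on the repeated k-means large-cluster loop
    iteration_cap: int = 20
    #: k-means restarts (Euclidean distance on RGB)
    kmeans_restarts: int = 10
    #: minimum distance between watershed markers (pixels)
    marker_min_distance: int = 5


@dataclass(frozen=True)
class ColorParams:
    """Color-feature extraction settings."""

    #: luminance (Y) cutoff above which pixels are treated as white and dropped
    y_cutoff: float = 180.0
    #: bins per channel of the transformed-RGB histogram
    n_bins: int = 16
    #: standardized values are histogrammed on [-clip, clip]
    clip: float = 3.0
    #: fixed range of the red-blue difference histogram
    rb_range: tuple[float, float] = (-255.0, 255.0)


@dataclass(frozen=True)
class TextureParams:
    """Texture-feature extraction settings (GLCM, Gabor, LBP, mSFTA)."""

    glcm_levels: int = 64
    glcm_distances: tuple[int, ...] = (1, 2, 3, 4)
    #: LBP sampling points and radius (uniform rotation-invariant variant)
    lbp_points: int = 8
    lbp_radius: int = 1
    #: Gabor orientations: k * pi / n_orientations for k = 0..n-1
    gabor_orientations: int = 4
    #: radial frequencies in cycles per image width: base * 2**k, k = 0..n-1
    gabor_base_frequency: float = 2.0 * 2.0 ** 0.5
    gabor_n_frequencies: int = 7
    gabor_bandwidth: float = 1.0
    #: number of multi-level Otsu thresholds in the fractal texture analysis
    n_thresholds: int = 4
    #: histogram bins for the multi-level Otsu threshold search
    otsu_bins: int = 128
    #: bins of the Shannon-entropy histograms on grayscale regions
    entropy_bins: int = 256


@dataclass(frozen=True)
class GridConfig:
    """Hyperparameter grids of the nested cross-validation."""

    m_grid: tuple[int, ...] = (1, 5, 10, 30, 50, 70, 90, 100, 200, 300, 342)
    c_exponents: tuple[int, ...] = (-5, -3, -1, 1, 3, 5)
    gamma_exponents: tuple[int, ...] = (-5, -3, -1, 1, 3, 5)

    @property
    def c_grid(self) -> tuple[float, ...]:
        return tuple(2.0 ** e for e in self.c_exponents)

    @property
    def gamma_grid(self) -> tuple[float, ...]:
        return tuple(2.0 ** e for e in self.gamma_exponents)


@dataclass(frozen=True)
class AssociationParams:
    """Spearman association settings."""

    alpha: float = 0.05
    #: |row-mean rho| at or above which a feature is flagged as strong
    strong_threshold: float = 0.5
    #: apply Benjamini-Hochberg FDR control instead of per-cell alpha
    fdr: bool = False


@dataclass
class RunConfig:
    """One config + one seed determines every artifact of a run."""

    seed: int = 0
    out_dir: str = "runs/default"
    n_subjects: int = 10
    images_per_class: int = 2
    effect_size: float = 1.0
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    color: ColorParams = field(default_factory=ColorParams)
    texture: TextureParams = field(default_factory=TextureParams)
    grid: GridConfig = field(default_factory=GridConfig)
    association: AssociationParams = field(default_factory=AssociationParams)

    def to_dict(self) -> dict:
        return asdict(self)


def _coerce(cls, data: dict):
    fields = {f for f in cls.__dataclass_fields__}
    clean = {}
    for k, v in data.items():
        if k not in fields:
            raise KeyError(f"unknown {cls.__name__} option: {k!r}")
        clean[k] = tuple(v) if isinstance(v, list) else v
    return cls(**clean)


def load_config(path: str | Path) -> RunConfig:
    """Load a :class:`RunConfig` from YAML, applying defaults for omitted keys."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    sub = {
        "segmentation": SegmentationParams,
        "color": ColorParams,
        "texture": TextureParams,
        "grid": GridConfig,
        "association": AssociationParams,
    }
    kwargs = {}
    for key, value in data.items():
        if key in sub:
            kwargs[key] = _coerce(sub[key], value or {})
        elif key in RunConfig.__dataclass_fields__:
            kwargs[key] = value
        else:
            raise KeyError(f"unknown config option: {key!r}")
    return RunConfig(**kwargs)


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
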