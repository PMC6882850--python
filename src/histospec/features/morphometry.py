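"""Nuclear morphometry (44 scalars) and Delaunay topology (8 scalars).

Morphometry: the seven statistics (mean, median, std, min, max, skewness,
kurtosis) of six per-nucleus descriptors — area, major and minor axis
length, solidity, eccentricity, compactness (perimeter^2 / 4 pi area) —
plus the mean neighborhood radius (half the nearest-centroid distance) and
the nucleus-to-cytoplasm total-area ratio.

Topology: the Delaunay graph over nucleus centroids; mean, max, min and
disorder (1 - 1/(1 + sigma/mu)) of triangle areas and perimeters.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import Delaunay, QhullError, cKDTree
from skimage import measure

from .base import STAT_NAMES, FeatureBlock, concat_blocks, seven_stats

__all__ = [
    "morphometric_features",
    "topology_features",
    "MORPHOMETRY_FEATURE_COUNT",
    "TOPOLOGY_FEATURE_COUNT",
]

MORPHOMETRY_FEATURE_COUNT = 44
TOPOLOGY_FEATURE_COUNT = 8

_DESCRIPTORS = ("area", "major_axis", "minor_axis", "solidity", "eccentricity",
                "compactness")


def _morph_names() -> list[str]:
    names = [f"morph.{d}.{s}" for d in _DESCRIPTORS for s in STAT_NAMES]
    names += ["morph.neighborhood_radius.mean", "morph.nc_ratio"]
    return names


def morphometric_features(
    nuclei_labels: np.ndarray,
    cytoplasm_mask: np.ndarray,
) -> FeatureBlock:
    names = _morph_names()
    regions = measure.regionprops(np.asarray(nuclei_labels))
    if not regions:
        return FeatureBlock.invalid(names)

    table = {d: [] for d in _DESCRIPTORS}
    centroids = []
    for r in regions:
        table["area"].append(float(r.area))
        table["major_axis"].append(float(r.axis_major_length))
        table["minor_axis"].append(float(r.axis_minor_length))
        table["solidity"].append(float(r.solidity))
        table["eccentricity"].append(float(r.eccentricity))
        perim = float(r.perimeter)
        table["compactness"].append(perim**2 / (4.0 * np.pi * r.area))
        centroids.append(r.centroid)

    blocks = []
    for d in _DESCRIPTORS:
        vals, flags = seven_stats(np.asarray(table[d]))
        blocks.append(FeatureBlock([f"morph.{d}.{s}" for s in STAT_NAMES], vals, flags))

    if len(centroids) >= 2:
        tree = cKDTree(np.asarray(centroids))
        dists, _ = tree.query(np.asarray(centroids), k=2)
        radius = float(np.mean(dists[:, 1]) / 2.0)
        radius_ok = True
    else:
        radius, radius_ok = 0.0, False
    blocks.append(
        FeatureBlock(["morph.neighborhood_radius.mean"], [radius], [radius_ok])
    )

    cyto_area = float(np.asarray(cytoplasm_mask, dtype=bool).sum())
    nuc_area = float(sum(table["area"]))
    if cyto_area > 0:
        blocks.append(FeatureBlock(["morph.nc_ratio"], [nuc_area / cyto_area], [True]))
    else:
        blocks.append(FeatureBlock(["morph.nc_ratio"], [0.0], [False]))
    out = concat_blocks(blocks)
    assert len(out) == MORPHOMETRY_FEATURE_COUNT
    return out


def topology_features(centroids: np.ndarray) -> FeatureBlock:
    """Delaunay triangle area/perimeter statistics over nucleus centroids."""
    names = [
        f"topo.{measure_}.{stat}"
        for measure_ in ("area", "perimeter")
        for stat in ("mean", "max", "min", "disorder")
    ]
    pts = np.asarray(centroids, dtype=float).reshape(-1, 2)
    if len(pts) < 3:
        return FeatureBlock.invalid(names)
    try:
        tri = Delaunay(pts)
    except QhullError:
        return FeatureBlock.invalid(names)
    if tri.simplices.size == 0:
        return FeatureBlock.invalid(names)
    a = pts[tri.simplices[:, 0]]
    b = pts[tri.simplices[:, 1]]
    c = pts[tri.simplices[:, 2]]
    ab = b - a
    ac = c - a
    areas = 0.5 * np.abs(ab[:, 0] * ac[:, 1] - ab[:, 1] * ac[:, 0])
    perims = (
        np.linalg.norm(b - a, axis=1)
        + np.linalg.norm(c - b, axis=1)
        + np.linalg.norm(a - c, axis=1)
    )

    def _stats(x: np.ndarray) -> list[float]:
        mu, sigma = float(x.mean()), float(x.std())
        disorder = 0.0 if mu + sigma == 0 else 1.0 - 1.0 / (1.0 + sigma / mu)
        return [mu, float(x.max()), float(x.min()), disorder]

    values = np.array(_stats(areas) + _stats(perims))
    return FeatureBlock(names, values, np.ones(len(names), dtype=bool))
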