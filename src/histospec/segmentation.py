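"""Epithelium, nuclei and cytoplasm segmentation of H&E tongue crops.

The procedure follows the staged recipe the feature bank depends on:

1. *Epithelium*: the red channel shows the best epithelium/stroma contrast,
   so it is smoothed with an edge-preserving filter (a nucleus-scale median,
   which flattens nuclear texture while keeping the band edge), binarized
   with a global Otsu threshold (polarity chosen so tissue is true), hole
   filled, and opened to drop small spurious regions.
2. *Compartments*: k-means (k=3, Euclidean distance) on the RGB values of
   epithelial pixels; clusters are mapped to roles by color semantics —
   nuclei have the highest mean blue ratio, background the highest
   luminance, cytoplasm is the remainder.
3. *Cleanup*: fill holes, dilate (disk r=2), open (disk r=4), drop
   components under 50 px.
4. *Large clusters* (area > 500 px, solidity < 0.9): repeated k-means color
   splitting until none remain; components with mean red/blue > 1.2 are
   false detections and removed; holes filled; components under 25 px
   dropped.
5. *Small clusters* (area > 150 px, solidity < 0.9), twice: blue-ratio
   image, edge-preserving smoothing, marker-controlled watershed; holes
   filled; components under 50 px dropped.
6. *Finalize*: components with mean red/blue > 1 removed; moment-based
   ellipse fit per nucleus gives the smooth contour.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import measure, morphology
from skimage.feature import peak_local_max
from skimage.filters import median as median_filter
from skimage.filters import threshold_otsu
from skimage.morphology import disk
from skimage.segmentation import watershed
from sklearn.cluster import KMeans

from .config import SegmentationParams

__all__ = [
    "TissueMasks",
    "NucleusRecord",
    "segment_epithelium",
    "blue_ratio_image",
    "partition_epithelium",
    "refine_nuclei_mask",
    "split_large_clusters",
    "split_small_clusters",
    "finalize_nuclei",
    "segment_tissue",
]

DEFAULT_PARAMS = SegmentationParams()


@dataclass
class TissueMasks:
    """Binary compartment masks and the labeled nuclei image for one crop."""

    epithelium: np.ndarray
    nuclei_labels: np.ndarray
    cytoplasm: np.ndarray
    background: np.ndarray

    @property
    def nuclei(self) -> np.ndarray:
        return self.nuclei_labels > 0


@dataclass
class NucleusRecord:
    """Fitted-ellipse summary of one segmented nucleus."""

    label: int
    cx: float
    cy: float
    major_axis: float
    minor_axis: float
    orientation: float
    area: int
    solidity: float
    mean_rb_ratio: float



def _drop_small(mask: np.ndarray, min_area: int) -> np.ndarray:
    """Remove connected components with fewer than ``min_area`` pixels."""
    labels, n = ndi.label(mask)
    if n == 0:
        return mask
    areas = np.bincount(labels.ravel())
    keep = areas >= min_area
    keep[0] = False
    return keep[labels]

def _check_rgb(rgb: np.ndarray) -> np.ndarray:
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB image")
    return rgb


def _rb_ratio(rgb: np.ndarray, mask: np.ndarray) -> float:
    """Mean per-pixel red/blue ratio over a region (denominator >= 1)."""
    r = rgb[..., 0].astype(float)[mask]
    b = np.maximum(rgb[..., 2].astype(float)[mask], 1.0)
    return float(np.mean(r / b)) if r.size else 0.0


def segment_epithelium(
    rgb: np.ndarray, params: SegmentationParams = DEFAULT_PARAMS
) -> np.ndarray:
    """Binary epithelium mask from the red channel.

    A uniform image has no defined threshold and yields an empty mask with a
    warning.
    """
    rgb = _check_rgb(rgb)
    red = rgb[..., 0]
    if np.ptp(red) == 0:
        warnings.warn("uniform red channel: threshold undefined, empty mask")
        return np.zeros(red.shape, dtype=bool)
    # edge-preserving smoothing: a nucleus-scale grayscale closing erases
    # dark nuclear spots however densely packed, then a small median flattens
    # pixel noise; both are rank filters that keep the band's step edge
    smoothed = morphology.closing(red.astype(np.uint8), disk(params.median_radius))
    smoothed = median_filter(smoothed, footprint=disk(5))
    if np.ptp(smoothed) == 0:
        warnings.warn("red channel uniform after smoothing: empty mask")
        return np.zeros(red.shape, dtype=bool)
    t = threshold_otsu(smoothed)
    # tissue is darker than the unstained background in the red channel
    mask = smoothed <= t
    mask = ndi.binary_fill_holes(mask)
    mask = morphology.opening(mask, disk(params.epithelium_open_radius))
    return mask


def blue_ratio_image(rgb: np.ndarray) -> np.ndarray:
    """Blue-ratio transform emphasizing blue-dominant (nuclear) pixels.

    Per pixel on 8-bit channel values: (B / (1 + R + G)) / (1 + R + G + B).
    """
    rgb = _check_rgb(rgb).astype(float)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    return (b / (1.0 + r + g)) / (1.0 + r + g + b)


def _luminance(rgb: np.ndarray) -> np.ndarray:
    rgb = np.asarray(rgb, dtype=float)
    return 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]


def partition_epithelium(
    rgb: np.ndarray,
    epithelium: np.ndarray,
    params: SegmentationParams = DEFAULT_PARAMS,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """k=3 RGB clustering of epithelial pixels into nuclei/cytoplasm/background.

    Cluster-to-role assignment is by color statistics, not cluster index:
    nuclei = highest mean blue ratio, background = highest luminance among
    the rest, cytoplasm = remainder.  With fewer than three distinct colors
    the same rules apply to however many clusters exist; missing roles come
    back empty.
    """
    rgb = _check_rgb(rgb)
    epithelium = np.asarray(epithelium, dtype=bool)
    if not epithelium.any():
        raise ValueError("epithelium mask is empty")
    pixels = rgb[epithelium].astype(float)
    n_distinct = np.unique(pixels, axis=0).shape[0]
    k = min(3, n_distinct)
    if k == 1:
        assignments = np.zeros(len(pixels), dtype=int)
    else:
        km = KMeans(n_clusters=k, n_init=params.kmeans_restarts, random_state=0)
        assignments = km.fit_predict(pixels)

    blue = blue_ratio_image(rgb)[epithelium]
    lum = _luminance(rgb)[epithelium]
    clusters = list(range(k))
    roles: dict[str, int | None] = {"nuclei": None, "cytoplasm": None, "background": None}
    if k >= 1:
        roles["nuclei"] = max(clusters, key=lambda c: blue[assignments == c].mean())
        clusters = [c for c in clusters if c != roles["nuclei"]]
    if clusters:
        roles["background"] = max(clusters, key=lambda c: lum[assignments == c].mean())
        clusters = [c for c in clusters if c != roles["background"]]
    if clusters:
        roles["cytoplasm"] = clusters[0]

    out = {}
    for role in ("nuclei", "cytoplasm", "background"):
        mask = np.zeros(epithelium.shape, dtype=bool)
        if roles[role] is not None:
            sel = np.zeros(len(pixels), dtype=bool)
            sel[assignments == roles[role]] = True
            mask[epithelium] = sel
        out[role] = mask
    return out["nuclei"], out["cytoplasm"], out["background"]


def refine_nuclei_mask(
    raw_mask: np.ndarray, params: SegmentationParams = DEFAULT_PARAMS
) -> np.ndarray:
    """Morphological cleanup: fill holes, dilate r=2, open r=4, drop < 50 px."""
    mask = np.asarray(raw_mask, dtype=bool)
    mask = ndi.binary_fill_holes(mask)
    mask = morphology.dilation(mask, disk(params.dilate_radius))
    mask = morphology.opening(mask, disk(params.open_radius))
    mask = _drop_small(mask, params.min_area_refine)
    return mask


def _flagged_components(
    labels: np.ndarray, min_area: int, solidity_threshold: float
) -> list:
    flagged = []
    for region in measure.regionprops(labels):
        if region.area > min_area and region.solidity < solidity_threshold:
            flagged.append(region)
    return flagged


def split_large_clusters(
    mask: np.ndarray,
    rgb: np.ndarray,
    params: SegmentationParams = DEFAULT_PARAMS,
) -> np.ndarray:
    """Break large low-solidity nuclear clusters by repeated color k-means.

    Components with area > 500 px and solidity < 0.9 are re-clustered
    (k=2 on RGB) until none remain or the iteration cap hits; then false
    detections (mean red/blue > 1.2) are removed, holes filled, and
    components under 25 px dropped.
    """
    rgb = _check_rgb(rgb)
    mask = np.asarray(mask, dtype=bool).copy()
    for _ in range(params.iteration_cap):
        labels = measure.label(mask)
        flagged = _flagged_components(
            labels, params.large_cluster_area, params.solidity_threshold
        )
        if not flagged:
            break
        changed = False
        for region in flagged:
            comp = labels == region.label
            pixels = rgb[comp].astype(float)
            if np.unique(pixels, axis=0).shape[0] < 2:
                continue
            km = KMeans(n_clusters=2, n_init=params.kmeans_restarts, random_state=0)
            sub = km.fit_predict(pixels)
            # both sub-clusters remain nuclei; carve the pixels where the two
            # color groups touch so they become separate components
            sub_img = np.zeros(mask.shape, dtype=np.int8)
            sub_img[comp] = sub + 1
            carve = np.zeros(mask.shape, dtype=bool)
            for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0)):
                neighbor = np.zeros_like(sub_img)
                src = sub_img[
                    max(0, -dr) : sub_img.shape[0] - max(0, dr),
                    max(0, -dc) : sub_img.shape[1] - max(0, dc),
                ]
                neighbor[
                    max(0, dr) : sub_img.shape[0] - max(0, -dr),
                    max(0, dc) : sub_img.shape[1] - max(0, -dc),
                ] = src
                carve |= (sub_img > 0) & (neighbor > 0) & (sub_img != neighbor)
            if carve.any():
                mask[carve] = False
                changed = True
        if not changed:
            break
    else:
        warnings.warn("large-cluster splitting hit the iteration cap")

    labels = measure.label(mask)
    for region in measure.regionprops(labels):
        comp = labels == region.label
        if _rb_ratio(rgb, comp) > params.rb_ratio_false:
            mask[comp] = False
    mask = ndi.binary_fill_holes(mask)
    mask = _drop_small(mask, params.min_area_large_stage)
    return mask


def split_small_clusters(
    mask: np.ndarray,
    rgb: np.ndarray,
    params: SegmentationParams = DEFAULT_PARAMS,
) -> np.ndarray:
    """Separate touching nuclei by watershed on the smoothed blue-ratio image.

    The five-step procedure runs twice: flag components with area > 150 px
    and solidity < 0.9; compute the blue-ratio image; smooth it
    (edge-preserving); marker-controlled watershed (markers = regional maxima
    of the smoothed blue ratio inside the component); fill holes and drop
    components under 50 px.
    """
    rgb = _check_rgb(rgb)
    mask = np.asarray(mask, dtype=bool).copy()
    blue = blue_ratio_image(rgb)
    smoothed = median_filter(
        (blue / max(blue.max(), 1e-12) * 255).astype(np.uint8),
        footprint=disk(2),
    ).astype(float)
    for _ in range(params.small_stage_repeats):
        labels = measure.label(mask)
        flagged = _flagged_components(
            labels, params.small_cluster_area, params.solidity_threshold
        )
        for region in flagged:
            comp = labels == region.label
            # markers from distance-transform peaks: one per nucleus core even
            # when the blue-ratio relief is flat inside a same-color cluster
            dist = ndi.distance_transform_edt(comp)
            peaks = peak_local_max(
                dist,
                labels=comp.astype(int),
                min_distance=params.marker_min_distance,
                exclude_border=False,
            )
            if len(peaks) < 2:
                continue
            markers = np.zeros(mask.shape, dtype=int)
            markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
            ws = watershed(-smoothed, markers=markers, mask=comp)
            # carve 1-px boundaries between watershed basins
            boundary = np.zeros(mask.shape, dtype=bool)
            for ax, shift in ((0, 1), (1, 1)):
                a = ws
                b = np.roll(ws, shift, axis=ax)
                diff = (a != b) & (a > 0) & (b > 0)
                if ax == 0:
                    diff[0, :] = False
                else:
                    diff[:, 0] = False
                boundary |= diff
            mask[comp & boundary] = False
        mask = ndi.binary_fill_holes(mask)
        mask = _drop_small(mask, params.min_area_small_stage)
    return mask


def finalize_nuclei(
    mask: np.ndarray,
    rgb: np.ndarray,
    params: SegmentationParams = DEFAULT_PARAMS,
) -> tuple[np.ndarray, list[NucleusRecord]]:
    """Drop pink components (mean red/blue > 1), label, fit ellipses.

    An empty final mask is valid: zero nuclei, empty record list.
    """
    rgb = _check_rgb(rgb)
    mask = np.asarray(mask, dtype=bool).copy()
    labels = measure.label(mask)
    for region in measure.regionprops(labels):
        comp = labels == region.label
        if _rb_ratio(rgb, comp) > params.rb_ratio_final:
            mask[comp] = False
    labels = measure.label(mask).astype(np.int32)
    records: list[NucleusRecord] = []
    for region in measure.regionprops(labels):
        comp = labels == region.label
        records.append(
            NucleusRecord(
                label=int(region.label),
                cx=float(region.centroid[1]),
                cy=float(region.centroid[0]),
                major_axis=float(region.axis_major_length),
                minor_axis=float(region.axis_minor_length),
                orientation=float(region.orientation),
                area=int(region.area),
                solidity=float(region.solidity),
                mean_rb_ratio=_rb_ratio(rgb, comp),
            )
        )
    return labels, records


def segment_tissue(
    rgb: np.ndarray, params: SegmentationParams = DEFAULT_PARAMS
) -> tuple[TissueMasks, list[NucleusRecord]]:
    """Full segmentation pipeline for one crop."""
    rgb = _check_rgb(rgb)
    epithelium = segment_epithelium(rgb, params)
    if not epithelium.any():
        empty = np.zeros(rgb.shape[:2], dtype=bool)
        return TissueMasks(epithelium, empty.astype(np.int32), empty, empty), []
    raw_nuclei, cytoplasm, background = partition_epithelium(rgb, epithelium, params)
    mask = refine_nuclei_mask(raw_nuclei, params)
    mask = split_large_clusters(mask, rgb, params)
    mask = split_small_clusters(mask, rgb, params)
    mask &= epithelium  # nuclei are confined to the epithelium
    labels, records = finalize_nuclei(mask, rgb, params)
    cytoplasm = cytoplasm & epithelium & (labels == 0)
    background = background & epithelium & (labels == 0)
    masks = TissueMasks(
        epithelium=epithelium,
        nuclei_labels=labels,
        cytoplasm=cytoplasm,
        background=background,
    )
    return masks, records
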