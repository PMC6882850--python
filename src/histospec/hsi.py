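"""Hyperspectral cube handling: reflectance calibration, pathology line maps,
and per-class spectral signatures.

A hypercube is an H x W x B stack of intensities with a strictly increasing
wavelength axis (the instrument emulated here records 450-900 nm in 5 nm
steps, i.e. 91 bands).  Raw counts are converted to relative reflectance with
a white and a dark reference cube,

    I_ref(x, y, l) = (I_raw - I_dark) / (I_white - I_dark),

and per-pathology spectral signatures are the per-band means of the
reflectance pixels labeled with each class in a pathology map.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "CLASSES",
    "UNLABELED",
    "Hypercube",
    "PathologyMap",
    "SpectralSignature",
    "calibrate_reflectance",
    "build_pathology_map",
    "extract_spectral_signatures",
    "read_hypercube",
    "write_hypercube",
]

#: pathology grades in increasing order of severity
CLASSES = ("normal", "dysplasia", "cis", "carcinoma")
UNLABELED = "unlabeled"


@dataclass
class Hypercube:
    """H x W x B intensity stack with a wavelength axis.

    ``kind`` is one of ``raw``, ``white``, ``dark`` or ``reflectance``; for a
    reflectance cube ``valid`` marks voxels where the calibration denominator
    was positive (invalid voxels hold 0 and are skipped downstream).
    """

    values: np.ndarray
    wavelengths: np.ndarray
    kind: str = "raw"
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("hypercube values must be H x W x B")
        if self.values.shape[2] != self.wavelengths.size:
            raise ValueError("band count does not match wavelength axis")
        if self.wavelengths.size > 1 and np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.kind == "reflectance" and not np.all(np.isfinite(self.values)):
            raise ValueError("reflectance cube contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def band_subset(self, indices: Sequence[int]) -> "Hypercube":
        idx = np.asarray(indices)
        return Hypercube(
            self.values[:, :, idx],
            self.wavelengths[idx],
            kind=self.kind,
            valid=None if self.valid is None else self.valid[:, :, idx],
        )


@dataclass
class PathologyMap:
    """Label image whose annotated pixels lie on declared horizontal lines.

    Each whole-slide section corresponds to one straight line across the
    dorsal tongue surface, so per-class annotations arrive as column runs on
    individual rows.
    """

    labels: np.ndarray  # H x W array of class-name strings
    lines: list[tuple[int, list[tuple[int, int, str]]]] = field(default_factory=list)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def class_counts(self) -> dict[str, int]:
        names, counts = np.unique(self.labels, return_counts=True)
        return {n: int(c) for n, c in zip(names, counts) if n != UNLABELED}


@dataclass
class SpectralSignature:
    """Per-class mean reflectance over the band axis."""

    wavelengths: np.ndarray
    means: dict[str, np.ndarray]
    pixel_counts: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {cls: m for cls, m in self.means.items()},
            index=pd.Index(self.wavelengths, name="wavelength_nm"),
        ).T

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)


def calibrate_reflectance(
    raw: Hypercube, white: Hypercube, dark: Hypercube
) -> Hypercube:
    """Convert raw counts to relative reflectance with white/dark references.

    Voxels whose denominator ``white - dark`` is not positive are flagged
    invalid and set to 0 rather than propagated as Inf/NaN.  Values above 1
    (specular highlights) are kept, not clipped.
    """
    for ref in (white, dark):
        if ref.shape != raw.shape:
            raise ValueError("raw/white/dark cubes must share a shape")
        if not np.array_equal(ref.wavelengths, raw.wavelengths):
            raise ValueError("raw/white/dark cubes must share a wavelength grid")
    denom = white.values - dark.values
    valid = denom > 0
    if not valid.any():
        raise ValueError("all voxels have non-positive white-dark denominator")
    out = np.zeros_like(raw.values)
    np.divide(raw.values - dark.values, denom, out=out, where=valid)
    return Hypercube(out, raw.wavelengths, kind="reflectance", valid=valid)


def build_pathology_map(
    line_annotations: Iterable[tuple[int, Iterable[tuple[int, int, str]]]],
    shape: tuple[int, int],
) -> PathologyMap:
    """Paint per-row class runs into a label image.

    ``line_annotations`` is a list of ``(row, runs)`` where each run is
    ``(col_start, col_stop, class_name)`` with a half-open column interval.
    Runs on one row must not overlap.
    """
    h, w = shape
    labels = np.full((h, w), UNLABELED, dtype=object)
    lines: list[tuple[int, list[tuple[int, int, str]]]] = []
    for row, runs in line_annotations:
        if not 0 <= row < h:
            raise ValueError(f"row {row} outside image height {h}")
        runs = [(int(a), int(b), str(c)) for a, b, c in runs]
        covered = np.zeros(w, dtype=bool)
        for a, b, cls in runs:
            if cls not in CLASSES:
                raise ValueError(f"unknown pathology class {cls!r}")
            if not (0 <= a < b <= w):
                raise ValueError(f"run columns [{a}, {b}) out of range for width {w}")
            if covered[a:b].any():
                raise ValueError(f"overlapping runs on row {row}")
            covered[a:b] = True
            labels[row, a:b] = cls
        lines.append((row, runs))
    return PathologyMap(labels=labels, lines=lines)


def extract_spectral_signatures(
    cube: Hypercube, pathology_map: PathologyMap
) -> SpectralSignature:
    """Average reflectance spectra per pathology class under the map.

    Classes absent from the map are omitted.  Voxels flagged invalid by the
    calibration are excluded from the per-band means.
    """
    if cube.kind != "reflectance":
        raise ValueError("signatures are extracted from reflectance cubes")
    if cube.shape[:2] != pathology_map.shape:
        raise ValueError("cube and pathology map must share H x W")
    present = [c for c in CLASSES if (pathology_map.labels == c).any()]
    if not present:
        raise ValueError("pathology map contains no labeled pixels")
    valid = cube.valid if cube.valid is not None else np.ones(cube.shape, dtype=bool)
    means: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    for cls in present:
        sel = pathology_map.labels == cls
        spectra = cube.values[sel]  # n_pixels x B
        ok = valid[sel]
        n_ok = ok.sum(axis=0)
        if not n_ok.any():
            raise ValueError(f"all labeled pixels for class {cls!r} are masked")
        with np.errstate(invalid="ignore"):
            mean = np.where(n_ok > 0, (spectra * ok).sum(axis=0) / np.maximum(n_ok, 1), np.nan)
        means[cls] = mean
        counts[cls] = int(sel.sum())
    return SpectralSignature(cube.wavelengths.copy(), means, counts)


# ---------------------------------------------------------------------------
# I/O: multi-page TIFF (one page per band) + JSON wavelength sidecar
# ---------------------------------------------------------------------------

def write_hypercube(cube: Hypercube, path: str | Path) -> None:
    path = Path(path)
    tifffile.imwrite(
        path,
        np.moveaxis(cube.values.astype(np.float32), 2, 0),
        photometric="minisblack",
    )
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps({"wavelengths_nm": cube.wavelengths.tolist(), "kind": cube.kind})
    )


def read_hypercube(path: str | Path) -> Hypercube:
    path = Path(path)
    values = np.moveaxis(tifffile.imread(path), 0, 2)
    meta = json.loads(path.with_suffix(".json").read_text())
    return Hypercube(values, np.asarray(meta["wavelengths_nm"]), kind=meta.get("kind", "raw"))
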