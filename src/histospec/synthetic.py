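"""Synthetic H&E-style crops and hyperspectral cubes with ground truth.

The generator emulates the appearance the downstream pipeline depends on:
blue-purple elliptical nuclei scattered over pink cytoplasm inside an
epithelial band, white empty spaces, and a bright stroma/background region
below the band.  Neoplastic grades (dysplasia, carcinoma in situ, carcinoma)
receive more, larger, more irregular and more crowded nuclei than normal
tissue; their reflectance spectra have higher amplitude, and every spectrum
carries a hemoglobin absorption dip near 540 nm.

Nucleus outlines are ellipses with a sinusoidal radial perturbation whose
amplitude is ``boundary_irregularity`` times the local radius: one knob that
moves outline perimeter and fractal dimension together, the way atypical
nuclear shape does in graded lesions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image
from skimage.draw import polygon

from .hsi import CLASSES, Hypercube

__all__ = [
    "NEOPLASTIC",
    "TissueSpec",
    "SyntheticGroundTruth",
    "SpectrumSpec",
    "DatasetBundle",
    "tissue_spec_for_class",
    "generate_he_image",
    "class_spectrum",
    "generate_hypercube",
    "generate_paired_dataset",
]

NEOPLASTIC = ("dysplasia", "cis", "carcinoma")

#: default H&E palette: blue-dominant nuclei, pink cytoplasm, near-white
#: empty space.  Chosen so the segmentation color-ratio rules hold (nuclei
#: blue-ratio highest; red/blue > 1.2 only for artifacts).
DEFAULT_STAIN_COLORS = {
    "nuclei": (64, 48, 128),
    "cytoplasm": (230, 150, 180),
    "background": (250, 250, 250),
}

#: per-grade architecture at effect_size = 1 on the default 320 x 200 crop;
#: values interpolate linearly from the normal row with effect size.  The
#: epithelial band thickens with grade, as neoplastic epithelium does.
_CLASS_ARCHITECTURE = {
    #            n    axes_mean  axes_sd  irregularity  crowding  band
    "normal":    (35, 13.0, 1.5, 0.04, 0.90, 0.40),
    "dysplasia": (50, 15.0, 1.8, 0.10, 1.10, 0.48),
    "cis":       (60, 16.0, 2.0, 0.16, 1.25, 0.55),
    "carcinoma": (70, 18.0, 2.2, 0.22, 1.40, 0.62),
}

#: reflectance baseline amplitude per class (normal weakest, grades stronger)
_CLASS_AMPLITUDE = {
    "normal": 0.30,
    "dysplasia": 0.38,
    "cis": 0.43,
    "carcinoma": 0.48,
    "background": 0.85,
}


@dataclass(frozen=True)
class TissueSpec:
    """Generative parameters of one synthetic H&E crop."""

    image_height: int = 200
    image_width: int = 320
    pathology_class: str = "normal"
    #: fraction of the image height occupied by the epithelial band (from top)
    epithelium_band: float = 0.40
    n_nuclei: int = 35
    #: mean / sd of nucleus axis length (pixels, full axis not semi-axis)
    nucleus_axes_mean: float = 13.0
    nucleus_axes_sd: float = 1.5
    #: radial perturbation amplitude of the outline, as a fraction of radius
    boundary_irregularity: float = 0.04
    #: crowding knob: minimum centroid spacing = 1.1 * axes_mean / crowding,
    #: so larger values pack nuclei closer together
    crowding: float = 0.9
    stain_colors: dict = field(default_factory=lambda: dict(DEFAULT_STAIN_COLORS))
    #: per-channel Gaussian pixel noise and per-nucleus stain jitter (8-bit)
    pixel_noise_sd: float = 2.0
    nucleus_color_jitter: float = 8.0
    #: density of white empty-space lacunae in the band (per pixel)
    lacuna_density: float = 1.0 / 4000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height <= 0 or self.image_width <= 0:
            raise ValueError("image dimensions must be positive")
        if not 0 < self.epithelium_band <= 1:
            raise ValueError("epithelium_band must lie in (0, 1]")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        if self.nucleus_axes_mean <= 0:
            raise ValueError("nucleus axes must be positive")
        if self.boundary_irregularity < 0:
            raise ValueError("boundary_irregularity must be >= 0")
        if self.pathology_class not in CLASSES:
            raise ValueError(f"unknown pathology class {self.pathology_class!r}")

    @property
    def min_spacing(self) -> float:
        return 1.1 * self.nucleus_axes_mean / self.crowding


@dataclass
class SyntheticGroundTruth:
    """Rendered truth for one crop: nuclei geometry and the epithelium band."""

    nuclei: list[dict]  # cx, cy, major_axis, minor_axis, orientation
    epithelium_mask: np.ndarray
    class_label: str
    nuclei_labels: np.ndarray | None = None

    @property
    def n_nuclei(self) -> int:
        return len(self.nuclei)

    def centroids(self) -> np.ndarray:
        if not self.nuclei:
            return np.empty((0, 2))
        return np.array([[n["cx"], n["cy"]] for n in self.nuclei])


def tissue_spec_for_class(
    pathology_class: str,
    effect_size: float = 1.0,
    seed: int = 0,
    **overrides,
) -> TissueSpec:
    """Class-conditioned :class:`TissueSpec`, architecture scaled by effect size.

    ``effect_size`` interpolates every architectural parameter between the
    normal baseline (0) and the full class-default difference (1).
    """
    base = np.array(_CLASS_ARCHITECTURE["normal"])
    tgt = np.array(_CLASS_ARCHITECTURE[pathology_class])
    n, mean, sd, irr, crowd, band = base + effect_size * (tgt - base)
    spec = TissueSpec(
        pathology_class=pathology_class,
        n_nuclei=int(round(n)),
        nucleus_axes_mean=float(mean),
        nucleus_axes_sd=float(sd),
        boundary_irregularity=float(irr),
        crowding=float(crowd),
        epithelium_band=float(band),
        seed=seed,
    )
    return replace(spec, **overrides) if overrides else spec


def _nucleus_outline(
    cx: float,
    cy: float,
    semi_major: float,
    semi_minor: float,
    orientation: float,
    irregularity: float,
    n_lobes: int,
    phase: float,
    n_vertices: int = 72,
) -> tuple[np.ndarray, np.ndarray]:
    """Perturbed-ellipse outline vertices (rows, cols)."""
    t = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    bump = 1.0 + irregularity * np.sin(n_lobes * t + phase)
    x = semi_major * np.cos(t) * bump
    y = semi_minor * np.sin(t) * bump
    c, s = np.cos(orientation), np.sin(orientation)
    cols = cx + c * x - s * y
    rows = cy + s * x + c * y
    return rows, cols


def generate_he_image(spec: TissueSpec) -> tuple[np.ndarray, SyntheticGroundTruth]:
    """Render an 8-bit RGB crop and its ground truth.

    Nuclei are placed by rejection sampling (hard cap of 100 x n_nuclei
    attempts) with a minimum centroid spacing derived from the crowding knob;
    if fewer than half the requested nuclei fit, generation fails loudly.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_height, spec.image_width
    band_h = max(1, int(round(spec.epithelium_band * h)))
    colors = spec.stain_colors

    img = np.empty((h, w, 3), dtype=float)
    img[:] = colors["background"]
    img[:band_h] = colors["cytoplasm"]

    epithelium = np.zeros((h, w), dtype=bool)
    epithelium[:band_h] = True

    # white empty-space lacunae inside the band (drawn before nuclei so the
    # epithelium keeps three genuine color populations)
    n_lacunae = rng.poisson(spec.lacuna_density * band_h * w)
    for _ in range(n_lacunae):
        lr = rng.uniform(3, 7)
        cy = rng.uniform(lr, band_h - lr) if band_h > 2 * lr else band_h / 2
        cx = rng.uniform(lr, w - lr)
        rr, cc = _nucleus_outline(cx, cy, lr, lr * rng.uniform(0.6, 1.0),
                                  rng.uniform(0, np.pi), 0.1, 4, rng.uniform(0, 2 * np.pi))
        rr, cc = polygon(rr, cc, shape=(h, w))
        img[rr, cc] = colors["background"]

    # nucleus placement: rejection sampling with minimum centroid spacing
    margin = spec.nucleus_axes_mean * 0.75
    min_sp2 = spec.min_spacing ** 2
    centers: list[tuple[float, float]] = []
    max_attempts = 100 * max(spec.n_nuclei, 1)
    attempts = 0
    feasible_band = band_h > 2 * margin and w > 2 * margin
    while len(centers) < spec.n_nuclei and attempts < max_attempts:
        attempts += 1
        if not feasible_band:
            break
        cx = rng.uniform(margin, w - margin)
        cy = rng.uniform(margin, band_h - margin)
        if all((cx - px) ** 2 + (cy - py) ** 2 >= min_sp2 for px, py in centers):
            centers.append((cx, cy))
    if spec.n_nuclei and len(centers) < 0.5 * spec.n_nuclei:
        raise ValueError(
            f"could only place {len(centers)} of {spec.n_nuclei} nuclei at "
            f"minimum spacing {spec.min_spacing:.1f}px; requested count is "
            "infeasible for this geometry"
        )
    if len(centers) < spec.n_nuclei:
        warnings.warn(
            f"placed {len(centers)} of {spec.n_nuclei} requested nuclei",
            stacklevel=2,
        )

    labels = np.zeros((h, w), dtype=np.uint16)
    nuclei: list[dict] = []
    for k, (cx, cy) in enumerate(centers, start=1):
        major = max(4.0, rng.normal(spec.nucleus_axes_mean, spec.nucleus_axes_sd)
                    * rng.uniform(1.0, 1.25))
        minor = max(3.0, rng.normal(spec.nucleus_axes_mean, spec.nucleus_axes_sd)
                    * rng.uniform(0.65, 0.95))
        if minor > major:
            major, minor = minor, major
        theta = rng.uniform(0, np.pi)
        rr, cc = _nucleus_outline(
            cx, cy, major / 2, minor / 2, theta,
            spec.boundary_irregularity,
            n_lobes=int(rng.integers(3, 8)),
            phase=rng.uniform(0, 2 * np.pi),
        )
        rr, cc = polygon(rr, cc, shape=(h, w))
        color = np.asarray(colors["nuclei"], dtype=float)
        color = color + rng.normal(0, spec.nucleus_color_jitter, size=3)
        img[rr, cc] = np.clip(color, 0, 255)
        labels[rr, cc] = k
        nuclei.append(
            {"cx": float(cx), "cy": float(cy), "major_axis": float(major),
             "minor_axis": float(minor), "orientation": float(theta)}
        )

    if spec.pixel_noise_sd > 0:
        img = img + rng.normal(0, spec.pixel_noise_sd, size=img.shape)
    rgb = np.clip(img, 0, 255).astype(np.uint8)
    gt = SyntheticGroundTruth(
        nuclei=nuclei,
        epithelium_mask=epithelium,
        class_label=spec.pathology_class,
        nuclei_labels=labels,
    )
    return rgb, gt


# ---------------------------------------------------------------------------
# spectra and hypercubes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpectrumSpec:
    """Generative parameters of the class-conditioned reflectance spectra.

    Spectra are logistic-rising baselines scaled by a per-class amplitude,
    minus a Gaussian absorption dip centred on hemoglobin's 540 nm peak.
    """

    wavelengths: tuple = tuple(float(v) for v in range(450, 901, 5))
    baseline_amplitude: dict = field(default_factory=lambda: dict(_CLASS_AMPLITUDE))
    hemoglobin_dip_center: float = 540.0
    dip_width: float = 25.0
    dip_depth: float = 0.35
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        amps = self.baseline_amplitude
        if not all(amps[c] > amps["normal"] for c in NEOPLASTIC if c in amps):
            raise ValueError("neoplastic amplitude must exceed normal amplitude")


def class_spectrum(spec: SpectrumSpec, pathology_class: str) -> np.ndarray:
    """Noise-free reflectance spectrum of one class on the wavelength grid."""
    lam = np.asarray(spec.wavelengths)
    amp = spec.baseline_amplitude[pathology_class]
    baseline = 0.55 + 0.45 / (1.0 + np.exp(-(lam - 600.0) / 70.0))
    dip = 1.0 - spec.dip_depth * np.exp(
        -((lam - spec.hemoglobin_dip_center) ** 2) / (2 * spec.dip_width ** 2)
    )
    return amp * baseline * dip


def generate_hypercube(
    spec: SpectrumSpec, class_layout: np.ndarray
) -> tuple[Hypercube, Hypercube, Hypercube]:
    """Raw + white + dark reference cubes for a class-labeled scene.

    raw = dark + (reflectance + noise) * (white - dark), with the reflectance
    at each pixel given by its class's spectrum.  The white reference is
    strictly above the dark reference at every voxel.
    """
    layout = np.asarray(class_layout)
    allowed = set(spec.baseline_amplitude)
    present = set(np.unique(layout).tolist())
    if not present <= allowed:
        raise ValueError(f"layout classes {present - allowed} have no spectrum")
    rng = np.random.default_rng(spec.seed)
    lam = np.asarray(spec.wavelengths)
    h, w = layout.shape
    b = lam.size

    # smooth lamp profile for the white reference; constant dark current
    white_level = 3000.0 * (0.7 + 0.3 * (lam - lam[0]) / (lam[-1] - lam[0]))
    white = np.broadcast_to(white_level, (h, w, b)).copy()
    dark = np.full((h, w, b), 100.0)
    if not (white > dark).all():
        raise AssertionError("white reference must exceed dark reference everywhere")

    reflectance = np.empty((h, w, b))
    for cls in present:
        reflectance[layout == cls] = class_spectrum(spec, cls)
    if spec.noise_sd > 0:
        reflectance = reflectance + rng.normal(0, spec.noise_sd, size=reflectance.shape)
    raw = dark + reflectance * (white - dark)
    return (
        Hypercube(raw, lam, kind="raw"),
        Hypercube(white, lam, kind="white"),
        Hypercube(dark, lam, kind="dark"),
    )


# ---------------------------------------------------------------------------
# subject-structured paired dataset
# ---------------------------------------------------------------------------

@dataclass
class DatasetBundle:
    """Paired crops + cubes with subject structure for leave-one-subject-out CV."""

    records: list[dict]          # image_id, subject_id, class, rgb, ground_truth
    cubes: dict                  # (subject_id, class) -> dict(raw, white, dark, layout)
    spectrum_spec: SpectrumSpec
    effect_size: float
    seed: int

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "image_id": r["image_id"],
                    "image_path": f"crops/{r['image_id']}.png",
                    "cube_path": f"cubes/{r['subject_id']}_{r['class']}.tiff",
                    "subject_id": r["subject_id"],
                    "class": r["class"],
                }
                for r in self.records
            ]
        )

    def labels(self) -> pd.Series:
        return pd.Series(
            ["neoplastic" if r["class"] in NEOPLASTIC else "normal" for r in self.records],
            index=[r["image_id"] for r in self.records],
            name="label",
        )

    def write(self, out_dir: str | Path) -> Path:
        from .hsi import write_hypercube

        out = Path(out_dir)
        (out / "crops").mkdir(parents=True, exist_ok=True)
        (out / "cubes").mkdir(parents=True, exist_ok=True)
        for r in self.records:
            Image.fromarray(r["rgb"]).save(out / "crops" / f"{r['image_id']}.png")
            gt = r["ground_truth"]
            (out / "crops" / f"{r['image_id']}.json").write_text(
                json.dumps({"class": gt.class_label, "nuclei": gt.nuclei})
            )
            tifffile.imwrite(
                out / "crops" / f"{r['image_id']}_labels.tiff", gt.nuclei_labels
            )
        for (sid, cls), cube in self.cubes.items():
            write_hypercube(cube["raw"], out / "cubes" / f"{sid}_{cls}.tiff")
        self.manifest().to_csv(out / "manifest.csv", index=False)
        return out


def generate_paired_dataset(
    n_subjects: int,
    images_per_class: int = 2,
    effect_size: float = 1.0,
    seed: int = 0,
    image_height: int = 200,
    image_width: int = 320,
    cube_size: int = 32,
    noise_sd: float = 0.01,
) -> DatasetBundle:
    """Subject-structured crops + cubes emulating a small imaging cohort.

    ``effect_size`` scales the normal-vs-neoplastic difference in both the
    tissue architecture and the spectral amplitude; 0 makes the class labels
    uninformative.  Mild per-subject random effects make leave-one-subject-out
    folds non-exchangeable, as in a real cohort.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects for subject-structured CV")
    if images_per_class < 1:
        raise ValueError("images_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    records: list[dict] = []
    cubes: dict = {}
    base_spec = SpectrumSpec(noise_sd=noise_sd)

    for s in range(n_subjects):
        sid = f"S{s:02d}"
        arch_jitter = rng.normal(1.0, 0.04)
        size_jitter = rng.normal(1.0, 0.03)
        amp_shift = rng.normal(0.0, 0.012)
        amps = {}
        for cls, amp in base_spec.baseline_amplitude.items():
            if cls == "background":
                amps[cls] = amp
            else:
                scaled = _CLASS_AMPLITUDE["normal"] + effect_size * (
                    amp - _CLASS_AMPLITUDE["normal"]
                )
                amps[cls] = float(np.clip(scaled + amp_shift, 0.05, 0.95))
        # keep the invariant amplitude(neoplastic) > amplitude(normal)
        for cls in NEOPLASTIC:
            amps[cls] = max(amps[cls], amps["normal"] + max(effect_size, 0) * 1e-3 + 1e-6)
        sub_spec = SpectrumSpec(
            baseline_amplitude=amps, noise_sd=noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        for cls in CLASSES:
            for i in range(images_per_class):
                tissue = tissue_spec_for_class(
                    cls,
                    effect_size=effect_size,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    image_height=image_height,
                    image_width=image_width,
                )
                tissue = replace(
                    tissue,
                    n_nuclei=max(1, int(round(tissue.n_nuclei * arch_jitter))),
                    nucleus_axes_mean=tissue.nucleus_axes_mean * size_jitter,
                )
                rgb, gt = generate_he_image(tissue)
                records.append(
                    {
                        "image_id": f"{sid}_{cls}_{i:02d}",
                        "subject_id": sid,
                        "class": cls,
                        "rgb": rgb,
                        "ground_truth": gt,
                    }
                )
            layout = np.full((cube_size, cube_size), "background", dtype=object)
            q = cube_size // 4
            layout[q : cube_size - q, q : cube_size - q] = cls
            raw, white, dark = generate_hypercube(sub_spec, layout)
            cubes[(sid, cls)] = {
                "raw": raw, "white": white, "dark": dark, "layout": layout,
            }
    return DatasetBundle(
        records=records,
        cubes=cubes,
        spectrum_spec=base_spec,
        effect_size=effect_size,
        seed=seed,
    )
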