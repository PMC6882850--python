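"""End-to-end orchestration: synth -> segment -> features -> select -> cv,
and calibrate -> signatures -> associate, from one :class:`RunConfig`.

A fixed config + seed determines every artifact.  Per-image failures are
recorded and skipped rather than aborting the run; stage-contract
violations (wrong feature counts, leakage) raise immediately.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .association import plot_heatmap, spearman_matrix, summarize_heatmap
from .config import RunConfig
from .features import assemble_features
from .hsi import build_pathology_map, calibrate_reflectance, extract_spectral_signatures
from .modeling import nested_cv
from .segmentation import segment_tissue
from .selection import mrmr_rank
from .synthetic import NEOPLASTIC, DatasetBundle, generate_paired_dataset

logger = logging.getLogger("histospec")

__all__ = ["extract_feature_matrix", "signatures_from_bundle", "run_end_to_end"]


def extract_feature_matrix(
    bundle: DatasetBundle, config: RunConfig | None = None
) -> pd.DataFrame:
    """Segment every crop and assemble its feature vector.

    Returns images x (712 features + subject_id + class + label); failed
    images are dropped with a warning.
    """
    config = config or RunConfig()
    rows = []
    index = []
    meta = []
    for rec in bundle.records:
        try:
            masks, _ = segment_tissue(rec["rgb"], config.segmentation)
            fv = assemble_features(rec["rgb"], masks, config.color, config.texture)
        except Exception as exc:  # per-image failure: mark and continue
            warnings.warn(f"image {rec['image_id']} failed: {exc}")
            continue
        rows.append(fv.values)
        index.append(rec["image_id"])
        meta.append((rec["subject_id"], rec["class"]))
        names = fv.names
    if not rows:
        raise RuntimeError("no image produced a feature vector")
    df = pd.DataFrame(np.vstack(rows), index=index, columns=names)
    df.insert(0, "subject_id", [m[0] for m in meta])
    df.insert(1, "class", [m[1] for m in meta])
    df.insert(
        2, "label",
        ["neoplastic" if m[1] in NEOPLASTIC else "normal" for m in meta],
    )
    return df


def signatures_from_bundle(bundle: DatasetBundle) -> pd.DataFrame:
    """Calibrate every cube and extract its per-class spectral signature.

    Returns one row per (subject, class) with the class-mean reflectance
    over the 91 bands.
    """
    rows = {}
    for (sid, cls), cube in bundle.cubes.items():
        refl = calibrate_reflectance(cube["raw"], cube["white"], cube["dark"])
        layout = cube["layout"]
        runs = []
        for r in range(layout.shape[0]):
            row = layout[r]
            cols = np.flatnonzero(row != "background")
            if cols.size:
                runs.append((r, [(int(cols[0]), int(cols[-1]) + 1, cls)]))
        pmap = build_pathology_map(runs, layout.shape)
        sig = extract_spectral_signatures(refl, pmap)
        rows[(sid, cls)] = sig.means[cls]
    wavelengths = bundle.cubes[next(iter(bundle.cubes))]["raw"].wavelengths
    df = pd.DataFrame.from_dict(rows, orient="index", columns=[f"{w:.0f}" for w in wavelengths])
    df.index = pd.MultiIndex.from_tuples(df.index, names=["subject_id", "class"])
    return df


def representative_feature_table(
    bundle: DatasetBundle, config: RunConfig | None = None
) -> pd.DataFrame:
    """Per-(subject, class) means of two signature-tracking features.

    ``fd_edge`` is the box-counting fractal dimension of the boundary of the
    second upper-threshold decomposition image of the epithelium.  Under the
    H&E palette the second multi-level Otsu threshold sits in the wide gap
    between the nuclei and cytoplasm intensity modes, so this edge set traces
    actual nucleus outlines; the first threshold falls inside the broad
    nuclear-stain mode and its edge follows stain jitter instead of
    architecture.  ``delaunay_perimeter_mean`` is the mean perimeter of the
    Delaunay triangles over segmented nucleus centroids.  These are the
    representative positively- and negatively-associated features.
    """
    from skimage import measure as _measure

    from .features import luminance, msfta_features, topology_features

    config = config or RunConfig()
    rows = []
    for rec in bundle.records:
        masks, _ = segment_tissue(rec["rgb"], config.segmentation)
        blk = msfta_features(luminance(rec["rgb"]), masks.epithelium, config.texture)
        fd = {
            n: v for n, v, ok in zip(blk.names, blk.values, blk.valid) if ok
        }.get("msfta.b1.edge.fractal_dimension", np.nan)
        cents = np.array(
            [r.centroid for r in _measure.regionprops(masks.nuclei_labels)]
        ).reshape(-1, 2)
        topo = topology_features(cents)
        perim = topo.values[topo.names.index("topo.perimeter.mean")]
        rows.append(
            {
                "subject_id": rec["subject_id"],
                "class": rec["class"],
                "fd_edge": fd,
                "delaunay_perimeter_mean": perim if topo.valid.any() else np.nan,
            }
        )
    df = pd.DataFrame(rows).groupby(["subject_id", "class"]).mean()
    return df.dropna()


def run_end_to_end(config: RunConfig) -> Path:
    """Run the whole analysis into ``config.out_dir``; returns the run dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("generating synthetic cohort (seed=%d)", config.seed)
    bundle = generate_paired_dataset(
        n_subjects=config.n_subjects,
        images_per_class=config.images_per_class,
        effect_size=config.effect_size,
        seed=config.seed,
    )
    bundle.manifest().to_csv(out / "manifest.csv", index=False)

    logger.info("segmenting and extracting features")
    fm = extract_feature_matrix(bundle, config)
    fm.to_csv(out / "features.csv")
    feature_cols = [c for c in fm.columns if c not in ("subject_id", "class", "label")]

    logger.info("ranking features with mRMR on the full matrix")
    keep = fm[feature_cols].std() > 0
    ranked = mrmr_rank(
        fm[[c for c, k in zip(feature_cols, keep) if k]],
        fm["label"].to_numpy(),
        m=30,
    )
    ranked.to_frame().to_csv(out / "mrmr_ranking.csv", index=False)

    logger.info("nested leave-one-subject-out cross-validation")
    report = nested_cv(
        fm[feature_cols],
        fm["label"].to_numpy(),
        fm["subject_id"].to_numpy(),
        config.grid,
        image_ids=fm.index.to_numpy(),
    )
    report.write_json(out / "cv_report.json")

    logger.info("calibrating cubes and extracting signatures")
    sigs = signatures_from_bundle(bundle)
    sigs.to_csv(out / "signatures.csv")

    # association sample unit: (subject, class) mean feature values
    selected = ranked.names[: min(30, len(ranked.names))]
    per_sample = fm.groupby(["subject_id", "class"])[selected].mean()
    aligned = per_sample.join(sigs, how="inner")
    assoc = spearman_matrix(aligned[selected], aligned[sigs.columns], config.association)
    assoc.write_csv(str(out / "association"))
    summarize_heatmap(assoc, config.association).to_csv(out / "association_summary.csv")
    plot_heatmap(assoc, str(out / "association_heatmap.png"))

    summary = {
        "seed": config.seed,
        "n_images": int(len(fm)),
        "n_features": len(feature_cols),
        "cv_accuracy": report.accuracy,
        "cv_sensitivity": report.sensitivity,
        "cv_specificity": report.specificity,
        "confusion": {"tp": report.tp, "fp": report.fp, "tn": report.tn, "fn": report.fn},
        "n_strong_associations": int(
            (assoc.row_mean.abs() >= config.association.strong_threshold).sum()
        ),
        "top_features": ranked.names[:10],
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return out
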