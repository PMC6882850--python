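"""Spearman association between histology features and spectral signatures.

For aligned samples (one row per subject-and-pathology-class, carrying that
class's mean feature values and mean reflectance spectrum), every
(feature, wavelength) pair gets a Spearman rank correlation rho and a
two-sided p-value (t approximation on average ranks, tie-safe).  Cells with
p <= alpha form the significance mask; the heatmap convention is green for
significant positive, red for significant negative, white otherwise.
Row summaries (mean +/- sd of rho across wavelengths) flag features whose
|mean rho| reaches 0.5 as strongly associated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import AssociationParams

__all__ = ["AssociationReport", "spearman_matrix", "summarize_heatmap", "plot_heatmap"]

DEFAULT_PARAMS = AssociationParams()


@dataclass
class AssociationReport:
    rho: pd.DataFrame          # features x wavelengths
    pvalues: pd.DataFrame
    significant: pd.DataFrame  # boolean, p <= alpha (and valid)
    valid: pd.DataFrame        # False where a variable was constant
    row_mean: pd.Series
    row_sd: pd.Series
    alpha: float

    def write_csv(self, prefix: str) -> None:
        self.rho.to_csv(f"{prefix}_rho.csv")
        self.pvalues.to_csv(f"{prefix}_pvalues.csv")


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    flat = p.ravel()
    n = flat.size
    order = np.argsort(flat)
    ranked = flat[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0, 1)
    return out.reshape(p.shape)


def spearman_matrix(
    feature_table: pd.DataFrame,
    signature_table: pd.DataFrame,
    params: AssociationParams = DEFAULT_PARAMS,
) -> AssociationReport:
    """Feature x wavelength Spearman rho / p matrices with significance mask.

    Constant columns yield invalid (flagged) cells, not rho = 0.
    """
    if len(feature_table) != len(signature_table):
        raise ValueError("feature and signature tables must share samples")
    n = len(feature_table)
    if n < 3:
        raise ValueError("need at least 3 aligned samples")
    F = feature_table.to_numpy(dtype=float)
    S = signature_table.to_numpy(dtype=float)
    f_ok = F.std(axis=0) > 0
    s_ok = S.std(axis=0) > 0

    # Pearson correlation of average ranks (tie-safe Spearman)
    Fr = sps.rankdata(F, axis=0)
    Sr = sps.rankdata(S, axis=0)
    Fz = (Fr - Fr.mean(axis=0)) / np.where(Fr.std(axis=0) > 0, Fr.std(axis=0), 1.0)
    Sz = (Sr - Sr.mean(axis=0)) / np.where(Sr.std(axis=0) > 0, Sr.std(axis=0), 1.0)
    rho = (Fz.T @ Sz) / n
    rho = np.clip(rho, -1.0, 1.0)
    valid = np.outer(f_ok, s_ok)
    rho[~valid] = 0.0

    # two-sided p by the t approximation with n - 2 degrees of freedom
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - rho**2))
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    p[np.abs(rho) >= 1.0] = 0.0
    p[~valid] = 1.0
    if params.fdr:
        p_eff = _bh_adjust(p)
    else:
        p_eff = p
    sig = (p_eff <= params.alpha) & valid

    fi = feature_table.columns
    wi = signature_table.columns
    rho_df = pd.DataFrame(rho, index=fi, columns=wi)
    valid_df = pd.DataFrame(valid, index=fi, columns=wi)
    row_mean = rho_df.where(valid_df).mean(axis=1).fillna(0.0)
    row_sd = rho_df.where(valid_df).std(axis=1).fillna(0.0)
    return AssociationReport(
        rho=rho_df,
        pvalues=pd.DataFrame(p, index=fi, columns=wi),
        significant=pd.DataFrame(sig, index=fi, columns=wi),
        valid=valid_df,
        row_mean=row_mean,
        row_sd=row_sd,
        alpha=params.alpha,
    )


def summarize_heatmap(
    report: AssociationReport, params: AssociationParams = DEFAULT_PARAMS
) -> pd.DataFrame:
    """Cell categories plus per-feature row summaries and strength flags."""
    cat = np.full(report.rho.shape, "nonsignificant", dtype=object)
    sig = report.significant.to_numpy()
    rho = report.rho.to_numpy()
    cat[sig & (rho > 0)] = "positive-significant"
    cat[sig & (rho < 0)] = "negative-significant"
    table = pd.DataFrame(cat, index=report.rho.index, columns=report.rho.columns)
    table["row_mean_rho"] = report.row_mean
    table["row_sd_rho"] = report.row_sd
    table["strong"] = report.row_mean.abs() >= params.strong_threshold
    return table


def plot_heatmap(report: AssociationReport, path: str) -> None:
    """Green/red/white heatmap of signed significant correlations."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap

    shown = report.rho.where(report.significant, other=0.0)
    cmap = LinearSegmentedColormap.from_list("assoc", ["red", "white", "green"])
    fig, ax = plt.subplots(figsize=(10, max(3, 0.25 * len(shown))))
    im = ax.imshow(shown.to_numpy(), cmap=cmap, vmin=-1, vmax=1, aspect="auto")
    ax.set_yticks(range(len(shown.index)))
    ax.set_yticklabels(shown.index, fontsize=6)
    ax.set_xlabel("wavelength (nm)")
    fig.colorbar(im, ax=ax, label="Spearman rho (white = not significant)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
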