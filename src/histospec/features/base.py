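"""Shared feature-block plumbing.

Every extractor returns a :class:`FeatureBlock` of named scalars plus a
per-feature validity flag.  Features that are undefined on degenerate input
(empty region, constant intensity, too few nuclei) are 0 with the flag
cleared — never NaN — so downstream selection and cross-validation always
see finite matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FeatureBlock", "concat_blocks", "shannon_entropy", "seven_stats"]


@dataclass
class FeatureBlock:
    names: list[str]
    values: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (len(self.names) == self.values.size == self.valid.size):
            raise ValueError("names/values/valid lengths differ")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature block contains non-finite values")

    def __len__(self) -> int:
        return self.values.size

    def prefixed(self, prefix: str) -> "FeatureBlock":
        return FeatureBlock([f"{prefix}{n}" for n in self.names], self.values, self.valid)

    @classmethod
    def invalid(cls, names: list[str]) -> "FeatureBlock":
        n = len(names)
        return cls(names, np.zeros(n), np.zeros(n, dtype=bool))


def concat_blocks(blocks: list[FeatureBlock]) -> FeatureBlock:
    names = [n for b in blocks for n in b.names]
    if len(set(names)) != len(names):
        raise ValueError("duplicate feature names across blocks")
    return FeatureBlock(
        names,
        np.concatenate([b.values for b in blocks]) if blocks else np.empty(0),
        np.concatenate([b.valid for b in blocks]) if blocks else np.empty(0, bool),
    )


def shannon_entropy(values: np.ndarray, bins: int = 256,
                    value_range: tuple[float, float] | None = None) -> float:
    """Base-2 Shannon entropy of a binned intensity histogram.

    An empty or single-valued sample has zero entropy.
    """
    values = np.asarray(values).ravel()
    if values.size == 0:
        return 0.0
    if value_range is None:
        lo, hi = float(values.min()), float(values.max())
        if hi <= lo:
            return 0.0
        value_range = (lo, hi)
    hist, _ = np.histogram(values, bins=bins, range=value_range)
    p = hist[hist > 0] / values.size
    return float(-(p * np.log2(p)).sum())


def seven_stats(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(mean, median, std, min, max, skewness, kurtosis) with validity flags.

    Spread and shape statistics need at least 2 samples and non-zero
    variance; otherwise they are 0 and flagged invalid.
    """
    from scipy import stats as sps

    values = np.asarray(values, dtype=float).ravel()
    out = np.zeros(7)
    valid = np.zeros(7, dtype=bool)
    if values.size == 0:
        return out, valid
    out[0] = values.mean()
    out[1] = float(np.median(values))
    out[3] = values.min()
    out[4] = values.max()
    valid[[0, 1, 3, 4]] = True
    if values.size >= 2:
        out[2] = values.std(ddof=1)
        if out[2] > 0:
            valid[2] = True
            out[5] = float(sps.skew(values))
            out[6] = float(sps.kurtosis(values))
            valid[[5, 6]] = True
    return out, valid


STAT_NAMES = ("mean", "median", "std", "min", "max", "skewness", "kurtosis")
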