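"""Count normalization and the expression-filter cascade.

The cascade mirrors the study design: keep features expressed (raw count
> 0) in at least 75% of samples, normalize by median-of-ratios size factors,
keep features with normalized count >= 1 in at least 90% of samples, then
flag features whose mean normalized count exceeds 500 as highly expressed.
Fractional sample thresholds use the ceiling (0.75 x 226 -> 170).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

COND_CONTROL = "control"
COND_CO2 = "CO2"


def size_factors(raw: pd.DataFrame, allow_pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios per-sample size factors.

    The reference is the per-feature geometric mean over features with
    strictly positive counts in every sample; each sample's factor is the
    median of its count/reference ratios over those features. With
    ``allow_pseudo_reference`` a half-count pseudo-reference is used when no
    all-positive feature exists.
    """
    mat = raw.to_numpy(dtype=float)
    if (mat < 0).any():
        raise ValueError("counts must be non-negative")
    all_pos = (mat > 0).all(axis=1)
    if not all_pos.any():
        if not allow_pseudo_reference:
            raise ValueError(
                "no feature with all-positive counts; geometric-mean reference "
                "undefined (set allow_pseudo_reference=True for a half-count fallback)"
            )
        mat = mat + 0.5
        all_pos = np.ones(len(mat), dtype=bool)
    sub = mat[all_pos]
    log_geomean = np.log(sub).mean(axis=1)
    ratios = sub / np.exp(log_geomean)[:, None]
    factors = np.median(ratios, axis=0)
    if (factors <= 0).any():
        raise ValueError("non-positive size factor computed")
    return pd.Series(factors, index=raw.columns, name="size_factor")


def normalize(raw: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    if factors is None:
        factors = size_factors(raw)
    return raw / factors


def _required_samples(n_samples: int, min_frac: float) -> int:
    return math.ceil(min_frac * n_samples)


def prevalence_filter(raw: pd.DataFrame, min_frac: float = 0.75) -> pd.Index:
    """Features with raw count > 0 in at least ceil(min_frac * n) samples."""
    need = _required_samples(raw.shape[1], min_frac)
    keep = (raw > 0).sum(axis=1) >= need
    return raw.index[keep]


def abundance_filter(
    normalized: pd.DataFrame, min_norm: float = 1.0, min_frac: float = 0.90
) -> pd.Index:
    """Features with normalized count >= min_norm in at least ceil(min_frac*n) samples."""
    need = _required_samples(normalized.shape[1], min_frac)
    keep = (normalized >= min_norm).sum(axis=1) >= need
    return normalized.index[keep]


def flag_highly_expressed(
    normalized: pd.DataFrame, threshold: float = 500.0, stat: str = "mean"
) -> pd.Index:
    """Features whose average normalized count is strictly above ``threshold``.

    ``stat`` may be ``mean`` (default), ``median`` or ``all`` (every sample
    above the threshold).
    """
    if stat == "mean":
        values = normalized.mean(axis=1)
    elif stat == "median":
        values = normalized.median(axis=1)
    elif stat == "all":
        values = normalized.min(axis=1)
    else:
        raise ValueError(f"unknown stat {stat!r}")
    return normalized.index[values > threshold]


def pca_log2(normalized: pd.DataFrame, n_components: int | None = None) -> pd.DataFrame:
    """Sample coordinates on principal components of log2(x+1) expression.

    Rows of the input are features, columns samples; the returned frame has
    one row per sample. Deterministic up to component sign.
    """
    if normalized.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples")
    X = np.log2(normalized.to_numpy(dtype=float) + 1.0).T  # samples x features
    k = n_components or min(X.shape)
    pca = PCA(n_components=min(k, min(X.shape)), svd_solver="full")
    coords = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    out = pd.DataFrame(coords, index=normalized.columns, columns=cols)
    out.attrs["explained_variance"] = pca.explained_variance_
    out.attrs["explained_variance_ratio"] = pca.explained_variance_ratio_
    return out


@dataclass
class ExpressionSet:
    """Raw counts, conditions, size factors and filter flags in one object."""

    raw: pd.DataFrame
    conditions: pd.Series  # sample -> control/CO2
    size_factors: pd.Series | None = None
    normalized: pd.DataFrame | None = None
    flags: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.conditions = self.conditions.reindex(self.raw.columns)
        if self.conditions.isna().any():
            missing = list(self.raw.columns[self.conditions.isna()])
            raise ValueError(f"samples without condition: {missing}")

    def run_filters(
        self,
        min_prev_frac: float = 0.75,
        min_norm: float = 1.0,
        min_norm_frac: float = 0.90,
        high_threshold: float = 500.0,
        allow_pseudo_reference: bool = False,
    ) -> "ExpressionSet":
        """Prevalence filter on raw counts -> normalize -> abundance filter -> flag.

        Normalization factors are computed on the prevalence-passing features
        (the cascade order of the study); flags are recorded for every input
        feature, monotone by construction.
        """
        prev = set(prevalence_filter(self.raw, min_prev_frac))
        kept_raw = self.raw.loc[sorted(prev)]
        self.size_factors = size_factors(
            kept_raw, allow_pseudo_reference=allow_pseudo_reference
        )
        self.normalized = normalize(self.raw, self.size_factors)
        norm_kept = self.normalized.loc[sorted(prev)]
        abund = set(abundance_filter(norm_kept, min_norm, min_norm_frac))
        high = set(flag_highly_expressed(self.normalized.loc[sorted(abund)], high_threshold))
        self.flags = pd.DataFrame(
            {
                "prevalence_pass": [f in prev for f in self.raw.index],
                "abundance_pass": [f in abund for f in self.raw.index],
                "highly_expressed": [f in high for f in self.raw.index],
            },
            index=self.raw.index,
        )
        return self

    @property
    def final_features(self) -> pd.Index:
        """Features surviving the whole cascade."""
        return self.flags.index[self.flags["abundance_pass"]]

    @property
    def highly_expressed(self) -> pd.Index:
        return self.flags.index[self.flags["highly_expressed"]]
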