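"""Minimal signed weighted co-expression network analysis.

Signed adjacency a_ij = ((1 + cor_ij)/2)^beta with the soft power beta
(default 10) chosen by the scale-free topology criterion, topological
overlap (TOM) similarity, module detection by average-linkage clustering of
1 - TOM with a static tree cut, module eigengenes (first principal
component) and Pearson module-trait correlation with significance at
p < 0.01.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

# WGCNA's conventional color sequence, largest module first.
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue", "darkred",
    "darkgreen", "darkturquoise", "darkgrey", "orange", "darkorange", "white",
    "skyblue", "saddlebrown", "steelblue", "paleturquoise", "violet",
]
UNASSIGNED = "grey"


@dataclass
class NetworkConfig:
    power: float = 10.0
    network_type: str = "signed"
    min_module_size: int = 30
    cut_height: float = 0.99
    alpha: float = 0.01

    def __post_init__(self) -> None:
        if self.power < 1:
            raise ValueError("soft power must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def signed_adjacency(expr: pd.DataFrame | np.ndarray, beta: float = 10.0) -> np.ndarray:
    """Signed adjacency ((1 + cor)/2)^beta over feature-pairwise Pearson correlation.

    ``expr`` is features x samples (log2(normalized+1) in the pipeline).
    """
    X = np.asarray(expr, dtype=float)
    sd = X.std(axis=1)
    if (sd == 0).any():
        bad = np.flatnonzero(sd == 0)
        names = (
            [str(expr.index[i]) for i in bad[:10]]
            if isinstance(expr, pd.DataFrame)
            else [str(i) for i in bad[:10]]
        )
        raise ValueError(f"zero-variance features: {', '.join(names)}")
    cor = np.corrcoef(X)
    adj = ((1.0 + np.clip(cor, -1.0, 1.0)) / 2.0) ** beta
    np.fill_diagonal(adj, 1.0)
    return adj


def tom(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap similarity of a symmetric adjacency in [0, 1].

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) where the
    sum and the connectivities k exclude i and j themselves; TOM_ii = 1.
    """
    A = np.asarray(adjacency, dtype=float)
    if A.shape[0] != A.shape[1] or not np.allclose(A, A.T):
        raise ValueError("adjacency must be square and symmetric")
    n = A.shape[0]
    Ad = A.copy()
    np.fill_diagonal(Ad, 0.0)
    k = Ad.sum(axis=1)
    shared = Ad @ Ad  # includes u=i,j terms only via zeroed diagonal -> excluded
    num = shared + Ad
    kmin = np.minimum.outer(k, k)
    denom = kmin + 1.0 - Ad
    with np.errstate(invalid="ignore", divide="ignore"):
        T = np.where(denom > 0, num / denom, 0.0)
    np.fill_diagonal(T, 1.0)
    return T


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log10 frequency ~ log10 mean-connectivity regression.

    Connectivities are binned into ``n_bins`` equal-width bins; empty bins are
    dropped. The fit R^2 is sign-adjusted: positive slope (the opposite of a
    scale-free degree law) makes the index negative.
    """
    k = np.asarray(connectivity, dtype=float)
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        mean_k = k[mask].mean()
        if mean_k <= 0:
            continue
        xs.append(np.log10(mean_k))
        ys.append(np.log10(mask.sum() / k.size))
    if len(xs) < 3:
        raise ValueError(f"only {len(xs)} occupied connectivity bins; need >= 3")
    slope, _, r, _, _ = stats.linregress(xs, ys)
    return float(-np.sign(slope) * r**2)


def pick_power(
    expr: pd.DataFrame | np.ndarray,
    candidate_powers=range(1, 21),
    r2_min: float = 0.8,
    n_bins: int = 10,
) -> tuple[float, dict[float, float]]:
    """Smallest soft power with scale-free fit R^2 >= r2_min.

    Returns ``(beta, {beta: signed R^2})``. When no candidate reaches the
    cutoff, the best-fitting power is returned with a warning.
    """
    fits: dict[float, float] = {}
    for beta in candidate_powers:
        adj = signed_adjacency(expr, beta)
        np.fill_diagonal(adj, 0.0)
        fits[beta] = scale_free_fit(adj.sum(axis=1), n_bins=n_bins)
        if fits[beta] >= r2_min:
            return float(beta), fits
    best = max(fits, key=fits.get)
    warnings.warn(
        f"no candidate power reached scale-free R^2 >= {r2_min}; "
        f"returning best fit beta={best} (R^2={fits[best]:.3f})"
    )
    return float(best), fits


@dataclass
class ModuleAssignment:
    labels: pd.Series  # feature -> module color ("grey" = unassigned)
    eigengenes: pd.DataFrame = field(default_factory=pd.DataFrame)  # module x sample
    trait_correlation: pd.DataFrame = field(default_factory=pd.DataFrame)

    def members(self, label: str) -> pd.Index:
        return self.labels.index[self.labels == label]

    @property
    def module_names(self) -> list[str]:
        return [m for m in self.labels.unique() if m != UNASSIGNED]

    def significant_modules(self, alpha: float = 0.01) -> list[str]:
        if self.trait_correlation.empty:
            raise ValueError("module-trait correlation not computed")
        sig = self.trait_correlation[self.trait_correlation["p"] < alpha]
        return list(sig.index)


def detect_modules(
    tom_matrix: np.ndarray,
    feature_ids,
    min_size: int = 30,
    cut_height: float = 0.99,
) -> ModuleAssignment:
    """Average-linkage clustering of 1 - TOM with a static cut.

    Clusters smaller than ``min_size`` are pooled into "grey"; the rest are
    labelled by decreasing size with the conventional color sequence.
    """
    feature_ids = pd.Index(feature_ids)
    dissim = 1.0 - np.asarray(tom_matrix, dtype=float)
    np.fill_diagonal(dissim, 0.0)
    dissim = np.clip((dissim + dissim.T) / 2.0, 0.0, None)
    Z = linkage(squareform(dissim, checks=False), method="average")
    raw = fcluster(Z, t=cut_height, criterion="distance")
    sizes = pd.Series(raw).value_counts()
    labels = pd.Series(UNASSIGNED, index=feature_ids, dtype=object)
    color_iter = iter(MODULE_COLORS)
    # decreasing size; cluster id breaks ties deterministically
    for cluster_id in sorted(sizes.index, key=lambda c: (-sizes[c], c)):
        if sizes[cluster_id] < min_size:
            continue
        try:
            color = next(color_iter)
        except StopIteration:
            color = f"module{cluster_id}"
        labels[raw == cluster_id] = color
    return ModuleAssignment(labels=labels)


def eigengene(expr: pd.DataFrame, module_features) -> pd.Series:
    """First principal component of the module's standardized expression.

    Unit-norm per-sample vector, sign oriented so its mean correlation with
    the module's features is positive.
    """
    sub = expr.loc[list(module_features)]
    if sub.shape[0] == 0:
        raise ValueError("empty module")
    if sub.shape[1] < 2:
        raise ValueError("eigengene needs >= 2 samples")
    X = sub.to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=0)
    if (sd == 0).any():
        sd = np.where(sd == 0, 1.0, sd)
    Z = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    v = vt[0]
    corrs = Z @ v  # proportional to feature-eigengene correlation
    if corrs.mean() < 0:
        v = -v
    return pd.Series(v, index=expr.columns, name="eigengene")


def module_eigengenes(expr: pd.DataFrame, assignment: ModuleAssignment) -> pd.DataFrame:
    rows = {
        m: eigengene(expr, assignment.members(m)) for m in assignment.module_names
    }
    return pd.DataFrame(rows).T


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and the two-sided p from t = r sqrt(n-2)/sqrt(1-r^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant vector: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
    p = 2 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def module_trait(
    eigengenes: pd.DataFrame, trait, alpha: float = 0.01
) -> pd.DataFrame:
    """Per-module Pearson correlation with the condition trait (control=0, CO2=1)."""
    trait = np.asarray(trait, dtype=float)
    rows = []
    for module, eg in eigengenes.iterrows():
        r, p = pearson_with_p(eg.to_numpy(), trait)
        rows.append({"module": module, "r": r, "p": p, "significant": p < alpha})
    return pd.DataFrame(rows).set_index("module")


def run_wgcna(
    expr: pd.DataFrame,
    trait,
    config: NetworkConfig | None = None,
) -> ModuleAssignment:
    """Adjacency -> TOM -> modules -> eigengenes -> module-trait correlation."""
    config = config or NetworkConfig()
    adj = signed_adjacency(expr, config.power)
    T = tom(adj)
    assignment = detect_modules(
        T, expr.index, min_size=config.min_module_size, cut_height=config.cut_height
    )
    if assignment.module_names:
        assignment.eigengenes = module_eigengenes(expr, assignment)
        assignment.trait_correlation = module_trait(
            assignment.eigengenes, trait, alpha=config.alpha
        )
    return assignment
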