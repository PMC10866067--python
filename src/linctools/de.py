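"""Differential-expression decision rule, stand-in test and chi-squared contrast.

The decision rule marks a feature differentially expressed when BH-adjusted
p <= 0.05, basemean (mean normalized count over all samples) >= 10 and
|log2 fold change| >= 0.3. Statistics come either from the built-in
rank-sum stand-in test or from an imported table (e.g. DESeq2 output); the
rule is always re-applied on import.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import COND_CO2, COND_CONTROL

DE_COLUMNS = ("basemean", "log2fc", "pvalue", "padj", "de_flag")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-invariant)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def apply_de_rule(
    table: pd.DataFrame,
    padj_max: float = 0.05,
    basemean_min: float = 10.0,
    lfc_min: float = 0.3,
) -> pd.Series:
    """The study's DE flag; all three boundaries inclusive, |log2fc| two-sided."""
    return (
        (table["padj"] <= padj_max)
        & (table["basemean"] >= basemean_min)
        & (table["log2fc"].abs() >= lfc_min)
    )


def standin_test(
    normalized: pd.DataFrame,
    conditions: pd.Series,
    padj_max: float = 0.05,
    basemean_min: float = 10.0,
    lfc_min: float = 0.3,
) -> pd.DataFrame:
    """Two-group rank-sum DE test on normalized counts.

    Not a negative-binomial model: log2fc is the shifted ratio of group means
    log2((mean_CO2 + 0.5) / (mean_control + 0.5)), p comes from a two-sample
    Wilcoxon rank-sum (tie-corrected normal approximation) per feature, and
    BH adjustment runs over all tested features. Intended as a dependency-free
    route; externally computed tables import via :func:`import_de`.
    """
    conditions = conditions.reindex(normalized.columns)
    groups = {c: normalized.columns[conditions == c] for c in (COND_CONTROL, COND_CO2)}
    for cond, cols in groups.items():
        if len(cols) < 2:
            raise ValueError(f"condition {cond!r} has {len(cols)} samples; need >= 2")
    x = normalized[groups[COND_CO2]].to_numpy(dtype=float)
    y = normalized[groups[COND_CONTROL]].to_numpy(dtype=float)
    basemean = normalized.mean(axis=1).to_numpy()
    log2fc = np.log2((x.mean(axis=1) + 0.5) / (y.mean(axis=1) + 0.5))
    # vectorized tie-corrected rank-sum over features
    pvals = stats.mannwhitneyu(
        x, y, axis=1, alternative="two-sided", method="asymptotic", use_continuity=False
    ).pvalue
    # constant features across both groups: no evidence either way
    constant = (normalized.nunique(axis=1) == 1).to_numpy()
    pvals = np.where(constant, 1.0, pvals)
    table = pd.DataFrame(
        {
            "basemean": basemean,
            "log2fc": log2fc,
            "pvalue": pvals,
            "padj": bh_adjust(pvals),
        },
        index=normalized.index,
    )
    table["de_flag"] = apply_de_rule(table, padj_max, basemean_min, lfc_min)
    return table


def deseq2_test(
    counts: pd.DataFrame,
    conditions: pd.Series,
    padj_max: float = 0.05,
    basemean_min: float = 10.0,
    lfc_min: float = 0.3,
) -> pd.DataFrame:
    """Negative-binomial DE statistics via pydeseq2, mapped into a DETable.

    The headline route for the decision rule: raw counts (integer) go through
    the Wald test of the DESeq2 model and the resulting
    baseMean/log2FoldChange/pvalue/padj columns are consumed exactly like an
    imported table, with the DE flag recomputed from the rule.
    """
    from pydeseq2.dds import DeseqDataSet
    from pydeseq2.ds import DeseqStats

    conditions = conditions.reindex(counts.columns)
    meta = pd.DataFrame({"condition": conditions})
    dds = DeseqDataSet(
        counts=counts.T.round().astype(int), metadata=meta,
        design="~condition", quiet=True,
    )
    dds.deseq2()
    stats_res = DeseqStats(dds, contrast=["condition", COND_CO2, COND_CONTROL],
                           quiet=True)
    stats_res.summary()
    r = stats_res.results_df
    table = pd.DataFrame(
        {
            "basemean": r["baseMean"],
            "log2fc": r["log2FoldChange"],
            "pvalue": r["pvalue"].fillna(1.0),
            "padj": r["padj"].fillna(1.0),
        }
    )
    table.index = pd.Index(r.index, name="feature_id")
    table["de_flag"] = apply_de_rule(table, padj_max, basemean_min, lfc_min)
    return table


DEFAULT_COLMAP = {
    "feature_id": "feature_id",
    "basemean": "basemean",
    "log2fc": "log2fc",
    "pvalue": "pvalue",
    "padj": "padj",
}


def import_de(
    tsv,
    colmap: dict[str, str] | None = None,
    padj_max: float = 0.05,
    basemean_min: float = 10.0,
    lfc_min: float = 0.3,
) -> pd.DataFrame:
    """Read an external DE table; the DE flag is recomputed from the rule.

    ``colmap`` maps canonical names (feature_id, basemean, log2fc, pvalue,
    padj) to the file's column names, e.g. DESeq2's baseMean/log2FoldChange.
    """
    mapping = dict(DEFAULT_COLMAP)
    if colmap:
        mapping.update(colmap)
    df = pd.read_csv(tsv, sep="\t")
    missing = [v for v in mapping.values() if v not in df.columns]
    if missing:
        raise ValueError(f"DE table missing columns: {', '.join(missing)}")
    table = pd.DataFrame(
        {
            "basemean": df[mapping["basemean"]].astype(float).to_numpy(),
            "log2fc": df[mapping["log2fc"]].astype(float).to_numpy(),
            "pvalue": df[mapping["pvalue"]].astype(float).to_numpy(),
            "padj": df[mapping["padj"]].astype(float).to_numpy(),
        },
        index=pd.Index(df[mapping["feature_id"]].astype(str), name="feature_id"),
    )
    table["de_flag"] = apply_de_rule(table, padj_max, basemean_min, lfc_min)
    return table


@dataclass
class ChangeMagnitudeComparison:
    """2x2 contrast of high-|log2fc| rates between two DE-gene groups."""

    table: np.ndarray  # rows: with/without neighbor; cols: high/not-high
    statistic: float
    p_value: float
    proportion_with: float
    proportion_without: float


def chi2_high_change(
    n_high_with: int,
    n_with: int,
    n_high_without: int,
    n_without: int,
    correction: bool = False,
) -> ChangeMagnitudeComparison:
    """Pearson chi-squared (df=1) on counts of high-change DE genes.

    No continuity correction by default: the uncorrected statistic is the one
    whose p-value matches the headline contrast of high-|log2fc| rates.
    """
    table = np.array(
        [
            [n_high_with, n_with - n_high_with],
            [n_high_without, n_without - n_high_without],
        ]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError(f"degenerate 2x2 table (zero marginal): {table.tolist()}")
    res = stats.chi2_contingency(table, correction=correction)
    return ChangeMagnitudeComparison(
        table=table,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        proportion_with=n_high_with / n_with,
        proportion_without=n_high_without / n_without,
    )


def compare_change_magnitudes(
    de_table: pd.DataFrame,
    neighbored_genes,
    lfc_cut: float = 2.0,
    correction: bool = False,
) -> ChangeMagnitudeComparison:
    """Do DE genes with a neighboring lincRNA show larger expression changes?

    Partitions DE features by membership in ``neighbored_genes`` (the coding
    genes assigned as a lincRNA neighbor), calls |log2fc| > lfc_cut "high
    change", and tests the 2x2 with an uncorrected Pearson chi-squared.
    """
    neighbored = set(neighbored_genes)
    de = de_table[de_table["de_flag"]]
    has = de.index.isin(neighbored)
    high = de["log2fc"].abs() > lfc_cut
    return chi2_high_change(
        int((has & high).sum()),
        int(has.sum()),
        int((~has & high).sum()),
        int((~has).sum()),
        correction=correction,
    )
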