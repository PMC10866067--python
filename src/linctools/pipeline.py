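"""End-to-end orchestration: coding calls -> consensus -> positional
classification -> expression filters -> DE / co-expression -> cis/trans
candidates, with a manifest of every threshold used and per-stage survivor
counts."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import coding as cp
from . import coexpression as wg
from . import de as dem
from . import positional as pos
from . import regulatory as reg
from .annotation import GenomeAnnotation
from .expression import ExpressionSet

logger = logging.getLogger("linctools.pipeline")


@dataclass
class PipelineConfig:
    """All pipeline thresholds; the defaults are the study's printed values."""

    m_votes: int = 2
    window_bp: int = 100_000
    min_prev_frac: float = 0.75
    min_norm: float = 1.0
    min_norm_frac: float = 0.90
    high_threshold: float = 500.0
    padj_max: float = 0.05
    basemean_min: float = 10.0
    lfc_min: float = 0.3
    power: float = 10.0
    min_module_size: int = 30
    cut_height: float = 0.99
    module_alpha: float = 0.01
    rho_min: float = 0.9
    trans_p_max: float = 0.01
    e_max: float = 1e-3
    density_window_bp: int = 1_000_000
    density_high_cutoff: int = 10
    chi2_lfc_cut: float = 2.0
    seed: int = 0

    def validate(self, n_tools: int | None = None) -> None:
        if n_tools is not None and self.m_votes > n_tools:
            raise ValueError(
                f"m_votes={self.m_votes} exceeds the {n_tools} coding-potential tools"
            )
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        for frac in (self.min_prev_frac, self.min_norm_frac):
            if not 0 < frac <= 1:
                raise ValueError("sample fractions must be in (0, 1]")


@dataclass
class PipelineReport:
    consensus_genes: set = field(default_factory=set)
    classes: list = field(default_factory=list)
    category_counts: dict = field(default_factory=dict)
    expression: ExpressionSet | None = None
    de_table: pd.DataFrame | None = None
    modules: wg.ModuleAssignment | None = None
    cis: list = field(default_factory=list)
    trans: list = field(default_factory=list)
    summary: pd.DataFrame | None = None
    stage_counts: dict = field(default_factory=dict)

    def manifest(self, config: PipelineConfig) -> dict:
        return {"thresholds": asdict(config), "stage_counts": self.stage_counts}


def run_pipeline(
    lnc_annotation: GenomeAnnotation,
    coding_annotation: GenomeAnnotation,
    callset: cp.CodingCallSet | None,
    counts: pd.DataFrame,
    conditions: pd.Series,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> PipelineReport:
    """Run the full flow on in-memory inputs.

    When ``callset`` is None every gene of ``lnc_annotation`` is taken as a
    consensus lncRNA (external consensus already applied). ``counts`` holds
    both lncRNA genes and coding genes as features. Stage outputs and the
    threshold manifest are written under ``out_dir`` when given.
    """
    config = config or PipelineConfig()
    config.validate(n_tools=len(callset.tools) if callset is not None else None)
    report = PipelineReport()
    t0 = time.time()

    # stage 1: consensus coding-potential voting
    if callset is not None:
        report.consensus_genes = callset.consensus(m_votes=config.m_votes)
    else:
        report.consensus_genes = set(lnc_annotation.genes)
    report.stage_counts["consensus_lnc_genes"] = len(report.consensus_genes)
    logger.info("consensus: %d lncRNA genes", len(report.consensus_genes))

    # stage 2: positional classification
    lnc_genes = [
        lnc_annotation.genes[g]
        for g in sorted(report.consensus_genes)
        if g in lnc_annotation.genes
    ]
    report.classes = pos.classify(lnc_genes, coding_annotation, W=config.window_bp)
    report.category_counts = pos.category_counts(report.classes)
    lincs = {
        c.lnc_gene_id for c in report.classes if c.category == pos.CATEGORY_INTERGENIC
    }
    report.stage_counts["lincRNA_genes"] = len(lincs)

    # stage 3: expression filters (lincRNAs and coding genes together)
    expr = ExpressionSet(counts, conditions).run_filters(
        min_prev_frac=config.min_prev_frac,
        min_norm=config.min_norm,
        min_norm_frac=config.min_norm_frac,
        high_threshold=config.high_threshold,
    )
    report.expression = expr
    final = set(expr.final_features)
    final_lincs = lincs & final
    report.stage_counts["expression_filtered_lincs"] = len(final_lincs)
    report.stage_counts["highly_expressed_lincs"] = len(set(expr.highly_expressed) & lincs)

    # stage 4: differential expression (stand-in test)
    norm_final = expr.normalized.loc[sorted(final)]
    report.de_table = dem.standin_test(
        norm_final,
        conditions,
        padj_max=config.padj_max,
        basemean_min=config.basemean_min,
        lfc_min=config.lfc_min,
    )
    report.stage_counts["de_features"] = int(report.de_table["de_flag"].sum())

    # stage 5: co-expression modules on log2(normalized + 1)
    import numpy as np

    log_expr = np.log2(norm_final + 1.0)
    trait = (conditions == "CO2").astype(float).to_numpy()
    report.modules = wg.run_wgcna(
        log_expr,
        trait,
        wg.NetworkConfig(
            power=config.power,
            min_module_size=config.min_module_size,
            cut_height=config.cut_height,
            alpha=config.module_alpha,
        ),
    )
    sig_modules = (
        report.modules.significant_modules(config.module_alpha)
        if report.modules.module_names
        else []
    )
    report.stage_counts["significant_modules"] = len(sig_modules)

    # stage 6: cis and trans regulatory candidates
    module_map = report.modules.labels.to_dict()
    report.cis, _ = reg.cis_candidates(
        report.classes,
        set(expr.highly_expressed) & lincs,
        report.de_table,
        module_map,
        sig_modules,
    )
    report.trans = reg.trans_candidates(
        expr.normalized.loc[sorted(final)],
        report.de_table,
        module_map,
        sig_modules,
        report.classes,
        coding_ids=set(coding_annotation.genes) & final,
        rho_min=config.rho_min,
        p_max=config.trans_p_max,
    )
    report.summary = reg.summarize(report.cis + report.trans)
    report.stage_counts["cis_pairs"] = len(
        {(c.linc_gene_id, c.coding_gene_id) for c in report.cis}
    )
    report.stage_counts["trans_pairs"] = len(
        {(c.linc_gene_id, c.coding_gene_id) for c in report.trans}
    )
    logger.info("pipeline finished in %.1f s", time.time() - t0)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pos.classes_to_frame(report.classes).to_csv(out / "classes.tsv", sep="\t", index=False)
        expr.normalized.to_csv(out / "normalized.tsv", sep="\t")
        expr.flags.to_csv(out / "flags.tsv", sep="\t")
        report.de_table.to_csv(out / "de.tsv", sep="\t")
        report.modules.labels.rename("module").to_csv(out / "modules.tsv", sep="\t")
        reg.candidates_to_frame(report.cis + report.trans).to_csv(
            out / "candidates.tsv", sep="\t", index=False
        )
        report.summary.to_csv(out / "summary.tsv", sep="\t")
        with open(out / "manifest.json", "w") as fh:
            json.dump(report.manifest(config), fh, indent=2, default=str)
    return report
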