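"""Cis and trans regulatory candidate lincRNA-coding gene pairs.

Three cis routes pair a lincRNA with its assigned genomic neighbor: (a) the
lincRNA is highly expressed, (b) both lincRNA and neighbor are
differentially expressed, (c) both sit in the same significantly
trait-correlated co-expression module. Two trans routes screen distant
pairs — DE lincRNA x DE coding gene, and same-significant-module pairs —
keeping those with Spearman |rho| >= 0.9 and p <= 0.01 on normalized
counts. LincRNAs that have a genomic neighbor are excluded from the trans
screen by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .positional import CATEGORY_INTERGENIC, PositionalClass

MODE_CIS_HIGH = "cis_highexpr_neighbor"
MODE_CIS_DE = "cis_de_de_neighbor"
MODE_CIS_MODULE = "cis_module_neighbor"
MODE_TRANS_DE = "trans_de_pair"
MODE_TRANS_MODULE = "trans_module_pair"

CIS_MODES = (MODE_CIS_HIGH, MODE_CIS_DE, MODE_CIS_MODULE)
TRANS_MODES = (MODE_TRANS_DE, MODE_TRANS_MODULE)


@dataclass(frozen=True)
class RegulatoryCandidate:
    linc_gene_id: str
    coding_gene_id: str
    mode: str
    rho: float | None = None
    p_value: float | None = None
    distance_bp: int | None = None
    orientation: str | None = None
    module: str | None = None


def spearman(x, y, method: str = "t") -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    Ties get average ranks; ``method="t"`` (default) uses the t-approximation
    t = rho sqrt(n-2)/sqrt(1-rho^2); ``method="exact"`` enumerates all rank
    permutations (only for n <= 8).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("spearman needs n >= 4")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector: correlation undefined")
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if method == "t":
        if abs(rho) >= 1.0:
            return rho, 0.0
        t = rho * np.sqrt(n - 2) / np.sqrt(1 - rho**2)
        p = 2 * stats.t.sf(abs(t), df=n - 2)
        return rho, float(p)
    if method == "exact":
        if n > 8:
            raise ValueError("exact permutation p limited to n <= 8")
        count = 0
        total = 0
        for perm in permutations(ry):
            r = np.corrcoef(rx, np.array(perm))[0, 1]
            count += abs(r) >= abs(rho) - 1e-12
            total += 1
        return rho, count / total
    raise ValueError(f"unknown method {method!r}")


def _de_set(de_table: pd.DataFrame) -> set[str]:
    return set(de_table.index[de_table["de_flag"]])


def cis_candidates(
    classes: Sequence[PositionalClass],
    high_set: Iterable[str],
    de_table: pd.DataFrame,
    modules: Mapping[str, str] | pd.Series | None = None,
    significant_modules: Iterable[str] = (),
) -> tuple[list[RegulatoryCandidate], list[str]]:
    """Emit (lincRNA, assigned neighbor) pairs along the three cis routes.

    Returns ``(candidates, skipped)`` where ``skipped`` lists lincRNAs that
    had no assigned neighbor and so joined no cis route. A pair may appear
    under several modes.
    """
    high = set(high_set)
    de = _de_set(de_table)
    modules = dict(modules or {})
    significant = set(significant_modules)
    out: list[RegulatoryCandidate] = []
    skipped: list[str] = []
    for c in classes:
        if c.category != CATEGORY_INTERGENIC or c.neighbor_gene_id is None:
            skipped.append(c.lnc_gene_id)
            continue
        common = dict(
            linc_gene_id=c.lnc_gene_id,
            coding_gene_id=c.neighbor_gene_id,
            distance_bp=c.distance_bp,
            orientation=c.orientation,
        )
        if c.lnc_gene_id in high:
            out.append(RegulatoryCandidate(mode=MODE_CIS_HIGH, **common))
        if c.lnc_gene_id in de and c.neighbor_gene_id in de:
            out.append(RegulatoryCandidate(mode=MODE_CIS_DE, **common))
        m_linc = modules.get(c.lnc_gene_id)
        if (
            m_linc is not None
            and m_linc in significant
            and modules.get(c.neighbor_gene_id) == m_linc
        ):
            out.append(RegulatoryCandidate(mode=MODE_CIS_MODULE, module=m_linc, **common))
    return out, skipped


def trans_candidates(
    normalized: pd.DataFrame,
    de_table: pd.DataFrame,
    modules: Mapping[str, str] | pd.Series | None,
    significant_modules: Iterable[str],
    classes: Sequence[PositionalClass],
    coding_ids: Iterable[str] | None = None,
    rho_min: float = 0.9,
    p_max: float = 0.01,
    exclude_with_neighbor: bool = True,
) -> list[RegulatoryCandidate]:
    """Screen distant lincRNA-coding pairs by Spearman correlation.

    Universe (d): DE lincRNA x DE coding gene; universe (e): lincRNA x coding
    gene sharing a significant module. LincRNAs with an assigned neighbor are
    removed first when ``exclude_with_neighbor``. Pairs pass with
    |rho| >= rho_min and p <= p_max, computed on normalized counts.
    """
    modules = dict(modules or {})
    significant = set(significant_modules)
    linc_ids = {c.lnc_gene_id for c in classes}
    if exclude_with_neighbor:
        with_neighbor = {
            c.lnc_gene_id for c in classes if c.neighbor_gene_id is not None
        }
        linc_ids -= with_neighbor
    linc_ids &= set(normalized.index)
    if coding_ids is None:
        coding = set(normalized.index) - {c.lnc_gene_id for c in classes}
    else:
        coding = set(coding_ids) & set(normalized.index)
    de = _de_set(de_table)

    universe: dict[tuple[str, str], list] = {}
    for linc in sorted(linc_ids & de):
        for cg in sorted(coding & de):
            universe.setdefault((linc, cg), []).append((MODE_TRANS_DE, None))
    for linc in sorted(linc_ids):
        m = modules.get(linc)
        if m is None or m not in significant:
            continue
        for cg in sorted(coding):
            if modules.get(cg) == m:
                universe.setdefault((linc, cg), []).append((MODE_TRANS_MODULE, m))
    if not universe:
        import warnings

        warnings.warn("empty trans candidate universe")
        return []
    out: list[RegulatoryCandidate] = []
    for (linc, cg), modes in sorted(universe.items()):
        rho, p = spearman(normalized.loc[linc], normalized.loc[cg])
        if abs(rho) >= rho_min and p <= p_max:
            for mode, module in modes:
                out.append(
                    RegulatoryCandidate(
                        linc_gene_id=linc,
                        coding_gene_id=cg,
                        mode=mode,
                        rho=rho,
                        p_value=p,
                        module=module,
                    )
                )
    return out


def summarize(candidates: Iterable[RegulatoryCandidate]) -> pd.DataFrame:
    """Per-mode deduplicated pair counts with distinct-gene tallies."""
    rows = []
    by_mode: dict[str, set[tuple[str, str]]] = {}
    for c in candidates:
        by_mode.setdefault(c.mode, set()).add((c.linc_gene_id, c.coding_gene_id))
    for mode in CIS_MODES + TRANS_MODES:
        pairs = by_mode.get(mode, set())
        rows.append(
            {
                "mode": mode,
                "pairs": len(pairs),
                "distinct_lincs": len({p[0] for p in pairs}),
                "distinct_coding": len({p[1] for p in pairs}),
            }
        )
    all_pairs = set().union(*by_mode.values()) if by_mode else set()
    rows.append(
        {
            "mode": "all",
            "pairs": len(all_pairs),
            "distinct_lincs": len({p[0] for p in all_pairs}),
            "distinct_coding": len({p[1] for p in all_pairs}),
        }
    )
    return pd.DataFrame(rows).set_index("mode")


def candidates_to_frame(candidates: Iterable[RegulatoryCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "linc_gene_id": c.linc_gene_id,
                "coding_gene_id": c.coding_gene_id,
                "mode": c.mode,
                "rho": c.rho,
                "p_value": c.p_value,
                "distance_bp": c.distance_bp,
                "orientation": c.orientation,
                "module": c.module,
            }
            for c in candidates
        ]
    )
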