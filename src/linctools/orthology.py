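"""Reciprocal-best-hit lincRNA orthology from BLASTn tabular output.

Hits are outfmt-6 rows; per query the best subject is the minimum e-value
passing the cutoff (default 1e-3), ties broken by higher bit score then
lexicographic subject id. A pair is orthologous when the two directions'
best hits are reciprocal. Neighbor congruence asks whether the two
lincRNAs' nearest coding genes carry the same annotated gene name.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_blast_outfmt6(path) -> pd.DataFrame:
    """Read a BLAST tabular (outfmt 6) file; one row per HSP."""
    df = pd.read_csv(path, sep="\t", header=None, names=OUTFMT6_COLUMNS, comment="#")
    if (df["evalue"] < 0).any():
        raise ValueError("negative e-value in hit table")
    return df


def best_hits(
    hit_table: pd.DataFrame, e_max: float = 1e-3
) -> dict[str, tuple[str, float, float]]:
    """Per query, the best subject by e-value among hits with e <= e_max.

    Multiple HSPs per query-subject pair collapse to their minimum e-value
    (keeping the larger bit score). Returns query -> (subject, evalue,
    bitscore); queries with no passing hit are absent.
    """
    df = hit_table[hit_table["evalue"] <= e_max]
    if df.empty:
        return {}
    collapsed = (
        df.sort_values(["evalue", "bitscore"], ascending=[True, False])
        .groupby(["qseqid", "sseqid"], as_index=False)
        .first()
    )
    out: dict[str, tuple[str, float, float]] = {}
    for row in collapsed.itertuples(index=False):
        q, s = str(row.qseqid), str(row.sseqid)
        cand = (float(row.evalue), -float(row.bitscore), s)
        cur = out.get(q)
        if cur is None or cand < (cur[1], -cur[2], cur[0]):
            out[q] = (s, float(row.evalue), float(row.bitscore))
    return out


@dataclass
class OrthologPair:
    focal_linc_id: str
    other_linc_id: str
    species: str | None = None
    forward_evalue: float | None = None
    reverse_evalue: float | None = None
    congruent_neighbor: bool | None = None
    shared_neighbor_name: str | None = None


def reciprocal_best_hits(
    forward_map: Mapping[str, tuple[str, float, float]],
    reverse_map: Mapping[str, tuple[str, float, float]],
    species: str | None = None,
) -> list[OrthologPair]:
    """Pairs (q, s) with forward best q->s and reverse best s->q."""
    pairs = []
    for q in sorted(forward_map):
        s, fwd_e, _ = forward_map[q]
        rev = reverse_map.get(s)
        if rev is not None and rev[0] == q:
            pairs.append(
                OrthologPair(
                    focal_linc_id=q,
                    other_linc_id=s,
                    species=species,
                    forward_evalue=fwd_e,
                    reverse_evalue=rev[1],
                )
            )
    return pairs


def rbh_from_tables(
    forward_hits: pd.DataFrame,
    reverse_hits: pd.DataFrame,
    e_max: float = 1e-3,
    species: str | None = None,
) -> list[OrthologPair]:
    return reciprocal_best_hits(
        best_hits(forward_hits, e_max), best_hits(reverse_hits, e_max), species=species
    )


def neighbor_congruence(
    pairs: Iterable[OrthologPair],
    focal_neighbor_names: Mapping[str, str],
    other_neighbor_names: Mapping[str, str] | Mapping[str, Mapping[str, str]],
    by_species: bool = False,
) -> list[OrthologPair]:
    """Annotate pairs with whether the two neighbors share a gene name.

    Gene symbols are compared case-insensitively. With ``by_species`` the
    ``other_neighbor_names`` mapping is species -> {linc -> name}. Pairs with
    a missing neighbor annotation get ``congruent_neighbor=None`` (unknown),
    excluded from congruent counts.
    """
    out = []
    for p in pairs:
        focal = focal_neighbor_names.get(p.focal_linc_id)
        if by_species:
            table = other_neighbor_names.get(p.species, {})
        else:
            table = other_neighbor_names
        other = table.get(p.other_linc_id)
        if focal is None or other is None:
            congruent, shared = None, None
        else:
            congruent = focal.strip().upper() == str(other).strip().upper()
            shared = focal.strip().upper() if congruent else None
        out.append(
            OrthologPair(
                focal_linc_id=p.focal_linc_id,
                other_linc_id=p.other_linc_id,
                species=p.species,
                forward_evalue=p.forward_evalue,
                reverse_evalue=p.reverse_evalue,
                congruent_neighbor=congruent,
                shared_neighbor_name=shared,
            )
        )
    return out


def congruent_linc_count(pairs: Iterable[OrthologPair]) -> int:
    """Focal lincRNAs with a same-named neighbor in at least one species."""
    return len({p.focal_linc_id for p in pairs if p.congruent_neighbor})


def species_specificity(
    n_lincs: int, orthologous_lincs: Iterable[str] | int
) -> tuple[int, float, float]:
    """(n_orthologous, % orthologous, % species-specific), percentages to 2 dp."""
    if n_lincs == 0:
        raise ValueError("n_lincs must be positive")
    if isinstance(orthologous_lincs, int):
        n_orth = orthologous_lincs
    else:
        n_orth = len(set(orthologous_lincs))
    if n_orth > n_lincs:
        raise ValueError("orthologous set larger than the lincRNA universe")
    pct_orth = round(100.0 * n_orth / n_lincs, 2)
    pct_specific = round(100.0 * (n_lincs - n_orth) / n_lincs, 2)
    return n_orth, pct_orth, pct_specific
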