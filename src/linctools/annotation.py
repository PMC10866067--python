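"""Genomic data model, GTF I/O, interval indexing and descriptive statistics.

Coordinates are 0-based half-open internally; GTF is 1-based inclusive on
disk and all conversion happens at the I/O boundary.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

STRAND_UNKNOWN = "."
_VALID_STRANDS = {"+", "-", STRAND_UNKNOWN}


class GtfParseError(ValueError):
    """Record-level GTF error, carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


@dataclass
class TranscriptModel:
    """A stranded, exon-resolved transcript.

    ``exons`` are 0-based half-open ``(start, end)`` intervals, kept sorted
    and non-overlapping.
    """

    transcript_id: str
    gene_id: str
    seq_id: str
    strand: str
    exons: list[tuple[int, int]]
    biotype: str = "unassigned"

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id}: no exons")
        if self.strand not in _VALID_STRANDS:
            warnings.warn(
                f"transcript {self.transcript_id}: unknown strand symbol "
                f"{self.strand!r}, treating as unknown"
            )
            self.strand = STRAND_UNKNOWN
        exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if e1 > s2:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons "
                    f"({s1},{e1}) and ({s2},{e2})"
                )
        for s, e in exons:
            if s >= e:
                raise ValueError(
                    f"transcript {self.transcript_id}: empty/inverted exon ({s},{e})"
                )
        self.exons = exons

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def five_prime(self) -> int | None:
        """Coordinate of the 5' end (None when strand is unknown)."""
        s, e = self.span
        if self.strand == "+":
            return s
        if self.strand == "-":
            return e
        return None


@dataclass
class GeneModel:
    gene_id: str
    seq_id: str
    strand: str
    transcripts: list[TranscriptModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        for t in self.transcripts:
            if t.gene_id != self.gene_id or t.seq_id != self.seq_id:
                raise ValueError(
                    f"gene {self.gene_id}: transcript {t.transcript_id} "
                    "does not share gene_id/seq_id"
                )

    @property
    def span(self) -> tuple[int, int]:
        starts = [t.span[0] for t in self.transcripts]
        ends = [t.span[1] for t in self.transcripts]
        return min(starts), max(ends)

    @property
    def transcript_ids(self) -> list[str]:
        return [t.transcript_id for t in self.transcripts]

    @property
    def n_exons(self) -> int:
        """Exon count of the transcript with the most exons."""
        return max(t.n_exons for t in self.transcripts)


class GenomeAnnotation:
    """Gene models plus a per-scaffold interval index over gene spans."""

    def __init__(
        self,
        genes: Mapping[str, GeneModel] | Iterable[GeneModel],
        scaffold_lengths: Mapping[str, int] | None = None,
    ):
        if not isinstance(genes, Mapping):
            genes = {g.gene_id: g for g in genes}
        self.genes: dict[str, GeneModel] = dict(genes)
        self.scaffold_lengths: dict[str, int] = dict(scaffold_lengths or {})
        self._index: dict[str, IntervalTree] = {}
        for g in self.genes.values():
            tree = self._index.setdefault(g.seq_id, IntervalTree())
            s, e = g.span
            tree.addi(s, e, g.gene_id)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self.genes[gene_id]

    def scaffolds(self) -> list[str]:
        return sorted(
            set(self._index) | set(self.scaffold_lengths),
        )

    def overlapping(self, seq_id: str, start: int, end: int) -> list[str]:
        """Gene ids whose span overlaps [start, end) on seq_id."""
        tree = self._index.get(seq_id)
        if tree is None:
            return []
        return sorted(iv.data for iv in tree.overlap(start, end))

    def nearest(self, seq_id: str, start: int, end: int) -> tuple[str, int] | None:
        """Nearest gene on seq_id by edge-to-edge distance to [start, end).

        Overlapping genes have distance 0. Ties broken by smaller gene_id.
        Returns None when the scaffold holds no genes.
        """
        tree = self._index.get(seq_id)
        if tree is None or len(tree) == 0:
            return None
        best: tuple[int, str] | None = None
        for iv in tree:
            d = edge_distance((start, end), (iv.begin, iv.end))
            key = (d, iv.data)
            if best is None or key < best:
                best = key
        return best[1], best[0]


def edge_distance(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Edge-to-edge distance between half-open intervals; 0 if they overlap."""
    if a[0] < b[1] and b[0] < a[1]:
        return 0
    return max(a[0] - b[1], b[0] - a[1], 0)


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(text: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(text))


def read_gtf(
    path,
    feature_policy: Sequence[str] = ("exon",),
    scaffold_lengths: Mapping[str, int] | None = None,
) -> GenomeAnnotation:
    """Read a GTF file into a :class:`GenomeAnnotation`.

    Only rows whose feature type is in ``feature_policy`` contribute exons;
    transcripts are grouped into genes by ``gene_id``. Rows missing the
    mandatory ``gene_id``/``transcript_id`` attributes raise, carrying the
    line number; ``start > end`` likewise. Strand symbols other than
    ``+``/``-`` become unknown with a warning.
    """
    feature_policy = set(feature_policy)
    # (gene_id, transcript_id) -> accumulating exon rows
    tx_rows: dict[tuple[str, str], dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"expected 9 tab-separated fields, got {len(fields)}", lineno
                )
            seq_id, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature not in feature_policy:
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise GtfParseError(f"non-integer coordinates {start_s},{end_s}", lineno)
            if start > end:
                raise GtfParseError(f"malformed coordinate: start {start} > end {end}", lineno)
            attr = _parse_attributes(attrs)
            if "gene_id" not in attr or "transcript_id" not in attr:
                raise GtfParseError("missing mandatory gene_id/transcript_id attribute", lineno)
            if strand not in ("+", "-"):
                if strand not in (".", "?"):
                    warnings.warn(
                        f"line {lineno}: unknown strand symbol {strand!r}, treating as unknown"
                    )
                strand = STRAND_UNKNOWN
            key = (attr["gene_id"], attr["transcript_id"])
            rec = tx_rows.setdefault(
                key,
                {"seq_id": seq_id, "strand": strand, "exons": [],
                 "biotype": attr.get("gene_biotype", attr.get("transcript_biotype", "unassigned"))},
            )
            # GTF 1-based inclusive -> 0-based half-open
            rec["exons"].append((start - 1, end))

    genes: dict[str, GeneModel] = {}
    grouped: dict[str, list[TranscriptModel]] = {}
    for (gene_id, tx_id), rec in tx_rows.items():
        tx = TranscriptModel(
            transcript_id=tx_id,
            gene_id=gene_id,
            seq_id=rec["seq_id"],
            strand=rec["strand"],
            exons=rec["exons"],
            biotype=rec["biotype"] if rec["biotype"] in
            ("coding", "noncoding_candidate") else "unassigned",
        )
        grouped.setdefault(gene_id, []).append(tx)
    for gene_id, txs in grouped.items():
        genes[gene_id] = GeneModel(
            gene_id=gene_id,
            seq_id=txs[0].seq_id,
            strand=txs[0].strand if all(t.strand == txs[0].strand for t in txs)
            else STRAND_UNKNOWN,
            transcripts=sorted(txs, key=lambda t: t.transcript_id),
        )
    return GenomeAnnotation(genes, scaffold_lengths=scaffold_lengths)


def write_gtf(annotation: GenomeAnnotation, path) -> None:
    """Write exon rows (1-based inclusive) with gene_id/transcript_id attrs."""
    with open(path, "w") as fh:
        for gene_id in sorted(annotation.genes):
            g = annotation.genes[gene_id]
            for t in g.transcripts:
                for s, e in t.exons:
                    attrs = (
                        f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}";'
                    )
                    fh.write(
                        "\t".join(
                            [g.seq_id, "linctools", "exon", str(s + 1), str(e),
                             ".", t.strand, ".", attrs]
                        )
                        + "\n"
                    )


@dataclass
class DensityWindows:
    """Gene counts in non-overlapping windows tiling the concatenated genome.

    Scaffolds are concatenated longest-to-shortest before tiling, the
    convention used for whole-genome density displays.
    """

    window_bp: int
    counts_a: np.ndarray
    counts_b: np.ndarray
    high_cutoff: int

    @property
    def n_windows(self) -> int:
        return len(self.counts_a)

    @property
    def high_a(self) -> np.ndarray:
        return self.counts_a > self.high_cutoff

    @property
    def high_b(self) -> np.ndarray:
        return self.counts_b > self.high_cutoff


def gene_density_windows(
    annotation: GenomeAnnotation,
    gene_ids_a: Iterable[str],
    gene_ids_b: Iterable[str] = (),
    window_bp: int = 1_000_000,
    high_cutoff: int = 10,
    assignment: str = "midpoint",
) -> DensityWindows:
    """Count two gene sets in 1 Mb (default) windows over the genome.

    Every gene falls in exactly one window: by default the window containing
    its span midpoint (``assignment="midpoint"``); ``"any_overlap"`` counts a
    gene in every window its span touches (counts then need not sum to the
    gene total).
    """
    if assignment not in ("midpoint", "any_overlap"):
        raise ValueError(f"unknown assignment rule {assignment!r}")
    scaffolds = sorted(
        annotation.scaffold_lengths,
        key=lambda s: (-annotation.scaffold_lengths[s], s),
    )
    needed = {annotation.genes[g].seq_id for g in list(gene_ids_a) + list(gene_ids_b)}
    missing = needed - set(scaffolds)
    if missing:
        raise ValueError(f"missing scaffold length for: {', '.join(sorted(missing))}")
    offsets: dict[str, int] = {}
    total = 0
    for s in scaffolds:
        offsets[s] = total
        total += annotation.scaffold_lengths[s]
    n_windows = max(1, math.ceil(total / window_bp))

    def bin_counts(gene_ids: Iterable[str]) -> np.ndarray:
        counts = np.zeros(n_windows, dtype=int)
        for gid in gene_ids:
            g = annotation.genes[gid]
            s, e = g.span
            off = offsets[g.seq_id]
            if assignment == "midpoint":
                mid = off + (s + e) // 2
                counts[min(mid // window_bp, n_windows - 1)] += 1
            else:
                w0 = (off + s) // window_bp
                w1 = (off + e - 1) // window_bp
                for w in range(w0, min(w1, n_windows - 1) + 1):
                    counts[w] += 1
        return counts

    return DensityWindows(
        window_bp=int(window_bp),
        counts_a=bin_counts(gene_ids_a),
        counts_b=bin_counts(gene_ids_b),
        high_cutoff=high_cutoff,
    )


def descriptive_compare(values_a, values_b) -> tuple[float, float]:
    """Two-sample Wilcoxon rank-sum test (normal approximation, tie-corrected).

    Returns ``(W, p)`` where ``W`` is the rank-sum of sample ``a`` within the
    pooled ranking (average ranks for ties) and ``p`` is the two-sided
    tie-corrected normal-approximation p-value. Identical pooled values in
    both samples give p = 1 with a warning.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    w = float(ranks[: a.size].sum())
    if np.all(pooled == pooled[0]):
        warnings.warn("all values tied across both samples; p = 1")
        return w, 1.0
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                             use_continuity=False)
    return w, float(res.pvalue)


def gc_content(sequence: str) -> float:
    """GC fraction of a nucleotide sequence; N is excluded from the denominator."""
    seq = sequence.upper()
    counts = {c: seq.count(c) for c in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        raise ValueError("GC content undefined for empty or all-N sequence")
    return (counts["G"] + counts["C"]) / denom
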