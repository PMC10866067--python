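"""Seeded synthetic-fixture generators with machine-readable ground truth.

Every input the pipeline consumes can be generated at desk scale with known
truth: toy genome annotations with planted positional categories and
orientations, negative-binomial count matrices with planted two-group fold
changes and correlated module blocks, BLAST hit tables with planted
reciprocal/one-way structure, and coding-like/non-coding-like transcript
sequences with planted open reading frames. The defaults emulate the study
design at desk scale: two multi-megabase scaffolds, 7 high-CO2 vs 11
control samples, negative-binomial counts around mean 50.

All generators are deterministic functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import GeneModel, GenomeAnnotation, TranscriptModel
from .expression import COND_CO2, COND_CONTROL
from .orthology import OUTFMT6_COLUMNS
from .positional import (
    CATEGORY_GENIC,
    CATEGORY_INTERGENIC,
    CATEGORY_NON_NEIGHBORING,
    ORIENT_ANTISENSE,
    ORIENT_SENSE,
    ORIENT_UNKNOWN,
    SUBTYPE_BOTH,
    SUBTYPE_CONVERGENT,
    SUBTYPE_DIVERGENT,
    SUBTYPE_NA,
)

_BLOCK_BP = 250_000  # one planted unit per block keeps units > 100 kb apart


@dataclass
class AnnotationSpec:
    """Planted layout for a toy genome annotation."""

    seed: int = 0
    scaffold_lengths: dict[str, int] = field(
        default_factory=lambda: {"scaf1": 5_000_000, "scaf2": 5_000_000}
    )
    n_genic: int = 5
    n_intergenic: int = 10
    n_non_neighboring: int = 3
    n_extra_coding: int = 20
    # orientation mix for intergenic lincs, cycled deterministically
    orientations: tuple = (
        (ORIENT_SENSE, SUBTYPE_NA),
        (ORIENT_ANTISENSE, SUBTYPE_DIVERGENT),
        (ORIENT_ANTISENSE, SUBTYPE_CONVERGENT),
        (ORIENT_ANTISENSE, SUBTYPE_BOTH),
        (ORIENT_UNKNOWN, SUBTYPE_NA),
    )


def _blocks(scaffold_lengths: dict[str, int], n_units: int):
    """Yield (seq_id, block_start) for consecutive non-overlapping blocks."""
    out = []
    for seq_id in sorted(scaffold_lengths):
        length = scaffold_lengths[seq_id]
        for start in range(0, length - _BLOCK_BP + 1, _BLOCK_BP):
            out.append((seq_id, start))
            if len(out) == n_units:
                return out
    raise ValueError(
        f"infeasible layout: {n_units} units need "
        f"{n_units * _BLOCK_BP} bp, scaffolds hold fewer usable blocks"
    )


def _two_exon(start: int, end: int) -> list[tuple[int, int]]:
    third = (end - start) // 3
    return [(start, start + third), (end - third, end)]


def make_annotation(
    spec: AnnotationSpec,
) -> tuple[GenomeAnnotation, GenomeAnnotation, pd.DataFrame]:
    """Generate (lnc_annotation, coding_annotation, truth) with planted classes.

    Each planted unit occupies its own 400 kb block so categories are
    realized by construction: genic lincs overlap their block's coding gene,
    intergenic lincs sit 5-80 kb away with the planted orientation/subtype,
    non-neighboring lincs sit in coding-free blocks with > 100 kb to any
    coding gene.
    """
    rng = np.random.default_rng(spec.seed)
    n_units = (
        spec.n_genic + spec.n_intergenic + spec.n_non_neighboring + spec.n_extra_coding
    )
    blocks = _blocks(spec.scaffold_lengths, n_units)
    unit_kinds = (
        [CATEGORY_GENIC] * spec.n_genic
        + [CATEGORY_INTERGENIC] * spec.n_intergenic
        + [CATEGORY_NON_NEIGHBORING] * spec.n_non_neighboring
        + ["coding_only"] * spec.n_extra_coding
    )
    rng.shuffle(unit_kinds)

    coding: list[GeneModel] = []
    lncs: list[GeneModel] = []
    truth_rows = []
    n_coding = 0
    n_lnc = 0
    orient_cycle = 0

    def add_coding(seq_id: str, center: int, strand: str) -> str:
        nonlocal n_coding
        n_coding += 1
        gid = f"CG{n_coding:04d}"
        s, e = center - 5_000, center + 5_000
        tx = TranscriptModel(f"{gid}.t1", gid, seq_id, strand, _two_exon(s, e), "coding")
        coding.append(GeneModel(gid, seq_id, strand, [tx]))
        return gid

    def add_lnc(
        seq_id: str, spans: list[tuple[int, int]], strands: list[str]
    ) -> str:
        nonlocal n_lnc
        n_lnc += 1
        gid = f"LNC{n_lnc:04d}"
        txs = [
            TranscriptModel(f"{gid}.t{i + 1}", gid, seq_id, strand, [(s, e)],
                            "noncoding_candidate")
            for i, ((s, e), strand) in enumerate(zip(spans, strands))
        ]
        gene_strand = strands[0] if len(set(strands)) == 1 else strands[0]
        lncs.append(GeneModel(gid, seq_id, gene_strand, txs))
        return gid

    for (seq_id, block_start), kind in zip(blocks, unit_kinds):
        center = block_start + _BLOCK_BP // 2
        if kind == "coding_only":
            add_coding(seq_id, center, "+" if rng.random() < 0.5 else "-")
            continue
        if kind == CATEGORY_NON_NEIGHBORING:
            strand = "+" if rng.random() < 0.5 else "-"
            gid = add_lnc(seq_id, [(center - 1_000, center + 1_000)], [strand])
            truth_rows.append(
                {"lnc_gene_id": gid, "category": kind, "neighbor": None,
                 "orientation": ORIENT_UNKNOWN, "subtype": SUBTYPE_NA}
            )
            continue
        if kind == CATEGORY_GENIC:
            cg_strand = "+" if rng.random() < 0.5 else "-"
            cg = add_coding(seq_id, center, cg_strand)
            gid = add_lnc(seq_id, [(center - 2_000, center + 3_000)], ["+"])
            truth_rows.append(
                {"lnc_gene_id": gid, "category": kind, "neighbor": None,
                 "orientation": ORIENT_UNKNOWN, "subtype": SUBTYPE_NA}
            )
            continue
        # intergenic with a planted orientation/subtype
        orient, subtype = spec.orientations[orient_cycle % len(spec.orientations)]
        orient_cycle += 1
        dist = int(rng.integers(5_000, 80_000))
        right = bool(rng.random() < 0.5)
        if right:
            s = center + 5_000 + dist
            span = (s, s + 2_000)
        else:
            e = center - 5_000 - dist
            span = (e - 2_000, e)
        if orient == ORIENT_ANTISENSE and subtype in (SUBTYPE_DIVERGENT, SUBTYPE_CONVERGENT):
            # divergent = 5' ends face each other: a linc right of its
            # neighbor is head-to-head iff it runs rightward (+)
            linc_strand = ("+" if right else "-") if subtype == SUBTYPE_DIVERGENT \
                else ("-" if right else "+")
            cg_strand = "-" if linc_strand == "+" else "+"
            strands, spans = [linc_strand], [span]
        else:
            cg_strand = "+" if rng.random() < 0.5 else "-"
            opposite = "-" if cg_strand == "+" else "+"
            if orient == ORIENT_SENSE:
                strands, spans = [cg_strand], [span]
            elif orient == ORIENT_UNKNOWN:
                strands, spans = ["."], [span]
            else:
                # "both": two same-strand antisense transcripts flanking the
                # coding gene — one head-to-head with it, one tail-to-tail
                if right:
                    other_e = center - 5_000 - dist
                    spans = [span, (other_e - 2_000, other_e)]
                else:
                    other_s = center + 5_000 + dist
                    spans = [span, (other_s, other_s + 2_000)]
                strands = [opposite, opposite]
        cg = add_coding(seq_id, center, cg_strand)
        gid = add_lnc(seq_id, spans, strands)
        truth_rows.append(
            {"lnc_gene_id": gid, "category": CATEGORY_INTERGENIC, "neighbor": cg,
             "orientation": orient, "subtype": subtype}
        )

    lnc_ann = GenomeAnnotation(lncs, scaffold_lengths=spec.scaffold_lengths)
    coding_ann = GenomeAnnotation(coding, scaffold_lengths=spec.scaffold_lengths)
    truth = pd.DataFrame(
        truth_rows,
        columns=["lnc_gene_id", "category", "neighbor", "orientation", "subtype"],
    )
    return lnc_ann, coding_ann, truth


# ---------------------------------------------------------------------------
# Counts


@dataclass
class CountSpec:
    """Planted structure for a negative-binomial count matrix."""

    seed: int = 0
    n_features: int = 2_000
    n_control: int = 11
    n_co2: int = 7
    nb_mean: float = 50.0
    nb_size: float = 5.0
    mean_log_sd: float = 0.0  # lognormal scatter of per-feature base means
    n_de: int = 0
    de_log2fc: float = 2.0  # CO2 mean multiplied by 2^effect (sign alternates)
    n_high: int = 0  # features planted at mean `high_mean`
    high_mean: float = 10_000.0
    # planted correlated blocks: (size, loading, trait_linked)
    module_blocks: tuple = ()
    module_nb_size: float = 50.0
    feature_prefix: str = "F"


def make_counts(spec: CountSpec) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Generate (counts, conditions, truth) negative-binomial fixtures.

    Baseline counts are NB(mean, size). DE features multiply the CO2
    condition's mean by 2^effect with alternating sign. Module-block
    features share a per-sample latent factor with the given log2 loading
    (trait-linked blocks tie the factor to the condition), drawn at low
    dispersion so within-block correlation is high.
    """
    if spec.nb_mean <= 0 or spec.nb_size <= 0:
        raise ValueError("negative-binomial parameters must be positive")
    rng = np.random.default_rng(spec.seed)
    n_samples = spec.n_control + spec.n_co2
    samples = [f"C{i + 1:02d}" for i in range(spec.n_control)] + [
        f"T{i + 1:02d}" for i in range(spec.n_co2)
    ]
    conditions = pd.Series(
        [COND_CONTROL] * spec.n_control + [COND_CO2] * spec.n_co2,
        index=samples,
        name="condition",
    )
    trait = (conditions == COND_CO2).to_numpy(dtype=float)

    features = [f"{spec.feature_prefix}{i + 1:04d}" for i in range(spec.n_features)]
    base = np.full(spec.n_features, spec.nb_mean)
    if spec.mean_log_sd > 0:
        base = base * rng.lognormal(0.0, spec.mean_log_sd, spec.n_features)

    truth = pd.DataFrame(
        {
            "feature_id": features,
            "is_de": False,
            "effect_log2": 0.0,
            "is_high": False,
            "module_block": pd.array([pd.NA] * spec.n_features, dtype="Int64"),
        }
    ).set_index("feature_id")

    used = 0
    de_idx = np.arange(used, used + spec.n_de)
    used += spec.n_de
    high_idx = np.arange(used, used + spec.n_high)
    used += spec.n_high
    block_slices = []
    for b, (size, loading, trait_linked) in enumerate(spec.module_blocks):
        block_slices.append((np.arange(used, used + size), loading, trait_linked, b))
        used += size
    if used > spec.n_features:
        raise ValueError("planted structure exceeds n_features")

    base[high_idx] = spec.high_mean
    truth.iloc[high_idx, truth.columns.get_loc("is_high")] = True

    # per-feature, per-sample mean matrix
    mean = np.tile(base[:, None], (1, n_samples)).astype(float)
    signs = np.where(np.arange(spec.n_de) % 2 == 0, 1.0, -1.0)
    for j, (i, s) in enumerate(zip(de_idx, signs)):
        mean[i, trait == 1.0] *= 2.0 ** (s * spec.de_log2fc)
        truth.iloc[i, truth.columns.get_loc("is_de")] = True
        truth.iloc[i, truth.columns.get_loc("effect_log2")] = s * spec.de_log2fc
    size = np.full(spec.n_features, spec.nb_size)
    for idx, loading, trait_linked, b in block_slices:
        if trait_linked:
            z = (trait - trait.mean()) / max(trait.std(), 1e-9) + rng.normal(
                0.0, 0.3, n_samples
            )
        else:
            z = rng.normal(0.0, 1.0, n_samples)
        mean[idx, :] *= 2.0 ** (loading * z)[None, :]
        size[idx] = spec.module_nb_size
        truth.iloc[idx, truth.columns.get_loc("module_block")] = b

    p = size[:, None] / (size[:, None] + mean)
    counts = rng.negative_binomial(size[:, None], p)
    counts_df = pd.DataFrame(counts, index=features, columns=samples)
    return counts_df, conditions, truth


# ---------------------------------------------------------------------------
# BLAST hit tables


@dataclass
class BlastSpec:
    seed: int = 0
    n_reciprocal: int = 10
    n_one_way: int = 15
    n_decoy: int = 30
    e_max: float = 1e-3


def _hit_row(rng, q: str, s: str, evalue: float) -> dict:
    length = int(rng.integers(80, 400))
    return {
        "qseqid": q,
        "sseqid": s,
        "pident": float(np.round(rng.uniform(75, 100), 2)),
        "length": length,
        "mismatch": int(rng.integers(0, 20)),
        "gapopen": int(rng.integers(0, 4)),
        "qstart": 1,
        "qend": length,
        "sstart": 1,
        "send": length,
        "evalue": evalue,
        "bitscore": float(np.round(max(30.0, -10.0 * np.log10(max(evalue, 1e-180))), 1)),
    }


def make_blast(
    spec: BlastSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (forward_hits, reverse_hits, truth) outfmt-6 tables.

    Planted reciprocal pairs are mutual e-value minima in both directions;
    one-way pairs have a best forward hit whose reverse best points
    elsewhere; decoys are sub-threshold or non-best rows.
    """
    rng = np.random.default_rng(spec.seed)
    fwd_rows, rev_rows, truth_rows = [], [], []
    for i in range(spec.n_reciprocal):
        q, s = f"L{i + 1:04d}", f"X{i + 1:04d}"
        e = 10.0 ** rng.uniform(-50, -10)
        fwd_rows.append(_hit_row(rng, q, s, e))
        rev_rows.append(_hit_row(rng, s, q, 10.0 ** rng.uniform(-50, -10)))
        # a worse secondary hit in each direction
        fwd_rows.append(_hit_row(rng, q, f"X{rng.integers(1000, 2000):04d}", e * 1e3))
        truth_rows.append({"focal": q, "other": s, "reciprocal": True})
    for j in range(spec.n_one_way):
        q, s = f"L{100 + j + 1:04d}", f"Y{j + 1:04d}"
        fwd_rows.append(_hit_row(rng, q, s, 10.0 ** rng.uniform(-40, -10)))
        # the subject's reverse best points at a different focal linc
        rev_rows.append(_hit_row(rng, s, f"L{200 + j + 1:04d}", 10.0 ** rng.uniform(-60, -45)))
        truth_rows.append({"focal": q, "other": s, "reciprocal": False})
    for d in range(spec.n_decoy):
        q = f"L{300 + d + 1:04d}"
        fwd_rows.append(_hit_row(rng, q, f"Z{d + 1:04d}", 10.0 ** rng.uniform(-2.5, 1)))
    fwd = pd.DataFrame(fwd_rows, columns=OUTFMT6_COLUMNS)
    rev = pd.DataFrame(rev_rows, columns=OUTFMT6_COLUMNS)
    truth = pd.DataFrame(truth_rows)
    return fwd, rev, truth


# ---------------------------------------------------------------------------
# Transcript sequences


@dataclass
class SequenceSpec:
    seed: int = 0
    n_per_class: int = 100
    length: int = 500
    orf_frac: float = 0.6  # planted ORF length as a fraction of the transcript
    bias_strength: float = 1.0  # 0 = classes generated identically


_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]


def _strip_atg(seq: list[str], keep_start: int | None = None) -> None:
    """Mutate every ATG occurrence (except one at keep_start) to ATC in place.

    Replacing G with C can neither create a new ATG nor a stop codon, so the
    planted ORF is untouched apart from silent interior changes.
    """
    i = 0
    s = "".join(seq)
    while True:
        i = s.find("ATG", i)
        if i < 0:
            break
        if i != keep_start:
            seq[i + 2] = "C"
            s = "".join(seq)
        i += 1


def make_sequences(
    spec: SequenceSpec,
) -> tuple[list[str], list[str], pd.DataFrame]:
    """Generate (coding_like, noncoding_like, truth) transcript sequences.

    Coding-like sequences carry a planted ORF (ATG...stop) guaranteed to be
    the longest one, built from codons biased toward GC-rich usage in
    proportion to ``bias_strength``; non-coding-like sequences are plain
    random nucleotides. With ``bias_strength == 0`` the two classes are
    generated from the identical model (no planted ORF), giving an
    indistinguishable null.
    """
    rng = np.random.default_rng(spec.seed)
    bases = np.array(list("ACGT"))

    def random_seq(n: int) -> list[str]:
        return list(bases[rng.integers(0, 4, n)])

    truth_rows = []
    noncoding = ["".join(random_seq(spec.length)) for _ in range(spec.n_per_class)]
    if spec.bias_strength == 0:
        coding = ["".join(random_seq(spec.length)) for _ in range(spec.n_per_class)]
        for i in range(spec.n_per_class):
            truth_rows.append({"seq_index": i, "planted_orf_nt": np.nan})
        return coding, noncoding, pd.DataFrame(truth_rows)

    gc = np.array([sum(c in "GC" for c in codon) for codon in _CODONS], dtype=float)
    weights = np.exp(spec.bias_strength * gc)
    weights /= weights.sum()
    coding = []
    for i in range(spec.n_per_class):
        n_codons = max(4, int(spec.orf_frac * spec.length) // 3)
        orf_len = 3 * n_codons + 6  # ATG + codons + stop
        body = "".join(rng.choice(_CODONS, n_codons, p=weights))
        orf = "ATG" + body + "TAA"
        flank = spec.length - orf_len
        pre = random_seq(flank // 2)
        post = random_seq(flank - flank // 2)
        seq = pre + list(orf) + post
        _strip_atg(seq, keep_start=len(pre))
        coding.append("".join(seq))
        truth_rows.append({"seq_index": i, "planted_orf_nt": orf_len})
    return coding, noncoding, pd.DataFrame(truth_rows)


def write_fasta(sequences: dict[str, str], path) -> None:
    """Write sequences to FASTA (80-column wrapping)."""
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered name -> sequence mapping."""
    out: dict[str, str] = {}
    name = None
    parts: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    out[name] = "".join(parts)
                name = line[1:].split()[0]
                parts = []
            else:
                parts.append(line)
    if name is not None:
        out[name] = "".join(parts)
    return out
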