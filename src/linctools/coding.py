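"""Per-transcript coding/non-coding calls and the gene-level consensus vote.

Calls come either from imported score tables of external predictors (CPC-,
CPAT- or FEELnc-style) or from the built-in intrinsic-feature classifier:
longest-ORF statistics, a Fickett TESTCODE score and a hexamer usage
log-likelihood ratio combined by logistic regression. A gene is non-coding
under one tool only if every one of its transcripts is; a gene enters the
consensus lncRNA set when at least ``m_votes`` tools (default 2) call it
non-coding.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

STOP_CODONS = ("TAA", "TAG", "TGA")

VERDICT_CODING = "coding"
VERDICT_NONCODING = "noncoding"


# ---------------------------------------------------------------------------
# ORF scanning


def find_longest_orf(sequence: str) -> tuple[int, int, int, bool]:
    """Longest open reading frame on the forward strand (frames 0/1/2).

    An ORF runs ATG -> first in-frame stop, stop codon included. Returns
    ``(start, end, length_nt, integrity)`` with 0-based half-open
    coordinates. When no ATG has an in-frame stop, the longest open ATG ->
    frame-end stretch is reported with ``integrity=False``; with no ATG at
    all the result is ``(0, 0, 0, False)``. Length ties break toward the
    smaller start, complete ORFs beating incomplete ones of equal length.
    """
    seq = sequence.upper()
    n = len(seq)
    complete: list[tuple[int, int]] = []
    incomplete: list[tuple[int, int]] = []
    for frame in range(3):
        pending_starts: list[int] = []
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if codon == "ATG":
                pending_starts.append(i)
            elif codon in STOP_CODONS and pending_starts:
                # all pending ATGs terminate at this stop
                complete.append((pending_starts[0], i + 3))
                pending_starts = []
        if pending_starts:
            frame_end = frame + 3 * ((n - frame) // 3)
            incomplete.append((pending_starts[0], frame_end))
    best = None  # (length, start, incomplete_flag)
    for s, e in complete:
        cand = (-(e - s), s, 0)
        if best is None or cand < best:
            best = cand
    for s, e in incomplete:
        cand = (-(e - s), s, 1)
        if best is None or cand < best:
            best = cand
    if best is None:
        return (0, 0, 0, False)
    length, start, inc = -best[0], best[1], best[2]
    return (start, start + length, length, inc == 0)


# ---------------------------------------------------------------------------
# Fickett TESTCODE score

# Published TESTCODE lookup tables (Fickett 1982): probability that a window
# with the given position/composition parameter value is coding, plus the
# per-base weights reflecting each parameter's discriminative power.
_POSITION_PROB = {
    "A": [0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22],
    "C": [0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23],
    "G": [0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08],
    "T": [0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09],
}
_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
_POSITION_BOUNDS = [1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0]

_CONTENT_PROB = {
    "A": [0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21],
    "C": [0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31],
    "G": [0.40, 0.54, 0.47, 0.64, 0.64, 0.73, 0.41, 0.41, 0.33, 0.29],
    "T": [0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58],
}
_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}
_CONTENT_BOUNDS = [0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0]


def _lookup(value: float, bounds: Sequence[float], probs: Sequence[float]) -> float:
    for i, b in enumerate(bounds):
        if value >= b:
            return probs[i]
    return probs[-1]


def fickett_position_value(sequence: str, base: str) -> float:
    """max/(min+1) of the base's counts in the three codon phases."""
    seq = sequence.upper()
    counts = [seq[phase::3].count(base) for phase in range(3)]
    return max(counts) / (min(counts) + 1.0)


def fickett_score(sequence: str) -> float:
    """Fickett TESTCODE statistic from position and composition parameters.

    Deterministic table lookup; not symmetric under reverse complement.
    Needs at least 12 nt so each codon phase holds >= 3 positions.
    """
    seq = sequence.upper()
    if len(seq) < 12:
        raise ValueError("fickett_score needs a sequence of length >= 12")
    total = sum(seq.count(b) for b in "ACGT")
    if total == 0:
        raise ValueError("sequence contains no A/C/G/T")
    score = 0.0
    for base in "ACGT":
        pos_val = fickett_position_value(seq, base)
        score += _lookup(pos_val, _POSITION_BOUNDS, _POSITION_PROB[base]) * _POSITION_WEIGHT[base]
        content = seq.count(base) / total
        score += _lookup(content, _CONTENT_BOUNDS, _CONTENT_PROB[base]) * _CONTENT_WEIGHT[base]
    return score


# ---------------------------------------------------------------------------
# Hexamer usage


@dataclass
class HexamerTable:
    """In-frame hexamer frequencies under coding and non-coding models."""

    coding: dict[str, float]
    noncoding: dict[str, float]
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        for name, table in (("coding", self.coding), ("noncoding", self.noncoding)):
            total = sum(table.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} hexamer frequencies sum to {total}, not 1")

    @classmethod
    def train(
        cls,
        coding_seqs: Iterable[str],
        noncoding_seqs: Iterable[str],
        pseudocount: float = 1.0,
    ) -> "HexamerTable":
        def freq(seqs: Iterable[str]) -> dict[str, float]:
            counts: dict[str, float] = {}
            for seq in seqs:
                for hx in _iter_hexamers(seq):
                    counts[hx] = counts.get(hx, 0.0) + 1.0
            # pseudocount over the full 4^6 alphabet keeps unseen hexamers finite
            alphabet = _all_hexamers()
            total = sum(counts.values()) + pseudocount * len(alphabet)
            return {hx: (counts.get(hx, 0.0) + pseudocount) / total for hx in alphabet}

        return cls(freq(coding_seqs), freq(noncoding_seqs), pseudocount)


def _all_hexamers() -> list[str]:
    from itertools import product

    return ["".join(p) for p in product("ACGT", repeat=6)]


def _iter_hexamers(sequence: str):
    seq = sequence.upper()
    for i in range(0, len(seq) - 5, 3):
        hx = seq[i : i + 6]
        if set(hx) <= set("ACGT"):
            yield hx


def hexamer_llr(sequence: str, table: HexamerTable) -> float:
    """Mean log(coding/noncoding) frequency ratio over in-frame hexamers."""
    if len(sequence) < 6:
        raise ValueError("hexamer_llr needs a sequence of length >= 6")
    terms = []
    floor = 1e-12
    for hx in _iter_hexamers(sequence):
        cf = max(table.coding.get(hx, floor), floor)
        nf = max(table.noncoding.get(hx, floor), floor)
        terms.append(math.log(cf / nf))
    if not terms:
        return 0.0
    return float(np.mean(terms))


# ---------------------------------------------------------------------------
# Intrinsic-feature classifier

FEATURE_NAMES = ("orf_length", "orf_coverage", "orf_integrity", "fickett", "hexamer_llr")


def intrinsic_features(sequence: str, table: HexamerTable) -> np.ndarray:
    _, _, orf_len, integrity = find_longest_orf(sequence)
    coverage = orf_len / len(sequence) if sequence else 0.0
    fick = fickett_score(sequence) if len(sequence) >= 12 else 0.0
    llr = hexamer_llr(sequence, table) if len(sequence) >= 6 else 0.0
    return np.array([orf_len, coverage, float(integrity), fick, llr])


class IntrinsicCodingClassifier:
    """Logistic-regression coding-potential classifier over intrinsic features.

    A self-contained stand-in predictor in the family of alignment-free
    coding-potential tools: longest-ORF length/coverage/integrity, Fickett
    TESTCODE score and a hexamer log-likelihood ratio feed a logistic
    combiner. ``fit`` trains the hexamer table and the combiner on labelled
    coding/non-coding sequence sets; ``predict_proba`` returns coding
    probabilities; a transcript is called non-coding when its probability
    falls strictly below the cutoff (default 0.38).
    """

    def __init__(self, pseudocount: float = 1.0, seed: int = 0):
        self.pseudocount = pseudocount
        self.seed = seed

    def fit(self, coding_seqs: Sequence[str], noncoding_seqs: Sequence[str]):
        if len(coding_seqs) == 0 or len(noncoding_seqs) == 0:
            raise ValueError("both coding and noncoding training sequences required")
        self.hexamer_table_ = HexamerTable.train(
            coding_seqs, noncoding_seqs, pseudocount=self.pseudocount
        )
        X = np.array(
            [intrinsic_features(s, self.hexamer_table_) for s in
             list(coding_seqs) + list(noncoding_seqs)]
        )
        y = np.array([1] * len(coding_seqs) + [0] * len(noncoding_seqs))
        self.model_ = make_pipeline(
            StandardScaler(),
            LogisticRegression(max_iter=1000, random_state=self.seed),
        )
        self.model_.fit(X, y)
        self.training_accuracy_ = float(self.model_.score(X, y))
        return self

    def predict_proba(self, sequences: Sequence[str]) -> np.ndarray:
        """P(coding) per sequence."""
        X = np.array([intrinsic_features(s, self.hexamer_table_) for s in sequences])
        return self.model_.predict_proba(X)[:, 1]

    def classify(
        self,
        sequences: Mapping[str, str],
        cutoff: float = 0.38,
        tool_label: str = "intrinsic",
    ) -> list["CodingCall"]:
        ids = list(sequences)
        probs = self.predict_proba([sequences[i] for i in ids])
        return [
            CodingCall(
                transcript_id=tid,
                tool=tool_label,
                score=float(p),
                verdict=VERDICT_NONCODING if p < cutoff else VERDICT_CODING,
            )
            for tid, p in zip(ids, probs)
        ]

    def to_json(self) -> str:
        lr = self.model_.named_steps["logisticregression"]
        sc = self.model_.named_steps["standardscaler"]
        return json.dumps(
            {
                "coef": lr.coef_.tolist(),
                "intercept": lr.intercept_.tolist(),
                "scale_mean": sc.mean_.tolist(),
                "scale_var": sc.var_.tolist(),
                "features": FEATURE_NAMES,
            }
        )


def train_classifier(
    coding_seqs: Sequence[str], noncoding_seqs: Sequence[str], seed: int = 0
) -> IntrinsicCodingClassifier:
    """Fit the intrinsic classifier; see :class:`IntrinsicCodingClassifier`."""
    return IntrinsicCodingClassifier(seed=seed).fit(coding_seqs, noncoding_seqs)


def classify(
    sequences: Mapping[str, str],
    model: IntrinsicCodingClassifier,
    cutoff: float = 0.38,
) -> list["CodingCall"]:
    return model.classify(sequences, cutoff=cutoff)


# ---------------------------------------------------------------------------
# Imported calls and consensus


@dataclass
class CodingCall:
    transcript_id: str
    tool: str
    score: float
    verdict: str

    def __post_init__(self) -> None:
        if self.verdict not in (VERDICT_CODING, VERDICT_NONCODING):
            raise ValueError(f"invalid verdict {self.verdict!r}")


@dataclass
class CutoffSpec:
    """Verdict rule applied to a score column.

    ``direction`` is the comparison making a transcript *non-coding*, e.g.
    ``lt`` with threshold 0 for a CPC-style score or ``lt`` with 0.38 for a
    CPAT-style probability. ``verbatim`` takes an imported verdict column
    as-is (FEELnc-style data-derived cutoffs).
    """

    direction: str = "lt"
    threshold: float = 0.0
    verbatim: bool = False

    _OPS = {
        "lt": lambda s, t: s < t,
        "le": lambda s, t: s <= t,
        "gt": lambda s, t: s > t,
        "ge": lambda s, t: s >= t,
    }

    def verdict(self, score: float) -> str:
        if self.direction not in self._OPS:
            raise ValueError(f"unknown direction {self.direction!r}")
        noncoding = self._OPS[self.direction](score, self.threshold)
        return VERDICT_NONCODING if noncoding else VERDICT_CODING


def import_calls(
    tsv,
    tool_label: str,
    cutoff_spec: CutoffSpec | None = None,
    known_transcripts: Iterable[str] | None = None,
) -> tuple[list[CodingCall], list[str]]:
    """Read a per-transcript score/verdict TSV into CodingCalls.

    The table needs a ``transcript_id`` column plus ``score`` and/or
    ``verdict``. Returns ``(calls, unknown_ids)`` where ``unknown_ids`` lists
    transcript ids absent from ``known_transcripts`` (the reconciliation
    report; empty when no annotation is supplied).
    """
    df = pd.read_csv(tsv, sep="\t")
    if "transcript_id" not in df.columns:
        raise ValueError("score table must have a transcript_id column")
    use_verbatim = cutoff_spec is not None and cutoff_spec.verbatim
    if use_verbatim and "verdict" not in df.columns:
        raise ValueError("verbatim cutoff spec requires a verdict column")
    if not use_verbatim and "score" not in df.columns:
        if "verdict" in df.columns:
            use_verbatim = True
        else:
            raise ValueError("score table must have a score or verdict column")
    calls = []
    for row in df.itertuples(index=False):
        score = float(getattr(row, "score", np.nan))
        if use_verbatim:
            verdict = str(row.verdict)
        else:
            verdict = cutoff_spec.verdict(score) if cutoff_spec else (
                VERDICT_NONCODING if score < 0 else VERDICT_CODING
            )
        calls.append(CodingCall(str(row.transcript_id), tool_label, score, verdict))
    unknown: list[str] = []
    if known_transcripts is not None:
        known = set(known_transcripts)
        unknown = sorted({c.transcript_id for c in calls} - known)
    return calls, unknown


class CodingCallSet:
    """Per-tool transcript calls plus gene-level verdicts and consensus."""

    def __init__(self, gene_transcripts: Mapping[str, Sequence[str]]):
        # gene_id -> transcript ids (the gene universe being voted on)
        self.gene_transcripts = {g: list(ts) for g, ts in gene_transcripts.items()}
        self.calls: dict[tuple[str, str], CodingCall] = {}
        self.tools: list[str] = []

    def add_calls(self, calls: Iterable[CodingCall]) -> None:
        for c in calls:
            if c.tool not in self.tools:
                self.tools.append(c.tool)
            self.calls[(c.transcript_id, c.tool)] = c

    def gene_verdict(self, gene_id: str, tool: str, missing_policy: str = "coding") -> str:
        """Non-coding iff every transcript of the gene is non-coding under the tool.

        A transcript with no call under the tool counts per ``missing_policy``
        (default ``coding``: conservative, keeps spurious lncRNAs out).
        """
        for tid in self.gene_transcripts[gene_id]:
            call = self.calls.get((tid, tool))
            if call is None:
                verdict = missing_policy
            else:
                verdict = call.verdict
            if verdict != VERDICT_NONCODING:
                return VERDICT_CODING
        return VERDICT_NONCODING

    def vote_table(self, missing_policy: str = "coding") -> pd.DataFrame:
        """Genes x tools boolean table of non-coding gene verdicts, plus votes."""
        data = {
            tool: [
                self.gene_verdict(g, tool, missing_policy) == VERDICT_NONCODING
                for g in sorted(self.gene_transcripts)
            ]
            for tool in sorted(self.tools)
        }
        df = pd.DataFrame(data, index=sorted(self.gene_transcripts))
        df["votes"] = df.sum(axis=1)
        return df

    def consensus(
        self, m_votes: int = 2, level: str = "gene", missing_policy: str = "coding"
    ) -> set[str]:
        """Gene ids called non-coding by at least ``m_votes`` tools.

        ``level="gene"`` votes on per-tool gene verdicts (all-transcripts
        rule first, then the vote). ``level="transcript"`` first keeps
        transcripts non-coding under >= m_votes tools, then retains genes
        whose every transcript survived — the alternative reading of
        transcript-level intersection.
        """
        if len(self.tools) < 2:
            raise ValueError("consensus requires calls from at least 2 tools")
        if m_votes > len(self.tools):
            raise ValueError(
                f"m_votes={m_votes} exceeds the {len(self.tools)} tools present"
            )
        if level == "gene":
            out = set()
            for g in self.gene_transcripts:
                votes = sum(
                    self.gene_verdict(g, t, missing_policy) == VERDICT_NONCODING
                    for t in self.tools
                )
                if votes >= m_votes:
                    out.add(g)
            return out
        if level == "transcript":
            out = set()
            for g, tids in self.gene_transcripts.items():
                ok = True
                for tid in tids:
                    votes = 0
                    for t in self.tools:
                        call = self.calls.get((tid, t))
                        verdict = call.verdict if call is not None else missing_policy
                        votes += verdict == VERDICT_NONCODING
                    if votes < m_votes:
                        ok = False
                        break
                if ok:
                    out.add(g)
            return out
        raise ValueError(f"unknown consensus level {level!r}")


def consensus(
    callset: CodingCallSet, m_votes: int = 2, level: str = "gene"
) -> tuple[set[str], pd.DataFrame]:
    """Consensus gene set and the per-gene vote table."""
    return callset.consensus(m_votes=m_votes, level=level), callset.vote_table()
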