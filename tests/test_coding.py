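"""ORF scanning, Fickett/hexamer features, classifier and consensus voting."""

import numpy as np
import pandas as pd
import pytest

from linctools import coding as cp
from linctools import simulate as sim

BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# ORF scanning


def brute_force_longest_orf(seq):
    """Enumerate every (frame, ATG, stop) triple; mirror the tie-break rules."""
    seq = seq.upper()
    n = len(seq)
    complete, incomplete = [], []
    for frame in range(3):
        codons = [(i, seq[i:i + 3]) for i in range(frame, n - 2, 3)]
        for idx, (i, codon) in enumerate(codons):
            if codon != "ATG":
                continue
            stop = None
            for j, cod2 in codons[idx:]:
                if cod2 in cp.STOP_CODONS:
                    stop = j
                    break
            if stop is not None:
                complete.append((i, stop + 3))
            else:
                incomplete.append((i, frame + 3 * ((n - frame) // 3)))
    cands = [(-(e - s), s, 0) for s, e in complete] + [
        (-(e - s), s, 1) for s, e in incomplete
    ]
    if not cands:
        return (0, 0, 0, False)
    ln, s, inc = min(cands)
    return (s, s - ln, -ln, inc == 0)


class TestFindLongestOrf:
    def test_minimal_complete_orf(self):
        assert cp.find_longest_orf("ATGAAATGA") == (0, 9, 9, True)

    def test_no_orf(self):
        assert cp.find_longest_orf("CCCCCC") == (0, 0, 0, False)

    def test_start_without_stop_lacks_integrity(self):
        start, end, length, integrity = cp.find_longest_orf("ATGAAAAAA")
        assert (length, integrity) == (9, False)

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(100):
            seq = "".join(BASES[rng.integers(0, 4, 300)])
            assert cp.find_longest_orf(seq) == brute_force_longest_orf(seq)


# ---------------------------------------------------------------------------
# Fickett score


class TestFickett:
    def test_homopolymer_hand_lookup(self):
        """A*200: position value 1.0 for A (degenerate), 0 for C/G/T; content
        1.0 for A, 0 for the rest — score follows from the published tables."""
        expected = (
            0.22 * 0.26 + 0.23 * 0.18 + 0.08 * 0.31 + 0.09 * 0.33  # position
            + 0.28 * 0.11 + 0.31 * 0.12 + 0.29 * 0.15 + 0.58 * 0.14  # content
        )
        assert cp.fickett_score("A" * 200) == pytest.approx(expected)

    def test_deterministic(self):
        seq = "ACGT" * 50
        assert cp.fickett_score(seq) == cp.fickett_score(seq)

    def test_reverse_complement_generally_differs(self):
        seq = "ATGGCGGCGGCGGCGTAA" * 3
        comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
        rc = "".join(comp[c] for c in reversed(seq))
        assert cp.fickett_score(seq) != cp.fickett_score(rc)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            cp.fickett_score("ACGTACGTACG")  # 11 nt


# ---------------------------------------------------------------------------
# Hexamer log-likelihood ratio


class TestHexamerLLR:
    def test_identical_tables_give_zero(self, rng):
        uniform = {h: 1 / 4096 for h in cp._all_hexamers()}
        table = cp.HexamerTable(dict(uniform), dict(uniform))
        seq = "".join(BASES[rng.integers(0, 4, 120)])
        assert cp.hexamer_llr(seq, table) == pytest.approx(0.0)

    def test_single_hexamer_ratio_e(self):
        """A hexamer with coding/noncoding frequency ratio e scores exactly 1."""
        base = {h: 1 / 4096 for h in cp._all_hexamers()}
        noncoding = dict(base)
        noncoding["AAAAAA"] = 1e-4
        noncoding["CCCCCC"] = 2 / 4096 - 1e-4
        coding = dict(base)
        coding["AAAAAA"] = 1e-4 * np.e
        coding["CCCCCC"] = 2 / 4096 - 1e-4 * np.e
        table = cp.HexamerTable(coding, noncoding)
        assert cp.hexamer_llr("AAAAAA", table) == pytest.approx(1.0)

    def test_matches_direct_summation(self, rng):
        cod, non, _ = sim.make_sequences(sim.SequenceSpec(seed=5, n_per_class=20))
        table = cp.HexamerTable.train(cod, non)
        seq = "".join(BASES[rng.integers(0, 4, 99)])
        terms = [
            np.log(table.coding[seq[i:i + 6]] / table.noncoding[seq[i:i + 6]])
            for i in range(0, len(seq) - 5, 3)
        ]
        assert cp.hexamer_llr(seq, table) == pytest.approx(np.mean(terms))

    def test_frequency_columns_validated(self):
        with pytest.raises(ValueError, match="sum"):
            cp.HexamerTable({"AAAAAA": 0.5}, {"AAAAAA": 1.0})


# ---------------------------------------------------------------------------
# Classifier


class TestClassifier:
    def test_separable_classes_perfect_training_accuracy(self):
        cod, non, _ = sim.make_sequences(sim.SequenceSpec(seed=7, n_per_class=60))
        model = cp.train_classifier(cod, non, seed=0)
        assert model.training_accuracy_ == 1.0

    def test_shuffled_labels_near_chance(self, rng):
        cod, non, _ = sim.make_sequences(sim.SequenceSpec(seed=8, n_per_class=100))
        pool = cod + non
        idx = rng.permutation(len(pool))
        half = len(pool) // 2
        fake_cod = [pool[i] for i in idx[:half]]
        fake_non = [pool[i] for i in idx[half:]]
        model = cp.train_classifier(fake_cod, fake_non, seed=0)
        # held-out evaluation on a fresh shuffled draw
        cod2, non2, _ = sim.make_sequences(sim.SequenceSpec(seed=9, n_per_class=100))
        pool2 = cod2 + non2
        idx2 = rng.permutation(len(pool2))
        probs = model.predict_proba([pool2[i] for i in idx2])
        labels = np.array([1 if i < len(cod2) else 0 for i in idx2])
        acc = ((probs >= 0.5) == labels).mean()
        assert abs(acc - 0.5) <= 0.1

    def test_auc_above_095_on_separable_benchmark(self):
        from sklearn.metrics import roc_auc_score

        cod, non, _ = sim.make_sequences(sim.SequenceSpec(seed=10, n_per_class=500))
        model = cp.train_classifier(cod[:250] + [], non[:250], seed=0)
        probs = model.predict_proba(cod[250:] + non[250:])
        auc = roc_auc_score([1] * 250 + [0] * 250, probs)
        assert auc > 0.95

    def test_logistic_coefficients_recovered_in_ci(self, rng):
        """The logistic combiner recovers known coefficients at n=2000."""
        import statsmodels.api as sm

        n, beta = 2000, np.array([1.0, -2.0, 0.5])
        X = rng.normal(size=(n, 3))
        p = 1 / (1 + np.exp(-(X @ beta)))
        y = rng.random(n) < p
        fit = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        ci = fit.conf_int(alpha=0.01)
        for k, b in enumerate(beta):
            lo, hi = ci[k + 1]
            assert lo <= b <= hi

    def test_single_class_input_rejected(self):
        with pytest.raises(ValueError):
            cp.train_classifier([], ["ACGT" * 30])

    def test_classify_equals_threshold_on_probabilities(self):
        cod, non, _ = sim.make_sequences(sim.SequenceSpec(seed=11, n_per_class=50))
        model = cp.train_classifier(cod, non, seed=0)
        seqs = {f"t{i}": s for i, s in enumerate(cod + non)}
        calls = model.classify(seqs, cutoff=0.38)
        probs = model.predict_proba([seqs[c.transcript_id] for c in calls])
        for call, p in zip(calls, probs):
            assert call.verdict == ("noncoding" if p < 0.38 else "coding")


# ---------------------------------------------------------------------------
# Imported calls


class TestImportCalls:
    def _table(self, tmp_path, rows, cols=("transcript_id", "score")):
        p = tmp_path / "calls.tsv"
        pd.DataFrame(rows, columns=list(cols)).to_csv(p, sep="\t", index=False)
        return p

    def test_cpc_style_negative_score_noncoding(self, tmp_path):
        p = self._table(tmp_path, [("t1", -0.5)])
        calls, _ = cp.import_calls(p, "cpc", cp.CutoffSpec("lt", 0.0))
        assert calls[0].verdict == "noncoding"

    def test_zero_score_boundary_is_coding(self, tmp_path):
        p = self._table(tmp_path, [("t1", 0.0)])
        calls, _ = cp.import_calls(p, "cpc", cp.CutoffSpec("lt", 0.0))
        assert calls[0].verdict == "coding"

    def test_probability_cutoff_boundary_is_coding(self, tmp_path):
        p = self._table(tmp_path, [("t1", 0.38), ("t2", 0.3799), ("t3", 0.0)])
        calls, _ = cp.import_calls(p, "cpat", cp.CutoffSpec("lt", 0.38))
        assert [c.verdict for c in calls] == ["coding", "noncoding", "noncoding"]

    def test_mixed_table_matches_hand_thresholding(self, tmp_path, rng):
        scores = np.round(rng.normal(0, 1, 20), 3)
        rows = [(f"t{i}", s) for i, s in enumerate(scores)]
        p = self._table(tmp_path, rows)
        calls, _ = cp.import_calls(p, "cpc", cp.CutoffSpec("lt", 0.0))
        assert [c.verdict for c in calls] == [
            "noncoding" if s < 0 else "coding" for s in scores
        ]

    def test_unknown_transcripts_reported(self, tmp_path):
        p = self._table(tmp_path, [("t1", -1.0), ("novel", -1.0)])
        _, unknown = cp.import_calls(p, "cpc", cp.CutoffSpec("lt", 0.0),
                                     known_transcripts={"t1"})
        assert unknown == ["novel"]

    def test_verbatim_verdicts(self, tmp_path):
        p = self._table(tmp_path, [("t1", "noncoding"), ("t2", "coding")],
                        cols=("transcript_id", "verdict"))
        calls, _ = cp.import_calls(p, "feelnc", cp.CutoffSpec(verbatim=True))
        assert [c.verdict for c in calls] == ["noncoding", "coding"]


# ---------------------------------------------------------------------------
# Consensus voting


def _callset(gene_tx, verdicts):
    """verdicts: {(transcript, tool): 'coding'/'noncoding'}"""
    cs = cp.CodingCallSet(gene_tx)
    cs.add_calls(
        cp.CodingCall(t, tool, 0.0, v) for (t, tool), v in verdicts.items()
    )
    return cs


class TestConsensus:
    def test_unanimous_gene_in_consensus(self):
        cs = _callset({"g": ["t"]}, {("t", t): "noncoding" for t in "ABC"})
        assert cs.consensus(2) == {"g"}

    def test_single_vote_excluded(self):
        cs = _callset(
            {"g": ["t"]},
            {("t", "A"): "noncoding", ("t", "B"): "coding", ("t", "C"): "coding"},
        )
        assert cs.consensus(2) == set()

    def test_gene_level_rule_worked_example(self):
        """Two transcripts; tool A calls one coding -> gene coding under A;
        B and C call all noncoding -> 2 votes -> included."""
        v = {("t1", "A"): "coding", ("t2", "A"): "noncoding"}
        for tool in "BC":
            v[("t1", tool)] = v[("t2", tool)] = "noncoding"
        cs = _callset({"g": ["t1", "t2"]}, v)
        assert cs.gene_verdict("g", "A") == "coding"
        assert cs.consensus(2) == {"g"}

    def test_missing_call_counts_as_coding(self):
        cs = _callset({"g": ["t1", "t2"]},
                      {("t1", "A"): "noncoding", ("t1", "B"): "noncoding",
                       ("t2", "B"): "noncoding"})
        # t2 has no call under A -> gene coding under A -> only 1 vote
        assert cs.consensus(2) == set()
        # permissive policy flips it
        assert cs.consensus(2, missing_policy="noncoding") == {"g"}

    def test_random_matrix_matches_brute_force_votes(self, rng):
        genes = {f"g{i:03d}": [f"g{i:03d}.t{k}" for k in range(rng.integers(1, 4))]
                 for i in range(500)}
        tools = ["A", "B", "C"]
        verdicts = {
            (t, tool): ("noncoding" if rng.random() < 0.6 else "coding")
            for g, ts in genes.items() for t in ts for tool in tools
        }
        cs = _callset(genes, verdicts)
        for m in (1, 2, 3):
            expect = set()
            for g, ts in genes.items():
                votes = sum(
                    all(verdicts[(t, tool)] == "noncoding" for t in ts)
                    for tool in tools
                )
                if votes >= m:
                    expect.add(g)
            assert cs.consensus(m) == expect
        # monotone in m_votes
        assert cs.consensus(3) <= cs.consensus(2) <= cs.consensus(1)

    def test_adding_allnoncoding_tool_never_shrinks(self, rng):
        genes = {f"g{i}": [f"g{i}.t"] for i in range(50)}
        verdicts = {
            (f"g{i}.t", tool): ("noncoding" if rng.random() < 0.5 else "coding")
            for i in range(50) for tool in "AB"
        }
        cs = _callset(genes, verdicts)
        before = cs.consensus(2)
        cs.add_calls(cp.CodingCall(f"g{i}.t", "D", 0.0, "noncoding") for i in range(50))
        assert before <= cs.consensus(2)

    def test_invariant_to_tool_and_transcript_order(self):
        genes = {"g1": ["a", "b"], "g2": ["c"]}
        v = {("a", "X"): "noncoding", ("b", "X"): "noncoding", ("c", "X"): "coding",
             ("a", "Y"): "noncoding", ("b", "Y"): "noncoding", ("c", "Y"): "noncoding"}
        cs1 = _callset(genes, v)
        cs2 = _callset({"g2": ["c"], "g1": ["b", "a"]},
                       dict(reversed(list(v.items()))))
        assert cs1.consensus(2) == cs2.consensus(2)

    def test_m_votes_exceeding_tools_rejected(self):
        cs = _callset({"g": ["t"]}, {("t", "A"): "noncoding", ("t", "B"): "noncoding"})
        with pytest.raises(ValueError):
            cs.consensus(4)

    def test_transcript_level_mode(self):
        # t1 noncoding under 2 tools, t2 under only 1 -> gene fails
        v = {("t1", "A"): "noncoding", ("t1", "B"): "noncoding",
             ("t2", "A"): "noncoding", ("t2", "B"): "coding"}
        cs = _callset({"g": ["t1", "t2"]}, v)
        assert cs.consensus(2, level="transcript") == set()
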