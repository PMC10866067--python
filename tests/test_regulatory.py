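"""Spearman screening and the cis/trans candidate routes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from linctools import regulatory as reg
from linctools.positional import PositionalClass


def _de_table(flags):
    return pd.DataFrame(
        {"basemean": 100.0, "log2fc": 1.0, "pvalue": 0.001, "padj": 0.001,
         "de_flag": list(flags.values())},
        index=list(flags),
    )


def _intergenic(linc, neighbor, dist=10_000):
    return PositionalClass(linc, "intergenic", neighbor, dist, "sense", "n/a")


def _non_neighboring(linc):
    return PositionalClass(linc, "non_neighboring")


class TestSpearman:
    def test_monotone_increasing_is_one(self):
        rho, _ = reg.spearman([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert rho == pytest.approx(1.0)

    def test_monotone_decreasing_is_minus_one(self):
        rho, _ = reg.spearman([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self, rng):
        x = rng.normal(size=18)
        y = rng.normal(size=18)
        rho, p = reg.spearman(x, y)
        rho_hand = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
        assert rho == pytest.approx(rho_hand)
        t = rho_hand * np.sqrt(16) / np.sqrt(1 - rho_hand**2)
        assert p == pytest.approx(2 * stats.t.sf(abs(t), df=16))

    def test_ties_use_average_ranks(self):
        rho, _ = reg.spearman([1, 1, 2, 3], [1, 2, 3, 4])
        expect = np.corrcoef(stats.rankdata([1, 1, 2, 3]), [1, 2, 3, 4])[0, 1]
        assert rho == pytest.approx(expect)

    def test_exact_permutation_small_n(self):
        x = [1.0, 2, 3, 4, 5]
        y = [1.0, 2, 3, 5, 4]
        rho, p = reg.spearman(x, y, method="exact")
        # brute check: fraction of permutations with |rho| >= observed
        assert 0 < p < 1
        with pytest.raises(ValueError):
            reg.spearman(list(range(9)), list(range(9)), method="exact")

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            reg.spearman([1, 1, 1, 1], [1, 2, 3, 4])

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            reg.spearman([1, 2, 3], [1, 2, 3])


class TestCisRoutes:
    def test_high_expression_route_planted(self):
        classes = [_intergenic(f"L{i}", f"C{i}") for i in range(3)]
        cands, _ = reg.cis_candidates(classes, {"L0", "L1", "L2"}, _de_table({}))
        assert len(cands) == 3
        assert {c.mode for c in cands} == {reg.MODE_CIS_HIGH}
        assert {(c.linc_gene_id, c.coding_gene_id) for c in cands} == {
            ("L0", "C0"), ("L1", "C1"), ("L2", "C2")
        }

    def test_de_route_requires_both_de(self):
        classes = [_intergenic("L1", "C1")]
        cands, _ = reg.cis_candidates(
            classes, set(), _de_table({"L1": True, "C1": False})
        )
        assert cands == []
        cands, _ = reg.cis_candidates(
            classes, set(), _de_table({"L1": True, "C1": True})
        )
        assert [c.mode for c in cands] == [reg.MODE_CIS_DE]

    def test_module_route_requires_significant_module(self):
        classes = [_intergenic("L1", "C1")]
        modules = {"L1": "turquoise", "C1": "turquoise"}
        # shared module but not significant (trait p = 0.5) -> no pair
        cands, _ = reg.cis_candidates(classes, set(), _de_table({}), modules, [])
        assert cands == []
        cands, _ = reg.cis_candidates(
            classes, set(), _de_table({}), modules, ["turquoise"]
        )
        assert [c.mode for c in cands] == [reg.MODE_CIS_MODULE]
        assert cands[0].module == "turquoise"

    def test_linc_without_neighbor_skipped_and_reported(self):
        classes = [_non_neighboring("L9"), _intergenic("L1", "C1")]
        cands, skipped = reg.cis_candidates(classes, {"L9", "L1"}, _de_table({}))
        assert skipped == ["L9"]
        assert [(c.linc_gene_id, c.coding_gene_id) for c in cands] == [("L1", "C1")]

    def test_seeded_fixture_matches_brute_force_rules(self, rng):
        n = 100
        classes = [_intergenic(f"L{i}", f"C{i}") for i in range(n)]
        high = {f"L{i}" for i in range(n) if rng.random() < 0.3}
        de_flags = {}
        for i in range(n):
            de_flags[f"L{i}"] = bool(rng.random() < 0.4)
            de_flags[f"C{i}"] = bool(rng.random() < 0.4)
        modules = {}
        for i in range(n):
            modules[f"L{i}"] = rng.choice(["turquoise", "blue", "grey"])
            modules[f"C{i}"] = rng.choice(["turquoise", "blue", "grey"])
        sig = ["turquoise"]
        cands, _ = reg.cis_candidates(classes, high, _de_table(de_flags), modules, sig)
        got = {(c.linc_gene_id, c.coding_gene_id, c.mode) for c in cands}
        expect = set()
        for i in range(n):
            li, ci = f"L{i}", f"C{i}"
            if li in high:
                expect.add((li, ci, reg.MODE_CIS_HIGH))
            if de_flags[li] and de_flags[ci]:
                expect.add((li, ci, reg.MODE_CIS_DE))
            if modules[li] == modules[ci] == "turquoise":
                expect.add((li, ci, reg.MODE_CIS_MODULE))
        assert got == expect

    def test_cis_pairs_only_ever_use_assigned_neighbor(self, rng):
        classes = [_intergenic(f"L{i}", f"C{i}") for i in range(20)]
        cands, _ = reg.cis_candidates(
            classes, {f"L{i}" for i in range(20)}, _de_table({})
        )
        neighbor_of = {c.lnc_gene_id: c.neighbor_gene_id for c in classes}
        for c in cands:
            assert c.coding_gene_id == neighbor_of[c.linc_gene_id]


class TestTransRoutes:
    def _planted(self, rng, n_planted=5, n_decoy=50, n_samples=18):
        """Planted lincs copy a coding profile (+ tiny noise); decoys are
        independent. Everything is DE so the (d) universe covers all pairs."""
        rows, de_flags, classes = {}, {}, []
        for i in range(n_planted):
            prof = rng.uniform(10, 1000, n_samples)
            rows[f"CP{i}"] = prof
            rows[f"LP{i}"] = prof + rng.normal(0, 0.01, n_samples)
            de_flags[f"CP{i}"] = de_flags[f"LP{i}"] = True
            classes.append(_non_neighboring(f"LP{i}"))
        for i in range(n_decoy):
            rows[f"LD{i}"] = rng.uniform(10, 1000, n_samples)
            de_flags[f"LD{i}"] = True
            classes.append(_non_neighboring(f"LD{i}"))
        norm = pd.DataFrame(rows).T
        coding_ids = [f"CP{i}" for i in range(n_planted)]
        return norm, _de_table(de_flags), classes, coding_ids

    def test_planted_pairs_recovered_no_decoys(self, rng):
        norm, de, classes, coding_ids = self._planted(rng)
        cands = reg.trans_candidates(norm, de, None, [], classes,
                                     coding_ids=coding_ids)
        got = {(c.linc_gene_id, c.coding_gene_id) for c in cands}
        assert got == {(f"LP{i}", f"CP{i}") for i in range(5)}

    def test_p_rule_drops_high_rho_small_evidence(self):
        """|rho| large but p above 0.01 (tiny n) is rejected."""
        x = np.array([1.0, 2, 3, 5, 4])
        rho, p = reg.spearman(x, np.arange(5.0))
        assert abs(rho) == pytest.approx(0.9) and p > 0.01
        norm = pd.DataFrame({"L1": x, "C1": np.arange(5.0)}).T
        de = _de_table({"L1": True, "C1": True})
        # rho_min relaxed below the observed rho: only the p rule can reject
        cands = reg.trans_candidates(norm, de, None, [], [_non_neighboring("L1")],
                                     coding_ids=["C1"], rho_min=0.85)
        assert cands == []

    def test_rho_boundary_inclusive(self):
        """rho exactly 0.9 at n=9 (three planted rank swaps) with p < 0.01 is kept."""
        x = np.arange(1.0, 10.0)
        y = x.copy()
        y[[0, 2]] = y[[2, 0]]  # distance-2 swap: sum d^2 = 8
        y[[3, 4]] = y[[4, 3]]  # adjacent swaps: 2 each
        y[[5, 6]] = y[[6, 5]]
        rho, p = reg.spearman(x, y)
        assert rho == pytest.approx(0.9)
        assert p <= 0.01
        norm = pd.DataFrame({"L1": x, "C1": y}).T
        cands = reg.trans_candidates(
            norm, _de_table({"L1": True, "C1": True}), None, [],
            [_non_neighboring("L1")], coding_ids=["C1"],
        )
        assert [(c.linc_gene_id, c.coding_gene_id) for c in cands] == [("L1", "C1")]

    def test_neighbor_exclusion(self, rng):
        norm, de, classes, coding_ids = self._planted(rng, n_planted=2, n_decoy=0)
        classes[0] = _intergenic("LP0", "C_elsewhere")
        cands = reg.trans_candidates(norm, de, None, [], classes,
                                     coding_ids=coding_ids)
        lincs = {c.linc_gene_id for c in cands}
        assert lincs == {"LP1"}
        cands_keep = reg.trans_candidates(norm, de, None, [], classes,
                                          coding_ids=coding_ids,
                                          exclude_with_neighbor=False)
        assert {c.linc_gene_id for c in cands_keep} == {"LP0", "LP1"}

    def test_module_route_universe(self, rng):
        norm, de, classes, coding_ids = self._planted(rng, n_planted=3, n_decoy=0)
        de["de_flag"] = False  # kill route (d)
        modules = {"LP0": "turquoise", "CP0": "turquoise",
                   "LP1": "turquoise", "CP1": "blue",
                   "LP2": "blue", "CP2": "blue"}
        cands = reg.trans_candidates(norm, de, modules, ["turquoise"], classes,
                                     coding_ids=coding_ids)
        assert {(c.linc_gene_id, c.coding_gene_id) for c in cands} == {("LP0", "CP0")}
        assert all(c.mode == reg.MODE_TRANS_MODULE for c in cands)

    def test_tightening_thresholds_never_enlarges(self, rng):
        norm, de, classes, coding_ids = self._planted(rng, n_planted=4, n_decoy=10)
        loose = reg.trans_candidates(norm, de, None, [], classes,
                                     coding_ids=coding_ids, rho_min=0.5, p_max=0.05)
        tight = reg.trans_candidates(norm, de, None, [], classes,
                                     coding_ids=coding_ids, rho_min=0.9, p_max=0.01)
        assert {(c.linc_gene_id, c.coding_gene_id) for c in tight} <= {
            (c.linc_gene_id, c.coding_gene_id) for c in loose
        }

    def test_empty_universe_warns(self):
        norm = pd.DataFrame({"L1": np.arange(5.0)}).T
        with pytest.warns(UserWarning, match="empty"):
            out = reg.trans_candidates(norm, _de_table({"L1": False}), None, [],
                                       [_non_neighboring("L1")], coding_ids=[])
        assert out == []


class TestSummarize:
    def test_empty_input(self):
        out = reg.summarize([])
        assert (out["pairs"] == 0).all()

    def test_shared_linc_tally(self):
        cands = [
            reg.RegulatoryCandidate("L1", f"C{i}", reg.MODE_TRANS_DE, rho=0.95,
                                    p_value=0.001)
            for i in range(3)
        ]
        out = reg.summarize(cands)
        assert out.loc[reg.MODE_TRANS_DE, "pairs"] == 3
        assert out.loc[reg.MODE_TRANS_DE, "distinct_lincs"] == 1
        assert out.loc[reg.MODE_TRANS_DE, "distinct_coding"] == 3

    def test_duplicates_within_mode_collapse(self):
        c = reg.RegulatoryCandidate("L1", "C1", reg.MODE_CIS_HIGH)
        out = reg.summarize([c, c])
        assert out.loc[reg.MODE_CIS_HIGH, "pairs"] == 1
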