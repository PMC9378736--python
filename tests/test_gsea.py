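"""Correlation ranking, enrichment score, permutation null, prioritisation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from circscreen.errors import ParameterError, StageError
from circscreen.expression import ExpressionMatrix
from circscreen.gsea import (RankedList, GeneSet, pearson_profile, gsea_es,
                             gsea_permutation, prioritize, _es_fast)
from circscreen.orfs import CircOrf, OrfScreenRecord
from circscreen.synthetic import simulate_expression


def running_sum_oracle(genes, scores, members, weight):
    """Independent literal running-sum: walk the list, track the extremum."""
    members = set(members)
    hits = [g in members for g in genes]
    n, N = sum(hits), len(genes)
    W = sum(abs(s) ** weight for g, s in zip(genes, scores) if g in members)
    rs, cur = [], 0.0
    for g, s in zip(genes, scores):
        if g in members:
            cur += (abs(s) ** weight) / W if W else 1.0 / n
        else:
            cur -= 1.0 / (N - n)
        rs.append(cur)
    es = max(rs, key=abs)
    return es, rs


def make_ranked(n=200, seed=0):
    rng = np.random.default_rng(seed)
    scores = np.sort(rng.uniform(-1, 1, n))[::-1]
    return RankedList([f"g{i:03d}" for i in range(n)], scores)


class TestPearsonProfile:
    def _matrix(self, rows, samples=8):
        cols = [f"s{i}" for i in range(samples)]
        return pd.DataFrame(rows, columns=cols)

    def test_identical_and_negated_profiles(self):
        circ = np.array([1.0, 4, 2, 8, 3, 6, 5, 7])
        m = self._matrix([circ, -circ + 10, 2 * circ])
        m.index = ["same", "neg", "double"]
        ranked = pearson_profile(circ, m)
        r = dict(zip(ranked.genes, ranked.scores))
        assert r["same"] == pytest.approx(1.0)
        assert r["double"] == pytest.approx(1.0)   # linearity
        assert r["neg"] == pytest.approx(-1.0)

    def test_constant_gene_flagged_zero(self):
        circ = np.array([1.0, 2, 3, 4])
        m = self._matrix([[5.0, 5, 5, 5], [1, 2, 3, 4]], samples=4)
        m.index = ["const", "var"]
        ranked = pearson_profile(circ, m)
        assert ranked.constant_genes == ["const"]
        assert dict(zip(ranked.genes, ranked.scores))["const"] == 0.0

    def test_descending_with_lexicographic_ties(self):
        circ = np.array([1.0, 2, 3, 4])
        m = self._matrix([[5.0] * 4, [5.0] * 4], samples=4)
        m.index = ["b", "a"]
        ranked = pearson_profile(circ, m)
        assert ranked.genes == ["a", "b"]

    def test_sample_mismatch_errors(self):
        m = self._matrix([[1.0, 2, 3, 4]], samples=4)
        with pytest.raises(ParameterError):
            pearson_profile(pd.Series([1.0, 2, 3], index=["x", "y", "z"]), m)


class TestEnrichmentScore:
    @pytest.mark.parametrize("weight", [0.0, 1.0])
    def test_matches_running_sum_oracle(self, weight):
        ranked = make_ranked(seed=1)
        rng = np.random.default_rng(2)
        for trial in range(20):
            members = tuple(rng.choice(ranked.genes, 12, replace=False))
            res = gsea_es(ranked, GeneSet(f"s{trial}", members), weight=weight)
            es_o, rs_o = running_sum_oracle(ranked.genes, ranked.scores, members, weight)
            assert res.es == pytest.approx(es_o)
            np.testing.assert_allclose(res.running_sum, rs_o, atol=1e-12)

    def test_top_block_weight0_closed_form(self):
        # all n members in the top n ranks, weight 0: ES = 1 - n/(N-n) * 0 ... =
        # max of running sum = 1 (all hits first), per the literal oracle
        ranked = make_ranked(100, seed=3)
        members = tuple(ranked.genes[:10])
        res = gsea_es(ranked, GeneSet("top", members), weight=0.0)
        es_o, _ = running_sum_oracle(ranked.genes, ranked.scores, members, 0.0)
        assert res.es == pytest.approx(es_o) == pytest.approx(1.0)
        assert res.leading_edge == list(members)

    def test_bottom_block_negative(self):
        ranked = make_ranked(100, seed=4)
        res = gsea_es(ranked, GeneSet("bot", tuple(ranked.genes[-10:])), weight=1.0)
        assert res.es < 0
        assert set(res.leading_edge) <= set(ranked.genes[-10:])

    def test_degenerate_whole_list_flagged(self):
        ranked = make_ranked(50, seed=5)
        res = gsea_es(ranked, GeneSet("all", tuple(ranked.genes)))
        assert not res.evaluable

    def test_no_overlap_flagged(self):
        ranked = make_ranked(50, seed=6)
        res = gsea_es(ranked, GeneSet("none", ("zz1", "zz2")))
        assert not res.evaluable

    @pytest.mark.parametrize("weight", [0.0, 1.0])
    def test_antisymmetry_under_list_reversal(self, weight):
        # reversing the ranked list negates ES (exact at weight 0; the
        # weighted case holds because |r| weights travel with the genes)
        ranked = make_ranked(120, seed=7)
        rng = np.random.default_rng(8)
        members = tuple(rng.choice(ranked.genes, 15, replace=False))
        fwd = gsea_es(ranked, GeneSet("s", members), weight=weight).es
        rev = RankedList(ranked.genes[::-1], ranked.scores[::-1])
        bwd = gsea_es(rev, GeneSet("s", members), weight=weight).es
        assert fwd == pytest.approx(-bwd, abs=1e-9)

    def test_fast_path_equals_full_scan(self):
        ranked = make_ranked(300, seed=9)
        abs_w = np.abs(ranked.scores)
        rng = np.random.default_rng(10)
        for _ in range(50):
            idx = np.sort(rng.choice(300, 20, replace=False))
            members = tuple(ranked.genes[i] for i in idx)
            full = gsea_es(ranked, GeneSet("s", members), weight=1.0).es
            assert _es_fast(abs_w, idx, 300) == pytest.approx(full)

    def test_agrees_with_gseapy_prerank(self):
        gseapy = pytest.importorskip("gseapy")
        ranked = make_ranked(200, seed=11)
        rng = np.random.default_rng(12)
        members = list(rng.choice(ranked.genes, 15, replace=False))
        ours = gsea_es(ranked, GeneSet("s", tuple(members)), weight=1.0).es
        rnk = pd.DataFrame({"gene": ranked.genes, "score": ranked.scores})
        res = gseapy.prerank(rnk=rnk, gene_sets={"s": members}, permutation_num=10,
                             min_size=2, max_size=500, weight=1.0, seed=1,
                             threads=1, outdir=None, no_plot=True)
        assert float(res.res2d["ES"].iloc[0]) == pytest.approx(ours, abs=1e-6)


class TestPermutation:
    def test_seed_determinism_and_p_floor(self):
        ranked = make_ranked(150, seed=13)
        gs = GeneSet("top", tuple(ranked.genes[:12]))
        a = gsea_permutation(ranked, gs, n_perm=200, seed=5)
        b = gsea_permutation(ranked, gs, n_perm=200, seed=5)
        assert a.pvalue == b.pvalue and a.nes == b.nes
        assert a.pvalue >= 1.0 / 201  # +1 correction: never zero

    def test_null_p_uniform(self):
        # random sets: permutation p stochastically uniform (KS test)
        ranked = make_ranked(300, seed=14)
        rng = np.random.default_rng(15)
        ps = []
        for i in range(200):
            members = tuple(rng.choice(ranked.genes, 15, replace=False))
            ps.append(gsea_permutation(ranked, GeneSet(f"s{i}", members),
                                       n_perm=200, seed=1000 + i).pvalue)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_planted_anticorrelated_set_detected(self, circ_profile):
        members = [f"g{i:04d}" for i in range(1, 28)]
        sd = 0.3 * circ_profile.std(ddof=1)
        detected = 0
        for rep in range(10):
            m, _, _ = simulate_expression(500, 12, circ_profile, corr_set=members,
                                          target_r=-0.6, noise_sd=sd, seed=100 + rep)
            ranked = pearson_profile(pd.Series(circ_profile, index=m.samples), m)
            res = gsea_permutation(ranked, GeneSet("nk", tuple(members)),
                                   n_perm=500, seed=rep)
            detected += res.es < 0 and res.pvalue < 0.05
        assert detected >= 9

    def test_n_perm_minimum(self):
        ranked = make_ranked(50)
        with pytest.raises(ParameterError):
            gsea_permutation(ranked, GeneSet("s", (ranked.genes[0],)), n_perm=10)


class TestPrioritize:
    def _stage_outputs(self):
        de = pd.DataFrame({"log2fc": [2.5, 1.4, -1.2, 0.1],
                           "pvalue": [1e-5, 1e-3, 1e-4, 0.9],
                           "padj": [4e-5, 2e-3, 2e-4, 0.9],
                           "call": ["up", "up", "down", "ns"]},
                          index=["circA", "circB", "circC", "circD"])

        def rec(cid, aa, spans=True):
            orf = CircOrf(cid, 0, aa * 3, aa, True, 1 if spans else 0,
                          spans, False, "M" * aa, "")
            return OrfScreenRecord(cid, orf, upregulated=True)

        orfs = {"circA": rec("circA", 92), "circB": rec("circB", 150),
                "circC": rec("circC", 40), "circD": rec("circD", 50)}
        from circscreen.gsea import GseaResult
        gsea = {"circA": GseaResult("nk", -0.8, -2.5, 0.002, 1000, ["g1"], "negative")}
        return de, orfs, gsea

    def test_single_hit_ranked_first(self):
        de, orfs, gsea = self._stage_outputs()
        table = prioritize(de, orfs, gsea, GeneSet("nk", ("g1", "g2")))
        # circB excluded by the 150-aa ORF; circC is down; circD is ns
        assert list(table["circ_id"]) == ["circA"]
        assert bool(table["hit"].iloc[0]) is True

    def test_long_orf_excluded(self):
        de, orfs, gsea = self._stage_outputs()
        table = prioritize(de, orfs, gsea, GeneSet("nk", ("g1",)))
        assert "circB" not in set(table["circ_id"])

    def test_no_upregulated_circles(self):
        de, orfs, gsea = self._stage_outputs()
        de = de.assign(call="ns")
        table = prioritize(de, orfs, gsea, GeneSet("nk", ("g1",)))
        assert table.empty

    def test_missing_stage_named(self):
        de, orfs, _ = self._stage_outputs()
        with pytest.raises(StageError, match="GSEA"):
            prioritize(de, orfs, {}, GeneSet("nk", ("g1",)))
        with pytest.raises(StageError, match="ORF"):
            prioritize(de, {}, {}, GeneSet("nk", ("g1",)))
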