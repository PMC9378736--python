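"""Junction detection: index, partition, anchors, extension, calling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import circscreen as cs
from circscreen.detect import (partition_linear, extract_anchors, detect_headtotail,
                               extend_to_breakpoint, call_candidates, run_detection,
                               BacksplicedJunction, ProvisionalJunction)
from circscreen.index import KmerIndex, Placement
from circscreen.seqtools import revcomp
from circscreen.synthetic import simulate_reads, SimulationTruth


def brute_placements(refs: dict, kmer: str) -> set:
    out = set()
    for name, seq in refs.items():
        for i in range(len(seq) - len(kmer) + 1):
            if seq[i:i + len(kmer)] == kmer:
                out.add((name, i, "+"))
            if seq[i:i + len(kmer)] == revcomp(kmer):
                out.add((name, i, "-"))
    return out


class TestKmerIndex:
    @given(st.text(alphabet="ACGT", min_size=40, max_size=200), st.data())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_lookup_matches_brute_force_scan(self, seq, data):
        idx = KmerIndex({"r": seq}, k=8)
        start = data.draw(st.integers(0, len(seq) - 8))
        kmer = seq[start:start + 8]
        assert set(idx.lookup(kmer)) == brute_placements({"r": seq}, kmer)

    def test_absent_and_both_strand_kmers(self):
        # palindrome-free kmer present forward once and revcomp once
        seq = "A" * 30 + "ACGTTGCACGATCGTACGTA" + "C" * 30 \
            + revcomp("ACGTTGCACGATCGTACGTA") + "G" * 30
        idx = KmerIndex({"chr": seq}, k=20)
        hits = idx.lookup("ACGTTGCACGATCGTACGTA")
        assert {h.strand for h in hits} == {"+", "-"}
        absent = "TGTGTGTGTGTGTGTGTGTG"
        assert brute_placements({"chr": seq}, absent) == set()
        assert idx.lookup(absent) == []

    def test_k_larger_than_reference(self):
        with pytest.raises(cs.ParameterError):
            KmerIndex({"r": "ACGTACGT"}, k=20)


@pytest.fixture(scope="module")
def ref_index(small_world):
    genome, genes, _ = small_world
    refs = dict(genome.chroms)
    refs.update({g.gene_id: g.spliced_sequence(genome) for g in genes})
    return KmerIndex(refs, k=20)


class TestPartitionLinear:
    def test_verbatim_transcript_read_maps(self, small_world, ref_index):
        genome, genes, _ = small_world
        tx = genes[0].spliced_sequence(genome)
        res = partition_linear([("r1", tx[5:155])], ref_index)
        assert res.mapped_count == 1 and not res.unmapped

    def test_substitution_budget(self, small_world, ref_index):
        genome, genes, _ = small_world
        tx = genes[0].spliced_sequence(genome)
        read = list(tx[5:155])
        for pos in (10, 60, 110):  # 3 substitutions > m=2
            read[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[pos]]
        three = "".join(read)
        assert partition_linear([("r", three)], ref_index, m=2).mapped_count == 0
        assert partition_linear([("r", three)], ref_index, m=3).mapped_count == 1

    def test_junction_read_is_unmapped(self, small_world, ref_index):
        _, _, truth = small_world
        c = truth.circs[0]
        read = (c.sequence * 2)[c.length - 70:c.length - 70 + 150]
        res = partition_linear([("r", read)], ref_index)
        assert res.mapped_count == 0 and len(res.unmapped) == 1

    def test_empty_input(self, ref_index):
        res = partition_linear([], ref_index)
        assert res.mapped_count == 0 and res.unmapped == []


class TestAnchorsAndHeadToTail:
    def test_anchors_partition_40nt_read(self, small_world):
        genome, _, _ = small_world
        idx = KmerIndex(genome.chroms, k=20)
        read = genome.chroms["chr1"][100:140]
        pair = extract_anchors("r", read, idx)
        assert pair.left + pair.right == read
        assert pair.left_status == pair.right_status == "unique"

    def test_short_read_skipped(self, small_world):
        genome, _, _ = small_world
        idx = KmerIndex(genome.chroms, k=20)
        assert extract_anchors("r", "ACGT" * 5, idx) is None

    def test_colinear_gives_none(self):
        pair_stub = _pair(pl=Placement("chr1", 100, "+"), pr=Placement("chr1", 230, "+"))
        assert detect_headtotail(pair_stub) is None

    def test_reversed_order_detected_and_span_cap(self):
        pair = _pair(pl=Placement("chr1", 1130, "+"), pr=Placement("chr1", 100, "+"))
        assert detect_headtotail(pair) is not None
        far = _pair(pl=Placement("chr1", 1_000_130, "+"), pr=Placement("chr1", 100, "+"))
        assert detect_headtotail(far, span_cap=100_000) is None
        assert detect_headtotail(far, span_cap=2_000_000) is not None

    def test_ambiguous_anchor_discards_read(self):
        two = (Placement("chr1", 5, "+"), Placement("chr1", 50, "+"))
        pair = cs.AnchorPair("r", "A" * 20, "C" * 20, two, (Placement("chr1", 0, "+"),))
        assert pair.left_status == "ambiguous"
        assert detect_headtotail(pair) is None


def _pair(pl, pr):
    return cs.AnchorPair("r", "A" * 20, "C" * 20, (pl,), (pr,))


class TestExtension:
    def test_recovers_planted_breakpoint(self, small_world):
        genome, _, truth = small_world
        idx = KmerIndex(genome.chroms, k=20)
        for c in truth.circs:
            read = (c.sequence * 2)[c.length - 70:c.length - 70 + 150]
            pair = extract_anchors("r", read, idx)
            prov = detect_headtotail(pair)
            assert prov is not None
            j = extend_to_breakpoint(read, genome.chroms, prov)
            assert j is not None
            assert j.key == c.junction_key

    def test_mutated_flank_gives_none(self, small_world):
        genome, _, truth = small_world
        c = next(x for x in truth.circs if x.strand == "+")
        chrom = genome.chroms[c.chrom]
        # break the donor GT flank in a copied genome
        broken = {c.chrom: chrom[:c.donor_pos] + "CC" + chrom[c.donor_pos + 2:]}
        read = (c.sequence * 2)[c.length - 70:c.length - 70 + 150]
        idx = KmerIndex(genome.chroms, k=20)
        prov = detect_headtotail(extract_anchors("r", read, idx))
        assert extend_to_breakpoint(read, broken, prov) is None

    def test_gt_ag_disambiguates_equivalent_breakpoints(self):
        # repeat base at the junction: two split points align equally well,
        # but only one has AG upstream / GT downstream in the genome
        # acceptor exon starts with G, so the split point can slide right by
        # one with a perfect alignment (read base == the G of the donor's GT
        # flank): two breakpoints align, only one is GT/AG-consistent
        core_a = "GTTGCCGTAACCGGTTAACCGGAATTCCGGATCGATCGTG"   # acceptor-side exon, 40 nt
        core_d = "CATGCATTACGTTGCAATCGGATGCCATTAAGGCCTTGCA"   # donor-side exon, 40 nt
        chrom = ("TTCTTCTTCTTCTTCTTCTTAG" + core_a + "GTCCACCATTGCAAGGTTGGCCAATT"
                 + core_d + "GTAGATAGATAGATAGATAGAT")
        A = chrom.index(core_a)
        D = chrom.index(core_d) + 40
        circ = chrom[A:A + 40] + chrom[D - 40:D]
        read = (circ + circ)[40:110]  # 40 nt donor arm + 30 nt acceptor arm
        idx = KmerIndex({"chr1": chrom}, k=20)
        pair = extract_anchors("r", read, idx)
        prov = detect_headtotail(pair, k=20)
        assert prov is not None
        j = extend_to_breakpoint(read, {"chr1": chrom}, prov, k=20)
        assert j is not None and (j.acceptor_pos, j.donor_pos) == (A, D)


class TestCallCandidates:
    def _junc(self):
        return BacksplicedJunction("chr1", "+", 100, 400)

    def test_two_distinct_reads_in_one_sample_called(self):
        j = self._junc()
        ev = [(j, "s1", "r1", "AAAA"), (j, "s1", "r2", "CCCC")]
        out = call_candidates(ev, min_unique=2)
        assert len(out) == 1 and out[0].support == {"s1": 2}

    def test_duplicates_collapse(self):
        j = self._junc()
        ev = [(j, "s1", f"r{i}", "AAAA") for i in range(5)]
        assert call_candidates(ev, min_unique=2) == []

    def test_one_read_in_each_of_three_samples_not_called(self):
        j = self._junc()
        ev = [(j, s, f"r{s}", seq) for s, seq in
              [("s1", "AAAA"), ("s2", "CCCC"), ("s3", "GGGG")]]
        assert call_candidates(ev, min_unique=2) == []

    def test_catalogue_annotation(self):
        j = self._junc()
        ev = [(j, "s1", "r1", "AAAA"), (j, "s1", "r2", "CCCC")]
        known = call_candidates(ev, catalogue={j.key})[0]
        novel = call_candidates(ev, catalogue={("chr9", "+", 1, 2)})[0]
        assert known.known is True and novel.known is False


class TestEndToEnd:
    def test_planted_truth_recovery_and_no_leakage(self, small_world, small_reads):
        genome, genes, truth = small_world
        det = run_detection(small_reads.reads, genome.chroms,
                            {g.gene_id: g.spliced_sequence(genome) for g in genes})
        called = {c.junction.key for c in det.candidates}
        assert called == {c.junction_key for c in truth.circs}
        for c in det.candidates:
            assert all("|circ|" in rid for rid in c.read_ids)

    def test_strand_symmetry(self, small_world):
        # reverse-complement genome + reads: same candidates, strands flipped
        genome, genes, truth = small_world
        rs = simulate_reads(truth, genome, depth=1500, seed=5)
        tx = {g.gene_id: g.spliced_sequence(genome) for g in genes}
        det = run_detection(rs.reads, genome.chroms, tx)
        n = len(genome.chroms["chr1"])
        rc_genome = {"chr1": revcomp(genome.chroms["chr1"])}
        rc_reads = {s: [(name, revcomp(seq)) for name, seq in recs]
                    for s, recs in rs.reads.items()}
        det_rc = run_detection(rc_reads, rc_genome, tx)
        fwd = {(c.junction.strand, c.junction.acceptor_pos, c.junction.donor_pos)
               for c in det.candidates}
        flipped = {("-" if s == "+" else "+", n - d, n - a)
                   for s, a, d in {(c.junction.strand, c.junction.acceptor_pos,
                                    c.junction.donor_pos) for c in det_rc.candidates}}
        assert fwd == flipped

    def test_min_unique_threshold(self, small_world, small_reads):
        genome, genes, _ = small_world
        det = run_detection(small_reads.reads, genome.chroms,
                            {g.gene_id: g.spliced_sequence(genome) for g in genes},
                            min_unique=10_000)
        assert det.candidates == []
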