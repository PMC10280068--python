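"""Tests for haplotype calling rules, the star alignment (against independent
alignment oracles), NJ trees and the haplotype-vs-length curve."""

import io
import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ighap.haplotypes import (
    GAP_EXTEND,
    GAP_OPEN,
    MATCH,
    MISMATCH,
    align_haplotypes,
    alignment_score,
    call_single_cell_haplotypes,
    call_tissue_haplotypes,
    flag_singleton_site_errors,
    haplotype_length_curve,
    nj_tree,
    p_distance,
    pairwise_global,
)

REF = "ACGTACGTACGTACGTACGT"  # 20 bp


def sub(seq, pos, base):
    assert seq[pos] != base
    return seq[:pos] + base + seq[pos + 1 :]


class TestTissueCall:
    def test_threshold_literal(self, make_uniques):
        # proportions 0.500, 0.300, 0.191, 0.009: the last is excluded
        uniques = make_uniques(
            [("AAAA", 500), ("CCCC", 300), ("TTTT", 191), ("GGGG", 9)]
        )
        hset = call_tissue_haplotypes(uniques)
        assert [e.sequence for e in hset.entries] == ["AAAA", "CCCC", "TTTT"]
        assert all(e.valid for e in hset.entries)

    def test_0182_is_over_one_percent(self, make_uniques):
        uniques = make_uniques([("AAAA", 65600), ("CCCC", 1219)])
        hset = call_tissue_haplotypes(uniques)
        assert len(hset.entries) == 2
        assert hset.entries[1].proportion == 0.0182

    def test_exactly_one_percent_excluded(self, make_uniques):
        uniques = make_uniques([("AAAA", 9900), ("CCCC", 100)])
        assert uniques[1].proportion == 0.01
        hset = call_tissue_haplotypes(uniques)
        assert len(hset.entries) == 1

    def test_nothing_passes_gives_empty_set(self, make_uniques):
        seqs = ["".join(p) for p in itertools.product("ACGT", repeat=4)][:200]
        hset = call_tissue_haplotypes(make_uniques([(s, 1) for s in seqs]))
        assert hset.entries == []


class TestSingleCellCall:
    def test_only_top1_valid(self, make_uniques):
        # one dominant sequence; nine sporadic variants all below 1%
        pairs = [(REF, 76851)]
        for i in range(9):
            pairs.append((sub(REF, i, "A" if REF[i] != "A" else "C"), 50 + i))
        hset = call_single_cell_haplotypes(make_uniques(pairs), top_n=10)
        assert sum(e.valid for e in hset.entries) == 1
        assert hset.entries[0].valid

    def test_private_singleton_over_threshold_is_error(self, make_uniques):
        # Top2 > 1% but its single distinguishing allele is private
        shared = sub(REF, 7, "A" if REF[7] != "A" else "C")
        pairs = [
            (REF, 52745),
            (sub(REF, 3, "C" if REF[3] != "C" else "A"), 1219),  # private site
            (shared, 300),
            (sub(shared, 15, "G" if shared[15] != "G" else "T"), 200),  # shares col 7
        ]
        hset = call_single_cell_haplotypes(make_uniques(pairs), top_n=10)
        by_count = {e.count: e for e in hset.entries}
        assert by_count[1219].proportion > 0.01
        assert by_count[1219].error_flag and not by_count[1219].valid
        assert not by_count[300].error_flag

    def test_single_unique_is_valid(self, make_uniques):
        hset = call_single_cell_haplotypes(make_uniques([(REF, 1000)]))
        assert len(hset.entries) == 1 and hset.entries[0].valid


class TestSingletonFlag:
    def test_rank1_never_flagged(self, make_uniques):
        pairs = [(REF, 100), (sub(REF, 0, "C" if REF[0] != "C" else "G"), 10)]
        hset = call_single_cell_haplotypes(make_uniques(pairs))
        assert not hset.entries[0].error_flag

    def test_shared_column_not_flagged(self, make_uniques):
        v = sub(REF, 5, "T" if REF[5] != "T" else "G")
        pairs = [(REF, 100), (v, 60), (sub(v, 12, "A" if v[12] != "A" else "C"), 30)]
        hset = call_single_cell_haplotypes(make_uniques(pairs))
        flagged = [e.error_flag for e in hset.entries]
        assert flagged == [False, False, False]


def brute_force_best_score(a, b):
    """Exhaustively enumerate global alignments of tiny strings and return
    the best affine score (independent of the DP implementation)."""
    best = [float("-inf")]

    def step(i, j, cols):
        if i == len(a) and j == len(b):
            ra = "".join(c[0] for c in cols)
            rb = "".join(c[1] for c in cols)
            best[0] = max(best[0], alignment_score(ra, rb))
            return
        if i < len(a):
            step(i + 1, j, cols + [(a[i], "-")])
        if j < len(b):
            step(i, j + 1, cols + [("-", b[j])])
        if i < len(a) and j < len(b):
            step(i + 1, j + 1, cols + [(a[i], b[j])])

    step(0, 0, [])
    return best[0]


class TestPairwiseAlignment:
    def test_matches_exhaustive_enumeration_on_tiny_strings(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(15):
            a = "".join(rng.choice(bases, size=rng.integers(1, 6)))
            b = "".join(rng.choice(bases, size=rng.integers(1, 6)))
            ra, rb = pairwise_global(a, b)
            assert ra.replace("-", "") == a and rb.replace("-", "") == b
            assert alignment_score(ra, rb) == brute_force_best_score(a, b)

    def test_matches_biopython_scores_up_to_20bp(self, rng):
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = MATCH
        aligner.mismatch_score = MISMATCH
        aligner.open_gap_score = GAP_OPEN
        aligner.extend_gap_score = GAP_EXTEND
        bases = np.array(list("ACGT"))
        for _ in range(40):
            a = "".join(rng.choice(bases, size=rng.integers(1, 21)))
            b = "".join(rng.choice(bases, size=rng.integers(1, 21)))
            ra, rb = pairwise_global(a, b)
            assert alignment_score(ra, rb) == aligner.score(a, b)

    def test_identical_entries_no_gap_columns(self):
        aln = align_haplotypes([REF, REF, REF])
        assert all("-" not in row for row in aln.rows)

    def test_single_deletion_single_gap(self):
        deleted = REF[:10] + REF[11:]
        aln = align_haplotypes([REF, deleted])
        assert aln.rows[1].count("-") == 1
        assert aln.rows[0] == REF

    def test_alignment_length_at_least_max_entry(self):
        seqs = [REF, REF[:8] + REF[10:], sub(REF, 4, "A" if REF[4] != "A" else "C")]
        aln = align_haplotypes(seqs)
        assert aln.n_columns >= max(len(s) for s in seqs)

    def test_rows_degap_to_inputs(self):
        seqs = [REF, REF[:5] + REF[6:], sub(REF, 2, "T" if REF[2] != "T" else "G")]
        aln = align_haplotypes(seqs)
        for row, seq in zip(aln.rows, seqs):
            assert row.replace("-", "") == seq

    def test_insertion_creates_ref_gap(self):
        inserted = REF[:10] + "ACG" + REF[10:]
        aln = align_haplotypes([REF, inserted])
        assert aln.rows[0].count("-") == 3
        assert aln.rows[1].replace("-", "") == inserted


class TestNJTree:
    def _set(self, make_uniques, pairs):
        return call_tissue_haplotypes(make_uniques(pairs))

    def test_zero_distance_pair_forms_zero_cherry(self, make_uniques):
        from skbio import TreeNode

        a = REF
        b = REF[:10] + REF[11:]  # deletion only: p-distance to REF is 0
        c = REF
        for p in (2, 5, 8, 12, 15, 18):
            c = sub(c, p, "A" if c[p] != "A" else "T")
        d = sub(c, 0, "G" if c[0] != "G" else "C")
        hset = self._set(make_uniques, [(a, 500), (b, 400), (c, 300), (d, 200)])
        assert hset.alignment is not None
        assert p_distance(hset.alignment.rows[0], hset.alignment.rows[1]) == 0.0
        tree = TreeNode.read(io.StringIO(nj_tree(hset)))
        tip = {t.name: t for t in tree.tips()}
        assert tip["H1"].parent is tip["H2"].parent
        # branch lengths are ~0 (exact zero only for perfectly additive input;
        # the deletion row has one fewer shared column against the outgroup)
        assert abs(tip["H1"].length) < 0.01 and abs(tip["H2"].length) < 0.01

    def test_additive_four_taxon_topology_recovered(self, make_uniques):
        from skbio import TreeNode

        A = REF
        B = sub(REF, 0, "C" if REF[0] != "C" else "G")
        C = REF
        for p in (8, 9, 10, 11, 12, 13):
            C = sub(C, p, "A" if C[p] != "A" else "T")
        D = sub(C, 19, "C" if C[19] != "C" else "G")
        hset = self._set(make_uniques, [(A, 500), (B, 400), (C, 300), (D, 200)])
        ids = {e.sequence: e.haplotype_id for e in hset.entries}
        tree = TreeNode.read(io.StringIO(nj_tree(hset)))
        tip = {t.name: t for t in tree.tips()}
        # (A,B) and (C,D) must be cherries in the unrooted NJ tree
        sibs = {frozenset(x.name for x in n.children if x.is_tip())
                for n in tree.non_tips(include_self=True)}
        assert frozenset((ids[C], ids[D])) in sibs or frozenset((ids[A], ids[B])) in sibs

    def test_two_entry_tree(self, make_uniques):
        hset = self._set(make_uniques, [(REF, 60), (sub(REF, 0, "C" if REF[0] != "C" else "G"), 40)])
        nwk = nj_tree(hset)
        assert nwk.startswith("(") and nwk.endswith(";")

    def test_p_distance_symmetric_and_gap_masked(self):
        assert p_distance("AC-T", "ACGT") == 0.0
        assert p_distance("ACGT", "ACGA") == 0.25
        assert p_distance("ACGT", "TCGA") == p_distance("TCGA", "ACGT")


class TestLengthCurve:
    def test_invariant_window_one_haplotype(self):
        inserts = [REF] * 50 + [sub(REF, 15, "A" if REF[15] != "A" else "C")] * 50
        curve = haplotype_length_curve(inserts, [10])
        assert curve == [(10, 1, 1)]

    def test_prethreshold_count_non_decreasing(self, rng):
        bases = np.array(list("ACGT"))
        inserts = []
        for _ in range(30):
            s = list(REF)
            for p in rng.choice(20, size=rng.integers(0, 4), replace=False):
                s[p] = str(rng.choice(bases))
            inserts.append("".join(s))
        curve = haplotype_length_curve(inserts, list(range(1, 21)))
        distinct = [d for _, d, _ in curve]
        assert distinct == sorted(distinct)

    def test_full_window_matches_tissue_call(self, make_uniques):
        v = sub(REF, 3, "G" if REF[3] != "G" else "C")
        inserts = [REF] * 70 + [v] * 30
        curve = haplotype_length_curve(inserts, [len(REF)])
        from ighap.readqc import dereplicate

        hset = call_tissue_haplotypes(dereplicate(inserts))
        assert curve[0][2] == len(hset.entries)
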