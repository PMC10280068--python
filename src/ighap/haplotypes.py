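"""Haplotype calling, alignment, trees and the haplotype-vs-length curve.

A 'haplotype' here is a cluster of identical amplicon reads: every distinct
unique sequence retained by the abundance rules is one haplotype.  Tissue
mode keeps unique sequences with proportion strictly over a threshold
(default 1%); single-cell mode keeps the top-N by count and additionally
invalidates entries whose distinguishing alleles are private singletons
(taken to be sequencing/WGA artifacts).

Alignment is a reference-anchored star alignment: each entry is globally
aligned to the rank-1 entry with affine gap scores (match +1, mismatch -1,
gap open -4, gap extend -1), and the pairwise gaps are projected into a
common coordinate system.  For same-locus amplicons differing by SNPs and
rare short indels this is exact in the no-indel case and deterministic
otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .readqc import UniqueSequence, dereplicate

log = logging.getLogger(__name__)

MATCH = 1
MISMATCH = -1
GAP_OPEN = -4  # score of a length-1 gap
GAP_EXTEND = -1

_NEG = float("-inf")


def pairwise_global(ref: str, qry: str) -> tuple[str, str]:
    """Needleman-Wunsch/Gotoh global alignment of ``qry`` against ``ref``.

    Affine scores: match +1, mismatch -1, gap open -4 (first gap base),
    extend -1 per additional base.  Ties are resolved deterministically,
    preferring substitution states over gaps (M over X over Y) during
    traceback, which places gaps as late-opening/leftmost as the score
    allows.  Returns the two gapped strings (ref row, query row).
    """
    n, m = len(ref), len(qry)
    if n == 0 or m == 0:
        return "-" * m + ref, qry + "-" * n
    M = [[_NEG] * (m + 1) for _ in range(n + 1)]
    X = [[_NEG] * (m + 1) for _ in range(n + 1)]  # gap in query (deletion)
    Y = [[_NEG] * (m + 1) for _ in range(n + 1)]  # gap in ref (insertion)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = GAP_OPEN + (i - 1) * GAP_EXTEND
    for j in range(1, m + 1):
        Y[0][j] = GAP_OPEN + (j - 1) * GAP_EXTEND
    for i in range(1, n + 1):
        ri = ref[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        for j in range(1, m + 1):
            s = MATCH if ri == qry[j - 1] else MISMATCH
            Mi[j] = max(Mp[j - 1], Xp[j - 1], Yp[j - 1]) + s
            Xi[j] = max(Mp[j] + GAP_OPEN, Xp[j] + GAP_EXTEND, Yp[j] + GAP_OPEN)
            Yi[j] = max(Mi[j - 1] + GAP_OPEN, Yi[j - 1] + GAP_EXTEND,
                        Xi[j - 1] + GAP_OPEN)
    # traceback, preferring M, then X, then Y on ties
    i, j = n, m
    best = max(M[n][m], X[n][m], Y[n][m])
    state = "M"
    for s_name, mat in (("M", M), ("X", X), ("Y", Y)):
        if mat[n][m] == best:
            state = s_name
            break
    ra: list[str] = []
    qa: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            s = MATCH if ref[i - 1] == qry[j - 1] else MISMATCH
            target = M[i][j] - s
            ra.append(ref[i - 1])
            qa.append(qry[j - 1])
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            for s_name, mat in (("M", M), ("X", X), ("Y", Y)):
                if mat[i][j] == target:
                    state = s_name
                    break
        elif state == "X":
            ra.append(ref[i - 1])
            qa.append("-")
            val = X[i][j]
            i -= 1
            if i == 0 and j == 0:
                break
            if M[i][j] + GAP_OPEN == val:
                state = "M"
            elif X[i][j] + GAP_EXTEND == val:
                state = "X"
            else:
                state = "Y"
        else:  # Y
            ra.append("-")
            qa.append(qry[j - 1])
            val = Y[i][j]
            j -= 1
            if i == 0 and j == 0:
                break
            if M[i][j] + GAP_OPEN == val:
                state = "M"
            elif Y[i][j] + GAP_EXTEND == val:
                state = "Y"
            else:
                state = "X"
    return "".join(reversed(ra)), "".join(reversed(qa))


def alignment_score(ref_row: str, qry_row: str) -> float:
    """Score of a gapped pair under the package's alignment scores."""
    if len(ref_row) != len(qry_row):
        raise ValueError("rows must have equal length")
    score = 0.0
    prev_gap_r = prev_gap_q = False
    for a, b in zip(ref_row, qry_row):
        if a == "-" and b == "-":
            raise ValueError("double-gap column")
        if a == "-":
            score += GAP_EXTEND if prev_gap_r else GAP_OPEN
            prev_gap_r, prev_gap_q = True, False
        elif b == "-":
            score += GAP_EXTEND if prev_gap_q else GAP_OPEN
            prev_gap_r, prev_gap_q = False, True
        else:
            score += MATCH if a == b else MISMATCH
            prev_gap_r = prev_gap_q = False
    return score


@dataclass
class Alignment:
    """Gapped matrix over entries; row 0 is the star center (rank-1 entry).

    ``col_refpos[c]`` is the reference (center, ungapped) coordinate of
    column ``c`` or ``None`` for an insertion column.
    """

    rows: list[str]
    col_refpos: list[int | None]

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def col_of_refpos(self, pos: int) -> int:
        for c, p in enumerate(self.col_refpos):
            if p == pos:
                return c
        raise ValueError(f"reference position {pos} not in alignment")

    def degapped(self, row: int) -> str:
        return self.rows[row].replace("-", "")


def align_haplotypes(sequences: Sequence[str]) -> Alignment:
    """Star alignment of all sequences against the first one.

    Pairwise gaps are merged into a shared coordinate system: a gap opened
    against the reference at offset o by any entry creates a shared column
    block of the maximal insertion length seen at o.  Every row degaps back
    to its input sequence; the reference row has gaps only where some entry
    carries an insertion.
    """
    if not sequences:
        raise ValueError("need at least one sequence")
    center = sequences[0]
    n = len(center)
    base_chars: list[list[str]] = []
    ins_maps: list[dict[int, str]] = []
    for seq in sequences:
        if seq == center:
            base_chars.append(list(center))
            ins_maps.append({})
            continue
        r_row, q_row = pairwise_global(center, seq)
        chars = ["-"] * n
        ins: dict[int, str] = {}
        p = 0
        for rc, qc in zip(r_row, q_row):
            if rc == "-":
                ins[p] = ins.get(p, "") + qc
            else:
                chars[p] = qc
                p += 1
        base_chars.append(chars)
        ins_maps.append(ins)

    ins_len = {o: max(len(m[o]) for m in ins_maps if o in m)
               for o in {o for m in ins_maps for o in m}}

    rows = ["" for _ in sequences]
    col_refpos: list[int | None] = []
    ref_parts: list[list[str]] = [[] for _ in sequences]
    for p in range(n + 1):
        w = ins_len.get(p, 0)
        if w:
            for k, m in enumerate(ins_maps):
                s = m.get(p, "")
                ref_parts[k].append(s + "-" * (w - len(s)))
            col_refpos.extend([None] * w)
        if p < n:
            for k in range(len(sequences)):
                ref_parts[k].append(base_chars[k][p])
            col_refpos.append(p)
    rows = ["".join(parts) for parts in ref_parts]
    return Alignment(rows=rows, col_refpos=col_refpos)


@dataclass
class HaplotypeEntry:
    haplotype_id: str
    sequence: str
    count: int
    proportion: float
    valid: bool = True
    error_flag: bool = False


@dataclass
class HaplotypeSet:
    mode: Literal["tissue", "single_cell"]
    entries: list[HaplotypeEntry]
    total_reads: int
    alignment: Alignment | None = None

    def valid_entries(self) -> list[HaplotypeEntry]:
        return [e for e in self.entries if e.valid]

    def valid_mask(self) -> list[bool]:
        return [e.valid for e in self.entries]


def _build_set(
    mode: Literal["tissue", "single_cell"],
    kept: Sequence[UniqueSequence],
    total: int,
) -> HaplotypeSet:
    entries = [
        HaplotypeEntry(
            haplotype_id=f"H{i + 1}",
            sequence=u.bases,
            count=u.count,
            proportion=u.proportion,
        )
        for i, u in enumerate(kept)
    ]
    aln = align_haplotypes([e.sequence for e in entries]) if entries else None
    return HaplotypeSet(mode=mode, entries=entries, total_reads=total, alignment=aln)


def call_tissue_haplotypes(
    uniques: Sequence[UniqueSequence], min_prop: float = 0.01
) -> HaplotypeSet:
    """Tissue-DNA haplotype call: keep proportions strictly over ``min_prop``.

    The threshold is applied to the rounded proportion, so exactly 1.00% is
    excluded while 1.82% ('over 1.0%') is retained.
    """
    total = sum(u.count for u in uniques)
    kept = [u for u in uniques if u.proportion > min_prop]
    if not kept:
        log.warning("no unique sequence exceeds proportion %.4f", min_prop)
    return _build_set("tissue", kept, total)


def call_single_cell_haplotypes(
    uniques: Sequence[UniqueSequence], top_n: int = 10, min_prop: float = 0.01
) -> HaplotypeSet:
    """Single-cell haplotype call: align the top-N, validate by proportion
    and the private-singleton error rule."""
    total = sum(u.count for u in uniques)
    if len(uniques) < top_n:
        log.info("only %d unique sequences for top_n=%d", len(uniques), top_n)
    kept = list(uniques[:top_n])
    hset = _build_set("single_cell", kept, total)
    for e in hset.entries:
        e.valid = e.proportion > min_prop
    flag_singleton_site_errors(hset)
    for e in hset.entries:
        e.valid = e.valid and not e.error_flag
    return hset


def flag_singleton_site_errors(hset: HaplotypeSet) -> HaplotypeSet:
    """Flag entries whose distinguishing alleles are all private singletons.

    An entry (other than rank 1) is error-flagged iff every alignment column
    where it differs from the rank-1 entry is a column where no other entry
    differs from rank 1.  Such a variant is supported by no second
    observation at any of its sites and is treated as a sequencing error.
    """
    if hset.alignment is None or len(hset.entries) < 2:
        return hset
    rows = hset.alignment.rows
    ref = rows[0]
    diff_cols = [
        {c for c in range(len(ref)) if row[c] != ref[c]} for row in rows
    ]
    for i in range(1, len(rows)):
        mine = diff_cols[i]
        if not mine:
            continue
        shared = any(
            mine & diff_cols[j]
            for j in range(len(rows))
            if j not in (0, i)
        )
        if not shared:
            hset.entries[i].error_flag = True
    return hset


def p_distance(row_a: str, row_b: str) -> float:
    """Proportion of differing bases over columns where both rows are ungapped."""
    shared = diff = 0
    for a, b in zip(row_a, row_b):
        if a == "-" or b == "-":
            continue
        shared += 1
        if a != b:
            diff += 1
    return diff / shared if shared else 0.0


def nj_tree(hset: HaplotypeSet) -> str:
    """Neighbor-joining tree (newick) over p-distances between entries.

    Identical sequences sit at distance 0 and form zero-length cherries;
    those clusters are the haplotype groups.  Degenerate 1- and 2-entry sets
    return trivial trees directly.
    """
    entries = hset.entries
    if not entries:
        raise ValueError("empty haplotype set")
    ids = [e.haplotype_id for e in entries]
    if len(entries) == 1:
        return f"{ids[0]};"
    assert hset.alignment is not None
    rows = hset.alignment.rows
    if len(entries) == 2:
        d = p_distance(rows[0], rows[1])
        return f"({ids[0]}:{d / 2:.6f},{ids[1]}:{d / 2:.6f});"
    import io

    from skbio import DistanceMatrix
    from skbio.tree import nj

    n = len(entries)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = p_distance(rows[i], rows[j])
    dm = DistanceMatrix(mat, ids)
    buf = io.StringIO()
    nj(dm).write(buf)
    return buf.getvalue().strip()


def haplotype_length_curve(
    inserts: Sequence[str],
    window_ends: Sequence[int],
    min_prop: float = 0.01,
) -> list[tuple[int, int, int]]:
    """Distinct-haplotype counts over nested prefix windows of the insert.

    For each window end the inserts are truncated to [0, end), dereplicated
    and thresholded as in tissue mode.  Returns
    ``(window_length, n_distinct_prethreshold, n_haplotypes)`` tuples; the
    pre-threshold count is non-decreasing in window length.  Windows past an
    insert's length use the full insert.
    """
    shortest = min(len(s) for s in inserts)
    out = []
    for end in window_ends:
        if end > shortest:
            log.warning("window end %d beyond shortest insert (%d)", end, shortest)
        truncated = [s[:end] for s in inserts]
        uniques = dereplicate(truncated)
        n_valid = sum(1 for u in uniques if u.proportion > min_prop)
        out.append((end, len(uniques), n_valid))
    return out


def write_haplotypes_fasta(hset: HaplotypeSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for e in hset.entries:
            fh.write(
                f">{e.haplotype_id}_{e.count}_{hset.total_reads}_"
                f"{e.proportion:.4f}_{'valid' if e.valid else 'invalid'}\n"
                f"{e.sequence}\n"
            )


def write_aligned_fasta(hset: HaplotypeSet, path: str | Path) -> None:
    if hset.alignment is None:
        raise ValueError("haplotype set has no alignment")
    with open(path, "w") as fh:
        for e, row in zip(hset.entries, hset.alignment.rows):
            fh.write(f">{e.haplotype_id}\n{row}\n")
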