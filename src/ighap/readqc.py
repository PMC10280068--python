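"""Read quality control and dereplication for amplicon sequencing data.

Implements the QC chain applied to merged amplicon reads before haplotype
calling: 3'-anchored quality trimming, exact primer matching with orientation
rescue, exact-string dereplication into counted unique sequences, and de novo
two-parent chimera flagging.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import reverse_complement

log = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")


@dataclass
class AmpliconRead:
    """One (already merged) amplicon sequencing read."""

    id: str
    bases: str
    quals: Sequence[int]

    def __post_init__(self) -> None:
        if len(self.quals) != len(self.bases):
            raise ValueError(
                f"read {self.id}: {len(self.quals)} qualities for "
                f"{len(self.bases)} bases"
            )
        bad = set(self.bases) - _VALID_BASES
        if bad:
            raise ValueError(f"read {self.id}: invalid symbols {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class UniqueSequence:
    """A dereplicated insert with abundance bookkeeping.

    ``proportion`` is count/total rounded half-up to 4 decimals, matching the
    rank_count_total_proportion encoding used in read-set reports
    (e.g. ``Top1_52745_66819_0.7894``).
    """

    bases: str
    count: int
    rank: int = 0
    proportion: float = 0.0
    chimera: bool = False


def read_fastq(path: str | Path) -> Iterator[AmpliconRead]:
    """Stream reads from a Sanger Phred+33 FASTQ file."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield AmpliconRead(
            id=rec.id,
            bases=str(rec.seq).upper(),
            quals=rec.letter_annotations["phred_quality"],
        )


def round_proportion(count: int, total: int) -> float:
    """count/total rounded half-up to 4 decimal places."""
    if total <= 0:
        raise ValueError("total must be positive")
    q = (Decimal(count) / Decimal(total)).quantize(
        Decimal("0.0001"), rounding=ROUND_HALF_UP
    )
    return float(q)


def quality_trim(
    read: AmpliconRead, q_min: int = 20, trim_both_ends: bool = False
) -> AmpliconRead:
    """Trim low-quality bases (< ``q_min``) from the 3' end inward.

    Scanning stops at the first base with quality >= ``q_min``; internal
    low-quality bases are retained.  ``trim_both_ends`` additionally applies
    the same rule from the 5' end (off by default).  May return an empty
    read, which downstream filters discard.
    """
    end = len(read.bases)
    while end > 0 and read.quals[end - 1] < q_min:
        end -= 1
    start = 0
    if trim_both_ends:
        while start < end and read.quals[start] < q_min:
            start += 1
    if start == 0 and end == len(read.bases):
        return read
    return AmpliconRead(read.id, read.bases[start:end], list(read.quals[start:end]))


def match_primers(read: AmpliconRead, fwd: str, rev: str) -> str | None:
    """Extract the insert when both primers match perfectly, else ``None``.

    The read must begin with ``fwd`` and end with the reverse complement of
    ``rev``; the reverse complement of the read is also tested (orientation
    rescue) and the insert is always returned in forward orientation.  Any
    mismatch in the primer regions -- including an N -- rejects the read, as
    does an insert shorter than one base.
    """
    if not fwd or not rev:
        raise ValueError("primers must be non-empty")
    fwd = fwd.upper()
    rev_rc = reverse_complement(rev.upper())
    min_len = len(fwd) + len(rev_rc) + 1
    for bases in (read.bases, reverse_complement(read.bases)):
        if len(bases) >= min_len and bases.startswith(fwd) and bases.endswith(rev_rc):
            return bases[len(fwd) : len(bases) - len(rev_rc)]
    return None


def dereplicate(inserts: Iterable[str]) -> list[UniqueSequence]:
    """Collapse identical insert strings into counted unique sequences.

    Ranked by count descending, ties broken lexicographically by sequence;
    proportions are count/total rounded half-up to 4 decimals.
    """
    counts = Counter(inserts)
    if not counts:
        raise ValueError("no inserts to dereplicate")
    total = sum(counts.values())
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [
        UniqueSequence(
            bases=seq,
            count=n,
            rank=i + 1,
            proportion=round_proportion(n, total),
        )
        for i, (seq, n) in enumerate(ordered)
    ]


def _lcp_lcs_matrix(cand: np.ndarray, parents: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Longest common prefix/suffix lengths of ``cand`` against each parent row."""
    neq = parents != cand[None, :]
    L = cand.size
    any_neq = neq.any(axis=1)
    first = np.where(any_neq, neq.argmax(axis=1), L)
    last_neq = np.where(any_neq, L - 1 - neq[:, ::-1].argmax(axis=1), -1)
    lcs = L - 1 - last_neq
    return first, lcs


def flag_chimeras(
    uniques: Sequence[UniqueSequence], parent_factor: float = 2.0
) -> list[UniqueSequence]:
    """Flag two-parent chimeras among ranked unique sequences.

    A candidate is chimeric iff two distinct equal-length parents exist, each
    with count >= ``parent_factor`` x the candidate's count, and a breakpoint
    b (1 <= b <= L-1) such that the candidate equals parent A over [0, b) and
    parent B over [b, L).  Sequences of unequal length are never flagged, nor
    is the most abundant sequence.  Returns a new list with ``chimera`` set.
    """
    out = [replace(u) for u in uniques]
    by_len: dict[int, list[UniqueSequence]] = {}
    for u in out:
        by_len.setdefault(len(u.bases), []).append(u)

    for length, group in by_len.items():
        if length == 0:
            continue
        enc = np.frombuffer(
            "".join(u.bases for u in group).encode("ascii"), dtype=np.uint8
        ).reshape(len(group), length)
        counts = np.array([u.count for u in group])
        for i, u in enumerate(group):
            thresh = parent_factor * u.count
            pidx = np.nonzero(counts >= thresh)[0]
            pidx = pidx[pidx != i]
            if pidx.size < 2:
                continue
            lcp, lcs = _lcp_lcs_matrix(enc[i], enc[pidx])
            # need distinct parents A (prefix) and B (suffix):
            # exists a != b with lcp[a] + lcs[b] >= L, lcp[a] >= 1, lcs[b] >= 1
            ok_p = lcp >= 1
            ok_s = lcs >= 1
            if not (ok_p.any() and ok_s.any()):
                continue
            a = int(np.argmax(np.where(ok_p, lcp, -1)))
            b = int(np.argmax(np.where(ok_s, lcs, -1)))
            if a != b:
                if lcp[a] + lcs[b] >= length:
                    u.chimera = True
            else:
                # best prefix and suffix from the same parent: try second-best
                lcp2 = np.where(ok_p, lcp, -1).copy()
                lcp2[a] = -1
                lcs2 = np.where(ok_s, lcs, -1).copy()
                lcs2[b] = -1
                cand_scores = []
                if (lcp2 >= 1).any():
                    cand_scores.append(lcp2.max() + lcs[b])
                if (lcs2 >= 1).any():
                    cand_scores.append(lcp[a] + lcs2.max())
                if cand_scores and max(cand_scores) >= length:
                    u.chimera = True
    return out


def remove_chimeras(
    uniques: Sequence[UniqueSequence], parent_factor: float = 2.0
) -> tuple[list[UniqueSequence], list[UniqueSequence]]:
    """Flag chimeras, drop them, and re-rank/re-proportion the survivors.

    Returns ``(kept, flagged)``; proportions of the kept list are recomputed
    over the post-chimera read total, as chimeric reads are removed before
    the abundance threshold is applied.
    """
    flagged_all = flag_chimeras(uniques, parent_factor)
    kept_raw = [u for u in flagged_all if not u.chimera]
    flagged = [u for u in flagged_all if u.chimera]
    if not kept_raw:
        return [], flagged
    total = sum(u.count for u in kept_raw)
    kept_raw.sort(key=lambda u: (-u.count, u.bases))
    kept = [
        UniqueSequence(
            bases=u.bases,
            count=u.count,
            rank=i + 1,
            proportion=round_proportion(u.count, total),
        )
        for i, u in enumerate(kept_raw)
    ]
    if flagged:
        log.info("removed %d chimeric unique sequences", len(flagged))
    return kept, flagged


def write_uniques_tsv(uniques: Sequence[UniqueSequence], path: str | Path) -> None:
    total = sum(u.count for u in uniques)
    with open(path, "w") as fh:
        fh.write("rank\tcount\ttotal\tproportion\tchimera\tsequence\n")
        for u in uniques:
            fh.write(
                f"{u.rank}\t{u.count}\t{total}\t{u.proportion:.4f}\t"
                f"{int(u.chimera)}\t{u.bases}\n"
            )


def write_uniques_fasta(uniques: Sequence[UniqueSequence], path: str | Path) -> None:
    """Write uniques with ``TopR_count_total_proportion`` headers."""
    total = sum(u.count for u in uniques)
    with open(path, "w") as fh:
        for u in uniques:
            fh.write(f">Top{u.rank}_{u.count}_{total}_{u.proportion:.4f}\n{u.bases}\n")
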