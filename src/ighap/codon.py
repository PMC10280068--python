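"""Codon-level impact of exon SNPs and DNA -> exon -> protein collapse.

Exon SNPs are lifted through the alignment onto spliced coding coordinates,
classified as synonymous or nonsynonymous under the standard genetic code,
and haplotypes are collapsed at three levels: distinct genomic sequences,
distinct spliced exon (CDS) strings, and distinct translated proteins.  The
collapse is monotone (n_protein <= n_exon <= n_dna): splicing discards
intronic variation and synonymous changes discard silent exon variation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

from Bio.Data import CodonTable
from Bio.Seq import reverse_complement

from .genemodel import GeneModel
from .haplotypes import Alignment, HaplotypeSet

log = logging.getLogger(__name__)

_STANDARD = CodonTable.unambiguous_dna_by_id[1]


def translate(cds: str, frame: int = 0) -> str:
    """Translate a CDS under the standard genetic code (table 1).

    Reading starts at ``frame`` (0-2); a trailing partial codon is dropped.
    Stop codons are retained as '*' (internal stops are logged); any codon
    containing a non-ACGT symbol translates to 'X' with a warning.
    """
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    seq = cds.upper()[frame:]
    aas: list[str] = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        if codon in _STANDARD.stop_codons:
            aas.append("*")
        elif codon in _STANDARD.forward_table:
            aas.append(_STANDARD.forward_table[codon])
        else:
            log.warning("untranslatable codon %r -> X", codon)
            aas.append("X")
    protein = "".join(aas)
    if "*" in protein[:-1]:
        log.warning("internal stop codon in translation")
    return protein


@dataclass
class CodonChange:
    """A reference/alternate codon pair and its amino-acid effect."""

    site_index: int | None
    ref_codon: str
    alt_codon: str
    codon_offset: int
    ref_aa: str
    alt_aa: str
    effect: Literal["synonymous", "nonsynonymous"]


def codon_effect(
    ref_codon: str, alt_codon: str, site_index: int | None = None
) -> CodonChange:
    """Classify a codon substitution by translation equality.

    ``codon_offset`` is the first differing base (0-2); for codons differing
    at several positions the effect is still computed on the whole codons.
    """
    ref_codon, alt_codon = ref_codon.upper(), alt_codon.upper()
    if len(ref_codon) != 3 or len(alt_codon) != 3:
        raise ValueError("codons must be 3 bases long")
    if ref_codon == alt_codon:
        raise ValueError("codons are identical")
    offset = next(i for i in range(3) if ref_codon[i] != alt_codon[i])
    ref_aa = translate(ref_codon)
    alt_aa = translate(alt_codon)
    effect = "synonymous" if ref_aa == alt_aa else "nonsynonymous"
    return CodonChange(site_index, ref_codon, alt_codon, offset, ref_aa, alt_aa, effect)


def count_effects(changes: Sequence[CodonChange]) -> dict[str, int]:
    """Tally synonymous vs nonsynonymous changes."""
    out = {"synonymous": 0, "nonsynonymous": 0}
    for c in changes:
        out[c.effect] += 1
    return out


@dataclass
class SplicedCDS:
    cds: str | None
    boundary_deleted: bool = False
    frameshift: bool = False

    @property
    def usable(self) -> bool:
        return self.cds is not None and not self.boundary_deleted and not self.frameshift


def _exon_columns(alignment: Alignment, model: GeneModel) -> list[int]:
    """Alignment columns contributing to the spliced exon sequence.

    Reference columns whose coordinate lies in an exon, plus insertion
    columns whose left-flanking reference base lies strictly inside an exon.
    """
    cols: list[int] = []
    last_ref: int | None = None
    for c, p in enumerate(alignment.col_refpos):
        if p is not None:
            if model.region_of(p) == "exon":
                cols.append(c)
            last_ref = p
        else:
            if last_ref is not None:
                for s, e in model.exon_intervals:
                    if s <= last_ref < e - 1:
                        cols.append(c)
                        break
    return cols


def splice_exons(
    alignment: Alignment, row: int, model: GeneModel
) -> SplicedCDS:
    """Project one haplotype row onto the spliced exons of the gene model.

    Exon-projected bases are degapped and concatenated in feature order,
    reverse-complemented for '-' strand models.  A deletion that removes a
    splice boundary (first or last base of an exon) flags the haplotype for
    exclusion from codon analysis, as its splice structure is uncertain; a
    net exon indel that is not a multiple of 3 flags a frameshift.
    """
    rowstr = alignment.rows[row]
    refstr = alignment.rows[0]
    boundary = False
    for s, e in model.exon_intervals:
        for pos in (s, e - 1):
            try:
                c = alignment.col_of_refpos(pos)
            except ValueError:
                continue
            if rowstr[c] == "-":
                boundary = True
    cols = _exon_columns(alignment, model)
    plus = "".join(rowstr[c] for c in cols).replace("-", "")
    ref_plus = "".join(refstr[c] for c in cols).replace("-", "")
    cds = reverse_complement(plus) if model.strand == "-" else plus
    frameshift = (len(plus) - len(ref_plus)) % 3 != 0
    if boundary:
        log.warning("haplotype row %d: deletion removes a splice boundary", row)
    return SplicedCDS(cds=cds, boundary_deleted=boundary, frameshift=frameshift)


def codon_changes(
    alignment: Alignment,
    model: GeneModel,
    valid_mask: Sequence[bool] | None = None,
) -> list[CodonChange]:
    """Codon changes at variable exon sites among valid haplotypes.

    Each variable exon column yields one change per observed non-reference
    base, with the reference codon read from the rank-1 spliced CDS and the
    alternate codon substituted at the affected base.  Site indices are
    sequential (1-based) over variable exon sites, reported in splice order.
    """
    n = len(alignment.rows)
    if valid_mask is None:
        valid_mask = [True] * n
    rows_idx = [i for i in range(n) if valid_mask[i]]
    cols = _exon_columns(alignment, model)
    refstr = alignment.rows[0]
    plus_ref = "".join(refstr[c] for c in cols)
    # plus-strand spliced offset of each (reference-base) exon column
    offsets: dict[int, int] = {}
    o = 0
    for c in cols:
        if refstr[c] != "-":
            offsets[c] = o
            o += 1
    L = o
    frame = model.frame
    changes: list[CodonChange] = []
    site = 0
    for c in cols:
        if c not in offsets:
            continue
        bases = {alignment.rows[i][c] for i in rows_idx} & set("ACGT")
        ref_base = refstr[c]
        alts = sorted(bases - {ref_base})
        if not alts or ref_base not in "ACGT":
            continue
        site += 1
        for alt_base in alts:
            if model.strand == "-":
                off = L - 1 - offsets[c]
                rbase = reverse_complement(ref_base)
                abase = reverse_complement(alt_base)
                cds_ref = reverse_complement(plus_ref.replace("-", ""))
            else:
                off = offsets[c]
                rbase, abase = ref_base, alt_base
                cds_ref = plus_ref.replace("-", "")
            if off < frame or (off - frame) // 3 * 3 + frame + 3 > len(cds_ref):
                continue  # outside complete codons of the read frame
            k = (off - frame) // 3
            codon_start = frame + 3 * k
            ref_codon = cds_ref[codon_start : codon_start + 3]
            pos_in_codon = off - codon_start
            alt_codon = (
                ref_codon[:pos_in_codon] + abase + ref_codon[pos_in_codon + 1 :]
            )
            assert ref_codon[pos_in_codon] == rbase
            changes.append(codon_effect(ref_codon, alt_codon, site_index=site))
    return changes


@dataclass
class CollapseSummary:
    """Distinct-haplotype counts at genomic DNA, spliced exon and protein level."""

    n_dna_haplotypes: int
    n_exon_haplotypes: int
    n_protein_haplotypes: int
    n_excluded: int = 0


def collapse_levels(hset: HaplotypeSet, model: GeneModel) -> CollapseSummary:
    """Collapse valid haplotypes at DNA -> exon -> protein levels.

    Haplotypes whose indels disrupt the splice structure or reading frame
    are excluded from the exon and protein counts and reported separately.
    """
    valid = [i for i, e in enumerate(hset.entries) if e.valid]
    n_dna = len({hset.entries[i].sequence for i in valid})
    assert hset.alignment is not None
    spliced = {i: splice_exons(hset.alignment, i, model) for i in valid}
    usable = [i for i in valid if spliced[i].usable]
    n_excluded = len(valid) - len(usable)
    cds_set = {spliced[i].cds for i in usable}
    prot_set = {translate(spliced[i].cds, model.frame) for i in usable}  # type: ignore[arg-type]
    return CollapseSummary(
        n_dna_haplotypes=n_dna,
        n_exon_haplotypes=len(cds_set),
        n_protein_haplotypes=len(prot_set),
        n_excluded=n_excluded,
    )


def write_codon_tsv(changes: Sequence[CodonChange], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("site\tref_codon\talt_codon\tref_aa\talt_aa\teffect\tcodon_offset\n")
        for c in changes:
            fh.write(
                f"{c.site_index or '.'}\t{c.ref_codon}\t{c.alt_codon}\t"
                f"{c.ref_aa}\t{c.alt_aa}\t{c.effect}\t{c.codon_offset}\n"
            )
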