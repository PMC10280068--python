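"""SNP site calling, classification and region-partitioned diversity stats.

Sites are called over the star alignment of valid haplotypes.  Substitution
columns are classified as transitions (A/G, T/C), transversions (A/T, A/C,
G/T, G/C) or multiallelic; maximal gap runs affecting the same haplotype
subset collapse into a single indel site, so an extended deletion counts as
one event.  The total SNP count is the sum of transitions, transversions
and indel sites.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Literal, Sequence

from .genemodel import GeneModel
from .haplotypes import Alignment

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

TRANSITION_PAIRS = (("A", "G"), ("C", "T"))
TRANSVERSION_PAIRS = (("A", "C"), ("A", "T"), ("C", "G"), ("G", "T"))
ALL_PAIRS = TRANSITION_PAIRS + TRANSVERSION_PAIRS

SiteClass = Literal["transition", "transversion", "multiallelic", "indel"]


def classify_substitution(a: str, b: str) -> Literal["transition", "transversion"]:
    """Classify an unordered base substitution.

    Purine<->purine or pyrimidine<->pyrimidine is a transition; any
    purine<->pyrimidine exchange is a transversion.  Symmetric in (a, b).
    """
    a, b = a.upper(), b.upper()
    if a == b:
        raise ValueError("substitution requires two different bases")
    for x in (a, b):
        if x not in PURINES | PYRIMIDINES:
            raise ValueError(f"not a DNA base: {x!r}")
    same_family = (a in PURINES) == (b in PURINES)
    return "transition" if same_family else "transversion"


@dataclass
class SNPSite:
    """One polymorphic event over the aligned haplotypes.

    ``column`` is the (first) alignment column; ``locus_pos`` the reference
    coordinate, ``None`` for insertion events, which carry the coordinate of
    the flanking reference base to the left in ``left_flank_pos``.
    """

    column: int
    locus_pos: int | None
    site_class: SiteClass
    alleles: dict[str, str]
    ref_allele: str
    region: Literal["exon", "intron"] | None = None
    left_flank_pos: int | None = None
    run_length: int = 1  # collapsed columns for indel events

    @property
    def observed_bases(self) -> set[str]:
        return {a for a in self.alleles.values() if a in "ACGT"}


def call_snp_sites(
    alignment: Alignment,
    valid_mask: Sequence[bool] | None = None,
    ids: Sequence[str] | None = None,
) -> list[SNPSite]:
    """Call polymorphic sites over the valid rows of an alignment.

    Every column with >= 2 distinct base symbols among valid rows yields a
    substitution site; maximal runs of consecutive gap columns carried by
    the same haplotype subset collapse into one indel site each (runs shared
    partially by different haplotypes split at subset-change boundaries).
    Fewer than two valid rows yield an empty list.
    """
    n_rows = len(alignment.rows)
    if valid_mask is None:
        valid_mask = [True] * n_rows
    if ids is None:
        ids = [f"H{i + 1}" for i in range(n_rows)]
    rows_idx = [i for i in range(n_rows) if valid_mask[i]]
    if len(rows_idx) < 2:
        import logging

        logging.getLogger(__name__).warning(
            "fewer than 2 valid haplotypes; no SNP sites called"
        )
        return []
    rows = {i: alignment.rows[i] for i in rows_idx}
    ref_row = alignment.rows[0]
    sites: list[SNPSite] = []

    def alleles_at(col: int) -> dict[str, str]:
        return {ids[i]: rows[i][col] for i in rows_idx}

    # substitution sites (per column, gaps ignored for base comparison)
    for c in range(alignment.n_columns):
        symbols = {rows[i][c] for i in rows_idx}
        bases = symbols & set("ACGT")
        if len(bases) >= 2:
            if len(bases) == 2:
                cls: SiteClass = classify_substitution(*sorted(bases))
            else:
                cls = "multiallelic"
            sites.append(
                SNPSite(
                    column=c,
                    locus_pos=alignment.col_refpos[c],
                    site_class=cls,
                    alleles=alleles_at(c),
                    ref_allele=ref_row[c],
                    left_flank_pos=_left_flank(alignment, c),
                )
            )

    # deletion events: gap runs over reference columns
    runs: list[tuple[int, int, frozenset[int]]] = []  # (start col, length, subset)
    prev_subset: frozenset[int] = frozenset()
    prev_refpos = None
    for c in range(alignment.n_columns):
        p = alignment.col_refpos[c]
        if p is None:
            continue
        subset = frozenset(i for i in rows_idx if rows[i][c] == "-")
        if subset and subset == prev_subset and prev_refpos == p - 1 and runs:
            s, ln, ss = runs[-1]
            runs[-1] = (s, ln + 1, ss)
        elif subset:
            runs.append((c, 1, subset))
        prev_subset = subset
        prev_refpos = p
    for start_col, length, _subset in runs:
        sites.append(
            SNPSite(
                column=start_col,
                locus_pos=alignment.col_refpos[start_col],
                site_class="indel",
                alleles=alleles_at(start_col),
                ref_allele=ref_row[start_col],
                left_flank_pos=_left_flank(alignment, start_col),
                run_length=length,
            )
        )

    # insertion events: runs over insertion columns, subset = rows with bases
    ins_runs: list[tuple[int, int, frozenset[int]]] = []
    prev_subset = frozenset()
    prev_col = -2
    for c in range(alignment.n_columns):
        if alignment.col_refpos[c] is not None:
            prev_col = -2
            continue
        subset = frozenset(i for i in rows_idx if rows[i][c] != "-")
        if subset and subset == prev_subset and c == prev_col + 1 and ins_runs:
            s, ln, ss = ins_runs[-1]
            ins_runs[-1] = (s, ln + 1, ss)
        elif subset:
            ins_runs.append((c, 1, subset))
        prev_subset = subset
        prev_col = c
    for start_col, length, _subset in ins_runs:
        sites.append(
            SNPSite(
                column=start_col,
                locus_pos=None,
                site_class="indel",
                alleles=alleles_at(start_col),
                ref_allele="-",
                left_flank_pos=_left_flank(alignment, start_col),
                run_length=length,
            )
        )

    sites.sort(key=lambda s: (s.column, s.site_class))
    return sites


def _left_flank(alignment: Alignment, col: int) -> int | None:
    """Reference coordinate of the nearest reference base at or left of col."""
    for c in range(col, -1, -1):
        p = alignment.col_refpos[c]
        if p is not None:
            return p
    return None


def snp_density(sites: Sequence[SNPSite], span_bases: int) -> float:
    """SNP sites per kilobase of ungapped reference span."""
    if span_bases <= 0:
        raise ValueError("span_bases must be positive")
    return len(sites) / span_bases * 1000.0


def partition_by_region(
    sites: Sequence[SNPSite], model: GeneModel
) -> dict[str, int]:
    """Assign each site to exon or intron; returns exhaustive counts.

    Substitution and deletion sites use their reference coordinate (half-open
    feature convention); insertion events take the region of the flanking
    reference base to the left (the model's first feature if inserted before
    position 0).  Also fills each site's ``region`` in place.
    """
    counts = {"exon": 0, "intron": 0}
    for site in sites:
        pos = site.locus_pos if site.locus_pos is not None else site.left_flank_pos
        if pos is None:
            region = model.features[0].kind
        else:
            region = model.region_of(pos)
        site.region = region
        counts[region] += 1
    return counts


def region_densities(
    sites: Sequence[SNPSite], model: GeneModel
) -> dict[str, float]:
    """Per-region SNP density (sites/kb of that region's reference length)."""
    counts = partition_by_region(sites, model)
    out = {}
    for region in ("exon", "intron"):
        span = model.region_length(region)  # type: ignore[arg-type]
        out[region] = counts[region] / span * 1000.0 if span else 0.0
    return out


@dataclass
class TsTvSummary:
    pair_counts: dict[tuple[str, str], int]
    proportions: dict[tuple[str, str], float]
    n_transitions: int
    n_transversions: int
    ratio: float
    infinite: bool = False


def tstv_summary(sites: Sequence[SNPSite]) -> TsTvSummary:
    """Spectrum over the six unordered substitution types, excluding indels.

    Biallelic sites contribute their pair once; a multiallelic site
    contributes each observed unordered allele pair once.  Proportions sum
    to 1 over all counted pairs; the Ts/Tv ratio is transitions over
    transversions, reported as infinite (with a flag) when no transversion
    was observed.
    """
    pair_counts = {p: 0 for p in ALL_PAIRS}
    any_sub = False
    for site in sites:
        if site.site_class == "indel":
            continue
        any_sub = True
        for a, b in combinations(sorted(site.observed_bases), 2):
            pair_counts[(a, b)] += 1
    if not any_sub:
        raise ValueError("no substitution sites to summarize")
    ts = sum(pair_counts[p] for p in TRANSITION_PAIRS)
    tv = sum(pair_counts[p] for p in TRANSVERSION_PAIRS)
    total = ts + tv
    proportions = {p: c / total for p, c in pair_counts.items()}
    infinite = tv == 0
    ratio = float("inf") if infinite else ts / tv
    return TsTvSummary(
        pair_counts=pair_counts,
        proportions=proportions,
        n_transitions=ts,
        n_transversions=tv,
        ratio=ratio,
        infinite=infinite,
    )


def write_snp_tsv(sites: Sequence[SNPSite], path: str | Path) -> None:
    """Human-readable SNP table (1-based reference coordinates)."""
    hids: list[str] = sorted(
        {h for s in sites for h in s.alleles}, key=lambda h: (len(h), h)
    )
    with open(path, "w") as fh:
        fh.write("column\tlocus_pos\tregion\tclass\t" + "\t".join(hids) + "\n")
        for s in sites:
            pos = "." if s.locus_pos is None else str(s.locus_pos + 1)
            row = "\t".join(s.alleles.get(h, ".") for h in hids)
            fh.write(f"{s.column + 1}\t{pos}\t{s.region or '.'}\t{s.site_class}\t{row}\n")


def write_vcf(
    sites: Sequence[SNPSite], locus_id: str, path: str | Path
) -> None:
    """Minimal VCF-flavored export of the called sites."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={locus_id}>\n")
        fh.write('##INFO=<ID=REGION,Number=1,Type=String,Description="Gene region">\n')
        fh.write('##INFO=<ID=CLASS,Number=1,Type=String,Description="Site class">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in sites:
            pos = s.locus_pos if s.locus_pos is not None else s.left_flank_pos
            pos1 = 1 if pos is None else pos + 1
            if s.site_class == "indel":
                ref, alt = (s.ref_allele if s.ref_allele != "-" else "N"), "<DEL>"
                if s.ref_allele == "-":
                    alt = "<INS>"
            else:
                ref = s.ref_allele
                alts = sorted(s.observed_bases - {ref})
                alt = ",".join(alts) if alts else "."
            info = f"REGION={s.region or '.'};CLASS={s.site_class}"
            fh.write(f"{locus_id}\t{pos1}\t.\t{ref}\t{alt}\t.\tPASS\t{info}\n")


def summary_dict(
    sites: Sequence[SNPSite], model: GeneModel, span_bases: int
) -> dict:
    """Machine-readable roll-up: densities, Ts/Tv, per-region counts."""
    counts = partition_by_region(sites, model)
    n_sub = sum(1 for s in sites if s.site_class != "indel")
    n_indel = len(sites) - n_sub
    out = {
        "n_sites": len(sites),
        "n_substitutions": n_sub,
        "n_indels": n_indel,
        "snp_density_per_kb": snp_density(sites, span_bases),
        "region_counts": counts,
        "region_densities_per_kb": region_densities(sites, model),
    }
    if n_sub:
        ts = tstv_summary(sites)
        out["tstv"] = {
            "n_transitions": ts.n_transitions,
            "n_transversions": ts.n_transversions,
            "ratio": None if ts.infinite else ts.ratio,
            "infinite": ts.infinite,
            "proportions": {f"{a}/{b}": v for (a, b), v in ts.proportions.items()},
        }
    return out
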