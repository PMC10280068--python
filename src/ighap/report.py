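"""End-to-end pipeline orchestration: QC -> haplotypes -> SNPs -> codons.

All randomness lives in the simulator; every analysis stage here is
deterministic, so identical inputs and configuration produce a
byte-identical report bundle.  Errors propagate with stage-labelled
messages and every applied threshold is logged, making a run auditable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import yaml

from . import codon as codon_mod
from . import haplotypes as hap_mod
from . import readqc, snpstats
from .genemodel import GeneModel
from .readqc import AmpliconRead

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one analysis run."""

    primer_fwd: str
    primer_rev: str
    fastq: str | None = None
    gene_model_path: str | None = None
    mode: Literal["tissue", "single_cell"] = "tissue"
    min_prop: float = 0.01
    top_n: int = 10
    q_min: int = 20
    trim_both_ends: bool = False
    chimera_factor: float = 2.0
    curve_windows: list[int] | None = None
    outdir: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("tissue", "single_cell"):
            raise ValueError(f"mode must be tissue or single_cell, got {self.mode!r}")
        if not 0.0 <= self.min_prop < 1.0:
            raise ValueError("min_prop must be in [0, 1)")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if self.q_min < 0:
            raise ValueError("q_min must be >= 0")
        if self.chimera_factor < 1.0:
            raise ValueError("chimera_factor must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)


def run_pipeline(
    cfg: RunConfig,
    reads: Sequence[AmpliconRead] | None = None,
    gene_model: GeneModel | None = None,
) -> dict:
    """Run QC, haplotype calling, SNP statistics and codon analysis.

    ``reads`` and ``gene_model`` may be given in memory; otherwise they are
    loaded from ``cfg.fastq`` / ``cfg.gene_model_path``.  Returns the summary
    dict and, when ``cfg.outdir`` is set, writes all module outputs there.
    """
    logging.basicConfig(level=cfg.log_level)

    # -- readqc -------------------------------------------------------------
    try:
        if reads is None:
            if cfg.fastq is None:
                raise ValueError("no reads given and cfg.fastq unset")
            reads = list(readqc.read_fastq(cfg.fastq))
        reads = list(reads)
        n_raw = len(reads)
        if n_raw == 0:
            raise ValueError("input contains no reads")
        log.info("readqc: q_min=%d trim_both_ends=%s", cfg.q_min, cfg.trim_both_ends)
        trimmed = [
            readqc.quality_trim(r, cfg.q_min, cfg.trim_both_ends) for r in reads
        ]
        trimmed = [r for r in trimmed if len(r) > 0]
        inserts = []
        for r in trimmed:
            ins = readqc.match_primers(r, cfg.primer_fwd, cfg.primer_rev)
            if ins is not None:
                inserts.append(ins)
        if not inserts:
            raise ValueError("no reads survive primer matching")
        uniques_raw = readqc.dereplicate(inserts)
        kept, flagged = readqc.remove_chimeras(uniques_raw, cfg.chimera_factor)
        n_post_chimera = sum(u.count for u in kept)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("readqc", str(exc)) from exc

    # -- haplotypes ---------------------------------------------------------
    try:
        log.info("haplotypes: mode=%s min_prop=%g top_n=%d",
                 cfg.mode, cfg.min_prop, cfg.top_n)
        if cfg.mode == "tissue":
            hset = hap_mod.call_tissue_haplotypes(kept, cfg.min_prop)
        else:
            hset = hap_mod.call_single_cell_haplotypes(kept, cfg.top_n, cfg.min_prop)
        tree = hap_mod.nj_tree(hset) if len(hset.entries) >= 2 else None
        curve = None
        if cfg.curve_windows:
            curve = hap_mod.haplotype_length_curve(
                inserts, cfg.curve_windows, cfg.min_prop
            )
    except Exception as exc:
        raise PipelineError("haplotypes", str(exc)) from exc

    # -- snpstats -----------------------------------------------------------
    model = gene_model
    snp_summary = None
    sites: list[snpstats.SNPSite] = []
    try:
        if model is None and cfg.gene_model_path:
            p = cfg.gene_model_path
            model = (
                GeneModel.from_gff3(p)
                if str(p).endswith((".gff", ".gff3"))
                else GeneModel.from_tsv(p)
            )
        if model is not None and hset.entries:
            span = len(hset.entries[0].sequence)
            if model.length != span:
                raise ValueError(
                    f"gene model length {model.length} != reference span {span}"
                )
            if len(hset.valid_entries()) >= 2 and hset.alignment is not None:
                sites = snpstats.call_snp_sites(
                    hset.alignment,
                    hset.valid_mask(),
                    ids=[e.haplotype_id for e in hset.entries],
                )
                snp_summary = snpstats.summary_dict(sites, model, span)
    except Exception as exc:
        raise PipelineError("snpstats", str(exc)) from exc

    # -- codon --------------------------------------------------------------
    codon_summary = None
    changes: list[codon_mod.CodonChange] = []
    try:
        if model is not None and hset.alignment is not None and hset.valid_entries():
            changes = codon_mod.codon_changes(
                hset.alignment, model, hset.valid_mask()
            )
            collapse = codon_mod.collapse_levels(hset, model)
            codon_summary = {
                "effects": codon_mod.count_effects(changes),
                "collapse": {
                    "n_dna_haplotypes": collapse.n_dna_haplotypes,
                    "n_exon_haplotypes": collapse.n_exon_haplotypes,
                    "n_protein_haplotypes": collapse.n_protein_haplotypes,
                    "n_excluded": collapse.n_excluded,
                },
            }
    except Exception as exc:
        raise PipelineError("codon", str(exc)) from exc

    summary = {
        "config": {
            "mode": cfg.mode,
            "min_prop": cfg.min_prop,
            "top_n": cfg.top_n,
            "q_min": cfg.q_min,
            "chimera_factor": cfg.chimera_factor,
            "seed": cfg.seed,
        },
        "read_counts": {
            "raw": n_raw,
            "trimmed_nonempty": len(trimmed),
            "primer_matched": len(inserts),
            "post_chimera": n_post_chimera,
        },
        "n_unique": len(uniques_raw),
        "n_chimera_flagged": len(flagged),
        "haplotypes": [
            {
                "id": e.haplotype_id,
                "count": e.count,
                "proportion": e.proportion,
                "valid": e.valid,
                "error_flag": e.error_flag,
            }
            for e in hset.entries
        ],
        "snp": snp_summary,
        "codon": codon_summary,
    }
    if curve is not None:
        summary["haplotype_length_curve"] = [
            {"length": l, "n_distinct": d, "n_haplotypes": h} for l, d, h in curve
        ]

    if cfg.outdir:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        readqc.write_uniques_tsv(kept, out / "uniques.tsv")
        readqc.write_uniques_fasta(kept, out / "uniques.fasta")
        hap_mod.write_haplotypes_fasta(hset, out / "haplotypes.fasta")
        if hset.alignment is not None:
            hap_mod.write_aligned_fasta(hset, out / "aligned.fasta")
        if tree is not None:
            (out / "tree.nwk").write_text(tree + "\n")
        if sites and model is not None:
            snpstats.write_snp_tsv(sites, out / "snps.tsv")
            snpstats.write_vcf(sites, model.locus_id, out / "snps.vcf")
        if changes:
            codon_mod.write_codon_tsv(changes, out / "codon_changes.tsv")
        if curve is not None:
            with open(out / "curve.tsv", "w") as fh:
                fh.write("length\tn_distinct\tn_haplotypes\n")
                for l, d, h in curve:
                    fh.write(f"{l}\t{d}\t{h}\n")
        (out / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n"
        )
    return summary
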