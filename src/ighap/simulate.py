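"""Synthetic mosaic-population amplicon read simulator.

Emulates the read structure produced by deep amplicon sequencing of a locus
in a genetically heterogeneous (mosaic) tissue: a mixture of K true
haplotypes at fixed frequencies, each haplotype carrying Poisson-distributed
substitutions at region-specific rates (denser in introns than exons), with
transition-biased substitutions, single-base deletions confined to introns,
i.i.d. per-base sequencing error, and optional two-parent PCR chimeras.
Reads are emitted already merged (one FASTQ record per molecule) with both
primers attached, plus a machine-readable truth table for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import yaml
from Bio.Seq import reverse_complement

from .genemodel import GeneModel
from .readqc import AmpliconRead

_BASES = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}


@dataclass
class SimulationConfig:
    """Study conditions for one simulated amplicon run.

    Defaults model a deep single-locus run: a 300 bp insert with two exons
    flanking one intron, five haplotypes at fixed frequencies, intron
    substitution density four times the exon density, a 2:1 transition bias,
    rare intron-only single-base deletions, depth 20,000 and a 0.2% per-base
    error rate.
    """

    locus_length: int = 300
    exon_intervals: list[tuple[int, int]] = field(
        default_factory=lambda: [(0, 100), (200, 300)]
    )
    n_haplotypes: int = 5
    haplotype_freqs: tuple[float, ...] = (0.40, 0.30, 0.15, 0.10, 0.05)
    snp_rate_exon: float = 0.005
    snp_rate_intron: float = 0.02
    tstv_kappa: float = 2.0
    indel_rate_intron: float = 0.001
    read_depth: int = 20_000
    per_base_error: float = 0.002
    chimera_rate: float = 0.01
    primer_fwd: str = "GTAGCTAGGATTCACGCTAG"
    primer_rev: str = "CATGGTACGATCCTTGACGA"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_haplotypes < 1:
            raise ValueError("n_haplotypes must be >= 1")
        if len(self.haplotype_freqs) != self.n_haplotypes:
            raise ValueError("haplotype_freqs length must equal n_haplotypes")
        if abs(sum(self.haplotype_freqs) - 1.0) > 1e-9:
            raise ValueError("haplotype_freqs must sum to 1 within 1e-9")
        for name in ("snp_rate_exon", "snp_rate_intron", "indel_rate_intron",
                     "per_base_error", "chimera_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        ivs = sorted(self.exon_intervals)
        prev_end = 0
        for s, e in ivs:
            if not (0 <= s < e <= self.locus_length) or s < prev_end:
                raise ValueError("exon_intervals must be sorted, non-overlapping "
                                 "and within the locus")
            prev_end = e
        self.exon_intervals = [tuple(iv) for iv in ivs]

    @property
    def gene_model(self) -> GeneModel:
        return GeneModel.from_exon_intervals(
            list(self.exon_intervals), self.locus_length
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "exon_intervals" in raw:
            raw["exon_intervals"] = [tuple(iv) for iv in raw["exon_intervals"]]
        if "haplotype_freqs" in raw:
            raw["haplotype_freqs"] = tuple(raw["haplotype_freqs"])
        return cls(**raw)


@dataclass(frozen=True)
class MutationEvent:
    pos: int  # reference (locus) coordinate, 0-based
    ref: str
    alt: str  # '-' for a deletion
    mclass: Literal["transition", "transversion", "deletion"]
    region: Literal["exon", "intron"]


@dataclass
class TruthHaplotype:
    haplotype_id: str
    sequence: str
    frequency: float
    events: list[MutationEvent]


@dataclass
class TruthTable:
    """Ground truth for one simulated population: id -> haplotype."""

    reference: str
    entries: dict[str, TruthHaplotype]

    def sequences(self) -> list[str]:
        return [h.sequence for h in self.entries.values()]

    def frequencies(self) -> dict[str, float]:
        return {hid: h.frequency for hid, h in self.entries.items()}

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("haplotype_id\tfrequency\tsequence\tevents\n")
            for h in self.entries.values():
                ev = ";".join(
                    f"{e.pos}:{e.ref}>{e.alt}:{e.mclass}:{e.region}" for e in h.events
                )
                fh.write(f"{h.haplotype_id}\t{h.frequency}\t{h.sequence}\t{ev}\n")


def random_reference(length: int, rng: np.random.Generator) -> str:
    """A uniform-random DNA reference of the given length."""
    return "".join(rng.choice(list(_BASES), size=length))


def _mutate(reference: str, subs: dict[int, str], dels: set[int]) -> str:
    out = []
    for i, b in enumerate(reference):
        if i in dels:
            continue
        out.append(subs.get(i, b))
    return "".join(out)


def spawn_haplotypes(
    reference: str,
    gene_model: GeneModel,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> TruthTable:
    """Draw the true haplotype population.

    Haplotype H1 is the unmutated reference.  Every other haplotype carries
    Poisson(rate x region length) substitutions per region; a substitution is
    a transition with probability kappa/(kappa+1), otherwise one of the two
    transversion partners uniformly.  Single-base deletions are drawn only in
    introns.  Every event is recorded in the truth table.
    """
    if len(reference) != cfg.locus_length:
        raise ValueError("reference length must equal cfg.locus_length")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    exon_pos = np.array(gene_model.positions("exon"), dtype=int)
    intron_pos = np.array(gene_model.positions("intron"), dtype=int)
    p_ts = cfg.tstv_kappa / (cfg.tstv_kappa + 1.0)

    def draw_one() -> tuple[str, list[MutationEvent]]:
        subs: dict[int, str] = {}
        dels: set[int] = set()
        events: list[MutationEvent] = []
        for region, pool, rate in (
            ("exon", exon_pos, cfg.snp_rate_exon),
            ("intron", intron_pos, cfg.snp_rate_intron),
        ):
            if pool.size == 0 or rate == 0:
                continue
            n = min(int(rng.poisson(rate * pool.size)), pool.size)
            if n == 0:
                continue
            positions = rng.choice(pool, size=n, replace=False)
            for pos in sorted(int(p) for p in positions):
                ref_base = reference[pos]
                if rng.random() < p_ts:
                    alt, mclass = _TRANSITION[ref_base], "transition"
                else:
                    alt = _TRANSVERSIONS[ref_base][rng.integers(2)]
                    mclass = "transversion"
                subs[pos] = alt
                events.append(MutationEvent(pos, ref_base, alt, mclass, region))
        if intron_pos.size and cfg.indel_rate_intron > 0:
            avail = np.array([p for p in intron_pos if p not in subs], dtype=int)
            n = min(int(rng.poisson(cfg.indel_rate_intron * intron_pos.size)),
                    avail.size)
            if n:
                for pos in sorted(int(p) for p in rng.choice(avail, size=n, replace=False)):
                    dels.add(pos)
                    events.append(
                        MutationEvent(pos, reference[pos], "-", "deletion", "intron")
                    )
        events.sort(key=lambda e: e.pos)
        return _mutate(reference, subs, dels), events

    entries: dict[str, TruthHaplotype] = {
        "H1": TruthHaplotype("H1", reference, cfg.haplotype_freqs[0], [])
    }
    seen = {reference}
    for k in range(2, cfg.n_haplotypes + 1):
        # the population consists of K *distinct* haplotypes: redraw the
        # (rare) event sets that leave a haplotype identical to another
        for _ in range(1000):
            seq, events = draw_one()
            if seq not in seen:
                break
        else:
            raise RuntimeError(
                "could not draw distinct haplotypes; mutation rates too low "
                "for the requested K"
            )
        seen.add(seq)
        hid = f"H{k}"
        entries[hid] = TruthHaplotype(hid, seq, cfg.haplotype_freqs[k - 1], events)
    return TruthTable(reference=reference, entries=entries)


def _phred_char(error: float) -> str:
    q = 40 if error <= 0 else min(40, round(-10.0 * math.log10(error)))
    return chr(q + 33)


def _apply_errors(
    seqs: list[str], error: float, rng: np.random.Generator
) -> list[str]:
    """I.i.d. per-base substitution errors, uniform among the 3 alternatives."""
    if error <= 0 or not seqs:
        return seqs
    code = {ord(b): i for i, b in enumerate(_BASES)}
    out: list[str] = []
    # group by length so each batch is a rectangular matrix
    by_len: dict[int, list[int]] = {}
    for i, s in enumerate(seqs):
        by_len.setdefault(len(s), []).append(i)
    out = [""] * len(seqs)
    lut = np.zeros(256, dtype=np.uint8)
    for b, i in code.items():
        lut[b] = i
    rev = np.frombuffer(_BASES.encode(), dtype=np.uint8)
    for L, idxs in by_len.items():
        mat = np.vstack([
            lut[np.frombuffer(seqs[i].encode(), dtype=np.uint8)] for i in idxs
        ])
        for start in range(0, len(idxs), 4096):
            chunk = mat[start : start + 4096]
            mask = rng.random(chunk.shape) < error
            n_err = int(mask.sum())
            if n_err:
                shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
                chunk[mask] = (chunk[mask] + shift) % 4
        for row, i in zip(mat, idxs):
            out[i] = rev[row].tobytes().decode()
    return out


def simulate_reads(
    truth: TruthTable,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[AmpliconRead]:
    """Sample the read pool: primered inserts with errors and chimeras.

    Each read is ``primer_fwd + insert + reverse_complement(primer_rev)``
    where the insert is a haplotype drawn multinomially by frequency, or —
    with probability ``chimera_rate`` — a two-parent splice at a uniform
    breakpoint.  Per-base errors are i.i.d. uniform among the three
    alternative bases; qualities are the flat Phred encoding of the error
    rate.  Same config and seed give a byte-identical read list.
    """
    if not cfg.primer_fwd or not cfg.primer_rev:
        raise ValueError("primers must be non-empty")
    if cfg.read_depth < 1:
        raise ValueError("read_depth must be >= 1")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    hids = list(truth.entries)
    seqs = {hid: truth.entries[hid].sequence for hid in hids}
    freqs = np.array([truth.entries[hid].frequency for hid in hids])
    freqs = freqs / freqs.sum()
    N = cfg.read_depth

    n_chim = (
        int(rng.binomial(N, cfg.chimera_rate))
        if cfg.chimera_rate > 0 and len(hids) >= 2
        else 0
    )
    counts = rng.multinomial(N - n_chim, freqs)

    inserts: list[str] = []
    labels: list[str] = []
    for hid, c in zip(hids, counts):
        inserts.extend([seqs[hid]] * int(c))
        labels.extend([hid] * int(c))
    for _ in range(n_chim):
        a, b = rng.choice(len(hids), size=2, replace=False)
        sa, sb = seqs[hids[a]], seqs[hids[b]]
        lim = min(len(sa), len(sb))
        bp = int(rng.integers(1, lim)) if lim > 1 else 1
        inserts.append(sa[:bp] + sb[bp:])
        labels.append(f"chimera_{hids[a]}_{hids[b]}_{bp}")

    rc_rev = reverse_complement(cfg.primer_rev)
    raw = [cfg.primer_fwd + ins + rc_rev for ins in inserts]
    order = rng.permutation(len(raw))
    raw = [raw[i] for i in order]
    labels = [labels[i] for i in order]
    raw = _apply_errors(raw, cfg.per_base_error, rng)

    qchar = _phred_char(cfg.per_base_error)
    q = ord(qchar) - 33
    return [
        AmpliconRead(id=f"read_{i:06d}_{lab}", bases=s, quals=[q] * len(s))
        for i, (s, lab) in enumerate(zip(raw, labels))
    ]


def write_fastq(reads: Sequence[AmpliconRead], path: str | Path) -> None:
    """Write reads as Sanger Phred+33 FASTQ."""
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.quals)
            fh.write(f"@{r.id}\n{r.bases}\n+\n{qual}\n")


def simulate_run(
    cfg: SimulationConfig, reference: str | None = None
) -> tuple[TruthTable, list[AmpliconRead]]:
    """Convenience wrapper: reference (random if not given) -> truth -> reads."""
    rng = np.random.default_rng(cfg.seed)
    if reference is None:
        reference = random_reference(cfg.locus_length, rng)
    truth = spawn_haplotypes(reference, cfg.gene_model, cfg, rng)
    reads = simulate_reads(truth, cfg, rng)
    return truth, reads
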