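"""Exon/intron gene model for a sequenced locus.

Coordinates are 0-based half-open on the locus (the amplicon reference);
human-readable reports convert to 1-based.  The model is typically supplied
from an ortholog's annotation, either as a simple interval TSV or as GFF3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

Region = Literal["exon", "intron"]


@dataclass(frozen=True)
class Feature:
    kind: Region
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.kind not in ("exon", "intron"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class GeneModel:
    """Ordered exon/intron features tiling a locus, with strand and frame."""

    locus_id: str
    features: list[Feature]
    strand: Literal["+", "-"] = "+"
    frame: int = 0

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.frame not in (0, 1, 2):
            raise ValueError("frame must be 0, 1 or 2")
        if not self.features:
            raise ValueError("gene model needs at least one feature")
        self.features = sorted(self.features, key=lambda f: f.start)
        pos = self.features[0].start
        for f in self.features:
            if f.start != pos:
                raise ValueError("features must tile the locus without gaps/overlap")
            pos = f.end

    @property
    def span(self) -> tuple[int, int]:
        return self.features[0].start, self.features[-1].end

    @property
    def length(self) -> int:
        s, e = self.span
        return e - s

    def region_of(self, pos: int) -> Region:
        """Region of a locus coordinate (half-open convention: a feature's
        start coordinate belongs to that feature)."""
        for f in self.features:
            if f.start <= pos < f.end:
                return f.kind
        raise ValueError(f"position {pos} outside model span {self.span}")

    def positions(self, kind: Region) -> list[int]:
        return [p for f in self.features if f.kind == kind for p in range(f.start, f.end)]

    def region_length(self, kind: Region) -> int:
        return sum(len(f) for f in self.features if f.kind == kind)

    @property
    def exon_intervals(self) -> list[tuple[int, int]]:
        return [(f.start, f.end) for f in self.features if f.kind == "exon"]

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_exon_intervals(
        cls,
        exons: list[tuple[int, int]],
        locus_length: int,
        locus_id: str = "locus",
        strand: Literal["+", "-"] = "+",
        frame: int = 0,
    ) -> "GeneModel":
        """Build a model from exon intervals; gaps become introns."""
        exons = sorted(exons)
        feats: list[Feature] = []
        pos = 0
        for s, e in exons:
            if not 0 <= s < e <= locus_length:
                raise ValueError(f"exon [{s},{e}) outside locus [0,{locus_length})")
            if s < pos:
                raise ValueError("exon intervals overlap")
            if s > pos:
                feats.append(Feature("intron", pos, s))
            feats.append(Feature("exon", s, e))
            pos = e
        if pos < locus_length:
            feats.append(Feature("intron", pos, locus_length))
        return cls(locus_id, feats, strand, frame)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneModel":
        """Read a simple interval TSV: ``kind<TAB>start<TAB>end`` lines, with
        optional ``#locus=``, ``#strand=``, ``#frame=`` header comments."""
        locus_id, strand, frame = "locus", "+", 0
        feats: list[Feature] = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                key = key.strip().lower()
                if key == "locus":
                    locus_id = val.strip()
                elif key == "strand":
                    strand = val.strip()
                elif key == "frame":
                    frame = int(val)
                continue
            kind, start, end = line.split("\t")[:3]
            if kind.lower() in ("kind", "feature"):  # header row
                continue
            feats.append(Feature(kind.lower(), int(start), int(end)))
        return cls(locus_id, feats, strand, frame)  # type: ignore[arg-type]

    @classmethod
    def from_gff3(cls, path: str | Path, locus_id: str | None = None) -> "GeneModel":
        """Read exon features of one locus from GFF3; introns are inferred.

        GFF3 is 1-based inclusive; converted to 0-based half-open.  Frame is
        taken from the phase column of the first CDS/exon if present.
        """
        exons: list[tuple[int, int]] = []
        strand, frame, seqid = "+", 0, None
        for line in Path(path).read_text().splitlines():
            if not line or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 8:
                continue
            if cols[2].lower() not in ("exon", "cds"):
                continue
            if locus_id is not None and cols[0] != locus_id:
                continue
            seqid = cols[0]
            exons.append((int(cols[3]) - 1, int(cols[4])))
            strand = cols[6] if cols[6] in ("+", "-") else "+"
            if cols[7] in ("0", "1", "2") and not frame:
                frame = int(cols[7])
        if not exons:
            raise ValueError(f"no exon/CDS features found in {path}")
        exons = sorted(set(exons))
        locus_length = max(e for _, e in exons)
        model = cls.from_exon_intervals(
            exons, locus_length, locus_id=seqid or "locus",
            strand=strand, frame=frame,  # type: ignore[arg-type]
        )
        return model

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#locus={self.locus_id}\n#strand={self.strand}\n#frame={self.frame}\n")
            for f in self.features:
                fh.write(f"{f.kind}\t{f.start}\t{f.end}\n")
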