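"""Core domain types shared across the screening pipeline.

Coordinates are uniformly 1-based inclusive, matching both the STAR
``SJ.out.tab`` junction convention (first/last intronic base) and Ensembl
GTF exon coordinates. Strand is ``'+'``, ``'-'`` or ``'.'`` (undetermined).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

#: chromosomes retained after filtering (autosomes + sex chromosomes)
VALID_CHROMS = frozenset({str(i) for i in range(1, 23)} | {"X", "Y"})

STRANDS = frozenset({"+", "-", "."})

UNKNOWN_STRAND = "."


def strands_compatible(a: str, b: str) -> bool:
    """Two strands are compatible if equal or either is undetermined."""
    return a == b or a == UNKNOWN_STRAND or b == UNKNOWN_STRAND


@dataclass(frozen=True, order=True)
class SpliceJunction:
    """An exon-exon junction, keyed by the intron it excises.

    ``intron_start``/``intron_end`` are the first and last intronic bases
    (1-based inclusive), i.e. STAR SJ.out.tab columns 2-3.
    """

    chrom: str
    intron_start: int
    intron_end: int
    strand: str = UNKNOWN_STRAND

    def __post_init__(self) -> None:
        if self.intron_start > self.intron_end:
            raise ValueError(
                f"intron_start > intron_end for {self.chrom}:"
                f"{self.intron_start}-{self.intron_end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.intron_start}-{self.intron_end}:{self.strand}"

    @property
    def length(self) -> int:
        return self.intron_end - self.intron_start + 1

    @classmethod
    def from_key(cls, key: str) -> "SpliceJunction":
        chrom, span, strand = key.rsplit(":", 2)
        start_s, end_s = span.split("-")
        return cls(chrom, int(start_s), int(end_s), strand)

    def coords(self) -> tuple[str, int, int]:
        return (self.chrom, self.intron_start, self.intron_end)

    def overlaps(self, other: "SpliceJunction") -> bool:
        """Intron-interval intersection on the same chromosome with
        compatible strands."""
        return (
            self.chrom == other.chrom
            and strands_compatible(self.strand, other.strand)
            and self.intron_start <= other.intron_end
            and other.intron_start <= self.intron_end
        )


@dataclass
class TranscriptModel:
    """A transcript with its exon chain and coding-region bounds."""

    transcript_id: str
    gene_id: str
    gene_symbol: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: Optional[int] = None  # genomic min of the CDS
    cds_end: Optional[int] = None  # genomic max of the CDS
    canonical: bool = False

    def __post_init__(self) -> None:
        self.exons = sorted(tuple(e) for e in self.exons)
        prev_end = 0
        for s, e in self.exons:
            if s > e:
                raise ValueError(
                    f"{self.transcript_id}: exon start {s} > end {e}"
                )
            if s <= prev_end:
                raise ValueError(
                    f"{self.transcript_id}: overlapping or unsorted exons"
                )
            prev_end = e
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError(f"{self.transcript_id}: partial CDS bounds")

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    @property
    def footprint(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    def junctions(self) -> list[SpliceJunction]:
        """Reference junctions: the introns between consecutive exons."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            out.append(SpliceJunction(self.chrom, e1 + 1, s2 - 1, self.strand))
        return out

    def spliced_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    def cds_intervals(self) -> list[tuple[int, int]]:
        """Exon chain clipped to the CDS window (genomic order)."""
        if not self.is_coding:
            return []
        out = []
        for s, e in self.exons:
            lo, hi = max(s, self.cds_start), min(e, self.cds_end)
            if lo <= hi:
                out.append((lo, hi))
        return out

    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_intervals())


@dataclass
class GeneFootprint:
    """Min/max genomic span of all transcripts of one gene."""

    gene_id: str
    gene_symbol: str
    chrom: str
    start: int
    end: int
    strand: str

    def overlap_length(self, junction: SpliceJunction) -> int:
        if self.chrom != junction.chrom:
            return 0
        if not strands_compatible(self.strand, junction.strand):
            return 0
        lo = max(self.start, junction.intron_start)
        hi = min(self.end, junction.intron_end)
        return max(0, hi - lo + 1)


class SegmentKind(str, Enum):
    EXTRACELLULAR = "extracellular"
    TRANSMEMBRANE = "transmembrane"
    INTRACELLULAR = "intracellular"


@dataclass
class SurfaceomeRecord:
    """Membrane topology of one cell-surface protein.

    Segment coordinates are 1-based inclusive amino-acid positions on the
    protein of ``reference_transcript``.
    """

    gene_id: str
    gene_symbol: str
    reference_transcript: str
    segments: list[tuple[str, int, int]]
    n_tm: int = field(init=False)

    def __post_init__(self) -> None:
        self.segments = sorted(
            ((str(k), int(s), int(e)) for k, s, e in self.segments),
            key=lambda seg: (seg[1], seg[2]),
        )
        prev_end = 0
        for kind, s, e in self.segments:
            SegmentKind(kind)  # raises on unknown kind
            if s > e or s <= prev_end:
                raise ValueError(
                    f"{self.gene_id}: invalid topology segment {kind}:{s}-{e}"
                )
            prev_end = e
        self.n_tm = sum(
            1 for k, _, _ in self.segments if k == SegmentKind.TRANSMEMBRANE
        )

    @property
    def is_single_pass(self) -> bool:
        return self.n_tm == 1

    def segments_of(self, kind: SegmentKind) -> list[tuple[int, int]]:
        return [(s, e) for k, s, e in self.segments if k == kind]

    @property
    def protein_length(self) -> int:
        return self.segments[-1][2]


class SplicePattern(str, Enum):
    """Splicing-pattern class of a non-annotated junction on one template."""

    ALT_3SS = "alt_3ss"
    ALT_5SS = "alt_5ss"
    EXON_SKIP = "exon_skip"
    CRYPTIC_INTRON = "cryptic_intron"
    COMPLEX = "complex"


class FrameStatus(str, Enum):
    IN_FRAME = "in_frame"
    FRAMESHIFT = "frameshift"


@dataclass
class ConsequenceReport:
    """Protein-level consequence of one junction on one template transcript."""

    junction_key: str
    transcript_id: str
    pattern: SplicePattern
    translatable: bool
    frame_status: Optional[FrameStatus] = None
    nt_delta: int = 0
    aa_deleted: int = 0
    aa_inserted: int = 0
    ptc_introduced: bool = False
    altered_protein: str = ""
    #: 1-based interval of the reference protein touched by the change;
    #: None when the protein is unchanged
    affected_aa_interval: Optional[tuple[int, int]] = None
    # topology verdicts (filled by assess_candidate)
    affects_extracellular: Optional[bool] = None
    tm_intact: Optional[bool] = None
    single_pass: Optional[bool] = None
    verdict_pass: bool = False
    fail_reason: Optional[str] = None
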