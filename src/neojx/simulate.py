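"""Synthetic desk-scale cohorts with planted splicing events and
machine-readable ground truth.

The generator emits every input the screening pipeline reads — genome
FASTA, GTF annotation, surfaceome topology table, per-sample SJ.out.tab
junction tables, a TPM matrix and a sample manifest — with a set of
planted non-annotated junctions. Five planted events are designed to pass
every filter; one decoy per class is designed to fail at exactly one
cascade stage (annotated, low supportive-read frequency, shared with
normals, rare across patients, frameshift/PTC, intracellular-only change,
multi-pass host protein, low host expression).

Counts are generated at the junction level, not by read simulation: the
screening statistics consume only junction counts. Locus depth is drawn
from a negative binomial (overdispersed RNA-seq coverage); a planted
event that is "on" in a sample receives a count of approximately
``frequency x locus depth``, floored per decoy class so it clears or
undershoots the positivity thresholds by a comfortable margin. Event
positivity across a group is assigned to ``round(p * n)`` samples chosen
at random, so the realized positive-sample rate equals the designed one
up to rounding.

Exon lengths and UTR lengths are multiples of 3, so every exon boundary
is codon-aligned; codon-aligned deletions then never create novel codons
at the junction, which makes planted in-frame events PTC-free by
construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from . import io_formats
from .io_formats import Annotation, build_annotation
from .types import SpliceJunction, SurfaceomeRecord, TranscriptModel

DECOY_CLASSES = [
    "annotated",
    "low_frequency",
    "normal_shared",
    "rare",
    "frameshift_ptc",
    "intracellular",
    "multi_pass",
    "low_expression",
]

_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]

NORMAL_TISSUES = [
    "brain",
    "liver",
    "lung",
    "heart",
    "kidney",
    "muscle",
    "skin",
    "colon",
    "spleen",
    "pancreas",
]


@dataclass
class SyntheticGene:
    """One generated gene with its transcript-order geometry."""

    gene_id: str
    symbol: str
    chrom: str
    strand: str
    offset: int  # genomic start (1-based)
    local_length: int
    exon_tlens: list[int]  # transcript-order exon lengths
    exon_tstarts: list[int]  # transcript-order 0-based transcript offsets
    exon_sense_local: list[tuple[int, int]]  # 1-based sense-local spans
    u5: int
    u3: int
    wt_cds: str
    sense_seq: str  # gene sequence in transcript orientation (with introns)
    transcript: TranscriptModel = None  # type: ignore[assignment]
    topology: Optional[SurfaceomeRecord] = None
    in_surfaceome: bool = True

    @property
    def cds_len(self) -> int:
        return len(self.wt_cds)

    @property
    def protein_len(self) -> int:
        return self.cds_len // 3 - 1

    @property
    def n_exons(self) -> int:
        return len(self.exon_tlens)

    def genomic_span(self, local_start: int, local_end: int) -> tuple[int, int]:
        """Map a 1-based sense-local interval to genomic coordinates."""
        if self.strand == "+":
            return (self.offset + local_start - 1, self.offset + local_end - 1)
        return (
            self.offset + self.local_length - local_end,
            self.offset + self.local_length - local_start,
        )

    def transcript_to_local(self, tpos: int) -> int:
        """Map a 1-based transcript position to a sense-local position."""
        for t, tstart in enumerate(self.exon_tstarts):
            if tstart < tpos <= tstart + self.exon_tlens[t]:
                es, _ = self.exon_sense_local[t]
                return es + (tpos - tstart) - 1
        raise ValueError(f"transcript position {tpos} outside exons")

    def exon_genomic(self, t: int) -> tuple[int, int]:
        s, e = self.exon_sense_local[t]
        lo, hi = self.genomic_span(s, e)
        return (lo, hi)

    def exon_cds_span(self, t: int) -> tuple[int, int]:
        """0-based [start, end) CDS-nt offsets covered by transcript exon t."""
        tstart = self.exon_tstarts[t]
        length = self.exon_tlens[t]
        c0 = max(0, tstart - self.u5)
        c1 = min(self.cds_len, tstart + length - self.u5)
        return (c0, max(c0, c1))

    def fully_coding(self, t: int) -> bool:
        tstart = self.exon_tstarts[t]
        return (
            tstart >= self.u5
            and tstart + self.exon_tlens[t] <= self.u5 + self.cds_len
        )


@dataclass
class SyntheticReference:
    genes: list[SyntheticGene]
    genome: dict[str, str]
    annotation: Annotation
    surfaceome: dict[str, SurfaceomeRecord]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "genome.fa", "w") as fh:
            for chrom in sorted(self.genome, key=lambda c: (len(c), c)):
                fh.write(f">{chrom}\n")
                seq = self.genome[chrom]
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        with open(out / "annotation.gtf", "w") as fh:
            fh.write(_to_gtf(self.genes))
        io_formats.write_surfaceome(
            self.surfaceome.values(), out / "surfaceome.tsv"
        )


def _to_gtf(genes: list[SyntheticGene]) -> str:
    lines = []
    for g in genes:
        t = g.transcript
        lo, hi = t.footprint
        attrs_gene = f'gene_id "{g.gene_id}"; gene_name "{g.symbol}";'
        attrs_tr = (
            f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}"; '
            f'gene_name "{g.symbol}"; tag "canonical";'
        )
        lines.append(
            f"{g.chrom}\tneojx\tgene\t{lo}\t{hi}\t.\t{g.strand}\t.\t"
            f"{attrs_gene}"
        )
        lines.append(
            f"{g.chrom}\tneojx\ttranscript\t{lo}\t{hi}\t.\t{g.strand}\t.\t"
            f"{attrs_tr}"
        )
        for s, e in t.exons:
            lines.append(
                f"{g.chrom}\tneojx\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                f"{attrs_tr}"
            )
        for s, e in t.cds_intervals():
            lines.append(
                f"{g.chrom}\tneojx\tCDS\t{s}\t{e}\t.\t{g.strand}\t0\t"
                f"{attrs_tr}"
            )
    return "\n".join(lines) + "\n"


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _ec_end(protein_len: int) -> int:
    return int(protein_len * 0.55)


def generate_reference(
    seed: int,
    n_genes: int = 16,
    surfaceome_fraction: float = 0.875,
    genes_per_chrom: int = 4,
) -> SyntheticReference:
    """Generate a deterministic toy genome/annotation/surfaceome.

    Multi-exon genes on both strands with valid start/stop codons; most
    genes are single-pass surfaceome members (extracellular segment up to
    ~55% of the protein, a 21-aa transmembrane segment, intracellular
    tail), one gene is four-pass, and the trailing genes are excluded
    from the surfaceome table.
    """
    if n_genes < 4:
        raise ValueError("n_genes must be >= 4")
    rng = np.random.default_rng(seed)
    n_surface = max(2, round(n_genes * surfaceome_fraction))
    multi_pass_index = n_surface - 1  # last surfaceome gene is four-pass
    genes: list[SyntheticGene] = []
    genome: dict[str, str] = {}
    chrom_cursor: dict[str, int] = {}
    chrom_seq: dict[str, list[str]] = {}
    for i in range(n_genes):
        chrom = str(i // genes_per_chrom + 1)
        if chrom not in chrom_cursor:
            chrom_cursor[chrom] = 1001  # first base after the 1 kb pad
            chrom_seq[chrom] = [_random_seq(rng, 1000)]
        n_exons = int(rng.integers(5, 8))
        exon_tlens = (3 * rng.integers(40, 81, n_exons)).tolist()
        u5 = int(3 * rng.integers(12, 18))
        u3 = int(3 * rng.integers(12, 18))
        cds_len = sum(exon_tlens) - u5 - u3
        ncod = cds_len // 3
        body = "".join(rng.choice(_CODONS, size=ncod - 2))
        wt_cds = "ATG" + body + "TAA"
        mrna = _random_seq(rng, u5) + wt_cds + _random_seq(rng, u3)
        intron_lens = rng.integers(100, 301, n_exons - 1).tolist()
        # assemble sense-local gene sequence and exon spans
        sense_parts = []
        exon_sense_local = []
        exon_tstarts = []
        pos = 0  # sense-local 0-based
        tpos = 0
        for t in range(n_exons):
            length = exon_tlens[t]
            exon_sense_local.append((pos + 1, pos + length))
            exon_tstarts.append(tpos)
            sense_parts.append(mrna[tpos : tpos + length])
            pos += length
            tpos += length
            if t < n_exons - 1:
                il = int(intron_lens[t])
                sense_parts.append(
                    "GT" + _random_seq(rng, il - 4) + "AG"
                )
                pos += il
        sense_seq = "".join(sense_parts)
        local_length = len(sense_seq)
        strand = "+" if i % 2 == 0 else "-"
        offset = chrom_cursor[chrom]
        chrom_cursor[chrom] = offset + local_length + 500
        genomic_seq = (
            sense_seq
            if strand == "+"
            else str(Seq(sense_seq).reverse_complement())
        )
        chrom_seq[chrom].append(genomic_seq)
        chrom_seq[chrom].append(_random_seq(rng, 500))

        gene = SyntheticGene(
            gene_id=f"SYNG{i:03d}",
            symbol=f"SG{i:03d}",
            chrom=chrom,
            strand=strand,
            offset=offset,
            local_length=local_length,
            exon_tlens=exon_tlens,
            exon_tstarts=exon_tstarts,
            exon_sense_local=exon_sense_local,
            u5=u5,
            u3=u3,
            wt_cds=wt_cds,
            sense_seq=sense_seq,
        )
        exons_genomic = sorted(
            gene.exon_genomic(t) for t in range(n_exons)
        )
        cds_lo, _ = gene.genomic_span(*(gene.transcript_to_local(u5 + 1),) * 2)
        cds_hi, _ = gene.genomic_span(
            *(gene.transcript_to_local(u5 + cds_len),) * 2
        )
        gene.transcript = TranscriptModel(
            transcript_id=f"SYNT{i:03d}",
            gene_id=gene.gene_id,
            gene_symbol=gene.symbol,
            chrom=chrom,
            strand=strand,
            exons=exons_genomic,
            cds_start=min(cds_lo, cds_hi),
            cds_end=max(cds_lo, cds_hi),
            canonical=True,
        )
        gene.in_surfaceome = i < n_surface
        if gene.in_surfaceome:
            P = gene.protein_len
            if i == multi_pass_index:
                loop = (P - 4 * 21) // 5
                segments = []
                kinds = [
                    "extracellular",
                    "transmembrane",
                    "intracellular",
                    "transmembrane",
                    "extracellular",
                    "transmembrane",
                    "intracellular",
                    "transmembrane",
                    "extracellular",
                ]
                cursor = 1
                for j, kind in enumerate(kinds):
                    length = 21 if kind == "transmembrane" else loop
                    if j == len(kinds) - 1:
                        length = P - cursor + 1
                    segments.append((kind, cursor, cursor + length - 1))
                    cursor += length
            else:
                ec = _ec_end(P)
                segments = [
                    ("extracellular", 1, ec),
                    ("transmembrane", ec + 1, ec + 21),
                    ("intracellular", ec + 22, P),
                ]
            gene.topology = SurfaceomeRecord(
                gene_id=gene.gene_id,
                gene_symbol=gene.symbol,
                reference_transcript=gene.transcript.transcript_id,
                segments=segments,
            )
        genes.append(gene)
    genome = {c: "".join(parts) for c, parts in chrom_seq.items()}
    annotation = build_annotation(g.transcript for g in genes)
    surfaceome = {
        g.gene_id: g.topology for g in genes if g.topology is not None
    }
    return SyntheticReference(genes, genome, annotation, surfaceome)


# ---------------------------------------------------------------------------
# event planting


@dataclass
class PlantedEvent:
    junction: SpliceJunction
    gene_id: str
    pattern: str
    decoy_class: str  # "none" for designed pass-filter events
    frequency: float
    group_probs: dict[str, float]
    normal_prob: float
    deleted_aa: Optional[tuple[int, int]]
    expected_final_pass: bool
    expected_fail_stage: Optional[str]
    count_floor: int = 24
    locus_scale: float = 2.0
    #: annotated locus junction whose depth the event competes against
    locus_junction: Optional[SpliceJunction] = None

    @property
    def key(self) -> str:
        return self.junction.key

    def to_dict(self) -> dict:
        return {
            "junction_key": self.key,
            "gene_id": self.gene_id,
            "pattern": self.pattern,
            "decoy_class": self.decoy_class,
            "designed_frequency": self.frequency,
            "group_probs": self.group_probs,
            "normal_prob": self.normal_prob,
            "deleted_aa": list(self.deleted_aa) if self.deleted_aa else None,
            "expected_final_pass": self.expected_final_pass,
            "expected_fail_stage": self.expected_fail_stage,
        }


def _annotated_intron(gene: SyntheticGene, t_intron: int) -> tuple[int, int]:
    """Genomic bounds of the intron between transcript exons t, t+1."""
    g = (
        t_intron
        if gene.strand == "+"
        else gene.n_exons - 2 - t_intron
    )
    exons = gene.transcript.exons
    return (exons[g][1] + 1, exons[g + 1][0] - 1)


def _extend_intron(
    gene: SyntheticGene, t_intron: int, side: str, shift: int
) -> tuple[int, int]:
    """Extend an annotated intron into the transcript-upstream exon
    (donor shift) or transcript-downstream exon (acceptor shift)."""
    s, e = _annotated_intron(gene, t_intron)
    into_right = (side == "downstream") == (gene.strand == "+")
    return (s, e + shift) if into_right else (s - shift, e)


def _aa_window_ok(
    gene: SyntheticGene, a1: int, a2: int, region: str
) -> bool:
    """Does the aa window [a1, a2] sit safely inside the target topology
    region (two-residue margin from segment edges and protein termini)?"""
    if not 2 <= a1 <= a2 <= gene.protein_len - 2:
        return False
    if region == "any":
        return True
    topo = gene.topology
    if topo is None:
        return False
    return any(
        lo + 1 <= a1 <= a2 <= hi - 2
        for kind, lo, hi in topo.segments
        if kind == region
    )


def _frameshift_has_ptc(gene: SyntheticGene, d0: int, removed: int) -> bool:
    """Codon-walk check that removing ``removed`` nt at CDS offset ``d0``
    yields an in-frame stop upstream of the canonical-stop position."""
    cds = gene.wt_cds
    altered = cds[:d0] + cds[d0 + removed :]
    nominal = len(altered)
    for p in range(0, len(altered) - 2, 3):
        if altered[p : p + 3] in _STOPS:
            return 3 * p < nominal - 3
    return False


def _plant_shift(
    gene: SyntheticGene,
    region: str,
    n_codons: int,
    extra_nt: int = 0,
    prefer_side: str = "downstream",
) -> Optional[tuple[SpliceJunction, str, tuple[int, int], int]]:
    """Plant an alternative-splice-site deletion.

    Deletes the first (acceptor shift / alt 3'SS) or last (donor shift /
    alt 5'SS) ``n_codons`` codons of an internal fully-coding exon, plus
    ``extra_nt`` bases for frameshift decoys. Returns (junction, pattern,
    deleted-aa range, CDS-offset of the deletion) or None if no exon fits.
    """
    shift = 3 * n_codons + extra_nt
    for t in range(1, gene.n_exons - 1):
        if not gene.fully_coding(t):
            continue
        c0, c1 = gene.exon_cds_span(t)
        if c1 - c0 < shift + 3:
            continue
        if prefer_side == "downstream":
            d0, t_intron = c0, t - 1
        else:
            d0, t_intron = c1 - shift, t
        a1 = d0 // 3 + 1
        a2 = (d0 + shift - 1) // 3 + 1
        if not _aa_window_ok(gene, a1, a2, region):
            continue
        if extra_nt and not _frameshift_has_ptc(gene, d0, shift):
            continue
        s, e = _extend_intron(gene, t_intron, prefer_side, shift)
        pattern = "alt_3ss" if prefer_side == "downstream" else "alt_5ss"
        junction = SpliceJunction(gene.chrom, s, e, gene.strand)
        return junction, pattern, (a1, a2), d0
    return None


def _plant_cryptic(
    gene: SyntheticGene, region: str, n_codons: int
) -> Optional[tuple[SpliceJunction, str, tuple[int, int], int]]:
    """Plant a cryptic intron: a codon-aligned window strictly inside an
    internal fully-coding exon (the window slides until the target
    topology region fits)."""
    for t in range(1, gene.n_exons - 1):
        if not gene.fully_coding(t):
            continue
        c0, c1 = gene.exon_cds_span(t)
        for d0 in range(c0 + 3, c1 - 3 - 3 * n_codons + 1, 3):
            d1 = d0 + 3 * n_codons
            a1, a2 = d0 // 3 + 1, d1 // 3
            if not _aa_window_ok(gene, a1, a2, region):
                continue
            es, _ = gene.exon_sense_local[t]
            # sense-local position of CDS offset d0 within exon t
            lstart = es + (gene.u5 + d0 - gene.exon_tstarts[t])
            lend = lstart + 3 * n_codons - 1
            glo, ghi = gene.genomic_span(lstart, lend)
            junction = SpliceJunction(gene.chrom, glo, ghi, gene.strand)
            return junction, "cryptic_intron", (a1, a2), d0
    return None


def _plant_exon_skip(
    gene: SyntheticGene, region: str
) -> Optional[tuple[SpliceJunction, str, tuple[int, int], int]]:
    """Plant a whole-exon skip of an internal fully-coding exon whose
    codons all lie in the target region."""
    for t in range(1, gene.n_exons - 1):
        if not gene.fully_coding(t):
            continue
        c0, c1 = gene.exon_cds_span(t)
        a1, a2 = c0 // 3 + 1, c1 // 3
        if not _aa_window_ok(gene, a1, a2, region):
            continue
        i_prev = _annotated_intron(gene, t - 1)
        i_next = _annotated_intron(gene, t)
        glo = min(i_prev[0], i_next[0])
        ghi = max(i_prev[1], i_next[1])
        junction = SpliceJunction(gene.chrom, glo, ghi, gene.strand)
        return junction, "exon_skip", (a1, a2), c0
    return None


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass
class CohortDesign:
    """Study design for a simulated bulk cohort.

    Defaults mirror a desk-scale version of the screen's conditions:
    three tumor disease groups, a pooled multi-tissue normal cohort an
    order of magnitude larger, five planted pass-filter events and one
    decoy per failure class.
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"IDHwt": 20, "IDH-A": 20, "IDH-O": 20}
    )
    n_normal: int = 300
    n_pass_events: int = 5
    decoy_classes: tuple[str, ...] = tuple(DECOY_CLASSES)
    depth_mean: float = 150.0
    depth_dispersion: float = 10.0
    depth_floor: int = 30
    pass_frequency: float = 0.15
    low_frequency: float = 0.005
    normal_shared_prob: float = 0.05
    rare_prob: float = 0.03
    shared_prob: float = 0.5
    leak_prob: float = 0.15
    host_tpm: float = 50.0
    low_expression_tpm: float = 2.0

    def validate(self) -> None:
        for p in (
            self.pass_frequency,
            self.low_frequency,
            self.normal_shared_prob,
            self.rare_prob,
            self.shared_prob,
            self.leak_prob,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"design probability {p} outside [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortDesign":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


_PASS_GROUP_PROBS = [
    {"IDHwt": 0.5, "IDH-A": 0.4, "IDH-O": 0.6},
    {"IDHwt": 0.2, "IDH-A": 0.5, "IDH-O": 0.5},
    {"IDHwt": 0.6, "IDH-A": 0.3, "IDH-O": 0.3},
    {"IDHwt": 0.5, "IDH-A": 0.5, "IDH-O": 0.2},
    {"IDHwt": 0.3, "IDH-A": 0.6, "IDH-O": 0.4},
]

_PASS_PATTERN_CYCLE = ["alt_3ss", "alt_5ss", "exon_skip", "cryptic_intron"]


def design_events(
    reference: SyntheticReference, design: CohortDesign
) -> list[PlantedEvent]:
    """Assign planted events and decoys to host genes.

    Hosts are distinct; each decoy class is placed on a gene whose
    properties make it fail at exactly its designed cascade stage.
    """
    genes = {g.gene_id: g for g in reference.genes}
    single_pass = [
        g
        for g in reference.genes
        if g.topology is not None and g.topology.n_tm == 1
    ]
    multi_pass = [
        g
        for g in reference.genes
        if g.topology is not None and g.topology.n_tm > 1
    ]
    used: set[str] = set()
    events: list[PlantedEvent] = []

    def take(pool: list[SyntheticGene]) -> Optional[SyntheticGene]:
        for g in pool:
            if g.gene_id not in used:
                return g
        return None

    def uniform_probs(p: float) -> dict[str, float]:
        return {g: p for g in design.group_sizes}

    # pass-filter events, cycling over splice patterns
    for i in range(design.n_pass_events):
        pattern_wanted = _PASS_PATTERN_CYCLE[i % len(_PASS_PATTERN_CYCLE)]
        planted = None
        for g in single_pass:
            if g.gene_id in used:
                continue
            if pattern_wanted == "alt_3ss":
                planted = _plant_shift(g, "extracellular", 6)
            elif pattern_wanted == "alt_5ss":
                planted = _plant_shift(
                    g, "extracellular", 6, prefer_side="upstream"
                )
            elif pattern_wanted == "exon_skip":
                planted = _plant_exon_skip(g, "extracellular")
            else:
                planted = _plant_cryptic(g, "extracellular", 8)
            if planted is not None:
                host = g
                break
        if planted is None:
            raise RuntimeError(
                f"no feasible host for pass event pattern {pattern_wanted}"
            )
        junction, pattern, aa, _ = planted
        used.add(host.gene_id)
        probs = _PASS_GROUP_PROBS[i % len(_PASS_GROUP_PROBS)]
        probs = {g: probs.get(g, design.shared_prob) for g in design.group_sizes}
        locus = _locus_junction(host, junction)
        events.append(
            PlantedEvent(
                junction=junction,
                gene_id=host.gene_id,
                pattern=pattern,
                decoy_class="none",
                frequency=design.pass_frequency,
                group_probs=probs,
                normal_prob=0.0,
                deleted_aa=aa,
                expected_final_pass=True,
                expected_fail_stage=None,
                locus_junction=locus,
            )
        )

    for decoy in design.decoy_classes:
        if decoy == "annotated":
            host = take(single_pass)
            junction = host.transcript.junctions()[0]
            events.append(
                PlantedEvent(
                    junction=junction,
                    gene_id=host.gene_id,
                    pattern="annotated",
                    decoy_class=decoy,
                    frequency=1.0,
                    group_probs=uniform_probs(0.0),
                    normal_prob=0.0,
                    deleted_aa=None,
                    expected_final_pass=False,
                    expected_fail_stage="non_annotated",
                )
            )
            used.add(host.gene_id)
            continue
        pool = multi_pass if decoy == "multi_pass" else single_pass
        if decoy == "intracellular":
            region = "intracellular"
        elif decoy in ("frameshift_ptc", "multi_pass"):
            region = "extracellular"
        else:
            # classes failing before the consequence stage: any coding spot
            region = "any"
        extra = 1 if decoy == "frameshift_ptc" else 0
        planted = None
        for g in pool:
            if g.gene_id in used:
                continue
            planted = _plant_shift(g, region, 6, extra_nt=extra)
            if (
                planted is None
                and extra == 0
                and decoy != "low_frequency"  # needs an overlapping locus
            ):
                planted = _plant_cryptic(g, region, 6)
            if planted is not None:
                host = g
                break
        if planted is None:
            raise RuntimeError(f"no feasible host for decoy class {decoy}")
        junction, pattern, aa, _ = planted
        used.add(host.gene_id)
        ev = PlantedEvent(
            junction=junction,
            gene_id=host.gene_id,
            pattern=pattern,
            decoy_class=decoy,
            frequency=design.pass_frequency,
            group_probs=uniform_probs(design.shared_prob),
            normal_prob=0.0,
            deleted_aa=aa,
            expected_final_pass=False,
            expected_fail_stage=None,
            locus_junction=_locus_junction(host, junction),
        )
        if decoy == "low_frequency":
            ev.frequency = design.low_frequency
            ev.locus_scale = 20.0
            ev.count_floor = 10
            ev.expected_fail_stage = "shared"
        elif decoy == "normal_shared":
            ev.normal_prob = design.normal_shared_prob
            ev.expected_fail_stage = "tumor_specific"
        elif decoy == "rare":
            ev.group_probs = uniform_probs(design.rare_prob)
            ev.expected_fail_stage = "shared"
        elif decoy == "frameshift_ptc":
            ev.expected_fail_stage = "protein_compatible"
        elif decoy == "intracellular":
            ev.expected_fail_stage = "extracellular"
        elif decoy == "multi_pass":
            ev.expected_fail_stage = "protein_compatible"
        elif decoy == "low_expression":
            ev.expected_fail_stage = "surfaceome_expressed"
        events.append(ev)
    return events


def _locus_junction(
    gene: SyntheticGene, event: SpliceJunction
) -> Optional[SpliceJunction]:
    """The annotated junction at the event's locus (overlapping intron
    with the largest overlap); None for events inside an exon."""
    best = None
    best_len = 0
    for j in gene.transcript.junctions():
        lo = max(j.intron_start, event.intron_start)
        hi = min(j.intron_end, event.intron_end)
        if hi - lo + 1 > best_len:
            best_len = hi - lo + 1
            best = j
    return best


@dataclass
class SimulatedCohort:
    reference: SyntheticReference
    design: CohortDesign
    sj_tables: dict[str, list[tuple[SpliceJunction, int]]]
    expression: pd.DataFrame
    manifest: pd.DataFrame
    truth: list[PlantedEvent]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.reference.write(out)
        sj_dir = out / "sj"
        sj_dir.mkdir(exist_ok=True)
        for sample, rows in self.sj_tables.items():
            io_formats.write_sj_tab(rows, sj_dir / f"{sample}.SJ.out.tab")
        self.expression.to_csv(out / "expression.tsv", sep="\t")
        self.manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
        with open(out / "truth.json", "w") as fh:
            json.dump([e.to_dict() for e in self.truth], fh, indent=2)


def simulate_cohort(
    seed: int,
    reference: SyntheticReference,
    design: Optional[CohortDesign] = None,
) -> SimulatedCohort:
    """Simulate per-sample junction tables, a TPM matrix and a manifest
    with planted ground truth (deterministic for a fixed seed)."""
    design = design or CohortDesign()
    design.validate()
    rng = np.random.default_rng(seed)
    events = design_events(reference, design)

    # manifest
    rows = []
    tumor_ids: dict[str, list[str]] = {}
    for group, n in design.group_sizes.items():
        ids = [f"TUM-{group}-{i:03d}" for i in range(n)]
        tumor_ids[group] = ids
        for sid in ids:
            rows.append(
                {
                    "sample_id": sid,
                    "cohort": "tumor",
                    "group": group,
                    "purity": round(float(rng.uniform(0.65, 0.98)), 3),
                    "vaf": (
                        round(float(rng.uniform(0.3, 0.5)), 3)
                        if group == "IDH-A"
                        else np.nan
                    ),
                    "patient_id": sid,
                    "piece_id": "p1",
                    "timepoint": "NA",
                }
            )
    normal_ids = [f"NORM-{i:04d}" for i in range(design.n_normal)]
    for i, sid in enumerate(normal_ids):
        rows.append(
            {
                "sample_id": sid,
                "cohort": "normal",
                "group": NORMAL_TISSUES[i % len(NORMAL_TISSUES)],
                "purity": np.nan,
                "vaf": np.nan,
                "patient_id": sid,
                "piece_id": "p1",
                "timepoint": "NA",
            }
        )
    manifest = pd.DataFrame(rows)
    all_samples = manifest["sample_id"].tolist()
    all_tumor = [s for g in tumor_ids.values() for s in g]

    # per-locus depth scale: events can boost their annotated locus junction
    locus_scale: dict[str, float] = {}
    for ev in events:
        if ev.locus_junction is not None and ev.decoy_class != "annotated":
            locus_scale[ev.locus_junction.key] = max(
                locus_scale.get(ev.locus_junction.key, 1.0), ev.locus_scale
            )

    # annotated junction counts per sample (negative binomial locus depth)
    r = design.depth_dispersion
    annotated_junctions = sorted(
        reference.annotation.reference_junctions
    )
    ann_counts: dict[str, np.ndarray] = {}
    for j in annotated_junctions:
        mean = design.depth_mean * locus_scale.get(j.key, 1.0)
        p = r / (r + mean)
        counts = rng.negative_binomial(r, p, size=len(all_samples))
        floor = int(design.depth_floor * locus_scale.get(j.key, 1.0))
        ann_counts[j.key] = np.maximum(counts, floor)
    sample_pos = {s: i for i, s in enumerate(all_samples)}

    # planted event counts
    event_counts: dict[str, dict[str, int]] = {ev.key: {} for ev in events}
    for ev in events:
        if ev.decoy_class == "annotated":
            continue  # its counts are the annotated locus counts
        positives: list[str] = []
        for group, ids in tumor_ids.items():
            k = round(ev.group_probs.get(group, 0.0) * len(ids))
            if k > 0:
                chosen = rng.choice(ids, size=k, replace=False)
                positives.extend(chosen.tolist())
        k_norm = round(ev.normal_prob * len(normal_ids))
        if k_norm > 0:
            positives.extend(
                rng.choice(normal_ids, size=k_norm, replace=False).tolist()
            )
        f = ev.frequency
        for sid in positives:
            if ev.locus_junction is None:
                c = max(
                    ev.count_floor,
                    int(rng.normal(ev.count_floor * 1.5, 3)),
                )
            else:
                depth = int(ann_counts[ev.locus_junction.key][sample_pos[sid]])
                c = round(f * depth / (1.0 - f))
                if ev.decoy_class == "low_frequency":
                    # stay strictly below the 1% frequency bar while
                    # clearing the 10-read detection floor
                    c = min(max(c, ev.count_floor), int(0.008 * depth))
                else:
                    c = max(c, ev.count_floor)
            event_counts[ev.key][sid] = int(c)
        # sub-threshold leak reads in other tumor samples
        if ev.decoy_class != "low_frequency":
            for sid in all_tumor:
                if sid in event_counts[ev.key]:
                    continue
                if rng.random() < design.leak_prob:
                    event_counts[ev.key][sid] = int(rng.integers(1, 4))

    # assemble per-sample SJ tables
    sj_tables: dict[str, list[tuple[SpliceJunction, int]]] = {}
    for sid in all_samples:
        i = sample_pos[sid]
        table = [
            (j, int(ann_counts[j.key][i])) for j in annotated_junctions
        ]
        for ev in events:
            if ev.decoy_class == "annotated":
                continue
            c = event_counts[ev.key].get(sid)
            if c:
                table.append((ev.junction, c))
        sj_tables[sid] = table

    # expression matrix
    gene_ids = [g.gene_id for g in reference.genes]
    host_low = {
        ev.gene_id for ev in events if ev.decoy_class == "low_expression"
    }
    base = np.array(
        [
            design.low_expression_tpm
            if gid in host_low
            else design.host_tpm
            for gid in gene_ids
        ]
    )
    noise = np.exp(rng.normal(0.0, 0.2, size=(len(gene_ids), len(all_samples))))
    expression = pd.DataFrame(
        base[:, None] * noise, index=gene_ids, columns=all_samples
    )
    expression.index.name = "gene_id"

    return SimulatedCohort(
        reference=reference,
        design=design,
        sj_tables=sj_tables,
        expression=expression,
        manifest=manifest,
        truth=events,
    )


# ---------------------------------------------------------------------------
# spatial / longitudinal designs


def simulate_spatial_design(
    seed: int,
    events: list[str],
    n_tumors: int = 24,
    pieces_range: tuple[int, int] = (3, 12),
    positive_prob: float = 0.4,
    tumor_wide_prob: float = 0.08,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a multi-region positivity matrix plus its manifest.

    Each tumor contributes 3-12 purity-gated pieces; each (tumor, event)
    pair is tumor-wide with a small probability, otherwise pieces are
    positive independently — emulating pronounced intratumoral
    heterogeneity with occasional homogeneous events.
    """
    rng = np.random.default_rng(seed)
    rows = []
    cols: dict[str, list[bool]] = {}
    groups = ["IDHwt", "IDH-A", "IDH-O"]
    for t in range(n_tumors):
        patient = f"SP{t:02d}"
        group = groups[t % 3]
        n_pieces = int(rng.integers(pieces_range[0], pieces_range[1] + 1))
        for p in range(n_pieces):
            sid = f"{patient}-{p:02d}"
            rows.append(
                {
                    "sample_id": sid,
                    "cohort": "tumor",
                    "group": group,
                    "purity": round(float(rng.uniform(0.5, 0.95)), 3),
                    "vaf": (
                        round(float(rng.uniform(0.26, 0.5)), 3)
                        if group == "IDH-A"
                        else np.nan
                    ),
                    "patient_id": patient,
                    "piece_id": f"p{p}",
                    "timepoint": "NA",
                }
            )
        piece_ids = [f"{patient}-{p:02d}" for p in range(n_pieces)]
        for sid in piece_ids:
            cols[sid] = []
        for event in events:
            if rng.random() < tumor_wide_prob:
                calls = [True] * n_pieces
            else:
                calls = (rng.random(n_pieces) < positive_prob).tolist()
            for sid, call in zip(piece_ids, calls):
                cols[sid].append(bool(call))
    manifest = pd.DataFrame(rows)
    positive = pd.DataFrame(cols, index=events)
    return positive, manifest


def simulate_longitudinal_design(
    seed: int,
    events: list[str],
    n_patients: int = 11,
    multi_piece_prob: float = 0.35,
    p_primary: float = 0.4,
    p_shared_given_primary: float = 0.3,
    p_emerge: float = 0.25,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate paired primary/recurrent positivity with mostly transient
    events: detected events usually disappear or newly emerge at
    recurrence."""
    rng = np.random.default_rng(seed)
    rows = []
    cols: dict[str, list[bool]] = {}
    sample_events: dict[str, list[bool]] = {}
    for i in range(n_patients):
        patient = f"LG{i:02d}"
        for tp in ("primary", "recurrent"):
            n_pieces = (
                int(rng.integers(2, 5))
                if rng.random() < multi_piece_prob
                else 1
            )
            for p in range(n_pieces):
                sid = f"{patient}-{tp[:4]}-{p}"
                rows.append(
                    {
                        "sample_id": sid,
                        "cohort": "tumor",
                        "group": "IDHwt",
                        "purity": round(float(rng.uniform(0.5, 0.95)), 3),
                        "vaf": np.nan,
                        "patient_id": patient,
                        "piece_id": f"p{p}",
                        "timepoint": tp,
                    }
                )
                sample_events[sid] = []
        for event in events:
            prim_on = rng.random() < p_primary
            rec_on = (
                rng.random() < p_shared_given_primary
                if prim_on
                else rng.random() < p_emerge
            )
            for sid in sample_events:
                if not sid.startswith(patient):
                    continue
                on = prim_on if "-prim-" in sid else rec_on
                # piece-level noise around the timepoint state
                call = on if rng.random() < 0.85 else not on
                sample_events[sid].append(bool(call))
    manifest = pd.DataFrame(rows)
    positive = pd.DataFrame(sample_events, index=events)
    return positive, manifest
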