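"""Splice-pattern classification and in-silico translation of candidate
junctions on canonical template transcripts.

The altered transcript is rebuilt by excising the novel intron from the
template's exon chain: exonic bases inside the novel intron are removed,
and template-intronic bases between an annotated splice site and a
shifted novel splice site are retained (alternative-splice-site inclusion
needs the genome sequence, which is why a FASTA is required). The CDS is
re-extracted from the annotated start codon, translated with the standard
code, and compared against the wild-type protein; all termination codons,
including premature ones, are marked '*'.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from Bio.Seq import Seq

from .types import (
    ConsequenceReport,
    FrameStatus,
    SegmentKind,
    SpliceJunction,
    SplicePattern,
    SurfaceomeRecord,
    TranscriptModel,
)


def _merge_intervals(
    intervals: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Merge touching/overlapping 1-based inclusive intervals."""
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def oriented_sequence(
    genome: Mapping[str, str],
    chrom: str,
    intervals: Sequence[tuple[int, int]],
    strand: str,
) -> str:
    """Spliced sequence over genomic intervals, reverse-complemented for
    minus-strand transcripts."""
    seq = "".join(genome[chrom][s - 1 : e] for s, e in sorted(intervals))
    if strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def classify_splice_pattern(
    junction: SpliceJunction, template: TranscriptModel
) -> SplicePattern:
    """Classify a non-annotated junction relative to one template.

    Both intron ends strictly inside one exon -> cryptic intron; both ends
    at annotated exon boundaries with >=1 whole exon in between -> exon
    skip; annotated donor with shifted acceptor -> alternative 3' splice
    site; annotated acceptor with shifted donor -> alternative 5' splice
    site; anything else -> complex. Donor/acceptor sides follow the
    template strand.
    """
    s, e = junction.intron_start, junction.intron_end
    lo, hi = template.footprint
    if junction.chrom != template.chrom or s < lo or e > hi:
        raise ValueError(
            f"junction {junction.key} outside transcript "
            f"{template.transcript_id} footprint"
        )
    exons = template.exons
    for a, b in exons:
        if a < s and e < b:
            return SplicePattern.CRYPTIC_INTRON
    end_idx = {b: i for i, (a, b) in enumerate(exons)}
    start_idx = {a: i for i, (a, b) in enumerate(exons)}
    left_at_boundary = (s - 1) in end_idx
    right_at_boundary = (e + 1) in start_idx
    if left_at_boundary and right_at_boundary:
        if start_idx[e + 1] - end_idx[s - 1] >= 2:
            return SplicePattern.EXON_SKIP
        return SplicePattern.COMPLEX
    if template.strand == "-":
        donor_annotated, acceptor_annotated = (
            right_at_boundary,
            left_at_boundary,
        )
    else:
        donor_annotated, acceptor_annotated = (
            left_at_boundary,
            right_at_boundary,
        )
    if donor_annotated and not acceptor_annotated:
        return SplicePattern.ALT_3SS
    if acceptor_annotated and not donor_annotated:
        return SplicePattern.ALT_5SS
    return SplicePattern.COMPLEX


@dataclass
class AlteredTranscript:
    """Template exon chain with the novel intron applied."""

    junction: SpliceJunction
    template: TranscriptModel
    exons: list[tuple[int, int]]
    nt_delta: int
    start_codon_intact: bool

    def cds_intervals(self) -> list[tuple[int, int]]:
        t = self.template
        out = []
        for s, e in self.exons:
            lo, hi = max(s, t.cds_start), min(e, t.cds_end)
            if lo <= hi:
                out.append((lo, hi))
        return out


def apply_event_to_transcript(
    junction: SpliceJunction,
    template: TranscriptModel,
    genome: Mapping[str, str],
) -> tuple[AlteredTranscript, str]:
    """Excise the novel intron from the template and return the altered
    chain plus the altered spliced mRNA sequence.

    ``nt_delta`` is the signed length change of the spliced CDS implied by
    the substitution (exonic bases lost minus template-intronic bases
    gained, within the CDS window).
    """
    s, e = junction.intron_start, junction.intron_end
    lo, hi = template.footprint
    if junction.chrom != template.chrom or s < lo or e > hi:
        raise ValueError(
            f"junction {junction.key} outside transcript "
            f"{template.transcript_id} footprint"
        )
    exons = template.exons
    left = [(a, min(b, s - 1)) for a, b in exons if a <= s - 1]
    right = [(max(a, e + 1), b) for a, b in exons if b >= e + 1]
    # retained intronic stubs where a novel splice site sits inside a
    # template intron
    for (a1, b1), (a2, b2) in zip(exons, exons[1:]):
        if b1 < s - 1 < a2:
            left.append((b1 + 1, s - 1))
        if b1 < e + 1 < a2:
            right.append((e + 1, a2 - 1))
    chain = _merge_intervals(left + right)

    if not template.is_coding:
        raise ValueError(
            f"template {template.transcript_id} has no annotated CDS"
        )
    altered = AlteredTranscript(
        junction=junction,
        template=template,
        exons=chain,
        nt_delta=0,
        start_codon_intact=False,
    )
    altered.nt_delta = (
        sum(b - a + 1 for a, b in altered.cds_intervals())
        - template.cds_length()
    )
    start_base = (
        template.cds_start if template.strand != "-" else template.cds_end
    )
    altered.start_codon_intact = any(
        a <= start_base <= b for a, b in chain
    )
    mrna = oriented_sequence(
        genome, template.chrom, chain, template.strand
    )
    return altered, mrna


def reference_protein(
    template: TranscriptModel, genome: Mapping[str, str]
) -> str:
    """Wild-type protein of a coding template (no trailing stop mark)."""
    cds = oriented_sequence(
        genome, template.chrom, template.cds_intervals(), template.strand
    )
    protein = str(Seq(cds[: len(cds) - len(cds) % 3]).translate())
    return protein[:-1] if protein.endswith("*") else protein


def validate_template(
    template: TranscriptModel, genome: Mapping[str, str]
) -> str:
    """Wild-type self-check: the unaltered CDS must start with ATG, end in
    a stop, and translate without internal stops. Returns the protein."""
    cds = oriented_sequence(
        genome, template.chrom, template.cds_intervals(), template.strand
    )
    if len(cds) < 3 or len(cds) % 3 != 0:
        raise ValueError(
            f"{template.transcript_id}: CDS length {len(cds)} not a "
            "positive multiple of 3"
        )
    if not cds.startswith("ATG"):
        raise ValueError(f"{template.transcript_id}: CDS lacks start codon")
    protein = str(Seq(cds).translate())
    if not protein.endswith("*"):
        raise ValueError(f"{template.transcript_id}: CDS lacks stop codon")
    if "*" in protein[:-1]:
        raise ValueError(
            f"{template.transcript_id}: internal stop in wild-type CDS"
        )
    return protein[:-1]


def _cds_to_transcript_end(
    altered: AlteredTranscript, genome: Mapping[str, str]
) -> str:
    """Sequence from the annotated start codon through the transcript 3'
    end (frameshifted stops may fall in the annotated 3' UTR)."""
    t = altered.template
    if t.strand == "-":
        intervals = [
            (a, min(b, t.cds_end))
            for a, b in altered.exons
            if a <= t.cds_end
        ]
    else:
        intervals = [
            (max(a, t.cds_start), b)
            for a, b in altered.exons
            if b >= t.cds_start
        ]
    return oriented_sequence(genome, t.chrom, intervals, t.strand)


def translate_and_flag(
    junction: SpliceJunction,
    template: TranscriptModel,
    genome: Mapping[str, str],
    pattern: Optional[SplicePattern] = None,
) -> ConsequenceReport:
    """Apply the event, translate, and report the protein consequence.

    ``ptc_introduced`` is any in-frame stop strictly upstream of the
    position aligned with the canonical stop; amino-acid deltas come from
    the common prefix/suffix against the wild-type protein.
    """
    if pattern is None:
        pattern = classify_splice_pattern(junction, template)
    altered, _ = apply_event_to_transcript(junction, template, genome)
    report = ConsequenceReport(
        junction_key=junction.key,
        transcript_id=template.transcript_id,
        pattern=pattern,
        translatable=altered.start_codon_intact,
        nt_delta=altered.nt_delta,
    )
    if not altered.start_codon_intact:
        report.fail_reason = "start_codon_lost"
        return report
    report.frame_status = (
        FrameStatus.IN_FRAME
        if altered.nt_delta % 3 == 0
        else FrameStatus.FRAMESHIFT
    )
    seq = _cds_to_transcript_end(altered, genome)
    seq = seq[: len(seq) - len(seq) % 3]
    if len(seq) < 3:
        raise ValueError(f"altered CDS of {junction.key} shorter than 3 nt")
    protein_full = str(Seq(seq).translate())
    nominal_len = template.cds_length() + altered.nt_delta
    stop_idx = protein_full.find("*")
    if stop_idx >= 0:
        report.altered_protein = protein_full[: stop_idx + 1]
        report.ptc_introduced = 3 * stop_idx < nominal_len - 3
        alt_trunc = protein_full[:stop_idx]
    else:
        report.altered_protein = protein_full
        alt_trunc = protein_full

    ref = reference_protein(template, genome)
    prefix = 0
    limit = min(len(ref), len(alt_trunc))
    while prefix < limit and ref[prefix] == alt_trunc[prefix]:
        prefix += 1
    suffix = 0
    while (
        suffix < limit - prefix
        and ref[len(ref) - 1 - suffix] == alt_trunc[len(alt_trunc) - 1 - suffix]
    ):
        suffix += 1
    report.aa_deleted = len(ref) - prefix - suffix
    report.aa_inserted = len(alt_trunc) - prefix - suffix
    if report.aa_deleted > 0:
        report.affected_aa_interval = (prefix + 1, len(ref) - suffix)
    elif report.aa_inserted > 0:
        report.affected_aa_interval = (
            max(1, prefix),
            min(len(ref), prefix + 1),
        )
    return report


def _transfer_segments(
    record: SurfaceomeRecord,
    template: TranscriptModel,
    wt_protein: str,
    reference_proteins: Optional[Mapping[str, str]],
) -> Optional[list[tuple[str, int, int]]]:
    """Map topology segments onto this template's protein.

    Coordinates apply directly on the named reference isoform; on other
    templates the transmembrane sequence is located by exact subsequence
    match and all segments are shifted accordingly. Returns None when the
    topology cannot be transferred.
    """
    if record.reference_transcript == template.transcript_id:
        return list(record.segments)
    if (
        reference_proteins is None
        or record.reference_transcript not in reference_proteins
    ):
        return None
    ref_iso = reference_proteins[record.reference_transcript]
    tms = record.segments_of(SegmentKind.TRANSMEMBRANE)
    if not tms:
        return None
    tm_start, tm_end = tms[0]
    tm_seq = ref_iso[tm_start - 1 : tm_end]
    pos = wt_protein.find(tm_seq)
    if pos < 0:
        return None
    offset = pos - (tm_start - 1)
    out = []
    for kind, s, e in record.segments:
        s2, e2 = s + offset, e + offset
        s2, e2 = max(1, s2), min(len(wt_protein), e2)
        if s2 > e2:
            return None
        out.append((kind, s2, e2))
    return out


def assess_candidate(
    report: ConsequenceReport,
    record: Optional[SurfaceomeRecord],
    template: TranscriptModel,
    genome: Mapping[str, str],
    reference_proteins: Optional[Mapping[str, str]] = None,
) -> ConsequenceReport:
    """Fill topology verdicts: does the change touch an extracellular
    segment, is every transmembrane segment retained verbatim, and is the
    protein single-pass? The candidate passes when all three hold, no PTC
    is introduced and the event is translatable."""
    if record is None:
        report.fail_reason = report.fail_reason or "no_topology"
        report.verdict_pass = False
        return report
    report.single_pass = record.is_single_pass
    if not report.translatable:
        report.verdict_pass = False
        return report
    wt = reference_protein(template, genome)
    segments = _transfer_segments(record, template, wt, reference_proteins)
    if segments is None:
        report.fail_reason = "topology_not_transferable"
        report.verdict_pass = False
        return report
    interval = report.affected_aa_interval
    if interval is None:
        report.affects_extracellular = False
    else:
        lo, hi = interval
        report.affects_extracellular = any(
            lo <= e and s <= hi
            for kind, s, e in segments
            if kind == SegmentKind.EXTRACELLULAR
        )
    alt_trunc = report.altered_protein.rstrip("*")
    report.tm_intact = all(
        wt[s - 1 : e] in alt_trunc
        for kind, s, e in segments
        if kind == SegmentKind.TRANSMEMBRANE
    )
    report.verdict_pass = bool(
        report.affects_extracellular
        and report.tm_intact
        and not report.ptc_introduced
        and report.single_pass
    )
    if not report.verdict_pass and report.fail_reason is None:
        if not report.single_pass:
            report.fail_reason = "multi_pass_protein"
        elif report.ptc_introduced:
            report.fail_reason = "ptc_introduced"
        elif not report.affects_extracellular:
            report.fail_reason = "extracellular_untouched"
        elif not report.tm_intact:
            report.fail_reason = "tm_disrupted"
    return report


def write_altered_proteins(
    reports: Sequence[ConsequenceReport], path
) -> None:
    """FASTA of predicted altered proteins, termination codons marked
    '*'; non-translatable reports are skipped."""
    with open(path, "w") as fh:
        for rep in reports:
            if not rep.translatable or not rep.altered_protein:
                continue
            fh.write(
                f">{rep.junction_key}|{rep.transcript_id}|"
                f"{rep.pattern.value}\n"
            )
            seq = rep.altered_protein
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def evaluate_junction(
    junction: SpliceJunction,
    templates: Sequence[TranscriptModel],
    genome: Mapping[str, str],
    record: Optional[SurfaceomeRecord],
) -> list[ConsequenceReport]:
    """Consequence reports for one junction on every canonical template.

    Templates the junction falls outside of are reported non-assessable
    rather than raising, so a gene-level verdict can still be formed from
    the remaining templates.
    """
    ref_proteins = {
        t.transcript_id: reference_protein(t, genome)
        for t in templates
        if t.is_coding
    }
    reports = []
    for template in templates:
        try:
            rep = translate_and_flag(junction, template, genome)
        except ValueError as exc:
            rep = ConsequenceReport(
                junction_key=junction.key,
                transcript_id=template.transcript_id,
                pattern=SplicePattern.COMPLEX,
                translatable=False,
                fail_reason=str(exc),
            )
            reports.append(rep)
            continue
        reports.append(
            assess_candidate(rep, record, template, genome, ref_proteins)
        )
    return reports
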