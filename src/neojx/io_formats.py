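"""Readers and writers for the on-disk formats the pipeline touches.

All coordinates are normalized to 1-based inclusive on load. Chromosome
names are stripped of a leading ``chr`` so TCGA/GENCODE-style and
Ensembl-style inputs key identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO

from .types import (
    VALID_CHROMS,
    GeneFootprint,
    SpliceJunction,
    SurfaceomeRecord,
    TranscriptModel,
)

logger = logging.getLogger(__name__)

_SJ_STRAND = {0: ".", 1: "+", 2: "-"}

MANIFEST_COLUMNS = [
    "sample_id",
    "cohort",
    "group",
    "purity",
    "vaf",
    "patient_id",
    "piece_id",
    "timepoint",
]


class SJParseError(ValueError):
    """Raised on a malformed SJ.out.tab row; carries the line number."""


def _norm_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.startswith("chr") else chrom


def read_sj_tab(
    path: str | Path, min_count: int = 1
) -> list[tuple[SpliceJunction, int]]:
    """Parse a STAR ``SJ.out.tab`` file.

    Returns ``(junction, unique_read_count)`` pairs for rows whose
    column-7 uniquely-mapped read count is >= ``min_count``. Strand codes
    0/1/2 map to '.'/'+'/'-'. Rows on chromosomes outside 1-22/X/Y are
    dropped. Column 8 (multi-mapped reads) is ignored.
    """
    out: list[tuple[SpliceJunction, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 7:
                raise SJParseError(
                    f"{path}: line {lineno}: expected >=7 columns, "
                    f"got {len(fields)}"
                )
            try:
                start = int(fields[1])
                end = int(fields[2])
                strand_code = int(fields[3])
                count = int(fields[6])
            except ValueError as exc:
                raise SJParseError(
                    f"{path}: line {lineno}: non-integer field ({exc})"
                ) from None
            chrom = _norm_chrom(fields[0])
            if chrom not in VALID_CHROMS:
                continue
            if count < min_count:
                continue
            strand = _SJ_STRAND.get(strand_code)
            if strand is None:
                raise SJParseError(
                    f"{path}: line {lineno}: invalid strand code {strand_code}"
                )
            out.append((SpliceJunction(chrom, start, end, strand), count))
    return out


def write_sj_tab(
    rows: Iterable[tuple[SpliceJunction, int]], path: str | Path
) -> None:
    """Emit junction counts in the 9-column SJ.out.tab dialect."""
    code = {v: k for k, v in _SJ_STRAND.items()}
    with open(path, "w") as fh:
        for sj, count in rows:
            annotated_col = 0  # STAR's own flag; the pipeline re-derives it
            fh.write(
                f"{sj.chrom}\t{sj.intron_start}\t{sj.intron_end}\t"
                f"{code[sj.strand]}\t0\t{annotated_col}\t{count}\t0\t30\n"
            )


@dataclass
class Annotation:
    """Transcript models plus derived reference-junction set and gene spans."""

    transcripts: dict[str, TranscriptModel]
    reference_junctions: set[SpliceJunction]
    gene_footprints: dict[str, GeneFootprint]
    #: (chrom, start, end) -> set of strands seen in the reference
    _ref_coords: dict[tuple[str, int, int], set[str]] = field(
        default_factory=dict, repr=False
    )

    def __post_init__(self) -> None:
        if not self._ref_coords:
            for j in self.reference_junctions:
                self._ref_coords.setdefault(j.coords(), set()).add(j.strand)

    def is_annotated(self, junction: SpliceJunction) -> bool:
        """Exact coordinate match; strand participates only when both
        the query and the reference entry have a defined strand."""
        strands = self._ref_coords.get(junction.coords())
        if not strands:
            return False
        if junction.strand == ".":
            return True
        return any(s == "." or s == junction.strand for s in strands)

    def coding_templates(self, gene_id: str) -> list[TranscriptModel]:
        """Canonical coding transcripts of a gene, the translation templates."""
        return [
            t
            for t in self.transcripts.values()
            if t.gene_id == gene_id and t.canonical and t.is_coding
        ]


def build_annotation(transcripts: Iterable[TranscriptModel]) -> Annotation:
    """Assemble an :class:`Annotation` from in-memory transcript models."""
    tdict: dict[str, TranscriptModel] = {}
    ref: set[SpliceJunction] = set()
    foot: dict[str, GeneFootprint] = {}
    for t in transcripts:
        if t.transcript_id in tdict:
            raise ValueError(f"duplicate transcript_id {t.transcript_id}")
        tdict[t.transcript_id] = t
        ref.update(t.junctions())
        lo, hi = t.footprint
        fp = foot.get(t.gene_id)
        if fp is None:
            foot[t.gene_id] = GeneFootprint(
                t.gene_id, t.gene_symbol, t.chrom, lo, hi, t.strand
            )
        else:
            fp.start = min(fp.start, lo)
            fp.end = max(fp.end, hi)
    return Annotation(tdict, ref, foot)


def load_annotation(gtf_path: str | Path) -> Annotation:
    """Load an Ensembl-dialect GTF into transcript models.

    Reference junctions are the introns between consecutive exons of every
    transcript (union over transcripts). A transcript is marked canonical
    when its ``tag`` attribute contains ``canonical``; if no transcript in
    the file carries such a tag, every coding transcript is treated as a
    template.
    """
    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        keep_order=True,
    )
    models: list[TranscriptModel] = []
    any_tagged = False
    for tr in db.features_of_type("transcript"):
        tid = tr.attributes["transcript_id"][0]
        gid = tr.attributes["gene_id"][0]
        symbol = (
            tr.attributes.get("gene_name", [gid])[0]
            if tr.attributes.get("gene_name")
            else gid
        )
        exons = [
            (ex.start, ex.end)
            for ex in db.children(tr, featuretype="exon", order_by="start")
        ]
        if not exons:
            continue
        cds = [
            (c.start, c.end)
            for c in db.children(tr, featuretype="CDS", order_by="start")
        ]
        # Ensembl CDS features exclude the stop codon; fold it back in so
        # the internal CDS window always ends on a termination codon
        cds += [
            (c.start, c.end)
            for c in db.children(tr, featuretype="stop_codon")
        ]
        cds_start = min(c[0] for c in cds) if cds else None
        cds_end = max(c[1] for c in cds) if cds else None
        tags = tr.attributes.get("tag", [])
        canonical = any("canonical" in t for t in tags)
        any_tagged = any_tagged or bool(tags)
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gid,
                gene_symbol=symbol,
                chrom=_norm_chrom(tr.seqid),
                strand=tr.strand if tr.strand in "+-" else ".",
                exons=exons,
                cds_start=cds_start,
                cds_end=cds_end,
                canonical=canonical,
            )
        )
    if not any_tagged:
        for m in models:
            m.canonical = m.is_coding
    return build_annotation(models)


def load_genome(fasta_path: str | Path) -> dict[str, str]:
    """Load a (small) genome FASTA into an in-memory chrom -> sequence map."""
    return {
        _norm_chrom(rec.id): str(rec.seq).upper()
        for rec in SeqIO.parse(str(fasta_path), "fasta")
    }


def load_expression(
    path: str | Path, encoding: str = "tpm"
) -> pd.DataFrame:
    """Load a gene x sample expression matrix (TSV, genes as row index).

    ``encoding='log2_tpm_plus_0.001'`` back-transforms Xena-style values:
    each cell x becomes ``2**x - 0.001``, clipped at 0 against round-off.
    """
    if encoding not in ("tpm", "log2_tpm_plus_0.001"):
        raise ValueError(f"unknown expression encoding {encoding!r}")
    mat = pd.read_csv(path, sep="\t", index_col=0)
    if mat.isna().any().any():
        bad = mat.index[mat.isna().any(axis=1)].tolist()
        raise ValueError(f"expression matrix contains NaN for genes: {bad}")
    if encoding == "log2_tpm_plus_0.001":
        mat = (np.power(2.0, mat) - 0.001).clip(lower=0.0)
    if (mat.values < 0).any():
        raise ValueError("expression matrix contains negative TPM values")
    return mat


def load_manifest(path: str | Path) -> pd.DataFrame:
    """Load the sample manifest TSV (one row per sample/piece)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    df["purity"] = pd.to_numeric(df["purity"], errors="coerce")
    df["vaf"] = pd.to_numeric(df["vaf"], errors="coerce")
    if df["sample_id"].duplicated().any():
        raise ValueError("manifest contains duplicate sample ids")
    return df


def gate_samples(
    manifest: pd.DataFrame,
    mode: str = "cohort",
    purity_min: float = 0.6,
    spatial_purity_min: float = 0.5,
    vaf_min: float = 0.25,
) -> pd.DataFrame:
    """Apply tumor-purity gating; normal samples are always retained.

    ``mode='cohort'``: tumor samples need purity >= ``purity_min``.
    ``mode='spatial'``: IDHwt/IDH-O pieces need purity >=
    ``spatial_purity_min``; IDH-A pieces need IDH1-R132 VAF strictly >
    ``vaf_min`` (purity is unreliable for these, so VAF stands in).
    Tumor samples with neither purity nor VAF are excluded with a warning.
    """
    if mode not in ("cohort", "spatial"):
        raise ValueError(f"unknown gating mode {mode!r}")
    is_normal = manifest["cohort"] == "normal"
    unknown = ~is_normal & manifest["purity"].isna() & manifest["vaf"].isna()
    if unknown.any():
        logger.warning(
            "excluding %d tumor samples with unknown purity/VAF: %s",
            unknown.sum(),
            manifest.loc[unknown, "sample_id"].tolist(),
        )
    if mode == "cohort":
        keep_tumor = manifest["purity"] >= purity_min
    else:
        is_idha = manifest["group"] == "IDH-A"
        keep_tumor = np.where(
            is_idha,
            manifest["vaf"] > vaf_min,
            manifest["purity"] >= spatial_purity_min,
        )
    return manifest[is_normal | (~is_normal & keep_tumor & ~unknown)].copy()


def load_surfaceome(path: str | Path) -> dict[str, SurfaceomeRecord]:
    """Load the surfaceome topology table.

    TSV columns: gene_id, gene_symbol, reference_transcript, segments —
    the last a ``kind:start-end`` list joined by ';' in protein
    coordinates of the reference isoform.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, SurfaceomeRecord] = {}
    for row in df.itertuples(index=False):
        segments = []
        for part in row.segments.split(";"):
            kind, span = part.split(":")
            s, e = span.split("-")
            segments.append((kind.strip(), int(s), int(e)))
        rec = SurfaceomeRecord(
            gene_id=row.gene_id,
            gene_symbol=row.gene_symbol,
            reference_transcript=row.reference_transcript,
            segments=segments,
        )
        out[rec.gene_id] = rec
    return out


def write_surfaceome(
    records: Iterable[SurfaceomeRecord], path: str | Path
) -> None:
    rows = []
    for rec in records:
        seg = ";".join(f"{k}:{s}-{e}" for k, s, e in rec.segments)
        rows.append(
            {
                "gene_id": rec.gene_id,
                "gene_symbol": rec.gene_symbol,
                "reference_transcript": rec.reference_transcript,
                "segments": seg,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_candidate_report(
    candidates: pd.DataFrame,
    consequences: pd.DataFrame,
    path: str | Path,
    provenance: Optional[dict] = None,
) -> None:
    """Write the screening report: candidate TSV, consequence TSV and a
    JSON sidecar with run provenance (thresholds, seeds, input digests)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    candidates.to_csv(path, sep="\t", index=False)
    cons_path = path.with_suffix(".consequences.tsv")
    consequences.to_csv(cons_path, sep="\t", index=False)
    sidecar = {
        "n_candidates": int(len(candidates)),
        "n_consequence_rows": int(len(consequences)),
        "provenance": provenance or {},
    }
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)


def read_candidate_report(
    path: str | Path,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    path = Path(path)
    candidates = pd.read_csv(path, sep="\t")
    consequences = pd.read_csv(path.with_suffix(".consequences.tsv"), sep="\t")
    with open(path.with_suffix(".json")) as fh:
        sidecar = json.load(fh)
    return candidates, consequences, sidecar
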