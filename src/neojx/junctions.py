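"""Cohort junction catalog: detection universe, annotation flags, gene
assignment to surfaceome genes."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import pandas as pd
from intervaltree import IntervalTree

from .io_formats import Annotation
from .types import (
    GeneFootprint,
    SpliceJunction,
    SurfaceomeRecord,
    strands_compatible,
)

logger = logging.getLogger(__name__)


@dataclass
class JunctionCatalog:
    """Junction x sample unique-read-count matrix over the detection universe.

    ``counts`` rows are junction keys, columns sample ids; absent
    observations are 0. ``junctions`` maps each key to its parsed form.
    """

    counts: pd.DataFrame
    junctions: dict[str, SpliceJunction]

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative junction counts")

    @property
    def keys(self) -> list[str]:
        return list(self.counts.index)


def resolve_unknown_strands(
    entries: list[tuple[SpliceJunction, int]],
    footprints: Mapping[str, GeneFootprint],
) -> list[tuple[SpliceJunction, int]]:
    """Resolve strand-undetermined junctions from the overlapping gene.

    If all overlapping gene footprints agree on a strand the junction
    adopts it; if they disagree the junction is dropped with a log entry;
    with no overlapping gene it stays undetermined.
    """
    out = []
    for sj, count in entries:
        if sj.strand != ".":
            out.append((sj, count))
            continue
        strands = {
            fp.strand
            for fp in footprints.values()
            if fp.chrom == sj.chrom
            and fp.start <= sj.intron_end
            and sj.intron_start <= fp.end
        }
        strands.discard(".")
        if len(strands) == 1:
            out.append(
                (
                    SpliceJunction(
                        sj.chrom, sj.intron_start, sj.intron_end, strands.pop()
                    ),
                    count,
                )
            )
        elif len(strands) > 1:
            logger.info(
                "dropping strand-undetermined junction %s: overlapping "
                "genes disagree on strand",
                sj.key,
            )
        else:
            out.append((sj, count))
    return out


def build_junction_matrix(
    per_sample_tables: Mapping[str, list[tuple[SpliceJunction, int]]],
    tumor_samples: Iterable[str],
    detection_min_count: int = 10,
    annotation: Optional[Annotation] = None,
) -> JunctionCatalog:
    """Build the cohort count matrix.

    The junction universe is every junction reaching
    ``detection_min_count`` uniquely-mapped reads in at least one *tumor*
    sample; normal-cohort tables never expand the universe. Counts below
    the floor in other samples are still recorded — they feed depth and
    frequency downstream. When an annotation is given, junctions with
    undetermined strand are first resolved against gene strands.
    """
    samples = list(per_sample_tables)
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample id in per-sample tables")
    tumor_samples = set(tumor_samples)
    footprints = annotation.gene_footprints if annotation is not None else None

    cells: dict[str, dict[str, int]] = {}
    junctions: dict[str, SpliceJunction] = {}
    universe: set[str] = set()
    for sample, table in per_sample_tables.items():
        if footprints is not None:
            table = resolve_unknown_strands(table, footprints)
        for sj, count in table:
            key = sj.key
            junctions.setdefault(key, sj)
            cells.setdefault(key, {})[sample] = count
            if sample in tumor_samples and count >= detection_min_count:
                universe.add(key)

    keys = sorted(universe)
    counts = pd.DataFrame(0, index=keys, columns=samples, dtype=int)
    for key in keys:
        for sample, count in cells[key].items():
            counts.at[key, sample] = count
    return JunctionCatalog(counts, {k: junctions[k] for k in keys})


def flag_annotated(
    catalog: JunctionCatalog, annotation: Annotation
) -> pd.Series:
    """Boolean Series (indexed like the catalog): junction is present in
    the reference annotation. Matching is by exact intron coordinates;
    strand participates only when defined on both sides."""
    return pd.Series(
        {k: annotation.is_annotated(sj) for k, sj in catalog.junctions.items()},
        dtype=bool,
    ).reindex(catalog.keys)


@dataclass
class GeneAssignment:
    gene_id: Optional[str]
    ambiguous: bool = False
    candidates: tuple[str, ...] = ()


def assign_gene(
    junction: SpliceJunction,
    footprints: Mapping[str, GeneFootprint],
    surfaceome: Mapping[str, SurfaceomeRecord],
) -> GeneAssignment:
    """Assign a junction to the surfaceome gene whose footprint overlaps
    any portion of the intron interval (strand-compatible).

    With several overlapping surfaceome genes the larger overlap wins; an
    exact tie is reported as ambiguous with both candidates listed.
    """
    overlaps: list[tuple[int, str]] = []
    for gid in surfaceome:
        fp = footprints.get(gid)
        if fp is None:
            continue
        length = fp.overlap_length(junction)
        if length > 0:
            overlaps.append((length, gid))
    if not overlaps:
        return GeneAssignment(None)
    overlaps.sort(key=lambda t: (-t[0], t[1]))
    best_len = overlaps[0][0]
    best = [gid for length, gid in overlaps if length == best_len]
    if len(best) > 1:
        return GeneAssignment(None, ambiguous=True, candidates=tuple(best))
    return GeneAssignment(best[0], candidates=(best[0],))


def assign_genes(
    catalog: JunctionCatalog,
    annotation: Annotation,
    surfaceome: Mapping[str, SurfaceomeRecord],
) -> dict[str, GeneAssignment]:
    """Vectorized gene assignment for every junction in the catalog."""
    trees: dict[str, IntervalTree] = {}
    for gid in surfaceome:
        fp = annotation.gene_footprints.get(gid)
        if fp is None:
            continue
        trees.setdefault(fp.chrom, IntervalTree()).addi(
            fp.start, fp.end + 1, fp
        )
    out: dict[str, GeneAssignment] = {}
    for key, sj in catalog.junctions.items():
        tree = trees.get(sj.chrom)
        if tree is None:
            out[key] = GeneAssignment(None)
            continue
        hits: list[tuple[int, str]] = []
        for iv in tree.overlap(sj.intron_start, sj.intron_end + 1):
            fp: GeneFootprint = iv.data
            if not strands_compatible(fp.strand, sj.strand):
                continue
            hits.append((fp.overlap_length(sj), fp.gene_id))
        hits = [(length, gid) for length, gid in hits if length > 0]
        if not hits:
            out[key] = GeneAssignment(None)
            continue
        hits.sort(key=lambda t: (-t[0], t[1]))
        best_len = hits[0][0]
        best = [gid for length, gid in hits if length == best_len]
        if len(best) > 1:
            out[key] = GeneAssignment(
                None, ambiguous=True, candidates=tuple(best)
            )
        else:
            out[key] = GeneAssignment(best[0], candidates=(best[0],))
    return out
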