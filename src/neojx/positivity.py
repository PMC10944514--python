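"""Per-sample positivity calls and group-level positive sample rates (PSR).

A junction is positive in a sample when its supportive read count, the
read depth at the locus, and the supportive read frequency all clear
cohort-specific thresholds. Depth is the junction count plus the count of
the *most dominant overlapping junction* — the most abundant annotated
junction whose intron intersects the query (fallback: most abundant
overlapping junction of any kind), ranked by total count across the tumor
cohort and reused unchanged for the normal cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .junctions import JunctionCatalog
from .types import SpliceJunction, strands_compatible


@dataclass
class Thresholds:
    """Positivity thresholds; defaults follow the bulk-cohort screen
    (tumor: count >= 10, depth >= 20, frequency >= 1%; normal: 2/10/1%,
    reflecting the smaller normal-tissue library sizes)."""

    tumor_min_count: int = 10
    tumor_min_depth: int = 20
    normal_min_count: int = 2
    normal_min_depth: int = 10
    min_frequency: float = 0.01

    def for_cohort(self, cohort_kind: str) -> tuple[int, int, float]:
        if cohort_kind == "tumor":
            return self.tumor_min_count, self.tumor_min_depth, self.min_frequency
        if cohort_kind == "normal":
            return (
                self.normal_min_count,
                self.normal_min_depth,
                self.min_frequency,
            )
        raise ValueError(f"unknown cohort kind {cohort_kind!r}")


@dataclass
class PositivityCall:
    """One junction x sample evaluation."""

    junction_key: str
    sample_id: str
    count: int
    dominant_count: int
    is_positive: bool

    @property
    def depth(self) -> int:
        return self.count + self.dominant_count

    @property
    def frequency(self) -> Optional[float]:
        return self.count / self.depth if self.depth > 0 else None


def compute_dominants(
    catalog: JunctionCatalog,
    annotated: pd.Series,
    tumor_samples: list[str],
    allow_self: bool = False,
) -> dict[str, Optional[str]]:
    """Most dominant overlapping junction for every catalog junction.

    Overlap means intron-interval intersection on the same chromosome with
    compatible strands. Annotated junctions are preferred; abundance is
    the summed count over the tumor cohort. Ties break on the larger
    total, then the lexicographically smaller key. The query itself is
    excluded unless ``allow_self``; with no overlapping junction the
    result is None (depth then equals the query count).
    """
    totals = catalog.counts[tumor_samples].sum(axis=1)
    trees: dict[str, IntervalTree] = {}
    for key, sj in catalog.junctions.items():
        trees.setdefault(sj.chrom, IntervalTree()).addi(
            sj.intron_start, sj.intron_end + 1, key
        )
    out: dict[str, Optional[str]] = {}
    for key, sj in catalog.junctions.items():
        candidates: list[str] = []
        for iv in trees[sj.chrom].overlap(sj.intron_start, sj.intron_end + 1):
            other_key: str = iv.data
            if other_key == key and not allow_self:
                continue
            other = catalog.junctions[other_key]
            if strands_compatible(sj.strand, other.strand):
                candidates.append(other_key)
        if not candidates:
            out[key] = None
            continue
        annotated_cands = [k for k in candidates if annotated.get(k, False)]
        pool = annotated_cands if annotated_cands else candidates
        out[key] = min(pool, key=lambda k: (-totals[k], k))
    return out


def dominant_overlapping_junction(
    query: str | SpliceJunction,
    catalog: JunctionCatalog,
    annotated: pd.Series,
    tumor_samples: list[str],
    allow_self: bool = False,
) -> Optional[str]:
    """Dominant overlapping junction for a single query (see
    :func:`compute_dominants`)."""
    key = query if isinstance(query, str) else query.key
    if key not in catalog.junctions:
        raise KeyError(f"junction {key} not in catalog")
    return compute_dominants(
        catalog, annotated, tumor_samples, allow_self=allow_self
    )[key]


def evaluate_sample(
    query: str,
    sample_id: str,
    cohort_kind: str,
    catalog: JunctionCatalog,
    dominant: Optional[str],
    thresholds: Thresholds = Thresholds(),
) -> PositivityCall:
    """Scalar positivity call for one junction in one sample."""
    count = int(catalog.counts.at[query, sample_id])
    dom_count = (
        int(catalog.counts.at[dominant, sample_id]) if dominant else 0
    )
    if count < 0 or dom_count < 0:
        raise ValueError("negative junction counts")
    min_count, min_depth, min_freq = thresholds.for_cohort(cohort_kind)
    depth = count + dom_count
    positive = (
        depth > 0
        and count >= min_count
        and depth >= min_depth
        and count / depth >= min_freq
    )
    return PositivityCall(query, sample_id, count, dom_count, positive)


@dataclass
class PositivityResult:
    """Vectorized calls for the whole catalog: aligned junction x sample
    frames of counts, dominant counts, depth, frequency and the boolean
    positivity matrix."""

    counts: pd.DataFrame
    dominant_counts: pd.DataFrame
    positive: pd.DataFrame
    dominants: dict[str, Optional[str]] = field(default_factory=dict)

    @property
    def depth(self) -> pd.DataFrame:
        return self.counts + self.dominant_counts

    @property
    def frequency(self) -> pd.DataFrame:
        depth = self.depth
        return self.counts.div(depth.where(depth > 0))


def call_positivity(
    catalog: JunctionCatalog,
    dominants: Mapping[str, Optional[str]],
    manifest: pd.DataFrame,
    thresholds: Thresholds = Thresholds(),
) -> PositivityResult:
    """Positivity calls for every junction x sample in one pass.

    Tumor and normal columns are evaluated under their respective
    thresholds; the dominant junction chosen on the tumor cohort is used
    for both.
    """
    counts = catalog.counts
    samples = [s for s in manifest["sample_id"] if s in counts.columns]
    counts = counts[samples]
    dom_rows = np.zeros(counts.shape, dtype=int)
    key_pos = {k: i for i, k in enumerate(counts.index)}
    for key, dom in dominants.items():
        if dom is not None and key in key_pos:
            dom_rows[key_pos[key]] = counts.loc[dom].values
    dominant_counts = pd.DataFrame(
        dom_rows, index=counts.index, columns=counts.columns
    )
    depth = counts + dominant_counts
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = counts.values / np.where(depth.values > 0, depth.values, np.nan)

    cohort = manifest.set_index("sample_id")["cohort"].reindex(samples)
    is_tumor = (cohort == "tumor").values
    min_count = np.where(
        is_tumor, thresholds.tumor_min_count, thresholds.normal_min_count
    )
    min_depth = np.where(
        is_tumor, thresholds.tumor_min_depth, thresholds.normal_min_depth
    )
    positive = (
        (counts.values >= min_count)
        & (depth.values >= min_depth)
        & (np.nan_to_num(freq, nan=-1.0) >= thresholds.min_frequency)
    )
    return PositivityResult(
        counts=counts,
        dominant_counts=dominant_counts,
        positive=pd.DataFrame(
            positive, index=counts.index, columns=counts.columns
        ),
        dominants=dict(dominants),
    )


def positive_sample_rate(
    positive: pd.DataFrame,
    manifest: pd.DataFrame,
    normal_label: str = "normal_pooled",
    per_tissue: bool = False,
) -> pd.DataFrame:
    """Group-level positive sample rates.

    One column per tumor disease group plus a pooled-normal column (and,
    optionally, one per normal tissue type). Denominators are the *full*
    group sizes from the manifest, not per-junction callable samples.
    """
    manifest = manifest[manifest["sample_id"].isin(positive.columns)]
    out: dict[str, pd.Series] = {}
    tumors = manifest[manifest["cohort"] == "tumor"]
    for group, sub in tumors.groupby("group", sort=True):
        ids = sub["sample_id"].tolist()
        if not ids:
            raise ValueError(f"empty group {group}")
        out[str(group)] = positive[ids].sum(axis=1) / len(ids)
    normals = manifest[manifest["cohort"] == "normal"]
    if len(normals):
        ids = normals["sample_id"].tolist()
        out[normal_label] = positive[ids].sum(axis=1) / len(ids)
        if per_tissue:
            for tissue, sub in normals.groupby("group", sort=True):
                tids = sub["sample_id"].tolist()
                out[f"normal:{tissue}"] = positive[tids].sum(axis=1) / len(
                    tids
                )
    return pd.DataFrame(out)
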