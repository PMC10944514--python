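"""Positivity calls: dominant-junction selection, threshold boundaries,
vectorized-vs-brute-force equivalence, and PSR arithmetic."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from neojx.junctions import JunctionCatalog
from neojx.positivity import (
    Thresholds,
    call_positivity,
    compute_dominants,
    dominant_overlapping_junction,
    evaluate_sample,
    positive_sample_rate,
)
from neojx.types import SpliceJunction, strands_compatible


def _catalog(rows, samples):
    """rows: {key: {sample: count}}; junction parsed from key."""
    counts = pd.DataFrame(0, index=list(rows), columns=samples, dtype=int)
    for k, cells in rows.items():
        for s, c in cells.items():
            counts.loc[k, s] = c
    return JunctionCatalog(
        counts, {k: SpliceJunction.from_key(k) for k in rows}
    )


def _manifest(tumor, normal):
    rows = [
        {"sample_id": s, "cohort": "tumor", "group": "IDHwt"} for s in tumor
    ] + [{"sample_id": s, "cohort": "normal", "group": "brain"} for s in normal]
    df = pd.DataFrame(rows)
    for col in ("purity", "vaf", "patient_id", "piece_id", "timepoint"):
        df[col] = None
    return df


# ---------------------------------------------------------------------------
# dominant overlapping junction


def test_dominant_prefers_annotated_over_more_abundant_novel():
    cat = _catalog(
        {
            "1:100-200:+": {"t": 50},  # query
            "1:150-400:+": {"t": 500},  # annotated A
            "1:120-300:+": {"t": 900},  # annotated B (most abundant annotated)
            "1:90-500:+": {"t": 2000},  # novel C, most abundant overall
        },
        ["t"],
    )
    annotated = pd.Series(
        {"1:100-200:+": False, "1:150-400:+": True,
         "1:120-300:+": True, "1:90-500:+": False}
    )
    dom = dominant_overlapping_junction("1:100-200:+", cat, annotated, ["t"])
    assert dom == "1:120-300:+"


def test_dominant_falls_back_to_most_abundant_novel():
    cat = _catalog(
        {
            "1:100-200:+": {"t": 50},
            "1:90-500:+": {"t": 2000},
            "1:150-220:+": {"t": 100},
        },
        ["t"],
    )
    annotated = pd.Series(False, index=cat.keys)
    dom = dominant_overlapping_junction("1:100-200:+", cat, annotated, ["t"])
    assert dom == "1:90-500:+"


def test_isolated_junction_has_no_dominant_and_frequency_one():
    cat = _catalog({"1:100-200:+": {"t": 25}}, ["t"])
    annotated = pd.Series(False, index=cat.keys)
    dom = dominant_overlapping_junction("1:100-200:+", cat, annotated, ["t"])
    assert dom is None
    call = evaluate_sample("1:100-200:+", "t", "tumor", cat, dom)
    assert call.depth == 25 and call.frequency == 1.0 and call.is_positive


def test_query_excluded_unless_allow_self():
    cat = _catalog(
        {"1:100-200:+": {"t": 5000}, "1:150-300:+": {"t": 10}}, ["t"]
    )
    annotated = pd.Series(False, index=cat.keys)
    assert (
        dominant_overlapping_junction("1:100-200:+", cat, annotated, ["t"])
        == "1:150-300:+"
    )
    assert (
        dominant_overlapping_junction(
            "1:100-200:+", cat, annotated, ["t"], allow_self=True
        )
        == "1:100-200:+"
    )


# ---------------------------------------------------------------------------
# threshold boundaries


@pytest.mark.parametrize(
    "cohort,count,dom,expected",
    [
        # tumor: all three thresholds exactly met
        ("tumor", 10, 10, True),
        ("tumor", 9, 11, False),  # count below 10
        ("tumor", 10, 9, False),  # depth 19 below 20
        ("tumor", 15, 2000, False),  # frequency 15/2015 ~ 0.0074 < 0.01
        # normal: boundaries 2 / 10 / 0.01
        ("normal", 2, 8, True),
        ("normal", 1, 9, False),
        ("normal", 2, 7, False),  # depth 9
    ],
)
def test_positivity_boundaries(cohort, count, dom, expected):
    cat = _catalog(
        {"1:100-200:+": {"s": count}, "1:150-400:+": {"s": dom}}, ["s"]
    )
    call = evaluate_sample(
        "1:100-200:+", "s", cohort, cat, "1:150-400:+", Thresholds()
    )
    assert call.is_positive is expected
    assert call.depth == count + dom


def test_zero_depth_is_negative():
    cat = _catalog({"1:100-200:+": {"s": 0}}, ["s"])
    call = evaluate_sample("1:100-200:+", "s", "tumor", cat, None)
    assert not call.is_positive and call.frequency is None


# ---------------------------------------------------------------------------
# vectorized implementation vs brute-force oracle


def _brute_force(cat, annotated, manifest, thresholds):
    """Per-pair re-implementation: O(n^2) overlap scan, explicit
    per-sample threshold checks."""
    tumor = manifest.loc[manifest.cohort == "tumor", "sample_id"].tolist()
    totals = {k: int(cat.counts.loc[k, tumor].sum()) for k in cat.keys}
    out = {}
    for k, sj in cat.junctions.items():
        overl = [
            k2
            for k2, sj2 in cat.junctions.items()
            if k2 != k
            and sj.chrom == sj2.chrom
            and strands_compatible(sj.strand, sj2.strand)
            and sj.intron_start <= sj2.intron_end
            and sj2.intron_start <= sj.intron_end
        ]
        ann = [k2 for k2 in overl if annotated[k2]]
        pool = ann if ann else overl
        dom = min(pool, key=lambda x: (-totals[x], x)) if pool else None
        for _, row in manifest.iterrows():
            s = row["sample_id"]
            c = int(cat.counts.loc[k, s])
            d = int(cat.counts.loc[dom, s]) if dom else 0
            depth = c + d
            if row["cohort"] == "tumor":
                mc, md = thresholds.tumor_min_count, thresholds.tumor_min_depth
            else:
                mc, md = (
                    thresholds.normal_min_count,
                    thresholds.normal_min_depth,
                )
            pos = (
                depth > 0
                and c >= mc
                and depth >= md
                and c / depth >= thresholds.min_frequency
            )
            out[(k, s)] = pos
    return out


def _random_catalog(rng, n_junctions, samples):
    rows = {}
    for _ in range(n_junctions):
        chrom = str(rng.integers(1, 3))
        s = int(rng.integers(1, 3000))
        e = s + int(rng.integers(20, 400))
        strand = rng.choice(["+", "-"])
        key = f"{chrom}:{s}-{e}:{strand}"
        rows[key] = {
            smp: int(c)
            for smp, c in zip(samples, rng.poisson(8, len(samples)))
            if c > 0
        }
    return _catalog(rows, samples)


@pytest.mark.parametrize("seed", range(5))
def test_vectorized_equals_brute_force(seed):
    rng = np.random.default_rng(seed)
    samples = [f"t{i}" for i in range(6)] + [f"n{i}" for i in range(4)]
    manifest = _manifest(samples[:6], samples[6:])
    cat = _random_catalog(rng, 40, samples)
    annotated = pd.Series(
        rng.random(len(cat.keys)) < 0.5, index=cat.keys
    )
    thresholds = Thresholds(tumor_min_count=5, tumor_min_depth=10)
    doms = compute_dominants(cat, annotated, samples[:6])
    result = call_positivity(cat, doms, manifest, thresholds)
    brute = _brute_force(cat, annotated, manifest, thresholds)
    for (k, s), expected in brute.items():
        assert bool(result.positive.loc[k, s]) == expected, (k, s)


def test_dominance_computed_on_tumor_reused_for_normal():
    """The dominant junction is chosen from tumor-cohort totals even when
    a normal sample would rank the locus differently."""
    cat = _catalog(
        {
            "1:100-200:+": {"t": 50, "n": 50},
            "1:150-400:+": {"t": 900, "n": 1},  # tumor-dominant
            "1:120-300:+": {"t": 100, "n": 900},  # normal-dominant
        },
        ["t", "n"],
    )
    annotated = pd.Series(
        {"1:100-200:+": False, "1:150-400:+": True, "1:120-300:+": True}
    )
    manifest = _manifest(["t"], ["n"])
    doms = compute_dominants(cat, annotated, ["t"])
    assert doms["1:100-200:+"] == "1:150-400:+"
    res = call_positivity(cat, doms, manifest, Thresholds())
    # normal-sample depth uses the tumor-selected dominant (count 1)
    assert res.dominant_counts.loc["1:100-200:+", "n"] == 1


# ---------------------------------------------------------------------------
# positive sample rate


def test_psr_division_and_denominators():
    tumor = [f"t{i}" for i in range(123)]
    manifest = _manifest(tumor, ["n0"])
    positive = pd.DataFrame(
        [[i < 52 for i in range(123)] + [False]],
        index=["j"],
        columns=tumor + ["n0"],
    )
    psr = positive_sample_rate(positive, manifest)
    assert psr.loc["j", "IDHwt"] == pytest.approx(52 / 123)
    assert round(100 * psr.loc["j", "IDHwt"], 1) == 42.3
    assert psr.loc["j", "normal_pooled"] == 0.0


def test_psr_extremes_and_group_of_one():
    manifest = _manifest(["t0"], [])
    positive = pd.DataFrame([[True]], index=["j"], columns=["t0"])
    psr = positive_sample_rate(positive, manifest)
    assert psr.loc["j", "IDHwt"] == 1.0
    positive.loc["j", "t0"] = False
    assert positive_sample_rate(positive, manifest).loc["j", "IDHwt"] == 0.0


def test_psr_full_group_size_denominator():
    """Samples without the junction called still count in the denominator."""
    tumor = [f"t{i}" for i in range(10)]
    manifest = _manifest(tumor, [])
    positive = pd.DataFrame(
        [[True] * 3 + [False] * 7], index=["j"], columns=tumor
    )
    assert positive_sample_rate(positive, manifest).loc["j", "IDHwt"] == 0.3


def test_psr_monotone_in_sample_positivity():
    """Raising a negative sample's count above every threshold never
    lowers the PSR."""
    samples = [f"t{i}" for i in range(8)]
    manifest = _manifest(samples, [])
    rows = {"1:100-200:+": {s: 3 for s in samples}}
    cat = _catalog(rows, samples)
    annotated = pd.Series(False, index=cat.keys)
    doms = compute_dominants(cat, annotated, samples)
    before = positive_sample_rate(
        call_positivity(cat, doms, manifest).positive, manifest
    ).loc["1:100-200:+", "IDHwt"]
    cat.counts.loc["1:100-200:+", "t0"] = 50
    after = positive_sample_rate(
        call_positivity(cat, doms, manifest).positive, manifest
    ).loc["1:100-200:+", "IDHwt"]
    assert after >= before
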