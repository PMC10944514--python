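"""The eight-stage screening cascade, from the junction detection
universe to the final candidate list.

Stages: (1) detection in the tumor cohort; (2) exclusion of annotated
junctions; (3) restriction to expressed surfaceome genes; (4) tumor
specificity against the pooled normal cohort; (5) sharedness across
disease groups; (6) extracellular impact; (7) protein compatibility
(in-frame, no PTC, transmembrane segment intact, single-pass host);
(8) a machine-readable manual-exclusion list. Every dropped junction
carries exactly one first-failure stage, and the per-stage survivor
ledger is non-increasing by construction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from . import io_formats
from .consequence import evaluate_junction, write_altered_proteins
from .io_formats import Annotation
from .junctions import (
    GeneAssignment,
    JunctionCatalog,
    assign_genes,
    build_junction_matrix,
    flag_annotated,
)
from .positivity import (
    PositivityResult,
    Thresholds,
    call_positivity,
    compute_dominants,
    positive_sample_rate,
)
from .types import ConsequenceReport, SurfaceomeRecord

logger = logging.getLogger(__name__)

STAGES = [
    "detected",
    "non_annotated",
    "surfaceome_expressed",
    "tumor_specific",
    "shared",
    "extracellular",
    "protein_compatible",
    "final",
]

NORMAL_PSR_COLUMN = "normal_pooled"


@dataclass
class ScreenConfig:
    """Inputs and thresholds for one screening run (YAML-serializable)."""

    sj_dir: Optional[str] = None
    gtf: Optional[str] = None
    fasta: Optional[str] = None
    expression: Optional[str] = None
    expression_encoding: str = "tpm"
    surfaceome: Optional[str] = None
    manifest: Optional[str] = None
    out: Optional[str] = None

    detection_min_count: int = 10
    purity_min: float = 0.6
    min_mean_tpm: float = 10.0
    max_normal_psr: float = 0.01
    min_group_psr: float = 0.10
    expression_statistic: str = "mean"  # or "median"
    per_tissue_normal_gate: bool = False
    allow_self_dominant: bool = False
    thresholds: Thresholds = field(default_factory=Thresholds)
    #: junction keys removed at the manual-review stage
    exclusion_list: list[str] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScreenConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        thr = Thresholds(**raw.pop("thresholds", {}))
        return cls(thresholds=thr, **raw)

    def to_dict(self) -> dict:
        d = {**self.__dict__}
        d["thresholds"] = {**self.thresholds.__dict__}
        return d


@dataclass
class ScreenResult:
    ledger: dict[str, int]
    candidates: pd.DataFrame
    consequences: pd.DataFrame
    first_failure: pd.Series
    psr: pd.DataFrame
    positivity: PositivityResult
    reports: dict[str, list[ConsequenceReport]] = field(default_factory=dict)

    @property
    def final_keys(self) -> list[str]:
        return self.candidates.loc[
            self.candidates["final"], "junction_key"
        ].tolist()


def filter_expression_surfaceome(
    keys: Sequence[str],
    assignments: Mapping[str, GeneAssignment],
    expression: pd.DataFrame,
    surfaceome: Mapping[str, SurfaceomeRecord],
    tumor_samples: Sequence[str],
    min_mean_tpm: float = 10.0,
    statistic: str = "mean",
) -> pd.Series:
    """Keep junctions assigned to a surfaceome gene whose average TPM in
    the tumor cohort clears ``min_mean_tpm`` (inclusive)."""
    cols = [s for s in tumor_samples if s in expression.columns]
    stats = (
        expression[cols].mean(axis=1)
        if statistic == "mean"
        else expression[cols].median(axis=1)
    )
    out = {}
    for key in keys:
        asg = assignments.get(key, GeneAssignment(None))
        gid = asg.gene_id
        if gid is None or gid not in surfaceome:
            out[key] = False
        elif gid not in stats.index:
            logger.warning("gene %s missing from expression matrix", gid)
            out[key] = False
        else:
            out[key] = bool(stats[gid] >= min_mean_tpm)
    return pd.Series(out, dtype=bool)


def filter_tumor_specific(
    keys: Sequence[str], psr: pd.DataFrame, max_normal_psr: float = 0.01
) -> pd.Series:
    """Keep junctions whose pooled-normal PSR is strictly below the cap."""
    return psr.loc[list(keys), NORMAL_PSR_COLUMN] < max_normal_psr


def filter_shared(
    keys: Sequence[str],
    psr: pd.DataFrame,
    group_columns: Sequence[str],
    min_group_psr: float = 0.10,
) -> pd.Series:
    """Keep junctions reaching ``min_group_psr`` (inclusive) in at least
    one tumor disease group."""
    return psr.loc[list(keys), list(group_columns)].max(axis=1) >= min_group_psr


def filter_extracellular(
    reports: Mapping[str, list[ConsequenceReport]],
    surfaceome_by_key: Mapping[str, Optional[SurfaceomeRecord]],
) -> pd.Series:
    """Combined protein-level gate: single-pass host and at least one
    canonical template with an extracellular alteration, no PTC and an
    intact transmembrane segment."""
    out = {}
    for key, reps in reports.items():
        rec = surfaceome_by_key.get(key)
        single = rec is not None and rec.is_single_pass
        out[key] = bool(single and any(r.verdict_pass for r in reps))
    return pd.Series(out, dtype=bool)


def screen_cohort(
    catalog: JunctionCatalog,
    annotation: Annotation,
    genome: Mapping[str, str],
    expression: pd.DataFrame,
    surfaceome: Mapping[str, SurfaceomeRecord],
    manifest: pd.DataFrame,
    config: Optional[ScreenConfig] = None,
) -> ScreenResult:
    """Run stages 1-8 on an in-memory cohort and return the ledger, the
    per-junction stage flags and the consequence reports."""
    config = config or ScreenConfig()
    thresholds = config.thresholds
    tumor_samples = manifest.loc[
        manifest["cohort"] == "tumor", "sample_id"
    ].tolist()
    group_columns = sorted(
        manifest.loc[manifest["cohort"] == "tumor", "group"].unique()
    )

    ledger: dict[str, int] = {}
    first_failure: dict[str, str] = {}
    keys = list(catalog.keys)
    ledger["detected"] = len(keys)

    # stage 2: non-annotated
    annotated = flag_annotated(catalog, annotation)
    survivors = [k for k in keys if not annotated[k]]
    for k in keys:
        if annotated[k]:
            first_failure[k] = "non_annotated"
    ledger["non_annotated"] = len(survivors)

    # stage 3: expressed surfaceome genes
    assignments = assign_genes(catalog, annotation, surfaceome)
    for k, asg in assignments.items():
        if asg.ambiguous:
            logger.warning(
                "junction %s overlaps several surfaceome genes equally: %s",
                k,
                asg.candidates,
            )
    expr_pass = filter_expression_surfaceome(
        survivors,
        assignments,
        expression,
        surfaceome,
        tumor_samples,
        config.min_mean_tpm,
        config.expression_statistic,
    )
    new_survivors = [k for k in survivors if expr_pass[k]]
    for k in survivors:
        if not expr_pass[k]:
            first_failure[k] = "surfaceome_expressed"
    survivors = new_survivors
    ledger["surfaceome_expressed"] = len(survivors)

    # positivity is computed on the full catalog: dominant-junction
    # selection needs annotated neighbours that stage 2 removed
    dominants = compute_dominants(
        catalog, annotated, tumor_samples, allow_self=config.allow_self_dominant
    )
    positivity = call_positivity(catalog, dominants, manifest, thresholds)
    psr = positive_sample_rate(
        positivity.positive,
        manifest,
        normal_label=NORMAL_PSR_COLUMN,
        per_tissue=config.per_tissue_normal_gate,
    )

    # stage 4: tumor-specific
    if survivors:
        spec_pass = filter_tumor_specific(
            survivors, psr, config.max_normal_psr
        )
        if config.per_tissue_normal_gate:
            tissue_cols = [c for c in psr.columns if c.startswith("normal:")]
            if tissue_cols:
                spec_pass &= (
                    psr.loc[survivors, tissue_cols] < config.max_normal_psr
                ).all(axis=1)
        new_survivors = [k for k in survivors if spec_pass[k]]
        for k in survivors:
            if not spec_pass[k]:
                first_failure[k] = "tumor_specific"
        survivors = new_survivors
    ledger["tumor_specific"] = len(survivors)

    # stage 5: shared
    if survivors:
        shared_pass = filter_shared(
            survivors, psr, group_columns, config.min_group_psr
        )
        new_survivors = [k for k in survivors if shared_pass[k]]
        for k in survivors:
            if not shared_pass[k]:
                first_failure[k] = "shared"
        survivors = new_survivors
    ledger["shared"] = len(survivors)

    # stages 6-7: consequence prediction on canonical templates
    reports: dict[str, list[ConsequenceReport]] = {}
    stage6: list[str] = []
    for k in survivors:
        gid = assignments[k].gene_id
        templates = annotation.coding_templates(gid) if gid else []
        if not templates:
            logger.warning("no canonical template for junction %s", k)
            first_failure[k] = "extracellular"
            reports[k] = []
            continue
        reps = evaluate_junction(
            catalog.junctions[k], templates, genome, surfaceome.get(gid)
        )
        reports[k] = reps
        if any(r.affects_extracellular for r in reps):
            stage6.append(k)
        else:
            first_failure[k] = "extracellular"
    survivors = stage6
    ledger["extracellular"] = len(survivors)

    stage7: list[str] = []
    for k in survivors:
        rec = surfaceome.get(assignments[k].gene_id)
        single = rec is not None and rec.is_single_pass
        if single and any(r.verdict_pass for r in reports[k]):
            stage7.append(k)
        else:
            first_failure[k] = "protein_compatible"
    survivors = stage7
    ledger["protein_compatible"] = len(survivors)

    # stage 8: manual-review exclusion list
    excluded = set(config.exclusion_list)
    final = [k for k in survivors if k not in excluded]
    for k in survivors:
        if k in excluded:
            first_failure[k] = "final"
    ledger["final"] = len(final)
    final_set = set(final)

    # assemble candidate table over all non-annotated junctions
    rows = []
    cons_rows = []
    for k in keys:
        asg = assignments.get(k, GeneAssignment(None))
        gid = asg.gene_id
        reps = reports.get(k, [])
        pattern = next(
            (r.pattern.value for r in reps if r.verdict_pass),
            reps[0].pattern.value if reps else None,
        )
        row = {
            "junction_key": k,
            "gene_id": gid,
            "gene_symbol": (
                annotation.gene_footprints[gid].gene_symbol if gid else None
            ),
            "ambiguous_gene": asg.ambiguous,
            "pattern": pattern,
            "first_failure": first_failure.get(k, "pass"),
            "final": k in final_set,
        }
        for g in group_columns:
            row[f"psr_{g}"] = float(psr.at[k, g])
        row["psr_normal"] = float(psr.at[k, NORMAL_PSR_COLUMN])
        stage_reached = True
        for stage in STAGES[1:]:
            stage_reached = stage_reached and first_failure.get(k) != stage
            row[f"pass_{stage}"] = stage_reached
        rows.append(row)
        for r in reps:
            cons_rows.append(
                {
                    "junction_key": r.junction_key,
                    "transcript_id": r.transcript_id,
                    "pattern": r.pattern.value,
                    "translatable": r.translatable,
                    "frame_status": (
                        r.frame_status.value if r.frame_status else None
                    ),
                    "nt_delta": r.nt_delta,
                    "aa_deleted": r.aa_deleted,
                    "aa_inserted": r.aa_inserted,
                    "ptc_introduced": r.ptc_introduced,
                    "affects_extracellular": r.affects_extracellular,
                    "tm_intact": r.tm_intact,
                    "single_pass": r.single_pass,
                    "verdict_pass": r.verdict_pass,
                    "fail_reason": r.fail_reason,
                }
            )
    candidates = pd.DataFrame(rows)
    consequences = pd.DataFrame(
        cons_rows,
        columns=[
            "junction_key",
            "transcript_id",
            "pattern",
            "translatable",
            "frame_status",
            "nt_delta",
            "aa_deleted",
            "aa_inserted",
            "ptc_introduced",
            "affects_extracellular",
            "tm_intact",
            "single_pass",
            "verdict_pass",
            "fail_reason",
        ],
    )
    return ScreenResult(
        ledger=ledger,
        candidates=candidates,
        consequences=consequences,
        first_failure=pd.Series(first_failure, dtype=object),
        psr=psr,
        positivity=positivity,
        reports=reports,
    )


def run_screen(config: ScreenConfig) -> ScreenResult:
    """Load every input named in the config, run the cascade, and (when
    ``config.out`` is set) write the candidate report and stage ledger."""
    for attr in ("sj_dir", "gtf", "fasta", "expression", "surfaceome",
                 "manifest"):
        if getattr(config, attr) is None:
            raise ValueError(f"config.{attr} is required for run_screen")
    annotation = io_formats.load_annotation(config.gtf)
    genome = io_formats.load_genome(config.fasta)
    expression = io_formats.load_expression(
        config.expression, config.expression_encoding
    )
    surfaceome = io_formats.load_surfaceome(config.surfaceome)
    manifest = io_formats.load_manifest(config.manifest)
    manifest = io_formats.gate_samples(
        manifest, mode="cohort", purity_min=config.purity_min
    )
    tables = {}
    for path in sorted(Path(config.sj_dir).glob("*.SJ.out.tab")):
        sample_id = path.name[: -len(".SJ.out.tab")]
        tables[sample_id] = io_formats.read_sj_tab(path)
    tables = {
        s: t
        for s, t in tables.items()
        if s in set(manifest["sample_id"])
    }
    tumor_samples = manifest.loc[
        manifest["cohort"] == "tumor", "sample_id"
    ].tolist()
    catalog = build_junction_matrix(
        tables,
        tumor_samples,
        detection_min_count=config.detection_min_count,
        annotation=annotation,
    )
    result = screen_cohort(
        catalog, annotation, genome, expression, surfaceome, manifest, config
    )
    if config.out:
        out = Path(config.out)
        out.mkdir(parents=True, exist_ok=True)
        io_formats.write_candidate_report(
            result.candidates,
            result.consequences,
            out / "candidates.tsv",
            provenance={"config": config.to_dict(), "ledger": result.ledger},
        )
        with open(out / "ledger.json", "w") as fh:
            json.dump(result.ledger, fh, indent=2)
        final_reports = [
            r for k in result.final_keys for r in result.reports.get(k, [])
        ]
        write_altered_proteins(final_reports, out / "altered_proteins.fa")
    return result
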