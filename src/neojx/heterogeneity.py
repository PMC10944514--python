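"""Spatial (multi-region) and longitudinal (primary/recurrent) positivity
summaries for candidate events.

Inputs are an event x sample boolean positivity matrix (tumor thresholds)
and a manifest carrying patient/piece/timepoint columns; pieces are
expected to be purity-gated upstream (see
:func:`neojx.io_formats.gate_samples` with ``mode='spatial'``).
"""

from __future__ import annotations

import logging

import pandas as pd

logger = logging.getLogger(__name__)

LONGITUDINAL_STATUSES = ["shared", "primary_only", "recurrent_only", "absent"]


def spatial_summary(
    positive: pd.DataFrame, manifest: pd.DataFrame
) -> pd.DataFrame:
    """Per (tumor, event) positive-piece fractions.

    ``tumor_wide`` is True only for events positive in 100% of a tumor's
    gated pieces. Tumors with no gated pieces in the call matrix are
    omitted with a warning.
    """
    rows = []
    for patient, sub in manifest.groupby("patient_id", sort=True):
        pieces = [s for s in sub["sample_id"] if s in positive.columns]
        if not pieces:
            logger.warning("tumor %s has no gated pieces; omitted", patient)
            continue
        calls = positive[pieces]
        n_pos = calls.sum(axis=1)
        for event in positive.index:
            n = len(pieces)
            k = int(n_pos[event])
            rows.append(
                {
                    "tumor_id": patient,
                    "event": event,
                    "n_pieces": n,
                    "n_positive": k,
                    "fraction": k / n,
                    "tumor_wide": k == n,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "tumor_id",
            "event",
            "n_pieces",
            "n_positive",
            "fraction",
            "tumor_wide",
        ],
    )


def _timepoint_positive(
    positive_row: pd.Series, pieces: list[str], piece_majority: float
) -> bool:
    """A timepoint is positive when the fraction of positive pieces
    reaches ``piece_majority`` (inclusive); a single-piece timepoint is
    that piece's call."""
    calls = positive_row[pieces]
    return bool(calls.sum() / len(pieces) >= piece_majority)


def longitudinal_classify(
    positive: pd.DataFrame,
    manifest: pd.DataFrame,
    piece_majority: float = 0.5,
) -> pd.DataFrame:
    """Per (patient, event) primary/recurrent status.

    Status is the truth table of the two timepoint calls: shared,
    primary_only, recurrent_only or absent. Patients missing either
    timepoint are omitted with a warning.
    """
    rows = []
    for patient, sub in manifest.groupby("patient_id", sort=True):
        tp_pieces: dict[str, list[str]] = {}
        for tp in ("primary", "recurrent"):
            tp_pieces[tp] = [
                s
                for s in sub.loc[sub["timepoint"] == tp, "sample_id"]
                if s in positive.columns
            ]
        if not tp_pieces["primary"] or not tp_pieces["recurrent"]:
            logger.warning(
                "patient %s lacks a complete primary/recurrent pair; omitted",
                patient,
            )
            continue
        for event in positive.index:
            row = positive.loc[event]
            prim = _timepoint_positive(
                row, tp_pieces["primary"], piece_majority
            )
            rec = _timepoint_positive(
                row, tp_pieces["recurrent"], piece_majority
            )
            if prim and rec:
                status = "shared"
            elif prim:
                status = "primary_only"
            elif rec:
                status = "recurrent_only"
            else:
                status = "absent"
            rows.append(
                {
                    "patient_id": patient,
                    "event": event,
                    "primary_positive": prim,
                    "recurrent_positive": rec,
                    "status": status,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "event",
            "primary_positive",
            "recurrent_positive",
            "status",
        ],
    )
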