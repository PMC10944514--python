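"""Shared fixtures: a deterministic synthetic reference/cohort and one
fully screened result reused across test modules."""

from __future__ import annotations

import pytest

from neojx.junctions import build_junction_matrix
from neojx.screening import screen_cohort
from neojx.simulate import generate_reference, simulate_cohort

FIXTURE_SEED = 11


@pytest.fixture(scope="session")
def reference():
    return generate_reference(FIXTURE_SEED)


@pytest.fixture(scope="session")
def cohort(reference):
    return simulate_cohort(FIXTURE_SEED, reference)


@pytest.fixture(scope="session")
def catalog(reference, cohort):
    tumor = cohort.manifest.loc[
        cohort.manifest["cohort"] == "tumor", "sample_id"
    ].tolist()
    return build_junction_matrix(
        cohort.sj_tables, tumor, annotation=reference.annotation
    )


@pytest.fixture(scope="session")
def screen_result(reference, cohort, catalog):
    return screen_cohort(
        catalog,
        reference.annotation,
        reference.genome,
        cohort.expression,
        reference.surfaceome,
        cohort.manifest,
    )
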