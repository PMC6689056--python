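"""Shared fixtures: synthetic references and a clean end-to-end simulation."""

from __future__ import annotations

import pytest

from scbcr.pipeline import PipelineConfig, run_pipeline
from scbcr.simulate import (
    SimConfig,
    make_germline_reference,
    simulate_reads,
    simulate_repertoire,
    write_fastq_pair,
)


@pytest.fixture(scope="session")
def ref_h():
    return make_germline_reference(20, 4, "H", seed=1)


@pytest.fixture(scope="session")
def ref_l():
    return make_germline_reference(20, 4, "K", seed=2)


@pytest.fixture(scope="session")
def ref(ref_h, ref_l):
    return ref_h.merged(ref_l)


@pytest.fixture(scope="session")
def big_ref_h():
    """50-gene heavy reference at 0.70-0.95 identity (benchmark scale)."""
    return make_germline_reference(50, 6, "H", seed=11)


@pytest.fixture(scope="session")
def clean_sim(ref_h, ref_l, ref, tmp_path_factory):
    """A clean 200-cell simulation run end to end through the pipeline.

    No sequencing errors and no somatic mutation, with a 2% ambient-read
    fraction; every stage of the pipeline should be exact on this input.
    """
    config = SimConfig(
        n_cells=200,
        n_lineages=50,
        shm_rate=0.0,
        sequencing_error_rate=0.0,
        ambient_barcode_fraction=0.02,
        seed=5,
    )
    cells, lineage_table = simulate_repertoire(ref_h, ref_l, config)
    records = simulate_reads(cells, config)
    prefix = tmp_path_factory.mktemp("clean_sim") / "sim"
    p1, p2 = write_fastq_pair(records, prefix)
    result = run_pipeline(p1, p2, ref, PipelineConfig(targeted_cells=6000))
    return {
        "cells": cells,
        "lineage_table": lineage_table,
        "config": config,
        "result": result,
    }
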