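"""End-to-end pipeline: FASTQ pair + germline references -> paired cells.

Thin orchestration over the demux, assemble, annotate and pair modules,
with per-stage counts logged at every filter step (cells called, cells with
both chains, cells passing quality filters).
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import assemble, demux, pair as pairing_mod
from .annotate import CHAIN_SCORE_THRESHOLD, AlignmentScoring, annotate_contig
from .assemble import AssemblyParams
from .reference import GermlineReference

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All pipeline tunables with their standard default values."""

    rank_fraction: float = demux.RANK_FRACTION          # 0.025
    cutoff_multiplier: float = demux.CUTOFF_MULTIPLIER  # 0.1
    targeted_cells: int = 6000
    downsample_cap: int = demux.DOWNSAMPLE_CAP          # 100000
    barcode_len: int = demux.BARCODE_LEN                # 16
    umi_len: int = demux.UMI_LEN                        # 10
    switch_len: int = demux.SWITCH_LEN                  # 13
    min_overlap: int = 25
    k_seed: int = 21
    expected_insert: int = 600
    insert_tolerance: int = 300
    chain_score_threshold: float = CHAIN_SCORE_THRESHOLD  # 30
    min_heavy_pairs: int = pairing_mod.MIN_HEAVY_PAIRS    # 10
    min_light_pairs: int = pairing_mod.MIN_LIGHT_PAIRS    # 100
    min_certainty: float = pairing_mod.MIN_CERTAINTY      # 0.8
    lineage_identity: float = 0.80
    reference_max_mismatch: int = 2
    seed: int = 0

    def assembly_params(self) -> AssemblyParams:
        return AssemblyParams(
            min_overlap=self.min_overlap,
            k_seed=self.k_seed,
            expected_insert=self.expected_insert,
            insert_tolerance=self.insert_tolerance,
        )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class PipelineResult:
    cell_set: demux.CellSet
    pairings: list
    airr: pd.DataFrame
    counts: dict


def run_pipeline(
    r1_path: str | Path,
    r2_path: str | Path,
    reference: GermlineReference,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Demultiplex, assemble, annotate and pair a FASTQ pair."""
    config = config or PipelineConfig()
    pairs = list(demux.parse_fastq_pair(r1_path, r2_path))
    log.info("parsed %d read pairs", len(pairs))
    counts: dict = {"read_pairs": len(pairs)}
    if not pairs:
        log.info("no reads parsed; zero cells called")
        return PipelineResult(
            cell_set=demux.CellSet(set(), 0.0, 0),
            pairings=[],
            airr=pd.DataFrame(),
            counts={**counts, "cells_called": 0, "cells_with_pairing": 0,
                    "cells_passing_filters": 0},
        )

    table = demux.count_barcodes(pairs)
    cell_set = demux.cell_rank_cutoff(table, config.targeted_cells)
    counts["cells_called"] = len(cell_set)
    log.info("called %d cells (cutoff %.1f at rank %d)",
             len(cell_set), cell_set.cutoff_value, cell_set.rank_used)

    bins, n_unassigned = demux.demultiplex(pairs, cell_set)
    counts["unassigned_read_pairs"] = n_unassigned

    params = config.assembly_params()
    scoring = AlignmentScoring()
    pairings = []
    n_paired = 0
    for barcode in sorted(bins):
        bin_pairs = demux.downsample_bin(
            bins[barcode], config.downsample_cap, seed=config.seed
        )
        contigs = assemble.assemble_and_trim(bin_pairs, params, barcode=barcode)
        annotations = []
        for contig in contigs:
            ann = annotate_contig(
                contig.sequence,
                reference,
                min_score=config.chain_score_threshold,
                scoring=scoring,
                contig_id=contig.contig_id,
                concordant_pairs=contig.concordant_pairs,
            )
            if ann is not None:
                annotations.append(ann)
        cp = pairing_mod.pair_cell(
            barcode,
            annotations,
            min_h=config.min_heavy_pairs,
            min_l=config.min_light_pairs,
            min_certainty=config.min_certainty,
        )
        if cp.heavy is not None and cp.light is not None:
            n_paired += 1
        pairings.append(cp)

    n_pass = sum(1 for p in pairings if p.passes_filter)
    counts["cells_with_pairing"] = n_paired
    counts["cells_passing_filters"] = n_pass
    log.info("cells in: %d, cells with VH+VL: %d, cells passing filters: %d",
             len(pairings), n_paired, n_pass)
    return PipelineResult(
        cell_set=cell_set,
        pairings=pairings,
        airr=pairing_mod.to_airr(pairings),
        counts=counts,
    )
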