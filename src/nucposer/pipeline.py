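"""End-to-end driver: simulate a dataset, run every analysis stage, score recovery.

This module glues the five analysis stages together for convenience (the
examples, CLI and reproduction script all run through it); each stage remains
independently usable through its own module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chip_occupancy import DEFAULT_MARK_CONFIGS, MarkConfig, call_all, occupancy_table
from .genomic_io import (
    CoverageTrack,
    FragmentSet,
    filter_fragments_by_length,
    fragments_to_coverage,
)
from .integration import build_gene_table
from .nucleosome_map import (
    FilterParams,
    PlusOneCall,
    PlusOneParams,
    call_nucleosomes,
    find_plus_one,
    flag_bidirectional,
    plus_one_table,
)
from .synthetic_data import (
    Annotation,
    SimConfig,
    generate_annotation,
    plant_chromatin,
    simulate_chip,
    simulate_expression,
    simulate_mnase,
)

__all__ = [
    "SimDataset",
    "AnalysisResult",
    "simulate_dataset",
    "analyze_dataset",
    "plus_one_recovery",
    "occupancy_confusion",
]


@dataclass
class SimDataset:
    """One simulated study: annotation, truth, and all raw evidence."""

    config: SimConfig
    annotation: Annotation
    truth: pd.DataFrame
    fragments: FragmentSet
    chip_tracks: dict[str, list[CoverageTrack]]
    expression: pd.DataFrame


@dataclass
class AnalysisResult:
    """All per-gene calls produced by the pipeline on one dataset."""

    mnase_coverage: CoverageTrack
    peaks: dict[str, list]
    plus_one_calls: list[PlusOneCall]
    occupancy: pd.DataFrame
    gene_table: pd.DataFrame


def simulate_dataset(
    cfg: SimConfig,
    marks: Sequence[str] = ("H2A.Z", "H3K4me3", "H3K27me3"),
) -> SimDataset:
    """Generate annotation, chromatin truth, MNase fragments, ChIP tracks, expression."""
    ann = generate_annotation(cfg)
    truth = plant_chromatin(ann, cfg)
    frags = simulate_mnase(ann, truth, cfg)
    chip = {m: simulate_chip(ann, truth, cfg, m) for m in marks}
    expr = simulate_expression(ann, truth, cfg)
    return SimDataset(cfg, ann, truth, frags, chip, expr)


def analyze_dataset(
    ds: SimDataset,
    frag_len_bounds: tuple[int, int] = (130, 170),
    filter_params: FilterParams = FilterParams(),
    plusone_params: PlusOneParams = PlusOneParams(),
    mark_configs: Mapping[str, MarkConfig] | None = None,
    bidirectional_tolerance: int = 50,
) -> AnalysisResult:
    """Run the full analysis exactly as on real data.

    MNase fragments are size-filtered (130-170 bp by default) and piled into
    raw coverage; nucleosomes are called by differential filter +
    zero-descent; per-gene +1/-1/NDR scans and bidirectional flagging follow;
    ChIP occupancy is called per mark; everything is joined with expression
    into the gene table.
    """
    frags = filter_fragments_by_length(ds.fragments, *frag_len_bounds)
    cov = fragments_to_coverage(frags, ds.annotation.chrom_lengths)
    peaks = call_nucleosomes(cov, filter_params)

    calls = [
        find_plus_one(peaks[g.chrom], cov.values(g.chrom), g, plusone_params)
        for g in ds.annotation.genes
    ]
    calls = flag_bidirectional(calls, ds.annotation.genes_by_id, bidirectional_tolerance)

    if mark_configs is None:
        mark_configs = {m: DEFAULT_MARK_CONFIGS[m] for m in ds.chip_tracks}
    occ_calls = call_all(ds.chip_tracks, ds.annotation.genes, mark_configs)
    occ = occupancy_table(occ_calls)

    table = build_gene_table(
        ds.annotation.genes,
        occupancy=occ,
        plusone_calls=calls,
        expression=ds.expression,
    )
    return AnalysisResult(cov, peaks, calls, occ, table)


def plus_one_recovery(
    truth: pd.DataFrame, calls: Sequence[PlusOneCall], tolerance: int = 20
) -> dict[str, float]:
    """Score +1 detection and bidirectional flagging against planted truth.

    Returns the fraction of genes whose called +1 lies within ``tolerance``
    bp of the planted dyad, and sensitivity/false-positive counts of the
    bidirectional flag.
    """
    by_id = {c.gene_id: c for c in calls}
    t = truth.set_index("gene_id")
    hits = sum(
        1
        for gid, row in t.iterrows()
        if (c := by_id.get(gid)) is not None
        and c.plus_one is not None
        and abs(c.plus_one.pos - row["plus_one_pos"]) <= tolerance
    )
    bid_true = t.index[t["bidirectional"]]
    bid_called = {gid for gid, c in by_id.items() if c.bidirectional}
    sens = (
        sum(1 for gid in bid_true if gid in bid_called) / len(bid_true)
        if len(bid_true)
        else float("nan")
    )
    false_flags = sum(1 for gid in bid_called if gid not in set(bid_true))
    return {
        "plus_one_recovery": hits / len(t),
        "n_genes": len(t),
        "bidirectional_sensitivity": sens,
        "bidirectional_false_flags": float(false_flags),
    }


_TRUTH_FLAG = {"H2A.Z": "h2az", "H3K4me3": "k4", "H3K27me3": "k27"}


def occupancy_confusion(truth: pd.DataFrame, occupancy: pd.DataFrame) -> pd.DataFrame:
    """Per-mark sensitivity and specificity of occupancy calls vs planted truth."""
    t = truth.set_index("gene_id")
    rows = []
    for mark, sub in occupancy.groupby("mark"):
        flag = _TRUTH_FLAG[mark]
        called = sub.set_index("gene_id")["positive"].reindex(t.index)
        actual = t[flag].astype(bool)
        tp = int((called & actual).sum())
        tn = int((~called & ~actual).sum())
        fp = int((called & ~actual).sum())
        fn = int((~called & actual).sum())
        rows.append(
            {
                "mark": mark,
                "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
                "specificity": tn / (tn + fp) if tn + fp else float("nan"),
                "tp": tp, "fp": fp, "tn": tn, "fn": fn,
            }
        )
    return pd.DataFrame(rows)
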