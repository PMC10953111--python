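"""Threshold-based ChIP occupancy calls at strand-aware promoter windows.

Each histone mark is scored per gene by the maximum CPM-normalized coverage
in a mark-specific window around the start codon; a gene is positive when
enough replicates reach the mark's CPM threshold. Default windows and
thresholds:

=========  ========  ==========  =========  ================  ==================
mark       upstream  downstream  threshold  replicates req'd  negative threshold
=========  ========  ==========  =========  ================  ==================
H2A.Z        200        600         15 CPM         2                 7.5 CPM
H3K4me3      200        600         20 CPM         1                 --
H3K27me3     100       1000         15 CPM         1                 --
=========  ========  ==========  =========  ================  ==================

The H2A.Z threshold corresponds to the 95% quantile of genome-wide peak
heights; :func:`quantile_threshold` re-derives such a cutoff from called
peaks when wanted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genomic_io import CoverageTrack, GeneModel, GenomicIOError, Window, tss_window

__all__ = [
    "MarkConfig",
    "OccupancyCall",
    "DEFAULT_MARK_CONFIGS",
    "quantile_threshold",
    "window_max",
    "call_mark",
    "call_all",
    "occupancy_table",
]


@dataclass(frozen=True)
class MarkConfig:
    """Window geometry and CPM thresholds for one histone mark.

    ``inclusive`` controls boundary behavior of the threshold comparison
    (``>=`` when true, the default). ``negative_threshold``, when set,
    defines an additional unoccupied class (all replicate maxima strictly
    below it), used for the mark-free control stratum.
    """

    mark_name: str
    upstream: int
    downstream: int
    threshold: float
    n_replicates_required: int = 1
    negative_threshold: float | None = None
    inclusive: bool = True

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError(f"{self.mark_name}: threshold must be positive")
        if self.n_replicates_required < 1:
            raise ValueError(f"{self.mark_name}: need at least one replicate")


DEFAULT_MARK_CONFIGS: dict[str, MarkConfig] = {
    "H2A.Z": MarkConfig("H2A.Z", upstream=200, downstream=600, threshold=15.0,
                        n_replicates_required=2, negative_threshold=7.5),
    "H3K4me3": MarkConfig("H3K4me3", upstream=200, downstream=600, threshold=20.0),
    "H3K27me3": MarkConfig("H3K27me3", upstream=100, downstream=1000, threshold=15.0),
}


@dataclass(frozen=True)
class OccupancyCall:
    gene_id: str
    mark_name: str
    max_cov_per_replicate: tuple[float, ...]
    positive: bool
    negative_class: bool = False


def quantile_threshold(peak_heights: Sequence[float], q: float = 0.95,
                       method: str = "linear") -> float:
    """Quantile of genome-wide peak heights, for deriving a CPM cutoff.

    Uses linear interpolation of order statistics (``h = (n - 1) q``) by
    default; other interpolation rules can be selected via ``method``.
    """
    heights = np.asarray(peak_heights, dtype=np.float64)
    if heights.size == 0:
        raise ValueError("cannot take a quantile of an empty height list")
    if not 0.0 < q < 1.0:
        raise ValueError(f"quantile fraction must be in (0, 1), got {q}")
    return float(np.quantile(heights, q, method=method))


def window_max(track: CoverageTrack, win: Window) -> float:
    """Maximum per-bp value of a (CPM-normalized) track over a window."""
    if not track.normalized:
        raise GenomicIOError("occupancy scoring expects a CPM-normalized track")
    arr = track.values(win.chrom)
    lo, hi = max(win.start, 0), min(win.end, len(arr))
    if lo >= hi:
        raise GenomicIOError(f"window [{win.start}, {win.end}) off chromosome {win.chrom}")
    return float(arr[lo:hi].max())


def call_mark(
    tracks_per_replicate: Sequence[CoverageTrack],
    gene: GeneModel,
    cfg: MarkConfig,
) -> OccupancyCall:
    """Score one gene for one mark across replicate tracks.

    Positive when at least ``n_replicates_required`` replicate maxima reach
    the threshold; negative_class (if configured) when every replicate
    maximum stays below the negative threshold.
    """
    if len(tracks_per_replicate) < cfg.n_replicates_required:
        raise ValueError(
            f"{cfg.mark_name}: {len(tracks_per_replicate)} replicate(s) supplied, "
            f"{cfg.n_replicates_required} required"
        )
    maxima = []
    for track in tracks_per_replicate:
        win = tss_window(gene, cfg.upstream, cfg.downstream,
                         chrom_length=track.length(gene.chrom))
        maxima.append(window_max(track, win))
    if cfg.inclusive:
        n_pass = sum(m >= cfg.threshold for m in maxima)
    else:
        n_pass = sum(m > cfg.threshold for m in maxima)
    positive = n_pass >= cfg.n_replicates_required
    negative = (
        cfg.negative_threshold is not None
        and all(m < cfg.negative_threshold for m in maxima)
    )
    return OccupancyCall(gene.gene_id, cfg.mark_name, tuple(maxima), positive, negative)


def call_all(
    tracks_by_mark: Mapping[str, Sequence[CoverageTrack]],
    genes: Sequence[GeneModel],
    configs: Mapping[str, MarkConfig] | None = None,
) -> list[OccupancyCall]:
    """Batch driver: every configured mark for every gene."""
    if configs is None:
        configs = {m: DEFAULT_MARK_CONFIGS[m] for m in tracks_by_mark}
    calls: list[OccupancyCall] = []
    for mark, cfg in configs.items():
        if mark not in tracks_by_mark:
            raise KeyError(f"no tracks supplied for configured mark {mark!r}")
        tracks = tracks_by_mark[mark]
        for gene in genes:
            calls.append(call_mark(tracks, gene, cfg))
    return calls


def occupancy_table(calls: Sequence[OccupancyCall]) -> pd.DataFrame:
    """Long-format table of calls, one row per (gene, mark)."""
    n_rep = max((len(c.max_cov_per_replicate) for c in calls), default=0)
    rows = []
    for c in calls:
        row = {"gene_id": c.gene_id, "mark": c.mark_name,
               "positive": c.positive, "negative_class": c.negative_class}
        for i in range(n_rep):
            row[f"max_rep{i + 1}"] = (
                c.max_cov_per_replicate[i] if i < len(c.max_cov_per_replicate) else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)
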