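"""Nucleosome calling from MNase coverage.

The peak caller runs a size-151 antisymmetric differential filter over the
per-bp coverage trace and reports a nucleosome dyad wherever the filtered
trace descends through zero, collecting the height from the unfiltered
coverage at that position. Downstream of peak calling, per-gene scanning of
adjacent peak pairs upstream of the start codon locates the
nucleosome-depleted region (NDR) and its flanking +1 (gene-side) and -1
(distal) nucleosomes, and divergent gene pairs sharing a promoter nucleosome
are flagged as bidirectional.

The filter is defined directly as right-window mean minus left-window mean,

    f(i) = (1/150) * ( sum_{j=1..75} cov(i+j) - sum_{j=1..75} cov(i-j) ),

so that coverage maxima are descents of ``f`` through zero. Positions within
75 bp of a chromosome end are undefined (NaN) and never yield peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genomic_io import CoverageTrack, GeneModel, Window

__all__ = [
    "FilterParams",
    "NucleosomePeak",
    "PlusOneParams",
    "PlusOneCall",
    "differential_filter",
    "locate_peaks",
    "call_nucleosomes",
    "find_plus_one",
    "find_minus_one",
    "flag_bidirectional",
    "plus_one_table",
    "peaks_to_bed",
]


@dataclass(frozen=True)
class FilterParams:
    """Differential filter geometry: two flanking windows of ``half_width`` bp.

    The kernel has ``2 * half_width + 1`` taps and sums to zero; ``coeff`` is
    the per-tap weight 1/(2*half_width).
    """

    half_width: int = 75

    @property
    def coeff(self) -> float:
        return 1.0 / (2 * self.half_width)

    @property
    def kernel_size(self) -> int:
        return 2 * self.half_width + 1


@dataclass(frozen=True)
class NucleosomePeak:
    """A called dyad: zero-descent position plus unfiltered coverage height."""

    chrom: str
    pos: int
    height: float


@dataclass(frozen=True)
class PlusOneParams:
    """Rules for the +1/-1/NDR scan upstream of the start codon.

    All distances are bp; heights are per-bp coverage in the unit of the
    supplied track (``height_units`` is descriptive metadata: the original
    protocol phrases the cutoff in raw reads per nucleotide).
    """

    min_peak_height: float = 20.0
    search_start_offset: int = 100   # begin this far downstream of the ATG
    search_limit: int = 2000         # give up this far upstream of the ATG
    min_peak_distance: int = 200     # adjacent peaks closer than this cannot flank an NDR
    valley_rel_fraction: float = 0.1
    min_valley_bp: int = 20
    height_units: str = "reads"


@dataclass(frozen=True)
class PlusOneCall:
    """Per-gene result of the NDR scan."""

    gene_id: str
    plus_one: NucleosomePeak | None = None
    minus_one: NucleosomePeak | None = None
    ndr: Window | None = None
    bidirectional: bool = False


def differential_filter(cov: np.ndarray, params: FilterParams = FilterParams()) -> np.ndarray:
    """Apply the antisymmetric two-window mean-difference filter.

    Returns an array of the same length with NaN at the ``half_width``
    undefined positions at each end. Implemented with a cumulative sum, so a
    chromosome-scale trace filters in O(n).
    """
    cov = np.asarray(cov, dtype=np.float64)
    w = params.half_width
    n = len(cov)
    if n <= params.kernel_size:
        raise ValueError(
            f"coverage length {n} shorter than filter kernel {params.kernel_size}"
        )
    c = np.concatenate(([0.0], np.cumsum(cov)))  # c[k] = sum(cov[:k])
    out = np.full(n, np.nan)
    i = np.arange(w, n - w)
    right = c[i + w + 1] - c[i + 1]  # sum of cov[i+1 .. i+w]
    left = c[i] - c[i - w]           # sum of cov[i-w .. i-1]
    out[i] = (right - left) * params.coeff
    return out


def locate_peaks(filtered: np.ndarray, cov: np.ndarray, chrom: str = "") -> list[NucleosomePeak]:
    """Report a peak at each descending zero-crossing of the filtered trace.

    A peak sits at position ``i`` where ``filtered[i] >= 0`` and
    ``filtered[i+1] < 0`` — on an exact-zero plateau this is the last index of
    the non-negative run, a deterministic tie-break. Heights come from the
    unfiltered coverage. NaN (undefined) filter values never participate.
    """
    filtered = np.asarray(filtered, dtype=np.float64)
    cov = np.asarray(cov, dtype=np.float64)
    if len(filtered) != len(cov):
        raise ValueError("filtered and coverage traces must be aligned")
    with np.errstate(invalid="ignore"):
        descent = (filtered[:-1] >= 0) & (filtered[1:] < 0)
    idx = np.flatnonzero(descent)
    return [NucleosomePeak(chrom, int(i), float(cov[i])) for i in idx]


def call_nucleosomes(
    track: CoverageTrack, params: FilterParams = FilterParams()
) -> dict[str, list[NucleosomePeak]]:
    """Run filter + zero-descent detection on every chromosome of a track."""
    out: dict[str, list[NucleosomePeak]] = {}
    for chrom in track.chroms():
        cov = track.values(chrom)
        filt = differential_filter(cov, params)
        out[chrom] = locate_peaks(filt, cov, chrom)
    return out


def _oriented_offset(pos: int | np.ndarray, gene: GeneModel) -> int | np.ndarray:
    """Signed distance from the start-codon anchor, positive downstream."""
    return pos - gene.atg if gene.strand == "+" else gene.atg - pos


def find_plus_one(
    peaks: Sequence[NucleosomePeak],
    cov: np.ndarray,
    gene: GeneModel,
    params: PlusOneParams = PlusOneParams(),
) -> PlusOneCall:
    """Locate the NDR and its flanking +1/-1 nucleosomes for one gene.

    Peaks below ``min_peak_height`` are discarded up front. Among the
    survivors between ``search_limit`` bp upstream and
    ``search_start_offset`` bp downstream of the ATG (transcription
    orientation), adjacent pairs are scanned from the gene side moving
    upstream; the first pair whose center-to-center distance exceeds
    ``min_peak_distance`` and whose inter-peak region contains more than
    ``min_valley_bp`` positions with coverage below
    ``min + valley_rel_fraction * (max - min)`` defines the NDR. The
    gene-side member of that pair is the +1 nucleosome, the distal member
    the -1. Genes with no qualifying pair yield an empty call.
    """
    cov = np.asarray(cov, dtype=np.float64)
    gene_peaks = [p for p in peaks if p.chrom == gene.chrom or p.chrom == ""]
    gene_peaks = [p for p in gene_peaks if p.height > params.min_peak_height]
    offsets = np.array([_oriented_offset(p.pos, gene) for p in gene_peaks])
    keep = (
        (offsets >= -params.search_limit) & (offsets <= params.search_start_offset)
        if len(offsets)
        else np.array([], dtype=bool)
    )
    cand = [gene_peaks[i] for i in np.flatnonzero(keep)]
    # scan from the gene side (largest downstream offset) moving upstream
    cand.sort(key=lambda p: _oriented_offset(p.pos, gene), reverse=True)
    for down, up in zip(cand, cand[1:]):
        dist = abs(down.pos - up.pos)
        if dist <= params.min_peak_distance:
            continue
        lo, hi = sorted((down.pos, up.pos))
        region = cov[lo + 1 : hi]  # open interval between the two centers
        if len(region) == 0:
            continue
        mn, mx = float(region.min()), float(region.max())
        cut = mn + params.valley_rel_fraction * (mx - mn)
        if int(np.sum(region < cut)) > params.min_valley_bp:
            ndr = Window(gene.chrom, lo + 1, hi, oriented=True, strand=gene.strand)
            return PlusOneCall(gene.gene_id, plus_one=down, minus_one=up, ndr=ndr)
    return PlusOneCall(gene.gene_id)


def find_minus_one(
    peaks: Sequence[NucleosomePeak],
    cov: np.ndarray,
    gene: GeneModel,
    params: PlusOneParams = PlusOneParams(),
) -> NucleosomePeak | None:
    """The NDR-flanking nucleosome facing away from the gene start."""
    return find_plus_one(peaks, cov, gene, params).minus_one


def flag_bidirectional(
    calls: Sequence[PlusOneCall],
    genes: Mapping[str, GeneModel],
    tolerance: int = 50,
) -> list[PlusOneCall]:
    """Mark +1 calls that share their promoter nucleosome with a divergent gene.

    A call is bidirectional when its -1 position coincides (within
    ``tolerance`` bp, same chromosome) with the +1 position of an
    oppositely-stranded gene, or symmetrically its +1 with another gene's -1.
    """
    plus_index: dict[tuple[str, str], list[int]] = {}
    minus_index: dict[tuple[str, str], list[int]] = {}
    for c in calls:
        g = genes[c.gene_id]
        if c.plus_one is not None:
            plus_index.setdefault((g.chrom, g.strand), []).append(c.plus_one.pos)
        if c.minus_one is not None:
            minus_index.setdefault((g.chrom, g.strand), []).append(c.minus_one.pos)

    def near(pos: int, index: dict, chrom: str, strand: str) -> bool:
        other = "-" if strand == "+" else "+"
        return any(abs(pos - q) <= tolerance for q in index.get((chrom, other), ()))

    out: list[PlusOneCall] = []
    for c in calls:
        g = genes[c.gene_id]
        flag = False
        if c.minus_one is not None and near(c.minus_one.pos, plus_index, g.chrom, g.strand):
            flag = True
        if not flag and c.plus_one is not None and near(
            c.plus_one.pos, minus_index, g.chrom, g.strand
        ):
            flag = True
        out.append(replace(c, bidirectional=flag))
    return out


def plus_one_table(calls: Sequence[PlusOneCall]) -> pd.DataFrame:
    """Tabulate calls (one row per gene; absent fields as <NA>)."""
    rows = []
    for c in calls:
        rows.append(
            {
                "gene_id": c.gene_id,
                "plus_one_pos": c.plus_one.pos if c.plus_one else pd.NA,
                "plus_one_height": c.plus_one.height if c.plus_one else pd.NA,
                "minus_one_pos": c.minus_one.pos if c.minus_one else pd.NA,
                "ndr_start": c.ndr.start if c.ndr else pd.NA,
                "ndr_end": c.ndr.end if c.ndr else pd.NA,
                "bidirectional": c.bidirectional,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "plus_one_pos", "plus_one_height", "minus_one_pos",
            "ndr_start", "ndr_end", "bidirectional",
        ],
    )


def peaks_to_bed(peaks_by_chrom: Mapping[str, Sequence[NucleosomePeak]], path) -> None:
    """Write peaks as BED6 with the height in the score column."""
    with open(path, "w") as fh:
        for chrom in peaks_by_chrom:
            for p in peaks_by_chrom[chrom]:
                fh.write(f"{chrom}\t{p.pos}\t{p.pos + 1}\tnuc\t{p.height:g}\t.\n")
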