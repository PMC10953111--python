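"""Genomic file I/O, coverage construction, and strand-aware window arithmetic.

All internal coordinates are 0-based, half-open. GFF3 (1-based, inclusive) is
converted on read and write. The translation-start anchor ("ATG") of a gene is
``gene.start`` on the plus strand and ``gene.end - 1`` on the minus strand, so
that windows expressed in transcription orientation mirror cleanly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneModel",
    "FragmentSet",
    "CoverageTrack",
    "Window",
    "read_gff3",
    "write_gff3",
    "read_bed_fragments",
    "write_bed_fragments",
    "filter_fragments_by_length",
    "fragments_to_coverage",
    "normalize_cpm",
    "tss_window",
    "oriented_values",
    "read_chrom_sizes",
]


class GenomicIOError(ValueError):
    """Raised for malformed input files or invalid interval parameters."""


@dataclass(frozen=True)
class GeneModel:
    """A gene locus with a strand-aware translation-start anchor.

    Coordinates are 0-based half-open on the chromosome. ``atg`` is the
    position of the first coding base: ``start`` for plus-strand genes and
    ``end - 1`` for minus-strand genes.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise GenomicIOError(
                f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not self.start < self.end:
            raise GenomicIOError(
                f"gene {self.gene_id!r}: require start < end, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def atg(self) -> int:
        """Chromosomal position of the annotated start codon."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class FragmentSet:
    """A collection of sequenced fragments as (chrom, start, end) intervals."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = ("chrom", "start", "end")
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise GenomicIOError(f"FragmentSet missing columns: {missing}")
        if len(self.df) and not (self.df["end"] > self.df["start"]).all():
            bad = self.df.index[self.df["end"] <= self.df["start"]][0]
            raise GenomicIOError(f"fragment at row {bad} has non-positive length")

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, int, int]]) -> "FragmentSet":
        df = pd.DataFrame(records, columns=["chrom", "start", "end"])
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        return cls(df)

    @property
    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class CoverageTrack:
    """Per-chromosome, per-bp non-negative signal.

    ``normalized`` marks counts-per-million scaling; ``total_fragments`` is
    the CPM denominator actually applied (0 while un-normalized).
    """

    data: dict[str, np.ndarray]
    normalized: bool = False
    total_fragments: int = 0

    def __post_init__(self) -> None:
        for chrom, arr in self.data.items():
            arr = np.asarray(arr, dtype=np.float64)
            if arr.ndim != 1:
                raise GenomicIOError(f"coverage for {chrom} must be 1-D")
            if len(arr) and arr.min() < 0:
                raise GenomicIOError(f"coverage for {chrom} contains negative values")
            self.data[chrom] = arr

    def chroms(self) -> list[str]:
        return list(self.data)

    def values(self, chrom: str) -> np.ndarray:
        try:
            return self.data[chrom]
        except KeyError:
            raise GenomicIOError(f"no coverage for chromosome {chrom!r}") from None

    def length(self, chrom: str) -> int:
        return len(self.values(chrom))


@dataclass(frozen=True)
class Window:
    """A half-open genomic interval, optionally carrying orientation.

    When ``oriented`` is true, consumers read the window's contents in
    transcription direction (reverse-complement order for minus strand).
    """

    chrom: str
    start: int
    end: int
    oriented: bool = False
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise GenomicIOError(
                f"window [{self.start}, {self.end}) on {self.chrom} is empty"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


class EmptyWindowError(GenomicIOError):
    """A requested window lies entirely off the chromosome."""


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(path: str | os.PathLike) -> list[GeneModel]:
    """Read gene features from a GFF3 file into :class:`GeneModel` records.

    Only features of type ``gene`` are considered; each must carry an ``ID``
    attribute. Duplicate gene IDs raise an error.
    """
    import gffutils

    path = os.fspath(path)
    if os.path.getsize(path) == 0 or _no_feature_lines(path):
        return []
    try:
        db = gffutils.create_db(
            path,
            dbfn=":memory:",
            merge_strategy="error",
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises several exception types
        raise GenomicIOError(f"failed to parse GFF3 {path!r}: {exc}") from exc
    genes: list[GeneModel] = []
    seen: set[str] = set()
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        ids = feat.attributes.get("ID")
        if not ids:
            raise GenomicIOError(f"gene feature without ID at {feat.seqid}:{feat.start}")
        gene_id = ids[0]
        if gene_id in seen:
            raise GenomicIOError(f"duplicate gene_id {gene_id!r} in {path!r}")
        seen.add(gene_id)
        # GFF3 1-based inclusive -> 0-based half-open
        genes.append(GeneModel(gene_id, feat.seqid, feat.start - 1, feat.end, feat.strand))
    return genes


def _no_feature_lines(path: str) -> bool:
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return False
    return True


def write_gff3(genes: Sequence[GeneModel], path: str | os.PathLike) -> None:
    """Write gene models as minimal GFF3 (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tnucposer\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# BED fragments


def read_bed_fragments(path: str | os.PathLike) -> FragmentSet:
    """Read intervals from a BED3+ file (0-based half-open, as on disk)."""
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            usecols=[0, 1, 2],
            names=["chrom", "start", "end"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64},
            comment="#",
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["chrom", "start", "end"])
    except (ValueError, pd.errors.ParserError) as exc:
        raise GenomicIOError(f"failed to parse BED {path!r}: {exc}") from exc
    return FragmentSet(df)


def write_bed_fragments(frags: FragmentSet, path: str | os.PathLike) -> None:
    frags.df[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


def read_chrom_sizes(path: str | os.PathLike) -> dict[str, int]:
    """Read a two-column ``chrom<TAB>length`` table."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"],
                     dtype={"chrom": str, "length": np.int64})
    return dict(zip(df["chrom"], df["length"]))


# ---------------------------------------------------------------------------
# Fragment filtering and coverage


def filter_fragments_by_length(frags: FragmentSet, lo: int, hi: int) -> FragmentSet:
    """Keep fragments with ``lo <= length <= hi`` (both bounds inclusive).

    The nucleosome-footprint filter of the MNase pipeline uses 130-170 bp.
    """
    if lo > hi:
        raise GenomicIOError(f"fragment length bounds inverted: lo={lo} > hi={hi}")
    lengths = frags.lengths
    keep = (lengths >= lo) & (lengths <= hi)
    return FragmentSet(frags.df.loc[keep].reset_index(drop=True))


def fragments_to_coverage(
    frags: FragmentSet, chrom_lengths: Mapping[str, int]
) -> CoverageTrack:
    """Pile fragments into raw per-bp coverage.

    The value at position ``p`` is the number of fragments whose half-open
    span contains ``p``. Fragments extending past chromosome bounds are an
    error (the caller is expected to have clipped or discarded them).
    """
    data = {chrom: np.zeros(int(n), dtype=np.float64) for chrom, n in chrom_lengths.items()}
    for chrom, sub in frags.df.groupby("chrom", sort=False):
        if chrom not in data:
            raise GenomicIOError(f"fragment on unknown chromosome {chrom!r}")
        n = len(data[chrom])
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        bad = (starts < 0) | (ends > n)
        if bad.any():
            i = sub.index[bad][0]
            row = frags.df.loc[i]
            raise GenomicIOError(
                f"fragment {row.chrom}:{row.start}-{row.end} outside chromosome (length {n})"
            )
        # difference-array pileup: O(fragments + chromosome length)
        diff = np.zeros(n + 1, dtype=np.float64)
        np.add.at(diff, starts, 1.0)
        np.add.at(diff, ends, -1.0)
        data[chrom] = np.cumsum(diff[:-1])
    return CoverageTrack(data, normalized=False, total_fragments=0)


def normalize_cpm(track: CoverageTrack, total_fragments: int) -> CoverageTrack:
    """Scale a raw track to counts-per-million: value * 1e6 / total_fragments.

    The denominator (filtered fragments for MNase, mapped pairs for ChIP) is
    supplied explicitly. Normalizing an already-normalized track is an error.
    """
    if track.normalized:
        raise GenomicIOError("track is already CPM-normalized")
    if total_fragments <= 0:
        raise GenomicIOError(f"total_fragments must be positive, got {total_fragments}")
    scale = 1e6 / float(total_fragments)
    data = {chrom: arr * scale for chrom, arr in track.data.items()}
    return CoverageTrack(data, normalized=True, total_fragments=int(total_fragments))


# ---------------------------------------------------------------------------
# bedGraph


def write_bedgraph(track: CoverageTrack, path: str | os.PathLike) -> None:
    """Write a track as bedGraph (0-based half-open), run-length merged."""
    with open(path, "w") as fh:
        for chrom in track.chroms():
            arr = track.values(chrom)
            if len(arr) == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(arr)]))
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\t{float(arr[s])!r}\n")


def read_bedgraph(
    path: str | os.PathLike,
    chrom_lengths: Mapping[str, int] | None = None,
    normalized: bool = False,
) -> CoverageTrack:
    """Read bedGraph into a dense :class:`CoverageTrack`.

    Without ``chrom_lengths``, each chromosome's length is taken as the
    largest interval end seen for it.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": np.float64},
            comment="#", float_precision="round_trip",
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["chrom", "start", "end", "value"])
    except (ValueError, pd.errors.ParserError) as exc:
        raise GenomicIOError(f"failed to parse bedGraph {path!r}: {exc}") from exc
    if chrom_lengths is None:
        chrom_lengths = df.groupby("chrom")["end"].max().to_dict()
    data = {chrom: np.zeros(int(n), dtype=np.float64) for chrom, n in chrom_lengths.items()}
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in data:
            raise GenomicIOError(f"bedGraph interval on unknown chromosome {chrom!r}")
        arr = data[chrom]
        for s, e, v in zip(sub["start"], sub["end"], sub["value"]):
            arr[s:e] = v
    return CoverageTrack(data, normalized=normalized, total_fragments=0)


# ---------------------------------------------------------------------------
# Strand-aware windows


def tss_window(
    gene: GeneModel,
    upstream: int,
    downstream: int,
    chrom_length: int | None = None,
) -> Window:
    """Window around the start-codon anchor, in transcription orientation.

    For a plus-strand gene the window is ``[atg - upstream, atg + downstream)``;
    for a minus-strand gene the mirror image around its anchor. The window is
    clipped to ``[0, chrom_length)`` when the length is given; a window falling
    entirely off-chromosome raises :class:`EmptyWindowError`.
    """
    if upstream < 0 or downstream < 0:
        raise GenomicIOError("upstream/downstream extents must be non-negative")
    if gene.strand == "+":
        start, end = gene.start - upstream, gene.start + downstream
    else:
        start, end = gene.end - downstream, gene.end + upstream
    start = max(start, 0)
    if chrom_length is not None:
        end = min(end, chrom_length)
    if start >= end:
        raise EmptyWindowError(
            f"window for gene {gene.gene_id!r} is empty after clipping"
        )
    return Window(gene.chrom, start, end, oriented=True, strand=gene.strand)


def oriented_values(track: CoverageTrack, win: Window) -> np.ndarray:
    """Coverage values over a window, read in transcription direction.

    Positions outside the chromosome (never produced by :func:`tss_window`,
    but possible for anchored flanking windows) are returned as NaN.
    """
    arr = track.values(win.chrom)
    n = len(arr)
    out = np.full(win.length, np.nan)
    lo, hi = max(win.start, 0), min(win.end, n)
    if lo < hi:
        out[lo - win.start : hi - win.start] = arr[lo:hi]
    if win.oriented and win.strand == "-":
        out = out[::-1]
    return out
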