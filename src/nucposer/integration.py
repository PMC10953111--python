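"""Per-gene integration of chromatin, transcription, and conservation evidence.

Joins occupancy flags, +1-nucleosome calls, expression (log2 RPKM, log2
fold-change, p-value), and BLAST-derived conservation classes into a single
gene table, and computes the derived summaries: differential-expression
classes, Venn/co-occupancy counts, +1-anchored coverage matrices, and binned
median profiles.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genomic_io import CoverageTrack, GeneModel, Window, oriented_values
from .nucleosome_map import PlusOneCall

__all__ = [
    "DEClass",
    "ConservationClass",
    "ExpressionRecord",
    "rpkm_log2",
    "classify_de",
    "venn_counts",
    "co_occupancy_fraction",
    "enrichment_matrix",
    "median_profile",
    "read_blast_outfmt6",
    "classify_conservation",
    "build_gene_table",
    "stratified_counts",
]


class DEClass(str, Enum):
    """Differential-expression class at |log2FC| >= 1 and p < 0.01."""

    UP = "up"
    DOWN = "down"
    NS = "ns"


class ConservationClass(str, Enum):
    """Proteome-wide homolog abundance class from filtered BLAST hit counts."""

    LOW = "low"
    INTERMEDIATE = "intermediate"
    HIGH = "high"


@dataclass(frozen=True)
class ExpressionRecord:
    """Per-gene expression evidence across strains.

    ``rpkm_log2`` maps strain name (e.g. wild type, depletion,
    overexpression) to log2 RPKM; ``log2fc`` and ``p_value`` refer to the
    depletion-vs-wild-type contrast.
    """

    gene_id: str
    rpkm_log2: Mapping[str, float]
    log2fc: float
    p_value: float

    def __post_init__(self) -> None:
        # NaN encodes missing evidence and is rejected later, at classification
        if not np.isnan(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"{self.gene_id}: p-value {self.p_value} outside [0, 1]")


def rpkm_log2(count: float, gene_length: int, library_size: float,
              pseudocount: float = 1.0) -> float:
    """log2 reads per kilobase per million library reads.

    ``log2(count / (gene_length/1e3) / (library_size/1e6) + pseudocount)``.
    The pseudocount (default 1) keeps zero-count genes finite at 0.
    """
    if gene_length <= 0:
        raise ValueError(f"gene_length must be positive, got {gene_length}")
    if library_size <= 0:
        raise ValueError(f"library_size must be positive, got {library_size}")
    rpkm = count / (gene_length / 1e3) / (library_size / 1e6)
    return float(np.log2(rpkm + pseudocount))


def classify_de(rec: ExpressionRecord, fc_cut: float = 1.0,
                p_cut: float = 0.01) -> DEClass:
    """Classify a gene as up/down/ns. The fold-change boundary is inclusive."""
    if rec.p_value is None or (isinstance(rec.p_value, float) and np.isnan(rec.p_value)):
        raise ValueError(f"{rec.gene_id}: missing p-value")
    if rec.p_value < p_cut:
        if rec.log2fc >= fc_cut:
            return DEClass.UP
        if rec.log2fc <= -fc_cut:
            return DEClass.DOWN
    return DEClass.NS


def venn_counts(set_a: Iterable, set_b: Iterable, set_c: Iterable | None = None,
                names: Sequence[str] = ("A", "B", "C")) -> dict[str, int]:
    """Counts of all disjoint regions of a 2- or 3-set Venn diagram.

    Keys name the exclusive regions (``"A"`` = in A only, ``"A&B"`` = in A
    and B but not C, ...); region counts always sum to ``|A U B (U C)|``.
    """
    a, b = set(set_a), set(set_b)
    if set_c is None:
        return {
            names[0]: len(a - b),
            names[1]: len(b - a),
            f"{names[0]}&{names[1]}": len(a & b),
        }
    c = set(set_c)
    return {
        names[0]: len(a - b - c),
        names[1]: len(b - a - c),
        names[2]: len(c - a - b),
        f"{names[0]}&{names[1]}": len((a & b) - c),
        f"{names[0]}&{names[2]}": len((a & c) - b),
        f"{names[1]}&{names[2]}": len((b & c) - a),
        f"{names[0]}&{names[1]}&{names[2]}": len(a & b & c),
    }


def co_occupancy_fraction(reference_set: Iterable, mark_set: Iterable) -> float:
    """Fraction of the reference gene set that also carries the mark."""
    ref = set(reference_set)
    if not ref:
        raise ValueError("reference set is empty")
    return len(ref & set(mark_set)) / len(ref)


def enrichment_matrix(
    track: CoverageTrack,
    calls: Sequence[PlusOneCall],
    genes: Mapping[str, GeneModel],
    flank_up: int = 1000,
    flank_down: int = 5000,
) -> tuple[np.ndarray, list[str]]:
    """+1-anchored coverage matrix, rows sorted by increasing gene length.

    Each row is the track read over ``[+1 - flank_up, +1 + flank_down)`` in
    transcription orientation; positions off the chromosome are NaN. Genes
    without a +1 call are excluded. Returns ``(matrix, gene_ids)`` with
    ``matrix.shape == (n_genes, flank_up + flank_down)``.
    """
    usable = [c for c in calls if c.plus_one is not None]
    usable.sort(key=lambda c: (genes[c.gene_id].length, c.gene_id))
    width = flank_up + flank_down
    mat = np.full((len(usable), width), np.nan)
    ids: list[str] = []
    for i, c in enumerate(usable):
        g = genes[c.gene_id]
        p = c.plus_one.pos
        if g.strand == "+":
            win = Window(g.chrom, p - flank_up, p + flank_down, oriented=True, strand="+")
        else:
            # mirror: oriented offset t in [-flank_up, flank_down) maps to
            # chromosome positions (p - flank_down, p + flank_up]
            win = Window(g.chrom, p - flank_down + 1, p + flank_up + 1,
                         oriented=True, strand="-")
        mat[i] = oriented_values(track, win)
        ids.append(c.gene_id)
    return mat, ids


def median_profile(matrix: np.ndarray, bin_width: int = 21) -> np.ndarray:
    """Median over all rows and positions per consecutive column bin.

    Missing (NaN) cells are ignored; a bin with no data is NaN. A trailing
    partial bin is kept. Returns one value per bin.
    """
    if bin_width < 1:
        raise ValueError(f"bin_width must be >= 1, got {bin_width}")
    matrix = np.asarray(matrix, dtype=np.float64)
    n_cols = matrix.shape[1]
    n_bins = int(np.ceil(n_cols / bin_width))
    out = np.full(n_bins, np.nan)
    for b in range(n_bins):
        chunk = matrix[:, b * bin_width : (b + 1) * bin_width]
        if np.any(~np.isnan(chunk)):
            out[b] = np.nanmedian(chunk)
    return out


_BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_blast_outfmt6(path: str | os.PathLike) -> pd.DataFrame:
    """Read BLAST tabular output (``-outfmt 6``, default 12 columns)."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=_BLAST6_COLUMNS,
                         comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=_BLAST6_COLUMNS)
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"failed to parse BLAST table {path!r}: {exc}") from exc
    if not pd.api.types.is_numeric_dtype(df["pident"]):
        raise ValueError(f"malformed BLAST table {path!r}: non-numeric pident column")
    return df


def classify_conservation(
    blast_rows: pd.DataFrame,
    min_identity: float = 40.0,
    low_cut: int = 50,
    high_cut: int = 300,
) -> tuple[ConservationClass, int]:
    """Class a query by its number of distinct subjects above an identity cutoff.

    Hits with percent identity strictly above ``min_identity`` are kept and
    collapsed to distinct subject IDs; fewer than ``low_cut`` hits is low
    conservation, more than ``high_cut`` is high, anything between is
    intermediate. Returns ``(class, hit_count)``.
    """
    for col in ("sseqid", "pident"):
        if col not in blast_rows.columns:
            raise ValueError(f"BLAST rows lack required column {col!r}")
    kept = blast_rows.loc[blast_rows["pident"] > min_identity]
    hits = int(kept["sseqid"].nunique())
    if hits < low_cut:
        cls = ConservationClass.LOW
    elif hits > high_cut:
        cls = ConservationClass.HIGH
    else:
        cls = ConservationClass.INTERMEDIATE
    return cls, hits


def build_gene_table(
    genes: Sequence[GeneModel],
    occupancy: pd.DataFrame | None = None,
    plusone_calls: Sequence[PlusOneCall] | None = None,
    expression: pd.DataFrame | None = None,
    conservation: Mapping[str, ConservationClass] | None = None,
    expressed_cutoff: float = 2.0,
) -> pd.DataFrame:
    """Join all per-gene evidence into one table (one row per gene).

    ``occupancy`` is the long table from :func:`..chip_occupancy.occupancy_table`
    (pivoted here to one boolean column per mark); ``expression`` must carry
    ``gene_id`` plus log2 RPKM columns, ``log2fc`` and ``p_value``. Genes
    missing from an input keep explicit missing values. A gene is counted as
    expressed when its wild-type log2 RPKM reaches ``expressed_cutoff``.
    """
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate gene_id in gene list")
    table = pd.DataFrame(
        {
            "gene_id": ids,
            "chrom": [g.chrom for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "strand": [g.strand for g in genes],
            "length": [g.length for g in genes],
        }
    ).set_index("gene_id")

    if occupancy is not None and len(occupancy):
        if occupancy.duplicated(["gene_id", "mark"]).any():
            raise ValueError("duplicate (gene_id, mark) rows in occupancy input")
        pos = occupancy.pivot(index="gene_id", columns="mark", values="positive")
        for mark in pos.columns:
            table[f"occ_{mark}"] = pos[mark].reindex(table.index).astype("boolean")
        if "negative_class" in occupancy.columns:
            neg = occupancy.pivot(index="gene_id", columns="mark", values="negative_class")
            for mark in neg.columns:
                col = neg[mark].reindex(table.index)
                if col.notna().any() and col.any():
                    table[f"neg_{mark}"] = col.astype("boolean")

    if plusone_calls is not None:
        byid = {c.gene_id: c for c in plusone_calls}
        if len(byid) != len(plusone_calls):
            raise ValueError("duplicate gene_id among +1 calls")
        table["plus_one_present"] = pd.array(
            [byid[g].plus_one is not None if g in byid else pd.NA for g in table.index],
            dtype="boolean",
        )
        table["plus_one_pos"] = [
            byid[g].plus_one.pos if g in byid and byid[g].plus_one else pd.NA
            for g in table.index
        ]
        table["bidirectional"] = pd.array(
            [byid[g].bidirectional if g in byid else pd.NA for g in table.index],
            dtype="boolean",
        )

    if expression is not None and len(expression):
        if expression["gene_id"].duplicated().any():
            raise ValueError("duplicate gene_id in expression input")
        expr = expression.set_index("gene_id").reindex(table.index)
        for col in expr.columns:
            table[col] = expr[col]
        de: list[object] = []
        for gid, row in expr.iterrows():
            if pd.isna(row.get("log2fc")) or pd.isna(row.get("p_value")):
                de.append(pd.NA)
            else:
                rec = ExpressionRecord(gid, {}, float(row["log2fc"]), float(row["p_value"]))
                de.append(classify_de(rec).value)
        table["de_class"] = de
        rpkm_cols = [c for c in expr.columns if c.startswith("rpkm_log2")]
        wt_col = next((c for c in rpkm_cols if "wt" in c), rpkm_cols[0] if rpkm_cols else None)
        if wt_col is not None:
            table["expressed_wt"] = pd.array(
                [pd.NA if pd.isna(v) else bool(v >= expressed_cutoff) for v in table[wt_col]],
                dtype="boolean",
            )

    if conservation is not None:
        table["conservation"] = [
            conservation[g].value if g in conservation else pd.NA for g in table.index
        ]
    return table.reset_index()


def stratified_counts(table: pd.DataFrame, mark: str = "H3K27me3") -> pd.DataFrame:
    """Gene counts stratified by (H2A.Z, mark, DE class).

    The substrate of the chromatin-state-vs-transcription summaries: how many
    genes in each (H2A.Z occupancy x mark occupancy) cell fall in each
    differential-expression class.
    """
    required = {"occ_H2A.Z", f"occ_{mark}", "de_class"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"gene table lacks columns {sorted(missing)}")
    sub = table.dropna(subset=["occ_H2A.Z", f"occ_{mark}", "de_class"])
    out = (
        sub.groupby(["occ_H2A.Z", f"occ_{mark}", "de_class"], observed=False)
        .size()
        .rename("n_genes")
        .reset_index()
    )
    return out
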