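"""Seed-reproducible synthetic chromatin datasets with machine-readable truth.

The generator emulates the statistical structure the analysis assumes for a
compact fungal genome:

* genes packed on one or more chromosomes with >= 2 kb intergenic spacing,
  a configurable fraction arranged as divergent pairs whose promoters share
  one nucleosome (the -1 of each gene is the +1 of its partner);
* a phased nucleosome array per gene: a well-positioned +1 nucleosome just
  downstream of the start codon, an NDR upstream of it, a -1 nucleosome and
  one further upstream nucleosome, then gene-body nucleosomes at the
  configured repeat length;
* MNase fragments drawn around each planted dyad (truncated-normal lengths
  around the ~147 bp nucleosome footprint, Gaussian positional jitter,
  Poisson per-nucleosome counts) plus a uniform background fraction;
* replicate ChIP coverage tracks per mark: Poisson noise around a smooth
  intensity profile that is flat background except over marked promoter
  windows (H2A.Z, H3K4me3) or contiguous multi-gene H3K27me3 domains
  (facultative heterochromatin, always >= 3 adjacent genes);
* expression counts per strain (wild type, depletion, overexpression) from
  class-specific log-normal means, with H2A.Z+/K27+ genes expressed in the
  wild type and silenced under simulated H2A.Z depletion.

Every component draws from its own child stream of the master seed, so
outputs are byte-identical across runs and components can be regenerated
independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chip_occupancy import DEFAULT_MARK_CONFIGS, MarkConfig
from .genomic_io import CoverageTrack, FragmentSet, GeneModel, write_gff3
from .integration import rpkm_log2

__all__ = [
    "SimConfig",
    "Annotation",
    "CHROMATIN_CLASSES",
    "NUC_FOOTPRINT",
    "generate_annotation",
    "plant_chromatin",
    "simulate_mnase",
    "simulate_chip",
    "simulate_expression",
]

#: canonical nucleosome-protected footprint, bp
NUC_FOOTPRINT = 147

#: chromatin classes planted per gene
CHROMATIN_CLASSES = ("h2az_k4", "h2az_k27", "k27_only", "h2az_only", "unmarked")

# child-stream indices under the master seed
_STREAM_ANNOTATION = 0
_STREAM_CHROMATIN = 1
_STREAM_MNASE = 2
_STREAM_CHIP = 3  # + per-mark, per-replicate offsets
_STREAM_EXPRESSION = 4


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the generator, with study-scale defaults.

    Distances in bp, coverage in expected fragments per planted dyad,
    proportions as fractions summing to 1.
    """

    n_chroms: int = 1
    chrom_length: int = 1_200_000
    n_genes: int = 200
    gene_length_range: tuple[int, int] = (1200, 3000)
    intergenic_gap: int = 2000
    divergent_fraction: float = 0.1
    nucleosome_repeat: int = 165
    ndr_width: int = 150
    plus_one_offset: int = 30          # +1 dyad this far downstream of the ATG
    frag_len_mean: float = 147.0
    frag_len_sd: float = 8.0
    frag_len_bounds: tuple[int, int] = (100, 250)
    frag_jitter_sd: float = 10.0
    mean_coverage: float = 50.0        # Poisson mean fragments per dyad
    bg_fragment_fraction: float = 0.1
    class_proportions: Mapping[str, float] = field(
        default_factory=lambda: {
            "h2az_k4": 0.25,
            "h2az_k27": 0.15,
            "k27_only": 0.20,
            "h2az_only": 0.15,
            "unmarked": 0.25,
        }
    )
    enrichment_fold: Mapping[str, float] = field(
        default_factory=lambda: {"H2A.Z": 6.0, "H3K4me3": 6.0, "H3K27me3": 6.0}
    )
    background_rel: float = 0.5        # ChIP background as a fraction of each threshold
    n_replicates: int = 2
    depletion_effect: float = 3.0      # |log2 FC| planted for silenced genes
    expressed_log2rpkm: tuple[float, float] = (6.0, 1.0)   # mean, sd
    silent_log2rpkm: tuple[float, float] = (0.5, 0.7)
    strain_noise_sd: float = 0.2
    unmarked_expressed_fraction: float = 0.4
    nominal_library_size: float = 5e6
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_proportions sum to {total}, expected 1")
        for name, val in (("n_chroms", self.n_chroms), ("chrom_length", self.chrom_length),
                          ("n_genes", self.n_genes), ("nucleosome_repeat", self.nucleosome_repeat),
                          ("ndr_width", self.ndr_width)):
            if val <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def peak_separation(self) -> int:
        """Center-to-center distance between the -1 and +1 dyads."""
        return self.ndr_width + NUC_FOOTPRINT

    @property
    def pair_atg_gap(self) -> int:
        """ATG-to-ATG distance inside a divergent pair (shared-NDR geometry)."""
        return self.peak_separation - 2 * self.plus_one_offset

    def rng(self, stream: int, *extra: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream, *extra])

    def to_dict(self) -> dict:
        d = asdict(self)
        d["class_proportions"] = dict(self.class_proportions)
        d["enrichment_fold"] = dict(self.enrichment_fold)
        return d


@dataclass
class Annotation:
    """Generated gene models plus pairing and genome-size bookkeeping."""

    genes: list[GeneModel]
    pairs: list[tuple[str, str]]            # (minus-strand id, plus-strand id)
    chrom_lengths: dict[str, int]

    @property
    def genes_by_id(self) -> dict[str, GeneModel]:
        return {g.gene_id: g for g in self.genes}

    def write(self, path) -> None:
        write_gff3(self.genes, path)


def generate_annotation(cfg: SimConfig) -> Annotation:
    """Pack genes onto chromosomes with >= 2 kb spacing between units.

    A transcription unit is either a single gene (random strand) or a
    divergent pair (minus-strand gene, then plus-strand gene, with the
    shared-NDR ATG gap between them). ``divergent_fraction`` is interpreted
    as pairs per gene: ``round(divergent_fraction * n_genes)`` pairs are
    planted. Raises when the genes cannot be packed into the genome.
    """
    rng = cfg.rng(_STREAM_ANNOTATION)
    n_pairs = int(round(cfg.divergent_fraction * cfg.n_genes))
    if 2 * n_pairs > cfg.n_genes:
        raise ValueError("divergent_fraction too large for n_genes")
    n_singles = cfg.n_genes - 2 * n_pairs

    units: list[str] = ["pair"] * n_pairs + ["single"] * n_singles
    rng.shuffle(units)

    margin = 3000
    lo, hi = cfg.gene_length_range
    genes: list[GeneModel] = []
    pairs: list[tuple[str, str]] = []
    chrom_lengths = {f"chr{i + 1}": cfg.chrom_length for i in range(cfg.n_chroms)}
    chrom_names = list(chrom_lengths)

    # deal units to chromosomes in contiguous blocks of near-equal unit count
    per_chrom = np.array_split(np.arange(len(units)), cfg.n_chroms)
    gid = 0

    def next_id() -> str:
        nonlocal gid
        gid += 1
        return f"g{gid:04d}"

    for chrom, unit_idx in zip(chrom_names, per_chrom):
        pos = margin
        for ui in unit_idx:
            gap = cfg.intergenic_gap + int(rng.integers(0, 1000))
            if units[ui] == "single":
                length = int(rng.integers(lo, hi + 1))
                strand = "+" if rng.random() < 0.5 else "-"
                start, end = pos, pos + length
                if end + margin > cfg.chrom_length:
                    raise ValueError(
                        f"cannot pack {cfg.n_genes} genes into "
                        f"{cfg.n_chroms} x {cfg.chrom_length} bp"
                    )
                genes.append(GeneModel(next_id(), chrom, start, end, strand))
                pos = end + gap
            else:
                len_a = int(rng.integers(lo, hi + 1))
                len_b = int(rng.integers(lo, hi + 1))
                # minus-strand gene A ends at its ATG; plus-strand gene B
                # starts pair_atg_gap downstream so the promoters share an NDR
                a_start, a_end = pos, pos + len_a
                b_start = (a_end - 1) + cfg.pair_atg_gap
                b_end = b_start + len_b
                if b_end + margin > cfg.chrom_length:
                    raise ValueError(
                        f"cannot pack {cfg.n_genes} genes into "
                        f"{cfg.n_chroms} x {cfg.chrom_length} bp"
                    )
                id_a, id_b = next_id(), next_id()
                genes.append(GeneModel(id_a, chrom, a_start, a_end, "-"))
                genes.append(GeneModel(id_b, chrom, b_start, b_end, "+"))
                pairs.append((id_a, id_b))
                pos = b_end + gap
    return Annotation(genes, pairs, chrom_lengths)


def _largest_remainder_quotas(proportions: Mapping[str, float], n: int) -> dict[str, int]:
    raw = {k: proportions.get(k, 0.0) * n for k in CHROMATIN_CLASSES}
    quotas = {k: int(np.floor(v)) for k, v in raw.items()}
    short = n - sum(quotas.values())
    order = sorted(CHROMATIN_CLASSES, key=lambda k: raw[k] - quotas[k], reverse=True)
    for k in order[:short]:
        quotas[k] += 1
    return quotas


def plant_chromatin(ann: Annotation, cfg: SimConfig) -> pd.DataFrame:
    """Assign chromatin classes and derived truth per gene.

    H3K27me3 is planted as contiguous domains of at least three adjacent
    genes (facultative heterochromatin). Divergent pair members share their
    full class (one promoter nucleosome, one state) and are excluded from
    K27 domains. Class counts follow largest-remainder quotas of
    ``class_proportions``. True +1/-1 dyad positions follow the shared
    promoter geometry; expression truth follows the class: H2A.Z-positive
    classes are expressed in the wild type, K27-only genes are silent, and
    H2A.Z+/K27+ genes flip to silenced under simulated depletion.
    """
    rng = cfg.rng(_STREAM_CHROMATIN)
    genes = ann.genes
    n = len(genes)
    quotas = _largest_remainder_quotas(cfg.class_proportions, n)
    paired: dict[str, str] = {}
    for a, b in ann.pairs:
        paired[a] = b
        paired[b] = a

    idx_of = {g.gene_id: i for i, g in enumerate(genes)}
    labels: list[str | None] = [None] * n
    domain_of = np.full(n, -1, dtype=int)

    # --- K27 domains over maximal runs of unpaired genes (genomic order)
    runs: list[list[int]] = []
    current: list[int] = []
    prev_chrom = None
    for i, g in enumerate(genes):
        if g.chrom != prev_chrom or g.gene_id in paired:
            if len(current) >= 3:
                runs.append(current)
            current = []
        if g.gene_id not in paired:
            current.append(i)
        prev_chrom = g.chrom
    if len(current) >= 3:
        runs.append(current)

    k27_needed = quotas["h2az_k27"] + quotas["k27_only"]
    free = [r[:] for r in runs]
    domain_id = 0
    k27_idx: list[int] = []
    while k27_needed >= 3:
        free = [r for r in free if len(r) >= 3]
        if not free:
            break
        weights = np.array([len(r) for r in free], dtype=float)
        ri = int(rng.choice(len(free), p=weights / weights.sum()))
        run = free.pop(ri)
        dlen = int(min(k27_needed, rng.integers(3, 8), len(run)))
        if 0 < k27_needed - dlen < 3 and k27_needed <= len(run):
            dlen = k27_needed
        off = int(rng.integers(0, len(run) - dlen + 1))
        chosen = run[off : off + dlen]
        for i in chosen:
            domain_of[i] = domain_id
        k27_idx.extend(chosen)
        domain_id += 1
        k27_needed -= dlen
        left, right = run[:off], run[off + dlen :]
        free.extend([left, right])
    deficit = (quotas["h2az_k27"] + quotas["k27_only"]) - len(k27_idx)

    k27_idx_arr = np.array(sorted(k27_idx), dtype=int)
    rng.shuffle(k27_idx_arr)
    n_zk27 = min(quotas["h2az_k27"], len(k27_idx_arr))
    for j, i in enumerate(k27_idx_arr):
        labels[i] = "h2az_k27" if j < n_zk27 else "k27_only"

    # --- non-K27 classes; any K27 shortfall falls back to 'unmarked'
    rest_quota = {
        "h2az_k4": quotas["h2az_k4"],
        "h2az_only": quotas["h2az_only"],
        "unmarked": quotas["unmarked"] + max(deficit, 0),
    }
    pair_list = list(ann.pairs)
    rng.shuffle(pair_list)
    for a, b in pair_list:
        remaining = np.array([max(rest_quota[c], 0) for c in rest_quota], dtype=float)
        classes = list(rest_quota)
        if remaining.sum() == 0:
            c = "unmarked"
        else:
            c = classes[int(rng.choice(len(classes), p=remaining / remaining.sum()))]
        rest_quota[c] -= 2
        labels[idx_of[a]] = c
        labels[idx_of[b]] = c
    singles_left = [i for i in range(n) if labels[i] is None]
    pool: list[str] = []
    for c, q in rest_quota.items():
        pool.extend([c] * max(q, 0))
    while len(pool) < len(singles_left):
        pool.append("unmarked")
    pool = pool[: len(singles_left)]
    rng.shuffle(pool)
    for i, c in zip(singles_left, pool):
        labels[i] = c

    # --- derived truth
    rows = []
    sep = cfg.peak_separation
    for i, g in enumerate(genes):
        label = labels[i]
        sign = 1 if g.strand == "+" else -1
        plus_one = g.atg + sign * cfg.plus_one_offset
        minus_one = plus_one - sign * sep
        ndr_lo, ndr_hi = sorted((plus_one, minus_one))
        h2az = label in ("h2az_k4", "h2az_k27", "h2az_only")
        expressed = (
            h2az
            or (label == "unmarked" and rng.random() < cfg.unmarked_expressed_fraction)
        )
        rows.append(
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "class_label": label,
                "h2az": h2az,
                "k4": label == "h2az_k4",
                "k27": label in ("h2az_k27", "k27_only"),
                "k27_domain": int(domain_of[i]),
                "pair_id": paired.get(g.gene_id) or "",
                "bidirectional": g.gene_id in paired,
                "plus_one_pos": plus_one,
                "minus_one_pos": minus_one,
                "ndr_start": ndr_lo + 1,
                "ndr_end": ndr_hi,
                "expressed_wt": expressed,
                "flips_down": label == "h2az_k27",
            }
        )
    return pd.DataFrame(rows)


def _planted_dyads(ann: Annotation, truth: pd.DataFrame, cfg: SimConfig) -> dict[str, np.ndarray]:
    """All planted dyad positions per chromosome (deduplicated by geometry).

    Pair members plant only their gene-body array: their -1 and further
    upstream dyads coincide with the partner's +1/+2 by construction.
    """
    genes = ann.genes_by_id
    dyads: dict[str, list[int]] = {chrom: [] for chrom in ann.chrom_lengths}
    by_id = truth.set_index("gene_id")
    for gid, row in by_id.iterrows():
        g = genes[gid]
        sign = 1 if g.strand == "+" else -1
        # downstream array: +1, +2, ... staying ~half a footprint inside the gene
        t = cfg.plus_one_offset
        while t <= g.length - NUC_FOOTPRINT // 2:
            dyads[g.chrom].append(g.atg + sign * t)
            t += cfg.nucleosome_repeat
        if not row["bidirectional"]:
            up = cfg.plus_one_offset - cfg.peak_separation
            dyads[g.chrom].append(g.atg + sign * up)                       # -1
            dyads[g.chrom].append(g.atg + sign * (up - cfg.nucleosome_repeat))  # -2
    return {chrom: np.array(sorted(v), dtype=np.int64) for chrom, v in dyads.items()}


def simulate_mnase(ann: Annotation, truth: pd.DataFrame, cfg: SimConfig) -> FragmentSet:
    """Draw MNase fragments around planted dyads plus uniform background.

    Per-dyad fragment counts are Poisson(``mean_coverage``); fragment centers
    get Gaussian positional jitter; lengths are normal around the nucleosome
    footprint, truncated to ``frag_len_bounds``. A further
    ``bg_fragment_fraction`` of all fragments is uniform over the genome.
    """
    rng = cfg.rng(_STREAM_MNASE)
    dyads = _planted_dyads(ann, truth, cfg)
    lo_len, hi_len = cfg.frag_len_bounds
    records = []
    for chrom in sorted(ann.chrom_lengths):
        positions = dyads[chrom]
        L = ann.chrom_lengths[chrom]
        counts = rng.poisson(cfg.mean_coverage, size=len(positions))
        centers = np.repeat(positions, counts).astype(np.float64)
        centers += rng.normal(0.0, cfg.frag_jitter_sd, size=len(centers))
        n_sig = len(centers)
        n_bg = int(round(n_sig * cfg.bg_fragment_fraction / (1 - cfg.bg_fragment_fraction)))
        bg_centers = rng.uniform(200, L - 200, size=n_bg)
        centers = np.concatenate([centers, bg_centers])
        lengths = np.clip(
            np.round(rng.normal(cfg.frag_len_mean, cfg.frag_len_sd, size=len(centers))),
            lo_len, hi_len,
        ).astype(np.int64)
        starts = np.round(centers).astype(np.int64) - lengths // 2
        starts = np.clip(starts, 0, np.maximum(L - lengths, 0))
        ends = starts + lengths
        records.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    df = pd.concat(records, ignore_index=True) if records else pd.DataFrame(
        columns=["chrom", "start", "end"]
    )
    df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    return FragmentSet(df)


def _mark_spans(ann: Annotation, truth: pd.DataFrame, mark: str) -> dict[str, list[tuple[int, int]]]:
    """Chromosomal spans carrying enrichment for one mark."""
    genes = ann.genes_by_id
    spans: dict[str, list[tuple[int, int]]] = {c: [] for c in ann.chrom_lengths}
    if mark in ("H2A.Z", "H3K4me3"):
        flag = "h2az" if mark == "H2A.Z" else "k4"
        for _, row in truth.loc[truth[flag]].iterrows():
            g = genes[row["gene_id"]]
            if g.strand == "+":
                spans[g.chrom].append((g.atg - 250, g.atg + 650))
            else:
                spans[g.chrom].append((g.atg - 649, g.atg + 251))
    elif mark == "H3K27me3":
        marked = truth.loc[truth["k27"]]
        for dom, sub in marked.groupby("k27_domain"):
            gs = [genes[gid] for gid in sub["gene_id"]]
            chrom = gs[0].chrom
            spans[chrom].append((min(g.start for g in gs) - 500, max(g.end for g in gs) + 500))
    else:
        raise ValueError(f"unknown mark {mark!r}")
    return spans


def _moving_average(arr: np.ndarray, width: int) -> np.ndarray:
    c = np.concatenate(([0.0], np.cumsum(arr)))
    half = width // 2
    i = np.arange(len(arr))
    lo = np.clip(i - half, 0, len(arr))
    hi = np.clip(i + half + 1, 0, len(arr))
    return (c[hi] - c[lo]) / (hi - lo)


def simulate_chip(
    ann: Annotation,
    truth: pd.DataFrame,
    cfg: SimConfig,
    mark: str,
    mark_configs: Mapping[str, MarkConfig] | None = None,
) -> list[CoverageTrack]:
    """Replicate CPM-scale ChIP tracks for one mark.

    The underlying intensity is ``background_rel * threshold`` everywhere and
    ``enrichment_fold`` times that over marked spans. Each replicate draws
    independent per-bp Poisson noise around the shared intensity, then a
    147-bp moving average reproduces the fragment-scale autocorrelation of
    real CPM coverage (and smooths enrichment edges).
    """
    configs = dict(DEFAULT_MARK_CONFIGS if mark_configs is None else mark_configs)
    if mark not in configs or mark not in cfg.enrichment_fold:
        raise ValueError(f"unknown mark {mark!r}")
    background = cfg.background_rel * configs[mark].threshold
    fold = cfg.enrichment_fold[mark]
    spans = _mark_spans(ann, truth, mark)

    intensity: dict[str, np.ndarray] = {}
    for chrom, L in ann.chrom_lengths.items():
        arr = np.full(L, background)
        for s, e in spans[chrom]:
            arr[max(s, 0) : min(e, L)] = background * fold
        intensity[chrom] = arr

    mark_idx = sorted(configs).index(mark)
    tracks = []
    for rep in range(cfg.n_replicates):
        rng = cfg.rng(_STREAM_CHIP, mark_idx, rep)
        data = {}
        for chrom, lam in intensity.items():
            noisy = rng.poisson(lam).astype(np.float64)
            data[chrom] = _moving_average(noisy, NUC_FOOTPRINT)
        tracks.append(CoverageTrack(data, normalized=True, total_fragments=0))
    return tracks


def simulate_expression(ann: Annotation, truth: pd.DataFrame, cfg: SimConfig) -> pd.DataFrame:
    """Per-gene counts and log2 RPKM for wild type, depletion, overexpression.

    Count means are log-normal per expression state; genes planted to flip
    (H2A.Z+/K27+) lose ``depletion_effect`` log2 units in the depletion
    strain and receive small p-values, all other genes receive uniform
    p-values. RPKM uses the configured nominal library size: the toy gene set
    stands in for a genome-scale library.
    """
    rng = cfg.rng(_STREAM_EXPRESSION)
    genes = ann.genes_by_id
    mu_e, sd_e = cfg.expressed_log2rpkm
    mu_s, sd_s = cfg.silent_log2rpkm
    scale = cfg.nominal_library_size / 1e6

    rows = []
    for _, t in truth.iterrows():
        g = genes[t["gene_id"]]
        len_kb = g.length / 1e3
        if t["expressed_wt"]:
            wt_true = rng.normal(mu_e, sd_e)
        else:
            wt_true = rng.normal(mu_s, sd_s)
        dep_true = wt_true + rng.normal(0.0, cfg.strain_noise_sd)
        if t["flips_down"]:
            dep_true = wt_true - cfg.depletion_effect
        oe_true = wt_true + rng.normal(0.0, cfg.strain_noise_sd)

        counts = {
            name: int(rng.poisson(max(2.0**v, 0.0) * len_kb * scale))
            for name, v in (("wt", wt_true), ("tetoff", dep_true), ("oe", oe_true))
        }
        rpkms = {
            name: rpkm_log2(c, g.length, cfg.nominal_library_size, pseudocount=1.0)
            for name, c in counts.items()
        }
        if t["flips_down"]:
            p = 10.0 ** (-rng.uniform(3.0, 8.0))
        else:
            p = rng.uniform(0.0, 1.0)
        rows.append(
            {
                "gene_id": t["gene_id"],
                "count_wt": counts["wt"],
                "count_tetoff": counts["tetoff"],
                "count_oe": counts["oe"],
                "rpkm_log2_wt": rpkms["wt"],
                "rpkm_log2_tetoff": rpkms["tetoff"],
                "rpkm_log2_oe": rpkms["oe"],
                "log2fc": rpkms["tetoff"] - rpkms["wt"],
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)
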