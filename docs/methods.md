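# Methods

This note documents the models and procedures implemented in `nucposer`,
the defaults and why they were chosen, what the synthetic data generator
does and does not emulate, and the numerical conventions that matter for
reproducibility.

## Nucleosome map

### Differential filter

Dyads are called from per-bp MNase coverage with a two-window
mean-difference filter of total size 151: at position *i*, the mean of
coverage over the 75 bp to the right minus the mean over the 75 bp to the
left. The filter is antisymmetric, so it is zero on constant coverage and
equals the local slope scale on ramps (exactly 38 for a unit ramp, since
Σ 2j/150 for j = 1..75). On a coverage bump the filtered trace is positive
on the ascending flank, negative on the descending flank, and crosses zero
at the apex: a **descending zero-crossing** (`f(i) ≥ 0 > f(i+1)`) is
therefore a nucleosome dyad. The implementation uses a cumulative sum
(O(n) per chromosome) and is tested to float precision against a direct
window-sum oracle.

Numerical conventions:

* the 75 positions at each chromosome end are undefined (NaN) and never
  yield peaks;
* on an exact-zero plateau the peak is the last index of the non-negative
  run — a deterministic tie-break;
* the peak height is read from the *unfiltered* coverage at the crossing.

The zero-crossing convention is asymmetric at the basepair level: under a
genome reflection a crossing at *i* maps to *L−2−i*, so mirrored dyad calls
can shift by exactly 1 bp. All boolean and gene-level results are exactly
mirror-invariant; positional results are mirror-invariant to within 1 bp,
and the tests assert exactly that.

### +1/−1 nucleosome and NDR scan

Per gene, peaks are first restricted to heights above the minimum peak
height (default 20 reads/bp). The protocol this implements phrases the
cutoff both as a global peak filter and as a condition on the NDR-proximal
nucleosome; we apply it globally, which implies the per-pair condition and
makes the scan robust to sub-threshold background bumps inside valleys.
Peaks between 2 kb upstream and 100 bp downstream of the ATG (transcription
orientation) are then scanned as adjacent pairs starting from the gene side.
A pair qualifies as NDR-flanking when

1. center-to-center distance > 200 bp;
2. within the open interval between the centers, more than 20 bp of
   coverage lie below `min + 0.1·(max − min)` of that interval;

and the first qualifying pair wins (the scan starts downstream and moves
upstream, so the hit nearest the ATG is reported). The gene-side peak is
the +1, the distal peak the −1, and the NDR is the open interval between
the centers. Distances are center-to-center because only centers are
estimated. The "ATG" anchor is the annotated gene start on the coding
strand; the scan is strand-aware (performed in transcription orientation),
which is the natural reading for a mixed-strand annotation.

All five scan parameters are exposed (`PlusOneParams`); heights default to
raw reads/bp (`height_units` records the convention; CPM-scaled coverage
can be supplied with a correspondingly scaled cutoff).

### Bidirectional promoters

A +1 call is flagged bidirectional when its −1 coincides, within a
tolerance (default 50 bp, configurable — shared-nucleosome geometry leaves
no principled exact value), with the +1 of an oppositely stranded gene on
the same chromosome, or symmetrically. Tolerance 0 demands exact identity.

## Occupancy calls

Occupancy is maximum CPM coverage in a strand-aware ATG window compared to
a fixed threshold; defaults per mark are H2A.Z (−200/+600, 15 CPM, both
replicates, negative class < 7.5 CPM), H3K4me3 (−200/+600, 20 CPM, one
replicate), H3K27me3 (−100/+1000, 15 CPM, one replicate). Two documented
protocol ambiguities are resolved as configuration:

* the H2A.Z window orientation is stated both as −200/+600 and −600/+200 in
  different places; the −200/+600 (5′-region) orientation is the default
  and the other is reachable through `MarkConfig`;
* the comparison is `≥` by default (`inclusive=False` gives strict `>`),
  since the protocol alternates between "above" and "greater than";
* "in both replicates" is written only for H2A.Z; we require
  `n_replicates_required` passing replicates per mark (2 for H2A.Z, 1
  otherwise).

Thresholds may be re-derived from data as the 95% quantile of genome-wide
peak heights (`quantile_threshold`, linear interpolation of order
statistics with `h = (n−1)q`; other interpolation rules via `method`).

## Integration

* log2 RPKM = `log2(count / (len/1e3) / (library/1e6) + pseudocount)`, with
  pseudocount 1 so zero counts map to 0 (the protocol is silent on zeros).
* DE classes: up ⇔ log2FC ≥ 1 ∧ p < 0.01; down mirrored; boundary fold
  change counts as significant. p-values are consumed, not computed — the
  DE model fit is upstream of this package.
* Co-occupancy fractions are computed over *genes* (the alternative,
  per-nucleosome counting, would need a nucleosome-resolved H2A.Z
  assignment; the gene-level number is what the per-gene table supports).
* +1-anchored matrices read coverage over `[+1 − flank_up, +1 + flank_down)`
  in transcription orientation (defaults 1 kb/5 kb, the asymmetric window
  that places the NDR left of the +1 anchor), rows sorted by increasing
  gene length, off-chromosome cells NaN; binned median profiles ignore NaN
  and keep a trailing partial bin.
* Conservation classes count *distinct* BLAST subjects with percent
  identity > 40: < 50 hits low, > 300 high. The e-value ceiling (1e−10) is
  an upstream BLAST setting, recorded but not re-enforced at parse time.

Coordinates are 0-based half-open internally; GFF3 is converted on
read/write; bedGraph is the coverage interchange format (values written with
full float precision and parsed round-trip).

## Synthetic data generator

The generator is the package's study-condition stand-in for real
sequencing data. Defaults encode the conditions the analysis is validated
under: 200 genes on a 1.2 Mb chromosome, gene lengths 1.2–3 kb, ≥ 2 kb
between transcription units, 10% of genes in divergent pairs, nucleosome
repeat 165 bp, NDR width 150 bp, +1 dyad at ATG+30, fragment lengths
N(147, 8) truncated to [100, 250], 10 bp dyad jitter, Poisson(50) fragments
per nucleosome (≈ 50× coverage), 10% uniform background fragments (enough
to exercise the valley-depth rule), ChIP background at 0.5× each mark's
threshold with 6-fold enrichment (= 3× threshold) over marked spans, two
replicates, and expression log2 RPKM ≈ N(6, 1) for expressed vs N(0.5, 0.7)
for silent genes with a 3-log2-unit planted depletion effect.

Structural choices worth knowing:

* **Divergent pairs share one NDR**: the pair ATG gap is
  `ndr_width + 147 − 2·plus_one_offset`, which makes each gene's −1
  coincide exactly with its partner's +1 (and each upstream array with the
  partner's gene-body array). Pair members share their full chromatin
  class — a shared promoter nucleosome carries one state, and independent
  classes would make the partner's 5′ window overlap foreign enrichment.
* **H3K27me3 is domain-structured**: planted only as runs of ≥ 3 adjacent
  unpaired genes, emulating facultative heterochromatin; the enriched span
  covers the domain's genes plus 500 bp flanks.
* **Chromatin classes** (H2A.Z+/K4+, H2A.Z+/K27+, K27-only, H2A.Z-only,
  unmarked; default proportions 0.25/0.15/0.20/0.15/0.25) are assigned by
  largest-remainder quotas, so realized counts track the configured
  proportions tightly.
* **Expression truth follows class**: H2A.Z-positive classes are expressed
  in the wild type; K27-only genes are silent; unmarked genes are expressed
  with probability 0.4; H2A.Z+/K27+ genes flip to silenced under the
  simulated depletion (small p-values planted for flips, uniform p
  otherwise).
* **ChIP noise is autocorrelated**: per-bp Poisson draws around the
  intensity profile are smoothed with a 147-bp moving average, reproducing
  the fragment-scale correlation of real CPM coverage (iid per-bp noise
  would make window maxima over ~1 kb windows exceed any threshold almost
  surely, which real coverage does not). Enrichment edges are thereby also
  smooth. `enrichment_fold` multiplies the background, so fold 1 is
  statistically indistinguishable from background.
* **Determinism**: each component (annotation, chromatin, MNase, each
  ChIP mark × replicate, expression) draws from its own child stream of the
  master seed; outputs are byte-identical for a fixed config.
* RPKM uses a nominal library size (5e6) rather than the toy dataset's own
  totals: the toy gene set stands in for a sub-sample of a genome-scale
  library, keeping log2 RPKM on the scale the expression cutoff (default 2)
  expects.

What the generator does **not** emulate: sequence-composition and
mappability biases, MNase digestion preference, fuzzy/delocalized
nucleosomes, partially penetrant chromatin states, input-control structure,
batch effects between replicates, and count-model dispersion in expression
(log2FC and p are generated directly, since DE fitting is out of scope).
Passing recovery tests therefore demonstrate correctness of the algorithms
under their stated model, not robustness to every artifact of real
libraries.

## Validation scale

The end-to-end checks run at 200 genes × 1.2 Mb × 50× coverage (≈ 160k
fragments, six ChIP tracks), a size chosen so the whole suite and the
reproduction script each complete in well under a minute while keeping
every stratum populated with tens of genes. `scripts/acceptance.py` reports
all recovery quantities from a fresh simulation at exactly these defaults.

## Known limitations

* The +1 scan reports the first qualifying pair; a promoter with a
  secondary, more distal NDR is represented only by its proximal one.
* Peak positions inherit the ±1 bp asymmetry of the zero-crossing
  convention (see above).
* Occupancy calling is purely threshold-based by design — no
  input-control subtraction or model-based peak calling.
* The bidirectional flag depends on both genes' scans succeeding; a pair
  in which one partner's +1 is missed is not flagged.
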