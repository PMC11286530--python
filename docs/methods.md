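# Methods

## Scope and model

`carna` analyzes RNA–DNA contact pairs of the kind produced by in-situ
proximity-ligation assays (iMARGI/GRID-seq-style): each record is one read
pair with an RNA end (the transcript fragment) and a DNA end (the genomic
locus it was ligated to). The package starts from valid pairs; read
alignment, valid-pair calling, deduplication and peak calling are upstream
concerns and are assumed done.

The analysis proceeds in four stages:

1. **Annotation.** The RNA end of each pair is attributed to a source gene
   and its RNA class (protein_coding, lncRNA, snoRNA, snRNA, miRNA, rRNA,
   other_ncRNA).
2. **Locality.** Each contact is *cis* when both ends map to the same
   chromosome — at any distance; no proximal-distance cutoff is applied,
   because the definition is purely chromosomal — and *trans* otherwise.
3. **Landscape and calling.** Counts are aggregated per class (shares of
   cis and of trans, within-class trans fraction) and per gene
   (`n_total`, `n_trans`, `trans_fraction`). A gene is called
   *trans-acting* when `n_total >= 10` and `trans_fraction >= 0.20`, both
   inclusive; both thresholds are parameters. Called genes are ranked by
   `n_trans` (ties: trans fraction, then gene id). Per-gene genome-wide
   interaction maps bin the DNA ends and export arcs for circos-style
   plotting.
4. **Chromatin overlay.** RNA-interacting regions are scored against
   CPM-normalized mark tracks (mean signal per region), clustered with
   k-means into activity groups C1..Ck, and optionally compared between
   two conditions as per-region log2 ratios.

## Gene assignment rule

The attribution rule is a declared design choice of this package (contact
assays do not dictate one):

* **Same strand only.** The RNA end derives from a transcript, so only
  genes on the RNA end's strand are candidates. Antisense-only overlap
  yields `unannotated` (a flag `--allow-antisense` relaxes this).
* **Class priority.** Among overlapping candidates the winner is chosen
  by RNA-class priority — default
  `snoRNA > snRNA > miRNA > rRNA > other_ncRNA > lncRNA > protein_coding`
  — then by larger overlap, then lexicographically smallest gene id.
  Small-ncRNA-first priority is essential: many snoRNAs live inside long
  host genes (SNHG-family lncRNAs), and without the priority every
  snoRNA-origin read would be credited to its host, emptying all
  small-ncRNA analyses. The priority order is configuration, not a
  constant; the nested-attribution experiment (below) demonstrates both
  the default and the inverted order.
* `unannotated` contacts are retained in global cis/trans totals (the
  global split is class-agnostic) but excluded from class shares and gene
  profiles (they are not an RNA class).

Coordinates are 0-based half-open internally; the 1-based conventions of
the pairs dialect and GTF are converted only in the parsers/writers.
Records on chromosomes absent from the assembly are skipped and counted,
never fatal (real pairs files contain scaffolds); positions beyond the
chromosome end are a hard parse error, since clipping would silently
distort locality statistics.

## Chromatin-state clustering

The overlay stage fixes choices the heatmap-style grouping leaves open:

* **Scores.** `score(region, mark)` is the length-weighted mean of the
  mark's bins over the region (equivalently the per-base mean), computed
  from bedGraph-derived binned tracks, CPM-normalized
  (`value * 1e6 / library_size`).
* **Clustering.** k-means (default `k = 4`, mirroring a four-group
  C1–C4 structure) on the column-z-scored matrix, best of `n_restarts`
  (default 10) by within-cluster sum of squares, seeded and
  deterministic. Zero-variance columns z-score to zero; a matrix with
  no variance anywhere is rejected with advice to use `k = 1`.
* **Naming.** Clusters are relabeled C1..Ck by descending mean *raw*
  signal of a labeling mark (default H3K27ac), so C1 is the
  transcriptionally most active group. The mark is configurable.
* **Comparison.** Condition ratios use
  `log2((score_b + pc) / (score_a + pc))` with pseudocount `pc = 1` CPM,
  keeping ratios finite at unmarked regions.
* **Average profiles** rescale each region (± flank) to `n_bins` equal
  segments by integrating the per-base step function, reversing
  minus-strand regions; values outside chromosome bounds contribute zero.

## Synthetic study conditions

The generator emulates the statistical structure of a chromatin-associated
RNA experiment with known truth; its defaults are the conditions under
which all recovery results below are measured.

* **Genome and annotation.** 2–4 chromosomes of ~2–10 Mb. Genes are
  placed uniformly without overlap, except that a configurable fraction
  of snoRNAs is nested strictly inside same-strand lncRNA hosts.
* **Contacts.** Per pair: a source gene is drawn proportional to
  per-class expression weights (protein-coding dominated:
  1.0 / 0.4 lncRNA / 0.3 snoRNA / 0.3 snRNA / ...); the RNA end is uniform
  in the gene span with the gene's strand; locality is Bernoulli with the
  gene's trans rate — defaults
  `protein_coding 0.02, lncRNA 0.03, miRNA 0.05, snoRNA 0.8, snRNA 0.8,
  rRNA 0.5, other_ncRNA 0.05`, encoding the observation that mRNAs and
  lncRNAs stay near their site of transcription while snoRNA/snRNA act
  predominantly in trans. A single global rate can replace the per-class
  map, and per-gene hotspot overrides model individually trans-enriched
  genes.
* **Cis kernel.** Cis DNA ends land at an exponentially distributed
  distance from the gene midpoint (scale 100 kb, a single-parameter
  monotone decay consistent with transcription-proximal contact),
  clipped to chromosome bounds. Trans DNA ends are uniform on a
  uniformly chosen other chromosome; trans target identity is
  deliberately not modeled — locality, not target choice, is what the
  downstream statistics consume.
* **Tracks.** Planted clusters assign each region a signature vector over
  the marks plus Gaussian noise (floored at zero); regions are
  bin-aligned so zero-noise scoring recovers signatures exactly.
* RNA ends are 1 bp wide, matching the single-position pairs dialect.
  Identical seeds give byte-identical outputs.

What the generator does **not** emulate — and hence what passing recovery
tests do not show about real data: ligation artifacts and PCR duplicates,
mappability and coverage biases, exon/intron structure and nascent
transcription gradients, non-uniform trans targeting (hotspot loci),
overlapping same-strand genes other than snoRNA nesting, and realistic
chromatin-domain autocorrelation in the mark tracks.

## Problem sizes and numerical choices

Recovery experiments run at desk scale, chosen so each completes in
seconds to about a minute on one CPU while leaving the binomial bands
tight enough to be meaningful: 1,000,000 pairs for the global cis/trans
split (3-sigma band ±0.05 percentage points around 3%), 200,000 pairs for
per-class fractions, 20 replicate simulations of 5,000 pairs each for the
caller sensitivity/specificity design (100 genes, 5 hotspots at trans
rate 0.6 against a 0.02 background, ~50 expected contacts per gene), 200
regions × 6 marks for clustering (signature separation 8 within-cluster
sd). Exactness tolerances: region scoring and bedGraph binning agree with
per-base accumulation oracles to 1e-9; the trans-acting caller is checked
against brute-force enumeration over the full integer grid `n_total <= 30`.

## Limitations

* Gene-level attribution only: no exon/intron or nascent-vs-mature
  distinction, and ambiguous same-class overlaps resolve by overlap
  length and id, not expression evidence.
* The trans-acting call is a fixed-threshold rule, not a statistical test
  against a background model; thresholds are exposed as parameters.
* bedGraph (not bigwig) is the required signal interchange; binning
  resolution is bounded by the track `bin_size`.
* k-means with z-scored columns is one defensible grouping; hierarchical
  or density-based alternatives could split borderline regions
  differently. Determinism is guaranteed only for a fixed seed,
  restart count and scikit-learn version.
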