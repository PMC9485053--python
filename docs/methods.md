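# Methods

## The question the pipeline operationalizes

Two models of MeCP2 targeting make different predictions about tandem CA
repeats.  If MeCP2 reads methylated CAC wherever it occurs, then (i) CAC
methylation inside [CA]n arrays should match the surrounding DNA, (ii) ChIP
enrichment over arrays should equal that of any region with the same mCAC,
and (iii) gene misregulation after MeCP2 loss should follow gene-body mCAC
content, not gene-body CA-repeat content.  If instead arrays are cooperative
high-affinity platforms, all three comparisons should show a repeat-specific
excess.  `carpet` computes the three comparisons on any suitably formatted
dataset and ships a synthetic-data generator whose planted structure makes
each comparison's expected outcome known exactly.

## Statistical kernel

* **Spearman R²** — squared Pearson correlation of average ranks (ties get
  the mean of their ranks).  R² is the square of the correlation
  coefficient, not a regression R².  At least 3 points; no missing values.
* **Pearson R²** — squared product-moment coefficient; zero variance in
  either input is a degenerate-input error rather than a silent NaN.
* **Equal-count bins** — values are stably sorted (ties keep input order)
  and cut into contiguous groups whose sizes differ by at most one, larger
  groups at the low end.  Deterministic, so binned curves are reproducible.
* **Mean ± SEM** — sample SD (n−1) over √n; a singleton group has SEM 0 by
  definition so report tables never contain missing cells.

## Repeat detection

De novo scanning finds *perfect* maximal in-phase runs of a unit and of its
reverse complement (a TG run is a CA-class array read from the other
strand), length ≥ 10 bp, partial trailing units excluded so
`length = unit_count × |unit|`.  N splits runs; runs may touch contig ends.
Where runs of different units overlap (possible for unit families), the
longer run wins with a deterministic tie-break.  Perfect-run scanning was
chosen over RepeatMasker-style diverged-repeat detection because it is
reproducible without alignment heuristics; annotation-driven workflows use
the RepeatMasker table reader instead (labels `(CA)n`/`(TG)n` → CA class,
the six CAN labels → CAN class, anything else → other).

Motif counting is overlap-inclusive on both strands (`CACAC` holds two
CACs; GTG occurrences are minus-strand CACs) and counts a motif into a
region if its first plus-strand base lies inside — unambiguous for motifs
straddling boundaries.  A canonical-k-mer counter would merge CAC/GTG;
strand occurrences are counted explicitly here.

## Methylation aggregation

Per-site ratios are computed first (methylated / total reads); aggregates
are *unweighted means of ratios over covered sites*, never read-weighted
sums, after the per-dataset coverage threshold (≥5 reads for the
lower-coverage bisulfite sets, ≥10 for the high-coverage one).  Uncovered
sites are kept in the table (flagged) and enter only coverage-fraction
denominators.  Context is the trinucleotide starting at the C, read 5′→3′
on the site's own strand; CAC ⊂ CA, disjoint from CG.  Inside repeat loci
the context filter can be dropped so all cytosines on both strands are
aggregated.

Two regional summaries exist and serve different purposes:

* **mCAC/kb** (`window_mcac_track`) — sum of covered CAC ratios per tiling
  window × 1000/width; the browser-track quantity.  Partial terminal
  windows scale by their true length.
* **mCAC level** — the mean per-site ratio of a region.  This is the binned
  covariate of the occupancy analysis, because it is scale-free: a CA array
  is wall-to-wall CAC (~1000 CAC/kb against ~31/kb genome-wide), so any
  per-kb density covariate would separate the sequence categories by ~30×
  even when per-site methylation is identical — exactly the confound the
  analysis exists to remove.  Binning by level makes "same methylation,
  same binding?" a like-for-like question.

Repeat loci are grouped greedily in genome order into chunks whose
cumulative repeat length first reaches 1 kb (the trailing chunk keeps its
true length); chunk methylation is summed over member loci only, never over
the intervening sequence.

### The paired inside-vs-outside test

Real (and simulated) methylomes vary regionally, so sites are correlated
over tens of kilobases and a site-level SE of the global inside/outside
difference would be dishonestly small.  `local_inside_outside` therefore
pairs every array with its own ±2 kb flanks (array bases excluded), takes
the per-array difference of mean CAC ratios, and reports the mean paired
difference with its SE *over arrays*.  Pairing cancels the regional field
exactly; the test asks precisely whether arrays deviate from their own
neighbourhood.  Global inside/outside means are still reported alongside.

## Occupancy analysis

Coverage tracks come from bedGraph.  The enrichment signal is the log2
ratio track, `log2((wt + p)/(ref + p))` per segment after scaling both
tracks to equal totals (pseudocount p = 1 by default keeps values finite);
a region's enrichment is the base-weighted *mean of the log2 track* over
its bases — the same summary a log2 bigWig averaged over genomic locations
gives, and identical machinery for repeat chunks and windows, so the three
categories are directly comparable.  A per-region log2-of-mean-coverage
variant (`log2_enrichment`) is also provided.

Background windows are drawn exactly uniformly over all valid placements
(valid-start segments are enumerated, then indexed), with replacement,
rejecting only overlap with CA arrays; the seed is recorded.

Each category's regions are cut into 30 equal-count bins of the level
covariate; categories with fewer regions than bins fall back to two regions
per bin (minimum three bins), keeping an empirical SEM per bin.  The
category summary is the squared Spearman correlation of (bin mean
covariate, bin mean enrichment).

Cross-category coincidence is tested at matched covariates, not matched bin
indices (the categories' covariate spreads differ): the background curve is
linearly interpolated at each repeat-category bin's mean covariate, and the
bin's z-score uses the pooled SD of all its category's region-level
residuals around the background curve, scaled by 1/√(bin members), combined
with the interpolated background SEM.  Pooling keeps the yardstick stable
for bins holding a handful of chunks, while a genuine category offset moves
every bin's z in the same direction and remains detectable.  Bins outside
the background covariate range are excluded as not comparable.

## Expression analysis

Differential-expression results are consumed (DESeq2-style columns; BH
adjustment is upstream).  Significance is strict `< 0.05` on padj (or
p-value for low-powered datasets).  The analyzed set for binned curves is
the significantly regulated genes; binning all genes is available as a
flag.  Per-gene covariates: %CA of gene-body bases; mCAC as the *sum of
per-site ratios* (the expected number of methylated CACs — a hard-call
count at ratio ≥ 0.5 is available as a sensitivity switch), including or
excluding array bases; mCA summed inside arrays; and mCAC per kb of gene
length.  Genes with no covered CAC enter with covariate 0 and a flag.
Covariate ties are broken by stable gene-id order.  R² is reported from the
unbinned (covariate, log2FC) pairs of the analyzed set; the 30-bin curve is
descriptive.

## The synthetic study

The generator produces a study whose statistical structure matches the
analysis assumptions, at a size a laptop handles in seconds.  Defaults (the
standard conditions used throughout the test suite):

| parameter | default | why |
|---|---|---|
| contigs | 2 × 500 kb | smallest size at which all three region categories have enough members |
| CA arrays | 200, 30–90 units | ≥ 10 bp guaranteed; unit counts chosen so 200 arrays yield ~23 chunks of ≥1 kb cumulative repeat, enough bins for a resolved curve |
| other repeats | 300 loci of CACG/CACT (20–50 units) + 40 CAN arrays | CAC-bearing units give every other-repeat chunk a defined covariate |
| rates | mCAC 0.06, mCA-other 0.01, mCG 0.8, other 0.002 | neuron-like ordering mCG ≫ mCAC ≫ mCA-other |
| regional field | lognormal σ = 0.7 on 25 kb blocks, mean 1 | broad regional variation of non-CG methylation; gives ChIP and per-gene analyses genuine signal to track |
| array enrichment | 1.0 | the null: equal per-site CAC rates inside and outside arrays |
| coverage | Poisson, mean 10 | mid-range bisulfite depth; both thresholds exercisable |
| ChIP | 100 bp tiles, slope 1.0, noise SD 0.3, depth 100 | expected log2(WT/ref) = slope × (tile mean true CAC level / genome mean level) + noise; binding depends only on methylation, never on repeat membership |
| genes | 300 of 1–3 kb, non-overlapping | repeat placements inside gene bodies accepted with probability 0.25, so arrays carry a realistic minor share of per-gene mCAC |
| expression | slope 0.5 per SD of true gene mCAC, noise SD 0.25, 50% regulated | regulated genes get near-zero p-values, others Uniform(0,1); BH applied across all genes so selection calibration is testable |

ChIP truth uses *true* methylation probabilities, not observed ratios, so
coverage noise and binding noise stay separable in tests.  The driver is
the local mean CAC level (normalized by its genome mean) rather than a
per-kb density, for the comparability reason given above.  Everything is
deterministic under (seed, config); each stage has its own child generator,
so e.g. the methylome can be re-simulated at a different planted enrichment
on a fixed genome.

### What the generator does and does not emulate

It reproduces the features the analysis logic depends on: planted perfect
arrays recoverable at exact coordinates, context-specific methylation with
regional correlation, coverage-limited binomial observation, occupancy
log-linear in methylation, fold-changes log-linear in gene mCAC with
calibrated p-values.  It does not emulate read-level artefacts (mapping
bias against repeats, bisulfite conversion failure, PCR duplicates),
realistic genome composition (CpG islands, isochores, diverged repeats),
hmC/mC ambiguity, or peak-shaped ChIP signal.  Green tests therefore
certify the *analysis machinery* — that the pipeline finds a repeat effect
exactly when one is planted and not otherwise — not the biological claim on
any real dataset.

## Numerical and edge-case conventions

Coordinates are 0-based half-open everywhere internally; cytosine reports
are 1-based on disk (Bismark dialect), RepeatMasker tables are 0-based with
a 1-based switch.  Aggregates over zero qualifying sites raise an
undefined-mean error instead of returning 0.  Pseudocounts guarantee finite
enrichment.  The background sampler enumerates valid placements, so a fully
excluded genome raises a placement error rather than looping.  Report
floats are written at 10 significant digits; manifests record SHA-256
digests of every output, and byte-identical reruns are a tested property.

## Known limitations

Per-gene covariate aggregation loops over genes (fine for thousands, slow
for hundreds of thousands); bigWig input is not supported (convert to
bedGraph); the chunking rule ("cumulative repeat length first reaching
1 kb") is one reasonable reading of extending repeat regions to ~1 kb
equivalents — it is isolated behind a single function so alternatives are
easy to slot in; imperfect/diverged repeats are annotation-only; and no
attempt is made to call MeCP2-enriched peaks, since genome-wide occupancy
with few discrete peaks makes peak counts a poor summary of this signal.
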