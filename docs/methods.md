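# Methods

This note documents the models, parameter choices and numerical
conventions behind `omlo`, and what the synthetic-data tests do and do
not establish about real organoid data.

## Barcode code and decoding

MERFISH encodes each gene as a 16-bit binary word read over sequential
imaging rounds.  The codebook is the set of weight-4 codewords of the
[16, 11, 4] extended Hamming code: a 16-bit word with support S is a
codeword exactly when the XOR of its set bit positions (each position as
a 4-bit vector) is zero and |S| is even; for |S| = 4 this yields 140
words.  Constant weight 4 equalizes per-round signal load; minimum
pairwise distance 4 makes single-bit correction unique (a word at
distance 1 from one codeword is at distance ≥ 3 from every other).  The
construction is deterministic and verified at build time: all pairwise
distances are checked, and maximality is confirmed by testing every one
of the C(16,4) = 1820 weight-4 words for admissibility.  Four words are
reserved as blanks by a seeded draw recorded in the codebook JSON; the
ratio of mean blank counts to mean gene counts estimates the spot
misidentification rate (its expectation is 0 for error-free reads and 1
for uniformly random words, since every codeword decodes exactly 17 of
the 2^16 words).

Decoding is exact-match first, then (optionally) unique distance-1
correction, else UNASSIGNED.  The decoder is dictionary-based and is
tested for exact agreement with a brute-force nearest-codeword oracle on
10,000 random words.

**Spot→cell assignment.**  Nuclear labels are dilated per label by 10 px
(14 px optional, matching higher-resolution rounds); a background pixel
reachable by several labels goes to the label with the nearer original
centroid, which keeps dilated cytoplasm territories disjoint.  Spots map
to pixels by `floor(coord_um / pixel_size_um)`, origin at the image
top-left, y down.  Spots on background after dilation, and UNASSIGNED
decodes, are excluded from the count matrix; assigned + dropped always
equals total.

**MERFISH QC.**  Blank columns are removed first; cells are kept when
both nucleus and cell area lie strictly inside the (2.5%, 97.5%)
quantile band of each metric (boundary ties removed — conservative), at
least 10 genes are detected and at least 13 reads are present.
Quantiles are recomputed per invocation; a frozen-threshold mode reuses
a previous pass's cutoffs, making the filter idempotent.  Panel
validation is the Pearson correlation of per-gene totals against bulk
FPKM over shared panel genes (log1p is a switch, default off).

**Probe-region filter.**  A target region passes with GC ∈ [0.35,
0.75], melting temperature ∈ [60, 80] °C, specificity index > 0.9, and
no exact shared substring longer than 15 nt with any off-target
(rRNA/tRNA) sequence; a gene needs ≥ 64 passing regions.  Tm defaults to
nearest-neighbor thermodynamics at 50 mM Na⁺ (Biopython `Tm_NN`); any
monotone Tm model satisfies the pass/fail contract, and the model and
salt conditions are what this package records.  The specificity index
can be supplied per region (e.g. from upstream probe-design software)
or computed as the fraction of the region's 15-mers unique to its gene
within a supplied transcriptome — a documented surrogate, not a
standardized formula.

## Interior/exterior zoning and spatial tests

The metabolic index M is the arithmetic mean of normalized expression of
P4HA1, STC2, PGK1, VEGFA, EGLN3 and PFKP — six glycolysis/hypoxia genes
that rise as oxygen falls toward the organoid core.  Cells with M
strictly above the 60th percentile (linear-interpolation quantile) are
interior; ties at the threshold go to exterior, so with distinct values
the interior fraction is exactly 0.40.  The direction (high M =
interior) follows from the hypoxic-core physiology that motivates the
gene set.  Zone composition differences are tested per cell type with
the exact two-sided Wilcoxon rank-sum after averaging image-level
proportions per organoid (organoids, not images, are the experimental
unit).

Edge validation computes each centroid's minimal perpendicular distance
to the convex hull of all centroids (exact point-segment geometry,
checked against a brute-force oracle at 1e-9); cells deeper than 400 µm
are flagged and excluded from edge-distance summaries only — zone calls
never use geometry.

Density maps: per-set bivariate Gaussian KDE (Scott's normal-reference
bandwidth) on a shared 100×100 grid over the joint bounding box, each
layer z-scored over grid nodes (mean 0, sd 1 exactly), difference A − B.

**Grid co-localization.**  50 µm square bins anchored at the joint
bounding-box minimum (hence translation invariant); only bins occupied
by ≥ 1 cell of either set enter, since empty bins would inflate the
correlation.  The observed Pearson r of binned abundances is compared
against n_perm = 10,000 label shuffles preserving group sizes;
one-sided p = (1 + #{null ≤ observed}) / (n_perm + 1) (add-one rule —
never 0, exact under exchangeability; calibration is verified by
simulation against a uniform ideal).  Cohort inference pairs each
section's observed r with its null **median** (the mean is a switch) and
applies the exact paired signed-rank test; with all sections one-sided
this gives 2/2^m — e.g. 0.00195 at m = 10.

## Signature scores and regional identity

The signature score ranks genes per cell by expression (descending,
average ranks for ties), caps ranks at r_max + 1 with r_max = 1500, and
sets `U = Σ ranks − n_g(n_g+1)/2`, `score = max(0, 1 − U/(n_g·r_max))`.
The score is rank-based, hence invariant to monotone transforms of the
normalization; its floor when an entire signature is buried below the
cap is (n_g − 1)/(2·r_max) (≈ 0.0013 for n_g = 5), effectively zero.
The ventrality index is the ratio of ventral to dorsal scores: V > 1 →
ventral, V ≤ 1 → dorsal (exact tie dorsal; zero dorsal with positive
ventral → +∞ → ventral), except that cells with both scores below their
25th-percentile cutoffs — computed over the full input population — are
ambiguous.  Regional markers come from a DE table filtered at
p_adj < 0.05, base mean ≥ 200 and |log2FC| > 3, split by sign.

Timepoint proportions are trend-tested with Mann-Kendall using the
continuity-corrected normal approximation at every n — this is the
convention of the widely used R implementation and reproduces the
standard n = 5 values (S = 10 → p = 0.027; |S| = 8 → 0.086; 6 → 0.22;
4 → 0.46).  An exact-enumeration mode exists but is not the default.
Adjacent collection days are merged (65/70 → 65, 99/105 → 102,
120/126 → 123, 150/156 → 153) via a configurable map.

Co-transmission: positivity is depth-corrected count ≥ 1; cells negative
for all of TH, TPH1 and GAD2 are excluded, and TH⁺ cells positive for
two or more of GAD2/TPH1/SLC17A6 are dropped before computing TH-only /
TH+GAD2 / TH+TPH1 / TH+SLC17A6 proportions.  SLC17A6 positivity does not
contribute to the initial inclusion step (it has no exclusive claim to a
transmitter class in this panel); it enters only as a co-transmission
partner.

Risk enrichment: a gene is "expressed" in a cell type when its mean
depth-corrected count per cell exceeds baseline = 1; a one-sided
(greater) Fisher exact test on the 2×2 risk × expressed table over the
gene universe (all matrix genes by default, overridable), Bonferroni
over the number of types tested.  Fisher tails are computed with exact
integer binomials, so they agree with enumeration to machine precision.

Label transfer: seeded per-label downsampling (to the smallest class or
a given target), 100 nearest reference neighbors by Euclidean distance
in the shared embedding, plurality vote, exact top-label tie → excluded.
Panel heatmaps: per-type mean of depth-corrected counts, log1p, z-score
per gene column, average-linkage Euclidean hierarchical ordering of rows
and columns (linkage recorded in the output).  Term-set deduplication
drops terms with < 6 genes, joins terms with Jaccard > 0.2, takes
connected components, and picks the largest gene set per component (tie
→ lexicographically smallest id); components are verified against an
independent union-find oracle.

## Synthetic data: what it emulates and what it does not

`gen_section` places cells uniformly over a disk by area (r = R√u),
defines truth depth analytically as (R − r)/R — deliberately independent
of the convex-hull estimator under test — and scales the six metabolic
genes' mean counts by exp(slope × depth) with slope 2 by default.  DaNs
and GabaNs draw angles from π-wide sectors whose centers are separated
by `segregation_angle` (π → disjoint half-disks).  Counts are negative
binomial with dispersion 0.3 (variance μ + 0.3 μ²), the overdispersion
scale typical of UMI counts, without fitting any dataset.  The default
section holds 6,000 cells in a 1,000 µm radius — the density at which a
ten-section MERFISH experiment yields several tens of thousands of cells
and ~2–5 cells per occupied 50 µm bin, enough for binned correlations to
be informative.  `gen_timecourse` plants ventral fractions
(0.45 … 0.85 over five timepoints by default) as Bernoulli identity
draws and enriches ventral/dorsal marker panels 2³-fold in matching
cells.

These generators reproduce the *statistical geometry* the methods assume
— gradients, sectors, overdispersion, bit-flip errors — but not tissue
realism: no segmentation errors, doublets, z-axis structure, probe
chemistry, batch effects, spatially varying detection efficiency, or
irregular section outlines.  Passing tests therefore demonstrate that
each method recovers the structure it claims to detect at realistic
noise and sample sizes, and that the exact tests match their
definitions; they do not certify performance on real sections, where the
unmodeled artifacts dominate error budgets.

## Numerical conventions

* Exact rank-sum p-values by dynamic programming over the rank-sum
  distribution (feasible when C(n1+n2, n1) ≤ 10⁶; cross-group ties fall
  back to the tie-corrected normal approximation, flagged in the
  result).  Exact signed-rank by generating function over doubled ranks
  (keeps tied half-ranks integral), n ≤ 25.  Two-sided exact p is
  2·min(tails) capped at 1 — the convention that yields 2/20 = 0.1 and
  2/1024 = 0.00195 for completely separated data.  Zero differences are
  dropped and reported.
* Permutation p-values use the add-one rule; all randomness flows
  through `numpy.random.default_rng(seed)` and seeds are echoed into
  outputs.
* Quantiles use NumPy's linear interpolation throughout.
* Degenerate inputs warn and take the conservative branch: all-equal
  metabolic indices → all exterior; constant z-score columns → zeros;
  all-zero paired differences → p = 1.
* Test-suite problem sizes are chosen for precision per check: planted
  recovery runs at n = 2,000 cells (100 seeds × 199 permutations for the
  detection-rate checks), the decoder oracle at 10,000 words, the
  blank-rate symmetry check at 400,000 words (the mean over only four
  blank barcodes needs that many draws for ±0.2 precision), and the
  Fisher oracle exhaustively over every table with N ≤ 60.

## Known limitations

* `build_codebook` is provably maximal only for (16, 4, 4); other
  parameter sets use a deterministic lexicographic greedy construction
  that satisfies the constraints but may be sub-maximal.
* The co-localization grid is the data bounding box, not a tissue
  outline; sections far from convex will include some off-tissue bins
  (they are empty and excluded, but bin anchoring still follows the
  bounding box).
* The exact signed-rank enumeration treats tied magnitudes with average
  ranks; alternative tie conventions (e.g. Pratt) are not implemented.
* `read_counts` densifies matrices; panels of a few hundred genes are
  the intended scale, not genome-wide single-cell atlases.
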