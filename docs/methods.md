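# Methods

## Scope and data flow

`tsnet` consumes the outputs of a standard isoform-level RNA-seq pipeline
(per-sample FPKM table with differential-expression calls), a genome FASTA,
an isoform annotation (GTF), TF motifs (JASPAR counts), an SF motif table
(factor, literal motif, signed affinity), a base-wise conservation track
(bedGraph) and gene sets (GMT). Read alignment, expression quantification
and differential calling are out of scope: the `de_flag` column is consumed
as given. The stages run in order — DEI filtering and clustering, promoter
(PRD) and exon–intron (EID) scoring, per-group LARS fits, network assembly,
enrichment — and every stage persists its outputs, so any stage can be
re-run from intermediates.

## Filtering and grouping

An isoform is analysed only if it is differentially expressed, validated at
the protein level, and has FPKM strictly greater than 5 in **every** sample
of the condition in which it is up-regulated. Boundary readings are strict
throughout the package: FPKM = 5 fails, motif |score| = 5 passes, motif
length = 15 passes, hit conservation = 2 passes, set sizes 10 and 100 pass.

Co-expression groups come from average-linkage hierarchical clustering on
the distance d = 1 − r (signed Pearson correlation across all samples —
co-expression means positive correlation, so |r| is deliberately not used).
Flat clusters are cut at d = 0.5; any cluster above 30 members is
recursively re-cut at its own merge heights, and clusters under 10 are
dropped and logged. The two-stage rule exists because a pure "split only
when > 30" top-down cut would merge two well-separated blocks whose union
happens to be ≤ 30; the correlation cutoff first separates incoherent
profiles, the recursion then enforces the 10–30 size constraint. Constant
expression rows (undefined correlation) are removed first. Tie-breaking is
deterministic: rows are sorted by isoform id before clustering and groups
are numbered by their first member.

## Interaction strengths

**TF side.** Promoters are the 2000 bp upstream of the TSS (reverse
complement of the downstream 2000 bp for minus-strand isoforms; contig-edge
truncations are flagged). PWM counts are converted to probabilities, a
pseudocount of 0.01 is added and columns renormalized (so log odds are
finite), and scoring is the log₂-odds sum against the background base
composition (uniform by default). Both strands are scanned — TF binding
sites are double-stranded elements — and windows containing N are skipped.
A window is a site when its score reaches `threshold_fraction` (default
0.8) of the PWM's maximum achievable score; with that default only
near-consensus matches survive, and all retained scores are positive. The
strength `T_ij` is the sum of site scores, zero when there are none; TFs
with no sites on any promoter are removed. Absolute strength values are
implementation-defined (an HMM-based scanner would give another scale);
this is immaterial because the regression standardizes every column.

**SF side.** SF motifs are short literal sequences with a signed affinity
score (positive = enhancer-type, negative = silencer-type); U is mapped to
T on input, motifs with |score| < 5 or length > 15 are discarded. Windows
are [p−200, p+200) around every internal splice site, clipped to contig
bounds and merged per isoform when they overlap; single-exon isoforms
contribute nothing. Occurrences are exact substring matches on the
isoform's sense strand (pre-mRNA reading; a flag enables both
orientations), deduplicated across merged windows. Each hit is scored by
the mean per-base conservation of the spanned nucleotides and deleted
below 2; `S_ik` is the mean conservation over retained hits — a mean, not
a sum, so isoforms with many exons are not trivially favoured — and 0 with
no hits (absence of evidence is treated as no interaction). Paralogous
hnRNP factors with near-identical binding profiles (A1/A2, H1/H2/H3,
C/C1/C2, E1/E2) are merged by element-wise strength averaging when all
members are present. Exact matching replaces an aligner here: the motifs
are short literals, and exact search is the reproducible core of
zero-mismatch alignment.

A single-factor genome-wide scan is also provided: all exact occurrences
of one motif are conservation-scored, the top ⌈keep_fraction · n⌉ (default
one third) by conservation are kept with coordinate tie-breaking, and the
kept hits are mapped to overlapping gene bodies.

## Regression and model selection

Per group, the response is one value per isoform — by default the mean
FPKM over the samples of the isoform's up-regulated condition (all-sample
mean and log₂ variants are available). The design is the TF strength block
followed by the SF block; members missing from a matrix contribute zero
rows (logged). Predictor columns are centered and scaled to unit Euclidean
norm (constant columns dropped), the response is centered, and scaling
factors are kept so coefficients and intercept are reported on the
original scale.

The path algorithm is plain LARS: the active set grows one predictor at a
time (no LASSO drop step), advancing along the equiangular direction of
the active set until an inactive predictor attains the same absolute
correlation with the residual. Ties break by column order. An entrant that
is collinear with the active set spans no new equiangular direction and is
set aside; the path truncates only if no entrant admits a well-posed step.
When no inactive predictor can catch up, the final segment runs to the
active-set least-squares solution, so a completed path ends at the OLS fit.

**Model size.** Three stopping rules are implemented.

* `ebic` (default): extended BIC, `N·ln(RSS_m/N) + m·ln N + 2γ·m·ln P`
  with γ = 1, evaluated on least-squares refits of each breakpoint's
  active set, over model sizes up to ⌊(N−1)/2⌋. The cap matters: with
  P ≥ N the near-saturated refits interpolate and would win on RSS alone,
  and EBIC's consistency argument assumes model size well below N.
* `cp`: Mallows' Cp, `RSS/σ̂² − N + 2m`, on the path estimates, with σ̂²
  from the largest path model retaining at least 4 residual degrees of
  freedom. This is the classical choice and works when P ≪ N, but in the
  P ≥ N regime greedy fitting drives σ̂² toward zero and Cp over-selects
  badly (it keeps ~20 of 60 predictors on pure noise); it is retained for
  low-dimensional designs and comparison, not as the default.
* `max_steps_k`: take step k, mirroring the classic "until k variables
  have entered" formulation.

In every mode an exact fit (RSS ≤ 10⁻¹⁰·TSS) short-circuits to the
smallest perfectly fitting step. Reported coefficients are the LARS path
coefficients at the chosen breakpoint, back-transformed to the original
scale; adjusted R² = 1 − (1−R²)(N−1)/(N−p−1) is computed for that step,
and a group is kept when adjusted R² ≥ `r2_min` (default 0.5, mirroring
the removal of ill-fitting groups).

## Networks and enrichment

A kept fit becomes a bipartite network: an edge factor→isoform exists iff
the factor was selected for the group **and** its strength on that isoform
is positive; the edge carries the strength as weight and the coefficient's
sign (negative read as putative inhibition). Target–target edges from
curated interaction databases are out of scope. Networks serialize to a
TSV (round-trip tested) and GraphML.

Enrichment maps each network to a deduplicated gene list (target genes
plus factor names) and applies a one-sided Fisher's exact test — the exact
hypergeometric upper tail, not a normal approximation — per gene set, with
BH q-values within each collection. GO-style collections are size-filtered
to 10–100 genes against the universe; pathway-style collections are not.
The universe defaults to the collection's genes intersected with the
experiment's measurable genes (configurable). Both a q < 0.05 flag and a
raw p < 10⁻⁴ flag are reported, matching the two reporting conventions for
pathway and GO results respectively.

## The synthetic-data generator

The generator emulates the statistical structure the model assumes, not
raw sequencing data (no reads, no realistic phylogeny — background
conservation is i.i.d. truncated normal). One chromosome carries isoforms
in non-overlapping 9 kb slots (promoters can never collide), each with
three exons whose four splice sites yield overlapping windows that
exercise merging. Defaults: 80 isoforms, 3 groups of 20–25 (explicit sizes
can be given), 12 TFs (8-mer PWMs, 0.85/0.05 probabilities, so the 0.8
threshold admits only exact consensus matches), 8 SFs (7-mer motifs,
|affinity| ∈ [5, 10]), GC 0.41, background conservation mean 0.5,
planted-site conservation ≥ 3, noise SD 0.05.

Per group, 5 support factors are drawn; every member isoform receives 1–3
planted sites per support factor (consensus matches in the promoter for
TFs; motif occurrences under elevated conservation inside splice windows
for SFs — so every planted hit survives the filters by construction, and
site-count/conservation variation makes the strength columns informative).
The expression summary is then the model read forward:
`y = intercept + Σ coef·strength + N(0, noise_sd)`, computed from the
strengths the package's own scanners produce on the planted genome (so
incidental background hits are part of the linear structure, and a
noiseless bundle is exactly linear in the strength columns). The intercept
shifts up as needed to keep all up-condition FPKMs above the >5 filter.
Per-sample values multiply `y` by a group profile built from mutually
orthogonal zero-mean vectors, normalized to mean 1 over the up-condition
samples (condition means recover `y` exactly) and damped on the down
condition; orthogonality keeps cross-group correlation low so the
clustering invariants are meaningful. Ungrouped isoforms each violate
exactly one DEI filter, exercising every rejection path. Identical
(config, seed) pairs produce byte-identical bundles; numbers are written
with fixed formats.

`simulate_design` is the fast harness for recovery experiments (no genome
scanning): its column statistics mirror what the genome-scale generator
measurably produces — support TF columns are sums of 1–3 near-maximal site
scores, support SF columns are means of 1–3 elevated conservation levels,
non-support TF columns are ~5 % nonzero (chance consensus hits in 2 kb)
and non-support SF columns ~1 % (background conservation almost never
clears the ≥ 2 filter). What passing recovery tests show is therefore
conditional on that planted world: strengths that genuinely carry the
signal and mostly-silent null factors. They do not show that the method
recovers regulators from real data, where strengths are noisy proxies of
binding, expression summaries are compositional, and the linear model is
at best an approximation.

## Numerical choices and degenerate inputs

Correlations are considered tied/zero below 10⁻¹⁰ relative to the initial
correlation scale. The bedGraph reader loads per-contig float arrays with
NaN for uncovered bases; querying uncovered bases is an error rather than
a silent zero, because an unfiltered hit without conservation evidence is
meaningless. Empty inputs degrade explicitly: fewer than 10 DEIs yields no
groups with a warning; a pipeline run with unreachable thresholds
completes with zero counts and empty outputs. All inference is
deterministic; the only randomness is the fixture seed, and two pipeline
runs from the same inputs produce byte-identical outputs except the
wall-clock field of the run report.

## Known limitations

* PWM scanning uses relative-score thresholds, not a p-value calibration
  per PWM; absolute TF strengths are scale-arbitrary (harmless after
  standardization, but not comparable across scanner settings).
* Exact SF motif matching admits no mismatches and ignores RNA secondary
  structure.
* One expression value per isoform (N = group size) keeps the regression
  as formulated, but discards per-sample replication; stacking samples
  would change the error structure.
* LARS with EBIC selects a parsimonious support; coefficients are path
  (shrunk) estimates, and no standard errors or p-values are attached.
* The enrichment universe choice materially affects p-values and is left
  configurable because no single default is right for all collections.
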