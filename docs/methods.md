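# Methods

This note records the models, parameter choices, and numerical
decisions behind `primatlas`, and what the synthetic-data validation
does and does not establish about real data.

## Atlas construction

Peak calls arrive in each species' native genome frame. Instead of
chain-file liftOver, the pipeline consumes an explicit ortholog
interval map (ref_chrom/ref_start/ref_end, species, native interval).
A peak projects to the reference interval of every map segment it
overlaps by ≥ 1 bp; projected peaks from all species are merged by
single linkage on ≥ 1 bp overlap (bookended intervals are not merged —
all coordinates are 0-based half-open), and merged regions lacking a
map segment in any of the three species are dropped, enforcing 1:1:1
homology. Map rows whose reference intervals overlap another row of the
same species are treated as ambiguous (many-to-one) and rejected with a
logged count. OCRs with a zero count in any sample are removed — in
real data a zero in one technical replicate is a mapping-artifact
signature; the filter is idempotent and logged.

The merge rule is a design choice: single-linkage overlap is the most
common convention for consensus peak sets, but other rules (bookended
merging, reciprocal-overlap fractions) exist; the rule is isolated in
`atlas.merge_intervals`.

## Count model

Counts follow NB(μ, α) with Var = μ + α·μ², log link, and per-sample
size-factor offsets estimated by median-of-ratios
(s_j = median_i count_ij / geomean_i; no further rescaling, so factors
are meaningful only up to a common constant). Replicate QC retains a
sample iff its best Pearson correlation (log2 normalized + 1) with
another same-species sample exceeds 0.85; a species with a single
sample is retained with a warning.

Because species is the only design factor, the GLM maximum likelihood
factorizes into independent per-species group means. Each group mean
solves the score equation Σ_j (y_j − s_j m)/(1 + α s_j m) = 0, which is
strictly decreasing in m; we solve it by vectorized bisection across
all OCRs simultaneously (64 iterations, relative precision far below
1e-12). Unit tests verify agreement of the log likelihood and the
coefficients with an independently fitted statsmodels NB GLM to 1e-4.
The species effect is the likelihood ratio against the intercept model,
referred to χ² with (n_species − 1) df; pairwise contrasts are Wald
tests on log m_A − log m_B with variance 1/I_A + 1/I_B from the
per-group Fisher information I_s = Σ_j μ_j/(1 + αμ_j). Reported fold
changes use a 0.5 pseudocount on the normalized group means; the Wald
statistic uses the raw coefficients.

Dispersion is estimated per OCR by pooled within-species method of
moments, (Var − mean)/mean², weighted by group degrees of freedom and
floored at 1e-8. With the few replicates of a cross-species design the
raw estimator is noisy, and OCRs whose dispersion is underestimated by
chance inflate the LRT: in a 2,000-OCR null simulation the raw
estimator gives ~10% rejections at nominal 5%, while the true α gives
5.2%. We therefore additionally floor each estimate at the dataset-wide
median of the raw estimates (`moderate=True`), which restores type-I
calibration (~5%) at the cost of power on genuinely low-dispersion
OCRs. This is a deliberate, deterministic alternative to
empirical-Bayes shrinkage; `moderate=False` recovers the raw estimator.
Technical replicates are kept as separate columns after QC; the design
matrix uses species as the only factor.

## State polarization

With q-values from BH within each test family (one family for the
species LRT, one per pairwise contrast):

- common ⇔ species-effect q ≥ 0.05;
- human_increased ⇔ human-vs-rhesus q < 0.05 with human higher,
  chimp-vs-rhesus q ≥ 0.05, and human-vs-chimp log2FC ≥ 1;
  human_decreased and the chimp states are the mirror images;
- anything else significant is ambiguous (e.g. both branches shifted).

"Similar accessibility between the other branch and the outgroup" is
operationalized as absence of significance (q ≥ 0.05), not an
equivalence test; the 2-fold rule is applied to the human–chimp
contrast only. Both choices are visible parameters (`fdr`, `fold`).

The matched common set takes the species-specific OCRs' mean
normalized counts and interval lengths as reference distributions and
keeps common OCRs inside both [P20, P80] windows (linear-interpolation
percentiles, bounds inclusive, intersection of the two criteria).

Completeness: an increased OCR is a complete gain iff neither other
species has a called peak over it; a decreased OCR is a complete loss
iff the focal species has none.

## Enrichment

All 2×2 comparisons use the two-sided Fisher exact test; the odds ratio
is the sample (a·d)/(b·c) with a Haldane +0.5 correction only when a
cell is zero. The default background is the matched common set.
Tissue-pleiotropy (row sums of an OCR × tissue openness matrix) is
compared via Fisher on pleiotropy > k (k = background median).
Expression association compares |log2FC| of nearest genes by Wilcoxon
rank-sum — exact null when both sides have ≤ 25 observations and no
ties, normal approximation with tie correction otherwise. BH q-values
are computed in one batch per group × annotation family.

Two textbook "invariants" were found not to hold exactly and are tested
in their correct form: median-of-ratios size factors are equivariant to
single-column scaling only up to a global constant (the geometric-mean
reference shifts), and BH is not idempotent (re-adjusting q-values can
change rejection sets); the test suite instead verifies the step-up
equivalence q_i ≤ α ⇔ i rejected by BH at α.

## Selection (ζ) test

Region alignments are scored under JC69 with Felsenstein pruning;
columns containing any gap or ambiguity are dropped (complete case),
and columns are collapsed to unique site patterns. Branch lengths come
from a neutral fit on concatenated putatively nonfunctional regions:
log-branch-length L-BFGS-B initialized from pairwise JC distances, with
the site likelihood floored at 1e-300 so the line search never meets
−inf at a zero-length branch. For a rooted tree under a reversible
model the two root edges are a likelihood ridge (only their sum is
identifiable); tests therefore check leaf-to-leaf path lengths, which
are identifiable and recovered within ±20% at 1 kb on three taxa.

Per region, the null maximizes a region rate r (bounded scalar search
in log r); the alternative maximizes (r, ζ) by L-BFGS-B in log space
from restarts {0.5, 1, 2}² plus the null optimum, guaranteeing
ℓ_alt ≥ ℓ_null. The LRT is referred to χ²₁; directional p-values halve
the two-sided p according to sign(ζ̂ − 1) — the null value ζ = 1 is
interior, so no boundary mixture applies. Under the null at 1 kb the
acceleration test rejects at 6 ± 2% (nominal 5%); at 300 bp (the
pipeline's default OCR length) the asymptotics are rougher and
one-sided constraint calls are anti-conservative, so genome-scale
inference should use q-values and longer regions where possible.
JC69 was chosen to keep the test transparent and calibratable; the
substitution model is isolated behind `jc69_transition` and an HKY
extension would only change that function and the root frequencies.

## Motifs

PWMs are probability matrices with per-cell pseudocount 0.01 and a
uniform background; the relative score of a window rescales its
log-odds so the worst attainable window is 0 and the best (consensus)
is 1. Both strands are scanned; windows containing N are skipped; the
default hit threshold is 0.8 (a conventional scanning default — no
principled value exists, and it is a parameter everywhere). The
built-in NFIA and PPARG matrices are synthetic stand-ins constructed
from the well-known consensus forms (NFI palindrome TTGGCN₅GCCAA;
PPARG:RXRA DR1 AGGTCAAAGGTCA) with 0.85 consensus-base probability —
they are for simulation and testing, not database matrices. The NFIA
stand-in, with its 5 uninformative spacer columns, has a ~11% false
hit rate per 300 bp at threshold 0.8; this is realistic for spacer
motifs and means co-occurrence estimates on small groups are noisy.

Nonredundant 6-mers are canonicalized as min(kmer, revcomp); weights
are log2 ratios of add-one-smoothed frequencies, positive vs null set.
The classifier scores a sequence by its summed canonical k-mer weights,
evaluated by stratified 5-fold cross-validation (weights fit on
training folds only) and summarized by ROC/AUC. This is an explicit,
transparent stand-in for a gapped-k-mer SVM: it shares the input/output
contract (discriminate species-specific from nearest-null sequences,
report AUC) but not the gapped kernel.

Nearest-null mapping pairs each species-specific OCR with the closest
common OCR by midpoint distance on the same chromosome (ties to the
lower start coordinate) to control local sequence composition.

## Synthetic data

The generator's defaults emulate the real study design: 2,000 OCRs
(lognormal lengths ~400 bp, spread over chromosomes), the
3 human / 2 chimp / 1 rhesus biological-replicate design with 2
technical replicates each, NB counts with α = 0.1, baseline
log2-counts ~ N(6, 1.5), per-sample size factors U(0.7, 1.4), 10% of
OCRs planted with 4-fold branch-specific changes (2.5% per state),
complete-gain/loss presence rates of 89.5/55.1/77.2/95.5% per state,
annotation rates per state mirroring the promoter/enhancer magnitudes
reported for real adipose OCR groups, a ((human:0.006, chimp:0.006)
:0.025, rhesus:0.03) tree in substitutions/site, and motif plant rates
that make decreased regions NFIA-enriched with frequent PPARG
co-occurrence. Alignments evolve sites independently under JC69 from
the OCR's reference sequence; the foreground (human) branch is scaled
by the planted ζ for human-state OCRs. Background sequences are i.i.d.
with configurable GC.

What the generator does **not** emulate: read-level noise and fragment
structure (counts are drawn directly from the NB), mapping bias between
genomes, correlated biological replicates beyond NB dispersion,
spatially structured GC/repeat content, indels in alignments, and
motif turnover. Passing tests therefore demonstrate that the
*inference machinery* is correct and calibrated under its own model
assumptions — not that those assumptions hold in any particular
tissue.

`corrupt_replicate` shuffles a chosen fraction of one sample's counts
across OCRs, destroying its correlation with replicates while keeping
its marginal distribution; it exists to exercise the QC rule.

## Problem sizes used in validation

The demo run uses 2,000 OCRs (seed 1). The FDR audit uses 20
replicates of 600 OCRs; ζ calibration uses 200 null 1-kb alignments
and 40 per planted ζ ∈ {0.2, 1, 2, 5}; the Fisher oracle enumerates
all 246,015 tables with row margins ≤ 30; motif audits use 100-500
random sequences. These sizes give Monte-Carlo error comfortably
inside the asserted tolerances while keeping a full validation run to
a few minutes.

## Known limitations

- The NB fit assumes a known per-OCR dispersion; uncertainty in α̂ is
  not propagated into the Wald/LRT p-values (the median floor
  compensates empirically).
- The ζ test models substitutions only; selection on indels or on
  motif spacing is invisible to it, and the χ²₁ reference is
  asymptotic in alignment length.
- With a single rhesus biological replicate (as in the emulated
  design), within-rhesus dispersion is informed mainly by technical
  replicates, which in real data underestimate biological variance.
- The k-mer classifier ignores k-mer positional information and gapped
  patterns.
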