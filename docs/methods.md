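# Methods

This note documents the statistical model, the numerical choices, and the
synthetic-data generator behind `apashift`, including what the validation
on synthetic data does and does not demonstrate about real data.

## Model and procedure

### Segmentation

A gene's candidate PAS peaks are filtered by two rules applied against the
gene's *pre-filtering* 3′-end read total: a peak must carry strictly more
than five reads and at least 5% (inclusive) of the total. Filtering runs
before merging by default; the opposite order is available via
`order="merge-first"` because the two differ on genes whose weak peaks sit
close to strong ones.

Merging is iterative closest-pair-first: while any two peaks are closer
than 50 nt (strictly; exactly 50 does not merge), the closest pair merges —
ties broken at the lower genomic coordinate — into a single peak at the
stronger member's position (count ties go to the more distal, i.e. 3′-most,
position) carrying the summed count. This order-independent deterministic
scheme is idempotent and conserves total counts; the test suite checks it
against a brute-force pair-enumeration oracle.

Segments are half-open genomic windows, each ending at (and including) its
delimiting PAS; segment 0 starts at the annotated TSS. The region
downstream of the distal PAS is not a segment: the score only needs
PAS-terminated windows, and coverage past the last PAS reflects run-through
rather than isoform abundance. Genes retaining fewer than two peaks are
ineligible.

### Quantification

Coverage is integrated per segment and sample from bedGraph tracks:
mass = Σ per-base depth, mean depth = mass / length, and an integer
pseudo-read count = round(mass / read_length). `read_length` defaults to
100 nt (2 × 100 bp paired-end sequencing). Ratios use mean depth (length
does not cancel between segments but does cancel in the ratio-of-ratios);
the GLM needs integers, hence the pseudo-counts.

### APA score

With replicate-averaged, size-factor-normalized mean depths of the most
proximal (P) and most distal (D) segments per condition:

    score = log2[ (D_mut / P_mut) / (D_wt / P_wt) ]

Size factors are median-of-ratios: per segment-row the geometric mean
across samples, per sample the median over all-positive rows of
count / geometric mean, computed in linear space (the median of linear
ratios; for odd row counts this equals the log-space version exactly).
Rows containing a zero are excluded from the median, and a matrix with no
all-positive row is an error suggesting a pseudo-count.

Zeros: when any of the four averaged depths is exactly zero, 0.5 is added
to all four (the Haldane–Anscombe convention, applied on demand) so the
score stays finite and antisymmetric; otherwise values enter untouched,
keeping closed-form cases exact. The score is antisymmetric under swapping
condition labels and invariant to per-sample scaling (absorbed by the size
factors).

### Significance

Per replicate r the distal pseudo-count d_r out of n_r = p_r + d_r trials
follows Binomial(n_r, π_c(r)) with logit π = β₀ + β₁·[condition = test].
The fit is iteratively reweighted least squares (statsmodels GLM, tolerance
1e-8, ≤ 50 iterations); the reported p-value is the two-sided Wald test on
β₁ (a likelihood-ratio option exists, `test="lrt"`). Raw within-replicate
counts enter the GLM — a replicate's proximal/distal proportion is
library-size-free, so normalization is unnecessary there and would break
the binomial likelihood. Overdispersion is not modelled by default;
`family="quasibinomial"` rescales the covariance by the Pearson dispersion
for data with extra-binomial noise.

Degenerate fits (perfect separation, non-convergence, a condition with
zero trials) fall back to the condition-pooled 2×2 table with 0.5 added to
all four totals and a Wald test on the pooled log-odds difference; such
genes are flagged `continuity_corrected`. All-zero genes get p = NaN and
are excluded from multiple testing.

Benjamini–Hochberg adjustment is applied across genes (NaNs excluded from
m). Events are classified proximal (score < −1, FDR < 0.01), distal
(score > 1, FDR < 0.01), or unchanged; both thresholds are configurable.

### Controls, features, sequences

The unaffected control group for sequence comparisons is selected by count,
not by fixed score thresholds: the n non-significant genes with |score|
closest to zero, n matching the affected group (ties broken by gene id).
Fixed numeric windows would be dataset-specific; rank selection transfers.

Feature assignment uses the proximal PAS (the site gaining usage in a
proximal shift): containment in the annotated 5′ UTR / CDS / 3′ UTR for
coding genes, with sites up to 200 nt beyond the annotated 3′ end counted
as 3′ UTR (cleavage sites routinely map slightly past annotated ends), and
ncRNA for noncoding genes. When UTR rows are missing from the annotation,
a site 3′ of the CDS counts as 3′ UTR and 5′ of it as 5′ UTR. No intron
category is modelled.

Flanking windows are strictly up/downstream 40-mers — the cleavage-site
nucleotide belongs to neither, since cleavage occurs between nucleotides —
reverse-complemented on the minus strand so both read 5′→3′ in
transcription direction, reported in the RNA alphabet. Uridine content is
compared per-window with a two-sided rank-sum test (robust, no pooling
assumption; a pooled chi-square would weight long-window genes more). The
discriminative k-mer scan enumerates exact words only (k = 4–7, window
presence/absence, one-sided hypergeometric, BH across all observed
k-mers); it is a deliberate simplification of discriminative motif
discovery, so a degenerate motif such as UUG[UC]UG surfaces as its
constituent exact words, and k-mers absent from both groups are not
tested.

The gene-set overlap test is the exact one-sided hypergeometric tail with
the sample odds ratio (a·d)/(b·c) reported alongside.

## Synthetic data

The generator emulates the two-condition design the analysis targets.
Defaults (chosen once, as the study conditions):

| parameter | default | meaning |
|---|---|---|
| n_genes | 200 | genes per bundle (2,000 in the validation runs) |
| pas_per_gene | 2–4 | PAS count drawn uniformly |
| baseline_distal_usage | 0.5 | distal PAS usage in the baseline |
| shift_fraction | 0.10 | genes given a true usage shift |
| effect_size | 2.0 | true \|log2 usage-odds\| change of a shift |
| proximal_fraction | 0.85 | shifts directed toward the proximal PAS |
| reads_per_gene | 1000 | NB mean of a gene's read total (≥150/tested segment) |
| threeprime_reads_per_gene | 200 | Poisson mean of 3′-end reads per gene |
| dispersion | 0.05 | NB dispersion (0 → Poisson) |
| replicates | 2 + 2 | per condition |
| read_length | 100 | nt, for depth ↔ count conversion |
| decoy_fraction | 0.05 | genes with a near-duplicate peak < 50 nt away |
| motif / rates | UUGUUG, 0.5 vs 0.05 | embedded downstream of affected proximal PASs |

Baseline usage over k PASs gives the distal site its configured fraction;
with k > 2 the proximal site takes 60% of the remainder and middle sites
share the rest, keeping both tested segments ≥ 150 expected reads at the
default depth. A shift multiplies the distal/proximal usage odds by
2^(±effect) while holding middle usage and the proximal+distal mass fixed,
so the truth-table score log2(odds_mut/odds_wt) is exact by construction.

Counts: per sample, a gene total ~ NB(library_multiplier × reads_per_gene,
dispersion) is allocated to segments multinomially by usage. Binomial
thinning of a Gamma–Poisson mixture preserves the dispersion parameter, so
each segment count is marginally NB with mean proportional to its usage —
while proportions remain binomial given the total, which is the GLM's
sampling model. Gene-level expression noise therefore cancels from the
usage proportion, exactly as biological expression variability (shared by
a gene's isoforms) should; noise that hits proximal and distal isoforms
*independently* is not simulated and would require the quasi-binomial
option on real data.

Coverage idealization: each segment's bedGraph depth is piecewise-constant,
count × read_length / length, and proportional to its *own* PAS usage.
Real RNA-seq coverage is cumulative — a base in segment i is covered by
every isoform terminating at PAS i or later — so on real data the
distal/proximal depth ratio estimates distal-isoform abundance relative to
total rather than the usage odds, compressing scores toward zero (the
wt(0.5,0.5)→mut(0.8,0.2) shift would score −1.32 instead of −2.0).
Passing the recovery tests therefore demonstrates correctness of the
estimator under its own sampling model, and a conservative bias (not a
false-positive risk) is expected on real coverage.

3′-end peaks are drawn multinomially from baseline usage; 5% of genes get
a decoy peak 20 nt upstream of the proximal PAS carrying a third of its
reads, exercising the merge rule inside the full pipeline (the merged peak
lands back on the true position). Genes are placed without overlap on
synthetic contigs (≤ 500 kb, random 300–800-nt intergenic gaps), strand
uniform, ~10% ncRNA; coding genes place the proximal PAS in the 3′ UTR
(80%), CDS (10%) or 5′ UTR (10%). All randomness flows from one seed;
identical seeds give byte-identical bundles (bedGraph depths printed with
%.10g, relative paths in the sample sheet).

Validation scales: the calibration and recovery runs use 2,000 genes with
2 + 2 replicates and the motif experiment 200 + 200 windows — sizes at
which every check completes in seconds while the binomial standard errors
are small against the tested margins.

## Known limitations

- Cumulative-coverage bias on real data (above); scores on real bedGraphs
  are conservative relative to true usage odds.
- Plain-binomial inference ignores isoform-specific biological noise;
  use `family="quasibinomial"` when replicates disagree beyond counting
  error.
- The k-mer scan has no degenerate-alphabet or positional model.
- PAS-to-gene assignment trusts the BED name column; the positional
  fallback (same strand, within the gene or ≤ 200 nt downstream) is a
  heuristic for peaks slightly past annotated ends.
- GFF3 sub-features beyond five_prime_UTR / CDS / three_prime_UTR are
  ignored; genes without CDS rows are treated as ncRNA.
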