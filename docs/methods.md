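# Methods

This note documents the models, conventions, and numerical choices behind
`codonbias`, and what the synthetic-data generator does and does not
establish.

## Scope of the statistics

All statistics operate on *sense* codons of in-frame coding sequences:
terminal stop codons are trimmed on read, CDS with internal stops are
excluded with a warning, and codons containing ambiguity characters
(N, R, Y, …) are dropped from all counts with a per-isolate tally logged.
The internal alphabet is RNA (T→U on read; writers accept a `dna`/`rna`
flag). An isolate's "full coding region" is the 5'→3' concatenation of its
annotated ORFs after the length filter; overlapping ORFs (e.g. a
replicase frameshift product) each contribute their full codon sequence,
so overlap nucleotides are counted once per reading frame in which they
are translated. ORFs shorter than `min_orf_nt` (default 150 nt,
pre-trimming length) are excluded.

The 59 *informative* codons are those of amino acids with ≥2 synonymous
codons; Met (AUG), Trp (UGG) and the three stops are excluded from RSCU,
Nc, and third-position composition throughout.

## Composition

A₃/U₃/C₃/G₃ are simple shares of third-position bases among informative
codons, so they sum to 100 and (G+C)₃ = C₃ + G₃. The alternative
"potential-base" definition (CodonW's X3s), which normalizes by codons
that *could* end in the base, does not sum to 100 and is not used: the
sum-to-100 convention matches how per-isolate composition rows are
conventionally tabulated. Ile (3-fold) and the 6-fold families are
included like any other family. Report writers round to 1 decimal place;
averages are taken over unrounded values, so the printed Average row can
disagree with re-averaging the printed rows in the last digit.

## Nc (effective number of codons)

Per family with n ≥ 2 observed codons, F̂ = (n·Σp̂ᵢ² − 1)/(n − 1); F̄_k
averages F̂ over observed families of degeneracy k; Nc = 2 + 9/F̄₂ + 1/F̄₃
+ 5/F̄₄ + 3/F̄₆. Families with n < 2 or F̂ = 0 are excluded from their
class mean. If an entire class is unobserved: the 3-fold class (Ile
alone) contributes the mean of 1/F̄₂ and 1/F̄₄; any other missing class
uses the mean F̄ of the observed classes. The reported Nc is clamped to
[20, 61]; the raw value is kept on the result (`nc_raw`). The neutral
expectation Nc* = 2 + s + 29/(s² + (1−s)²) is exposed for the Nc-plot;
note its maximizer is s ≈ 0.5022, not exactly 0.5, because of the linear
term.

## RSCU

RSCU_j = k·n_j/Σn over the family. A zero-count codon in an observed
family has RSCU 0.0; an entirely unobserved family is *missing* (its
codons are absent from the table and the family is flagged), not zero.
For the correspondence-analysis matrix, missing entries are imputed with
the family-neutral value 1.0 and flagged, keeping 59 columns aligned
across isolates.

## Correspondence analysis

Classic chi-square CA: with P the table normalized to sum 1, row masses
r and column masses c, the standardized residuals
S = D_r^{-1/2}(P − rcᵀ)D_c^{-1/2} are decomposed by SVD; principal
coordinates scale singular vectors by singular values; each axis explains
σᵢ²/Σσ² of the total inertia (= chi-square statistic / grand total,
verified as a test identity). Axis signs are arbitrary; each axis is
oriented so its largest-|loading| codon loads positively, making outputs
deterministic. Identical rows give total inertia 0 and are returned as a
flagged degenerate result rather than an error. Note that standard CA is
*not* invariant to per-row rescaling (row masses change); it is invariant
to a global rescaling, and both behaviors are tested.

## Correlations

Spearman (average-rank ties, two-sided t-approximation p) is the default
for axis–composition grids; significance stars follow the * p<0.05,
** p<0.01 convention with no multiple-testing correction (matching common
practice in this literature; the grids are small). Virus–host correlation
is computed on two scales — per-1000 codon frequencies ("codon
abundance", the default) and RSCU — with both Pearson and Spearman
coefficients always reported, because the frequency scale shares
amino-acid-composition structure between virus and host (its null is not
centred on zero), while the RSCU scale isolates synonymous-choice
resemblance.

## Phylogeny

The tree stage consumes an aligned, equal-length sequence set (alignment
itself is out of scope; any aligner can be used upstream). Distances are
p-distance or Kimura two-parameter, d = −½ln(1−2P−Q) − ¼ln(1−2Q), over
ungapped unambiguous columns; saturated pairs raise an error naming the
pair. Neighbor joining follows Saitou–Nei with the standard Q criterion;
taxa are processed in sorted label order and ties break deterministically,
so results are independent of input order. Negative branch-length
estimates are clamped to 0 with a warning; zero-length *internal* edges
are collapsed into polytomies, so e.g. identical sequences yield a star
tree rather than an arbitrary binary resolution. Bootstrap support is the
percentage of column-resampled replicate trees containing each internal
bipartition; replicates that saturate the distance are skipped (counted
against support). All randomness flows from one integer seed.

## Synthetic cohorts: what they state and what they omit

`simulate_cds` draws amino acids from a frequency vector and codons from
per-family probabilities — the model behind the RSCU/Nc parameter-recovery
tests, with the exact sampled counts retained for bookkeeping oracles.

`simulate_cohort` states a deliberately simple world. One root protein
sequence is drawn for the whole cohort. Each group's ancestor realizes
its codon model's family-conditional proportions *exactly* (largest-
remainder quotas, randomly placed), so codon-usage differences between
groups are exactly the stated model differences, free of multinomial
sampling noise; the random placement still makes ancestors diverge in
sequence, giving clade structure. Each isolate is its group's ancestor
with independent synonymous third-position substitutions (default rate
0.02 per codon, staying within same-prefix family blocks), preserving
protein identity so group structure is a pure codon-usage signal.

Defaults emulate the published CTV cohort: 20 isolates in groups of
11/6/3, twelve ORFs totalling 18,498 coding nt (≈6,166 codons, inside the
published isolate-length range), amino-acid and codon frequencies from
the shipped pooled CTV codon-count fixture, and C-ended codon weight
multipliers 0.90/1.00/1.10 (≈±2 percentage points of C₃ — the upper end
of the published genotype spread, a magnitude chosen once so that
genotype-level divergence is representable in a generator without
shared-ancestry covariance). One caveat is inherited from the source
tables themselves: the pooled codon counts imply overall G+C ≈ 45.5%,
whereas the per-isolate composition table reports ≈ 41.8% — the two
published tables are mutually inconsistent (their stated codon totals
also disagree), and the generator follows the pooled counts. The
qualitative structure (U-rich third positions, U₃ maximal, Nc ≈ 53–55,
points below the neutral Nc curve) is preserved.

What green tests on this world establish: the pipeline recovers planted
codon-usage structure (group separation on CA axes, C₃ as the top
correlate, monophyletic clades, host-resemblance contrasts) and its
estimators converge to stated parameters. What they do not establish:
behavior under recombination, indels, shared-ancestry covariance *within*
groups, non-synonymous divergence, or realistic branch-length
calibration — none of which the generator models.

The shipped host table (`citrus_sinensis_synthetic.kazusa.txt`) is a
synthetic stand-in in Kazusa standard format: counts reconstructed from
published within-family relative usage combined with the pooled CTV
amino-acid frequencies, with Met/Trp/stop frequencies set once to
plausible plant-coding values (2.3%, 1.1%, 0.06% each). It preserves the
relative synonymous structure of the real host table but not its absolute
amino-acid usage.

## Degenerate inputs and failure modes

Empty regions, constant correlation vectors, all-zero CA rows/columns,
<3 taxa, saturated K2P pairs, missing host-table codons, and an ORF
filter that removes everything all raise typed errors naming the stage
and offending record; the CLI maps input errors, filter emptiness, and
numerical failures to distinct exit codes (2/3/4). Rounding happens only
in writers; all internal values are full precision.
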