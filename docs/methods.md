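# Methods

## The comparison model

The unit of analysis is an *aligned pair*: two genotype matrices over the
same samples and the same SNPs, with per-SNP agreement on which physical
allele is counted. All statistics are functions of the paired allele
counts (0/1/2) with pairwise deletion: a cell enters a denominator only
when both platforms called it. Denominators are reported everywhere.

For counts c₁, c₂ the number of shared alleles is 2 − |c₁ − c₂|, the size
of the intersection of the two allele multisets. The literature usually
states only the het/hom case ("one allele in common"); extending by the
multiset intersection gives opposite homozygotes zero shared alleles and
makes allele concordance a simple linear function of |c₁ − c₂|:
AC = 1 − mean|c₁ − c₂|/2 = GC + p₁/2. These identities are property-tested
against a brute-force multiset oracle.

Pearson correlation is undefined when a restricted vector is constant
(monomorphic SNP, or an animal compared at fewer than two calls); such
units are reported as NA, excluded from mean correlations, and counted.
Per-unit aggregates (mean/min/max across animals or SNPs) are unweighted —
each unit counts equally — while the pooled "overall" statistic weights by
cells; both are reported because they answer different questions.

## Harmonization

Order of operations: SNP intersection first (an explicit drop list lets
known-bad assays be excluded without modelling why), then sample
call-rate filtering computed *on the matched SNP set* so per-sample rates
are comparable across platforms, then allele-coding reconciliation.
Sample exclusion is symmetric: a sample failing the threshold on either
platform leaves both. A regression test checks that matching and
filtering commute when rates are computed on the common SNP set.

Reconciliation tries, per SNP, the four vendor-coding relations in a
fixed order: identity, A/B swap (counts c → 2 − c), strand complement
(letters only), complement plus swap. For strand-ambiguous SNPs (A/T,
C/G) letters cannot distinguish a swap from a strand flip, so orientation
is chosen by B-allele-frequency proximity — but only when the reference
platform's MAF is below 0.4; nearer 0.5 the frequencies of the two
orientations become indistinguishable and the SNP is dropped as
unresolvable rather than guessed. The 0.4 cut bounds the miscoding risk;
it is deliberately conservative and configurable.

## Stratifications

* **MAF**: monomorphic SNPs (MAF exactly 0) form their own bin, then
  right-closed intervals of width 0.05 up to 0.5. Monomorphic SNPs are
  separated because their concordance behaves qualitatively differently
  and their correlation is undefined.
* **Quality**: SNPs are binned by per-SNP mean score; default edges are
  0.05-wide on the observed score range. Orientation is honoured: for
  lower-is-better scores (Affymetrix confidence) the displayed bin order
  is reversed so plots always run best-to-worst, and the
  quality-threshold restriction masks cells with score ≥ threshold
  instead of ≤.
* **Category**: the six Axiom cluster-quality labels
  (PolyHighResolution, NoMinorHom, MonoHighResolution, OffTargetVariant,
  CallRateBelowThres, Other), carried on the second platform's SNP
  records; missing labels group under "Unlabelled" rather than failing.
  The pooled concordance over *segregating* PolyHighResolution SNPs is
  reported separately, since restricting to well-clustered polymorphic
  assays is the common quality-control move.
* **Concordant vs discordant quality**: Welch's unequal-variance two-sided
  t-test; the per-cell statistic is the single platform's score for
  cross-platform comparisons and the worse of the two scores
  (minimum for GC-like scores) for duplicate runs. Welch was chosen
  because the two groups have wildly unequal sizes and no variance
  equality can be assumed. With fewer than two cells in a group the means
  are still reported but the test is NA.

## The simulator

What it emulates: per-SNP MAF drawn from a configurable law (uniform on
[0, 0.5] by default; Beta and point-mass laws available), a configurable
fraction of truly monomorphic SNPs, Hardy–Weinberg genotypes, and two
independent observation channels. The error channel is *allele-level*:
each of a call's two alleles flips with probability ε, so the observed
count is truth − Bin(truth, ε) + Bin(2 − truth, ε). This makes one-allele
errors O(ε) and opposite-homozygote errors O(ε²), reproducing the
empirical pattern that replicate discrepancies are overwhelmingly
het/hom. The exact 3×3 transition kernel of this channel is enumerable,
giving closed-form expected concordance and opposite-homozygote rates
used as independent oracles in the tests (simulation must agree within 3
binomial standard errors).

Quality scores are Beta draws on [0, 1]: Beta(44.5, 5.5) (mean 0.89) for
correct calls and Beta(42.5, 7.5) (mean 0.85) for erroneous calls when
coupling is enabled, matching the observed GC-score gap between correct
and incorrect genotypes; the variances are free parameters. For a
lower-is-better platform the score is reported as 1 − draw.

Default study conditions: 84 samples × 51,121 SNPs; allele error 0.002
and missingness 0.006 on the reference (Illumina-like) platform versus
0.01 and 0.026 on the second (Affymetrix-like) platform — chosen so
per-individual call rates (~0.994 vs ~0.974) and the scale of
cross-platform discordance (a few percent of genotypes) resemble a real
dual-vendor comparison. Category shares default to a realistic custom
Axiom panel composition (≈73.6% PolyHighResolution, 4.2% NoMinorHom,
1.9% MonoHighResolution, 8.4% CallRateBelowThres, 0.9% OffTargetVariant,
11.0% Other). Label-consistency constraints: MonoHighResolution only on
truly monomorphic SNPs (a config whose MonoHighResolution share exceeds
the monomorphic fraction is rejected), CallRateBelowThres adds 0.15 to
the SNP's missing rate, OffTargetVariant and Other multiply ε by 10
(capped at 0.45). All randomness flows through one `numpy` generator
seeded from the config; identical configs give bit-identical output.

What it does **not** emulate — and hence what passing tests do not show
about real data: intensity clustering and its failure modes (the category
labels are assigned, not derived, so "monomorphic SNPs concordant worst",
a clustering artefact, is not reproduced), linkage disequilibrium and
pedigree structure (irrelevant to per-cell statistics), DNA-quality and
laboratory batch effects, and platform-specific error asymmetries beyond
a scalar ε per platform. Headline concordances of a specific published
study are therefore matched only qualitatively, not numerically.

## Numerical and interface choices

* Missing calls are an explicit sentinel (−1) in an int8 matrix; a
  missing call's quality is ignored everywhere.
* PED reading assigns the B allele as the minor observed letter; at MAF
  0.5 the tie breaks alphabetically, for determinism. A SNP observed with
  one letter gets the alphabetically first other base as a placeholder B
  allele. Call tables carry counts only; allele letters and categories
  travel in a companion SNP table.
* The call-table writer emits every cell (missing as NA) so that
  all-missing samples survive the round trip; reading uses
  round-trip float parsing so quality scores are restored exactly.
* Correlation is computed from sums (n·Σxy − ΣxΣy …) per unit,
  vectorized with pairwise-deletion masks; zero-variance guards return
  NA instead of dividing by ~0.
* Report rendering: rates to 4 decimals, percentages to 2 (contingency
  diagonal to 1, the conventional layout); machine-readable outputs keep
  full precision, with NaN mapped to JSON null. Empty strata are omitted
  from the rendered report with a note, but retained in the bundle so
  bin totals always sum to the unstratified totals.
* Exit codes: 3 config, 4 parse, 5 data, 6 pipeline (empty result).

## Problem sizes in the checks

The bundled verification runs use exact-count fixtures at their natural
sizes (e.g. 84 × 50,754 cells for the re-clustering comparison) and
simulations of 500 × 5,000 for error-rate recovery and 84 × 51,121 for
the study-scale summaries — large enough that binomial standard errors
separate the hypotheses being checked, small enough to run in seconds.

## Known limitations

Only biallelic autosomal-style SNPs; no VCF or binary PLINK input; no
position-based matching across genome builds; no chance-corrected
agreement (kappa); a single planned test per quality comparison, so no
multiplicity control across strata; the ambiguous-SNP frequency rescue
can still miscode a SNP whose two platforms' frequencies straddle 0.5.
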