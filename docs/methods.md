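# Methods

This note records the statistical model behind `sexlinkscan`, the tunable
parameters with their defaults and rationale, what the simulator does and
does not emulate, and the numerical conventions used. Nothing here makes an
empirical claim that is not computed by the test suite or
`scripts/acceptance.py`.

## Data model

SNP loci use one-row DArTseq coding: `0` homozygous reference, `1` homozygous
alternate, `2` heterozygous, `-` (also `−` or empty) missing. PA
(SilicoDArT) loci are `1` present, `0` absent, `-` missing. Internally,
missing is `-9` in an `int8` matrix of shape loci × samples. Metadata columns
are parsed by header name, so column order is irrelevant; stored `CallRate`
values are validated against recomputed ones with slack for printed rounding
(a mismatch warns, it does not fail). Sex labels are normalized to
`M` / `F` / `UNKNOWN`; UNKNOWN individuals never enter any per-sex
denominator.

## Sex-linkage classification

For a locus with called genotypes, let `het_m`, `het_f` be the heterozygote
(or PRESENT) fractions among called males and females, and `hom_m`, `hom_f`
the homozygote (or ABSENT) fractions. With concordance threshold `c`:

- **XY** call iff `het_m ≥ c` and `hom_f ≥ c`;
- **ZW** call iff `het_f ≥ c` and `hom_m ≥ c`;
- otherwise **NONE**. A locus with no called individuals in either sex is
  **UNEVALUABLE** (distinct from NONE: the data are insufficient, not
  contradictory).

Because `c > 0.5` is enforced, the XY and ZW conditions are mutually
exclusive. A call is **PERFECT** iff both qualifying fractions equal 1.0
exactly, else **MODERATE**. Fractions are computed over *called* individuals
of each sex, so missing data shrink the denominator rather than counting
against the locus.

SNP candidates additionally pass a false-positive screen: in the homogametic
sex (females for XY, males for ZW), the majority homozygote class must
account for ≥ 80% of called individuals. A true Y-linked (or W-linked) SNP
has one fixed homozygote class in the homogametic sex; an autosomal locus
that passes the concordance filter by chance typically segregates both
homozygote classes. The screen is read as a single-majority-class condition;
a locus whose homogametic sex splits evenly between the two homozygote
classes fails.

### Parameters

| parameter | default | rationale |
|---|---|---|
| `call_rate_min` | 0.8 | standard DArT locus-quality filter; loci called in < 80% of individuals are dropped before classification |
| `concordance_min` | 0.8 | tolerates genotyping error and rare recombinants while excluding autosomal segregation at moderate cohort sizes |
| `strict` | False | when True, concordance is forced to 1.0 (only PERFECT patterns qualify) |
| `auto_strict_threshold` | 13 | with fewer than 13 individuals in the smaller sex, an 80% rule passes autosomal loci at a non-negligible rate, so the scan auto-escalates to strict mode (and warns); the directional effect is verified in the test suite |
| `fp_homozygosity_min` | 0.8 | majority-homozygote-class threshold of the false-positive screen |
| `min_called_per_sex` | 1 | below this a locus is UNEVALUABLE |

## Association statistics

**Hamming distance.** Genotypes are compared as categorical states (a
heterozygote differs from either homozygote — dominance-free identity, not
allele-sharing); the distance between two individuals is the fraction of
*co-called* loci at which they differ (pairwise-complete). Pairs with zero
co-called loci are NaN and flagged with a warning and `n_overlap == 0`.
Within/between-sex summaries are arithmetic means over defined entries.

**Cochran–Armitage trend test.** The classic 1-df statistic
`χ² = N·r²` with `r` the Pearson correlation between the dosage score
(0, 1, 2 by default) and the binary sex indicator; the asymptotic p-value
comes from χ²(1). Constant genotype vectors give NaN (flagged, not an
error). Permutation p-values shuffle sex labels with a seeded generator; the
default estimator `(b + 1)/(m + 1)` is valid but conservative because the
statistic is discrete (it has an atom at p = 1 when the observed statistic
is 0). `randomized_ties=True` returns instead the randomized p-value
`(G + U·(T + 1))/(m + 1)` (G strictly greater, T ties including the
observation, U ~ Uniform(0,1)), which is exactly uniform under the null and
is what the calibration test checks with a Kolmogorov–Smirnov test.

## Structure analysis

**Strict autosomal filter.** Removes declared sex-linked loci, then keeps
only loci with a recomputed call rate of exactly 1.0 and (when the metadata
carry `RepAvg`) reproducibility exactly 1.0. This is the conservative input
for PCA / F_ST / AMOVA, where missing data would otherwise need imputation
inside the variance decomposition.

**PCA.** Dosage encoding (0/1/2), per-locus mean imputation of any residual
missingness, centering, full-SVD principal components. Optional 2-means
clustering on the first two components assigns clusters when none are given.

**F_ST.** Weir & Cockerham (1984) variance components `a` (between
populations), `b` (between individuals within populations) and `c` (within
individuals), combined across loci as a ratio of sums. Loci are used for a
pair of clusters only if both clusters have ≥ 2 called individuals and the
locus is polymorphic in the pair; monomorphic panels give NaN with a warning.

**Nei distance.** Nei (1972) standard distance
`D = −ln( J_xy / sqrt(J_x · J_y) )` on allele frequencies.

**AMOVA.** Individuals contribute two 0/1 allele vectors each (N individuals
→ 2N allele rows); the total sum of squares is decomposed over three strata —
between clusters, between samples within clusters, within samples — by
centroid sums of squares, which equals the classical pairwise-squared-
distance/n formulation (verified against a pairwise oracle in the tests).
Degrees of freedom are (k−1, N−k, N, 2N−1). Variance components follow the
method of moments with coefficient `n_c = (N_a − Σ N_g²/N_a)/(k−1)` on allele
counts; negative estimates are truncated to zero for the percent-variance
column, with the raw value kept in `sigma_raw`. Significance: the
between-cluster component is tested by permuting individuals across clusters
and the within-individual component by permuting alleles among individuals
within clusters. (Classical AMOVA implementations permute at several
alternative levels; this scheme tests the two reported components directly.)

## Simulator

Each cluster's autosomal allele frequencies follow the Balding–Nichols model:
an ancestral frequency `p ~ Uniform(0.05, 0.95)` and cluster frequencies
`~ Beta(p(1−F)/F, (1−p)(1−F)/F)`, whose expected Wright F_ST between clusters
is the `fst_target` F. Genotypes are Hardy–Weinberg draws within clusters.
Sex-linked SNPs are heterozygous in the heterogametic sex and fixed for one
homozygote class (chosen per locus) in the homogametic sex; sex-linked PA
loci are present/absent accordingly. Autosomal PA loci (`n_autosomal_pa`) are
Bernoulli presence draws — an addition needed so that PA scans have a
non-sex-linked background to reject.

**Discordance.** Each individual violates the expected sex-linked pattern
with probability `discordance`, drawn per locus per sex as a binomial count —
but the count is redrawn while the realized per-sex rate would be ≥ 20%
(`DISCORDANCE_BOUND`). The bound models the regime of interest: a marker
discordant in ≥ 20% of one sex cannot qualify at the 80% concordance
threshold anyway, so the generator produces "sex-linked loci with bounded
noise", not i.i.d. error. Without the bound, a small cohort would routinely
contain true loci pushed past the threshold by sampling noise, and no
classifier could meet a high-sensitivity target; with it, the realized
discordance at rate 0.1 follows the truncated-binomial expectation checked
in the tests. The bound only binds when `discordance < 0.2`; larger values
are rejected by validation.

Missing calls are i.i.d. at `missing_rate` over all matrices. Metadata
(`CallRate`, `FreqHets`, `AvgPIC` via `PIC = 1 − p² − q²`, `RepAvg = 1.0`,
random 69-mer tag sequences) are computed from the *realized* matrix, so
written files round-trip like genuine reports. All randomness flows from one
`numpy` generator seeded by `SimConfig.seed`; outputs are bit-for-bit
reproducible, and derived per-locus seeds stay below 2³¹.

Not emulated: linkage disequilibrium between loci, allelic dropout biased by
fragment length, locus-specific error rates, X/Z-linked (gametologous)
variation visible as partial sex linkage, inbreeding, or more than two
clusters.

## Numerical conventions and problem sizes

- Distances and fractions are exact rationals evaluated in double precision;
  the "exactly 1 / exactly 0" acceptance identities hold bit-for-bit because
  they are ratios of equal integers.
- Undefined quantities (no overlap, monomorphic panels, constant genotype
  vectors, all-missing loci) are NaN with a warning or flag — never silently
  0.
- The intended scale is 10³–10⁵ loci × ≤ a few hundred individuals; the
  per-locus classification loop and the per-sample Hamming loop are linear in
  loci and quadratic in samples, comfortably within seconds at that scale.
- AMOVA requires complete data (use the strict autosomal filter first) and
  at least two clusters with two individuals each.

## Limitations

- The classifier assumes phenotypic sexing is correct; a mis-sexed
  individual depresses concordance at every true locus, which is why the
  moderate (80%) criterion exists for adequately sized cohorts.
- PA loci have no false-positive screen analogous to the SNP
  homozygosity test; at very small cohorts, chance-perfect autosomal PA
  patterns can pass the strict criterion, which is why reported PA counts
  should be read against cohort size.
- Permutation p-values are Monte Carlo estimates; their resolution is
  `1/(m + 1)`.
- The AMOVA permutation scheme tests the reported components directly rather
  than reproducing any single legacy package's scheme; p-values may differ
  slightly from other implementations on the same data.
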