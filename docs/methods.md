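# Methods

## Input model

The unit of input is one tumor's allele-specific copy-number profile: an
ordered set of non-overlapping segments per chromosome, each carrying the
copy numbers of the more and less abundant parental allele (n_major ≥
n_minor ≥ 0), together with the ASCAT estimates of tumor ploidy ψ (a real
number, the genome-wide average copy number) and tumor cell fraction.
Segmentation itself is upstream of this package: BAF/LogR processing and
the allele-specific segmentation algorithm are consumed, never recomputed.
Cohort assembly applies a single filter — samples whose tumor cell
fraction is strictly greater than a cutoff (default 0.20) are retained —
because below that purity the allele-specific estimates are unreliable.

All coordinates are 1-based and inclusive internally. refFlat annotation
(0-based half-open transcript starts) is shifted on read, and multiple
transcripts of one symbol are collapsed to their union span; a symbol
annotated on more than one chromosome is rejected rather than guessed.
Strand is carried but ignored: copy number is strand-agnostic. Frequency
tracks are written back out with 0-based starts per BED convention.

## Calling rules

For a segment with total copy number n = n_major + n_minor:

- adjusted copy number a = round(n − ψ), rounding ties half away from
  zero. ψ enters as a real number; pre-rounding it would shift every call
  in tumors with fractional ploidy. Half-away rounding keeps gains and
  losses symmetric at the ±0.5 boundaries, where banker's rounding would
  treat +0.5 and −0.5 asymmetrically relative to zero.
- state: a ≥ +1 gain, a ≤ −1 loss, a = 0 neutral.
- LOH: n_minor = 0 and n_major ≥ 1 — exactly one parental allele remains.
  Total loss of both alleles (n = 0) is *not* LOH (nothing remains to be
  homo- or heterozygous); it is flagged as homozygous deletion with state
  loss.
- copy-neutral LOH: LOH with a = 0 — one allele lost, the other
  duplicated, total at ploidy.

The genome instability index is the fraction of array probes lying in
gained or lost segments among probes lying in any segment. Probes in
unsegmented gaps carry no call and are excluded from numerator and
denominator; an all-gap profile has no defined GII and raises. The
high/low dichotomy defaults to a cohort-median split with ties low — the
cutoff is a parameter because no principled threshold exists.

## Gene-level projection

A gene takes the call of the overlapping segment with the largest
base-pair overlap. Ties are broken by larger |adjusted copy number|, then
by LOH present, then by the leftmost segment, which makes the call a
deterministic, order-invariant function of the profile. The covered
fraction (assigning segment overlap / gene length) is reported so
boundary-spanning genes are visible downstream. Genes overlapping no
segment yield a no-coverage marker rather than an imputed neutral call.
An alternative any-overlap rule would inflate LOH percentages for long
genes; the largest-overlap rule was chosen as the single-call rule that is
reproducible and declared, since gene-level behavior at segment
boundaries is otherwise underdetermined.

## Frequency tracks and group comparison

Chromosomes are tiled with fixed-width intervals (default 15 kb; the last
interval truncates at the chromosome end). A sample's state in an interval
is the state of its segment containing the interval midpoint — a 15-kb
window is thereby a single position query, avoiding double-counting of
windows split across segment boundaries; samples without a segment at the
midpoint leave that interval's denominator. Group tracks are compared
per interval with the two-sample proportion test with continuity
correction (algebraically the Yates-corrected 2×2 chi-square, the
`prop.test` default; a flag disables the correction). When neither group
has any aberration (or both are saturated) the proportions are equal by
construction and p = 1 is returned; intervals with an empty denominator
report a missing p. Raw p-values are the primary output with an optional
BH column, since the interval scan is conventionally read at raw p < 0.05.

## Association statistics

Contingency tables are built by pairwise-complete cross-tabulation —
samples missing either label are dropped for that table only, never
imputed, which is why different tables over one cohort have different
denominators. Defaults for testing a table: 2×2 → Yates-corrected
chi-square unless any expected count is below 5, in which case Fisher's
exact test; larger tables → uncorrected Pearson chi-square. Fisher's
two-sided p sums hypergeometric probabilities not exceeding the observed
table's probability (the R convention, not doubling of one tail), and the
reported estimate is the sample odds ratio ad/bc. Group means are compared
with Welch's t. The BH step-up is implemented directly (sorted p·m/j with
a reverse cumulative minimum, capped at 1) and cross-checked in the test
suite against the statsmodels implementation; the adjustment family for
the hotspot panel is the 13 non-KRAS genes, KRAS being excluded because
its association with itself is vacuous.

chi-square, Fisher, Welch t and Pearson correlation are delegated to
scipy; Kaplan–Meier, log-rank and Cox fitting to lifelines. The calling
rules, GII, gene projection, interval logic and BH step-up are authored
here.

## Expression integration

Copy-number/expression correlation uses per-gene Pearson r between the
gene's copy-number values and log2 expression across shared samples, BH
adjustment across all tested genes, and strict selection thresholds
(r > 0.4, q < 0.05). The copy-number value defaults to the ploidy-adjusted
total; genes with zero copy-number variance are excluded with a reason
code instead of returning an undefined r. Differential expression between
LOH groups is per-gene Welch t on log2 values with BH across genes — the
simplest defensible method for normalized array data — and cross-cohort
reproducibility is a plain set intersection of the significant genes.

Subtype assignment median-centers each signature gene across the cohort,
then assigns each sample to the centroid (TRU/PP/PI) with the highest
Pearson correlation; Spearman and Euclidean are options. Pearson
similarity makes the assignment invariant to per-sample affine transforms
of expression. At least half the centroid genes must be present
(configurable); exact ties go to the earlier subtype in column order and
are flagged ambiguous. Centroids are an external input — a published
506-gene predictor in real use — and tests use synthetic centroid sets.

## Survival analysis

Overall and relapse-free survival are months from surgery with 0/1 event
flags. Kaplan–Meier estimation, the log-rank test and Cox
proportional-hazards regression wrap lifelines with conventions pinned:
Efron handling of tied event times, Wald CIs and p-values, rows with any
missing model variable dropped pairwise. Stage enters models as the binary
contrast II+III vs I. Continuous expression covariates should be
standardized to unit variance by the caller so hazard ratios read per SD,
expression scale being platform-dependent. The bivariate scan fits one
two-covariate model per candidate confounder with the LOH flag fixed and
reports the flag's HR from each model — the design for asking whether a
single confounder explains the LOH effect. Exact collinearity with the
fixed covariate is rejected with a diagnostic error.

## Synthetic cohorts

The generator plants known truth in every emitted file. Defaults are the
study conditions of the motivating cohort: KRAS LOH prevalence 0.27 (of
which 12/62 ≈ 0.19 copy-neutral), KRAS mutation prevalence 0.365 (EGFR
0.15, mutually exclusive with KRAS), GII group means 0.57 (LOH) vs 0.46,
and an LOH overall-survival hazard ratio of 0.65 on an exponential
baseline (median 60 months OS, 80 months RFS, ~30% independent
exponential censoring with an administrative cap at 180 months). The
exponential baseline is the simplest model satisfying the proportional-
hazards assumption the analysis itself makes.

The genome is scaled down — 5 chromosomes × 60 Mb, probes every 15 kb,
~600 background genes plus the 14 hotspot-panel genes at fixed loci (KRAS
on chr2 standing in for 12p) — so a 500-sample cohort generates in about
a second; all problem sizes used by the tests and the acceptance script
(60–2000 samples) were chosen as the smallest that leave comfortable
statistical margins for the planted-parameter checks. Per sample, ploidy
is drawn from a bimodal near-diploid/genome-doubled mixture, chromosomes
are segmented with exponential segment lengths and occasional unsegmented
gaps, and each segment is aberrant with probability equal to the sample's
target GII (drawn around its group mean, sd 0.08). The segment covering
the KRAS span is replaced by a planted segment realizing the sample's LOH
flag: copy-neutral (n_major = round(ψ), n_minor = 0) or loss LOH
(round(ψ) − 1, 0); non-LOH samples keep both alleles with a background
gain rate of 0.21 at the locus. Expression is baseline + 0.5·(CN − 2) +
N(0, 0.9) per gene — about r ≈ 0.4 against copy number, matching the
observed KRAS correlation — plus a 1.5-log2 LOH shift in a designated
20-gene set for differential-expression truth. A two-cohort mode shares
the genome and the planted DE set between independently drawn cohorts.

What the generator does not emulate: probe-level platform noise, subclonal
copy-number states, linkage/haplotype structure, correlated segment states
between neighboring chromosomes, covariate-dependent censoring, and any
real dependence of survival on stage or age. Passing the recovery tests
therefore demonstrates correctness of the downstream arithmetic and
statistics under the stated generative model, not robustness to
segmentation error or array noise.

## Numerical choices and degenerate inputs

- Rounding: ties half away from zero everywhere an adjusted copy number is
  formed (an exact ±0.5 never arises with continuously drawn ploidy, but
  the rule is pinned for file-supplied ploidy).
- p-values of exactly 0 (underflow on exact fits) are clipped to the
  smallest positive double before BH, which requires p ∈ (0, 1].
- GII with no in-segment probes, contingency vectors with fewer than two
  levels after dropping missing values, log-rank with zero events, Cox
  with constant covariates, and Fisher with a zero margin all raise
  informative errors rather than returning conventional values.
- TSV readers parse floats in round-trip mode so write→read is exact.

## Known limitations

Cox models are fit without proportionality diagnostics beyond what
lifelines warns about; time-varying covariates and competing risks are out
of scope. The frequency-track midpoint rule can miss an aberration
confined to less than half an interval. Gene-level LOH percentages depend
on the declared largest-overlap rule and will differ from any-overlap
tabulations for genes spanning segment boundaries.
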