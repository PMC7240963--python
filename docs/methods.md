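# Methods

`ilnet` reconstructs significance-filtered correlation networks from
replicate-level trait measurements of a genotype panel — the setting of an
introgression-line (IL) survey, where ~76 lines are profiled on several
analytical platforms (primary/secondary metabolites, lipids, volatiles,
whole-plant phenotypes, transcript abundances) with very uneven replication.
This note records the statistical model, the defaults and why they were
chosen, and what the synthetic benchmark does and does not establish.

## Preprocessing

Replicate records `(line, group, replicate, trait, value)` are collapsed to
per-(line, trait) arithmetic means; a support count records how many
replicates entered each cell and cells without records stay missing.
Abundance traits are mapped `x -> ln(x + pseudo)` and z-scored per trait;
the z-score uses the sample (n−1) standard deviation, matching the default
of the usual statistics environments. The pseudo-count defaults to 1e-9 and
only guards exact zeros; because the downstream statistic is rank-based, its
value is irrelevant wherever it does not change the ordering (a property the
suite tests). Phenotypic counts and lengths can be listed in `skip_log` to
be z-scored without the log, since a log scale is not meaningful for them
and zeros are legitimate values. Traits with fewer than 3 observations or
zero variance are dropped with a logged warning rather than an exception —
in a 400-trait survey a handful of degenerate columns should not abort the
run.

Seasons measured on different scales are merged *after* standardization, by
averaging z-scores per (line, trait) over the seasons in which the trait was
measured, and summing support. Averaging standardized rather than raw values
is the least-assumption rule when seasons differ in calibration; it is the
package default and is recorded in the matrix's transform provenance. A
per-season analysis with a later union of edges is equally possible by
simply not merging.

## Correlation and significance

Spearman's rho is the Pearson correlation of mid-ranks (average ranks on
ties), computed on pairwise-complete observations; pairs with fewer than
`min_n` (default 10) complete observations get an undefined marker, never an
exception. Values within 1e-12 of ±1 are snapped to ±1 so exactly monotone
data report exactly ±1.

Significance uses a permutation test: the pairing is broken by permuting one
vector's ranks, which is exact under the exchangeability null of no
association. Two modes:

* **exhaustive** — all n! re-pairings (allowed while n! ≤ 40,320 = 8!);
  p is the fraction of permutations with |rho| at least the observed |rho|,
  the observed pairing included, so p ≥ 1/n!.
* **monte_carlo** — B random permutations (default B = 20,000) with the
  add-one estimator p = (1 + #exceedances)/(B + 1), which is conservative
  and strictly positive. The exceedance comparison carries a 1e-12 slack so
  permutations that tie the observed statistic in exact arithmetic count as
  extreme.

The p-value is two-sided throughout: networks keep positive and negative
edges alike, so the null must be sign-agnostic. Each column pair draws its
permutations from a random substream derived from `(seed, i, j)`, making
whole-matrix runs reproducible and order-independent. Measured calibration:
the marginal rejection rate at α = 0.05 over 8,000 independent-Gaussian
null pairs (n = 20, B = 2,000) is 0.048, against a theoretical 100/2001 ≈
0.050.

No multiple-testing correction is applied by default — edge filtering uses
the per-pair p < 0.05 convention of this analysis style. An optional
Benjamini–Hochberg mode (`adjust="bh"`) attaches an adjusted matrix for
users who want the comparison.

## Network assembly and summaries

An edge survives if p < 0.05 and the coefficient clears the cutoff. Two
cutoff conventions coexist deliberately: trait/trait networks use a strict
|r| > 0.3, trait/transcript networks an inclusive |r| ≥ 0.40; the boundary
semantics follow the conventions this kind of analysis reports and both are
recorded in the network's provenance attributes. Raising the coefficient
cutoff or lowering the p cutoff can only remove edges (tested as a
property). Isolated nodes are dropped unless requested.

Class-pair summaries count edges per unordered annotation-class pair
(within-class pairs included), with percent-positive kept at full precision
internally and rounded to integers only in the report-layout matrix.
Network-level statistics report node/edge counts, overall percent-positive
and per-group edge shares, which partition to 100%.

Exports: GraphML with node annotation and edge statistics as attributes,
SIF with `pos`/`neg` interaction labels, and an edge TSV printed at 17
significant digits and re-parsed with round-trip float precision, so
export→import is bit-exact.

## Transcript integration and group comparison

Transcript panels are correlated against metabolite matrices across the
shared lines (alignment on the intersection; an empty intersection is an
error). Every trait or transcript with at least one surviving edge is
selected into the heatmap matrix, which retains sub-threshold coefficients
for the selected rows and columns — the selection rule is monotone in the
cutoff. Candidate genes are transcripts with ≥ 1 surviving link, ranked by
(link count desc, max |r| desc, id asc); the dominant class is the most
frequent annotation class among a candidate's partners with alphabetical
tie-break. No stricter candidacy rule is imposed: the candidate count is a
config-dependent output, reported rather than asserted. Independent runs per
tissue can be joined into a table of transcripts recurring across tissues.

Group comparisons report the fold change as a ratio of raw-scale means
(matching how expression differences are usually quoted) and test location
on the natural-log scale with a two-sided Welch (unequal-variance) t-test —
the test behind published significance marks is typically unstated, and
log-scale Welch is the conservative default for positive, roughly
log-normal abundances with possibly unequal group spreads. Star codes mark
p < 0.05 (`*`) and p < 0.001 (`**`). Fold antisymmetry
(fold(a→b) = 1/fold(b→a)) holds to machine precision. One caveat is
inherent to pooling: when replicate values cluster by line (the generator's
line-latent term), pooling all replicates of a group treats correlated
values as independent and the t-test becomes anticonservative; the
calibration claim made by the test suite therefore concerns i.i.d.
replicates within groups, the regime of a designed expression comparison.

## The synthetic generator

The generator is the package's benchmark instrument: it produces panels
whose correlation structure is known exactly, so recovery can be scored.

* **Copula construction.** Each annotation class has a latent factor per
  line; a trait in the class loads on it with weight √a, where
  a = 2·sin(π·rho_s/6) converts the requested Spearman rho_s into the latent
  Pearson correlation of a bivariate normal. Inter-class blocks correlate
  the factors themselves (sign respected), with an eigenvalue-clipping
  repair if the requested block combination is not positive semi-definite.
  Line-level log-means are `base + line_sd · z`; replicate values are
  log-normal around them. Because the downstream pipeline log-transforms and
  Spearman is invariant to monotone maps, the planted rank correlations
  survive the abundance scale.
* **Replication and missingness.** Replicate counts are drawn uniformly
  from `replicate_range` per (line, platform) — default 1–12, the
  heterogeneity of a multi-platform survey — and individual replicate
  records are dropped with probability `missing_rate` (default 5%), forcing
  pairwise-complete handling downstream.
* **Defaults.** 76 lines; 50 traits in 5 classes (TAG, phospholipid,
  amino-acid, flavonoids, yield-related) of 10 traits each; intra-class
  Spearman 0.7; replicate noise sd 0.25 on the log scale against a line
  spread of 1.0, so line means are estimated with little attenuation at
  3–4 replicates and modest attenuation at 1–2; genotype groups REF / IL_1 /
  PEN sized 12/52/12 so group comparisons have enough lines per group for
  stable raw-mean ratios. Transcripts default to a line spread of 0.6, large
  enough that a planted rho of 0.6 is attenuated by < 3% at 3–4 replicates;
  fold-change demonstrations use 0.15 so that a 20-fold group effect is
  estimated with a group-mean log s.e. around 0.06 and lands within ±30%
  with large margin.
* **Truth bookkeeping.** Planted within-class and inter-class pairs,
  independent ("null") pairs, transcript–trait links and group effects are
  returned in a `SyntheticTruth`. The per-line latent trait scores ride
  along in memory (they seed transcript coupling) but are not serialized.

What the generator does *not* emulate: QTL genetics and introgression
segment structure (correlations are planted directly, not mediated by
genotype), platform-specific measurement artifacts, batch or season effects
beyond independent re-draws, heavy-tailed or zero-inflated abundance
distributions, and correlated missingness. Passing the recovery benchmarks
therefore shows the pipeline's statistics behave as designed under a clean
block-correlation model of realistic size, noise and missingness — not that
any particular biological network would be recovered from real data.

## Problem sizes and numerical choices

The standard benchmark sizes are: permutation-oracle suite at n = 6
(720 permutations, B = 50,000); type-I calibration over 1,000 null sets
(n = 20, B = 2,000); planted-edge recovery on the default 76 × 50 panel with
B = 2,000 (1,225 pairs); transcript-link recovery over 105 gene–trait pairs
at 74 shared lines; star-rate calibration over 1,000 two-group sets. These
run in seconds to a few minutes on one core; B = 20,000 remains the default
for analyses because p-resolution, not runtime, is the binding constraint
there.

Tie-breaks and degenerate inputs are fixed as follows: candidate ordering
and dominant-class ties break alphabetically; constant traits and sub-`min_n`
pairs yield undefined markers; identical constant groups in a comparison
report p = 1; empty networks yield empty summaries, not errors.

## Known limitations

* Pairwise-complete deletion can make the correlation matrix
  non-positive-definite as a whole; nothing downstream requires
  definiteness, but the matrices should not be fed to methods that do.
* The permutation test assumes exchangeability; replicate structure is
  collapsed to line means before correlation, so pseudo-replication at the
  correlation stage is avoided by construction, but blocked designs
  (e.g. permuting within seasons) are only available behind an explicit
  blocked-permutation choice that this version does not expose.
* Candidate-gene counts depend directly on the cutoff pair; they are
  reported, never compared across differently filtered runs.
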