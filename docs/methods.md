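# Methods

## The trial being modelled

A controlled-pollination crossing trial in kola: per cross, 20 hand
pollinations replicated by 3 pollinators (60 flowers in total), with pods,
pseudo-pods and dropped flowers counted two weeks after pollination, and pod
and nut traits measured on the harvested pods. Crosses are selfs or hybrids,
at two pedigree levels: single crosses between genotypes (`JX1/90 × JX1/51`)
and double crosses between F1 hybrid trees, each named by its parental pair
(`B1/11 × B1/71 × B1/157 × B1/149`). Kola expresses sporophytic
self-incompatibility: the pollen's incompatibility phenotype is set by the
diploid genotype of the pollen-producing tree, so selfing is blocked and
many cross combinations fail as well.

## Compatibility statistics

Pod set and pseudo-pod set are binomial proportions of the pollinated
flowers. Replicates are **pooled by counts** before forming percentages: the
trial reports a single percentage per cross, which is what pooling produces;
a mean-of-replicate-percentages mode is available (`aggregation="mean"`)
because the two differ when replicates are unbalanced. A pod set of exactly
0 is class 0; otherwise class k covers (20(k−1), 20k]. The printed scale
labels integer ranges ("21–40%"), leaving e.g. (20, 21) unassigned; the
half-open convention closes those gaps on the left of the next class and is
consistent with "81–100%" including 100.

The cross-type contrast fits logit(p) ~ cross-type to the per-record
success/failure counts (binomial GLM, IRLS) and reports the likelihood-ratio
deviance against the intercept-only model on 1 df. Because the group MLEs
are the pooled group proportions, this statistic equals the classical 2×2
likelihood-ratio G on pooled counts — which is also how the result is
computed under complete separation (a group with no successes or no
failures), where Wald output is degenerate; such results carry a
`separation` flag. Class-distribution tests are chi-square goodness-of-fit
against uniform occupancy of classes 0–5 (df = 5); pairwise class
comparisons use the binomial score test of an even split between the two
classes' counts, Holm-adjusted (the trial names no adjustment; Holm controls
FWER without independence assumptions).

## Yield and quality

Outturn is 100 · peeled/unpeeled nut weight. It is computed per replicate
and then averaged (mean-of-ratios). The packaged tables support this
reading: for low-pod crosses the printed outturn (e.g. 46.4 for GX1/2
selfed) sits far from the ratio of the printed weight means (67.1), which
only a before-averaging computation explains. A ratio-of-means mode is a
flag on `outturn_percent` usage, and packaged values are never recomputed.

Group tests run one-way ANOVA when Shapiro–Wilk on the pooled residuals
accepts normality at 0.05, otherwise Kruskal–Wallis (the trial says only
"where relevant"; the residual gate makes the choice reproducible). When the
global test is significant at α = 0.05, pairwise decisions use Fisher's LSD
with the pooled MSE (after ANOVA) or Dunn's rank comparisons with tie
correction (after KW), both unadjusted in the protected-test tradition LSD
belongs to. Letters come from the insert-and-absorb algorithm, which makes
letter-sharing exactly equivalent to the pairwise decision. A single
observation yields a missing s.e. (not 0); all-constant groups return a
degenerate-flagged exact-tie result.

## Heterosis

MPH, BPH and ECH as in the README, on per-cross means over replications.
Parents are resolved from the pedigree: the parents of a double cross are
its two component hybrid entities, valued by their double-self crosses.
Better parent means larger value — all three scored traits (pod set,
outturn, brix) are larger-is-better, so no direction flag exists in v1.
Standard-variety values are looked up as observed dataset means of the named
crosses (override table in config). Zero denominators and missing parental
selfs produce undefined results with provenance, since the trial prints no
convention for such cases. For positive parents BPH ≤ MPH always (BP ≥ MP);
this ordering is property-tested.

## Multivariate characterization

PCA standardizes traits to zero mean and unit variance (eigenstructure of
the correlation matrix, via SVD; ddof = 1 scaling as in `prcomp(scale=TRUE)`),
with a deterministic sign convention (largest-magnitude loading positive).
Missing cells are mean-imputed with a logged warning; zero-variance traits
are dropped. Ward clustering runs on the scores of the components reaching
80% cumulative variance (the trial reports dimension percentages but no
retention policy; 80% is a conventional default). Auto-k maximizes the
relative within-inertia drop (W(k−1) − W(k))/W(k−1) over k = 3..6 — bounded
there because the reported solutions were 3 or 5 clusters — with ties toward
smaller k. On the packaged GX1 table this rule selects k = 4 (relative drops
0.47 at k=3 vs 0.51 at k=4) where the trial reported 3; the selection method
used there is unprinted, so exact membership reproduction is not a goal and
the deviation is logged rather than forced.

Cluster description uses the v-test
v = (mean_c − mean) / sqrt((s²/n_c) · (N − n_c)/(N − 1)), with s² the
population (ddof = 0) variance, two-sided normal p-values, and a 0.001
reporting threshold (configurable). Correlations are Pearson on
pairwise-complete observations with t-distributed p-values; cells with
fewer than 3 complete pairs are missing.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, not
kola physiology:

- **S-locus**: `n_s_alleles = 6` alleles in a strict linear dominance
  hierarchy; each genotype draws two alleles uniformly (homozygotes
  allowed). The sporophyte expresses its most dominant allele; a cross is
  compatible iff the two parents' expressed sets are disjoint. A codominance
  option (both alleles expressed) is a flag. Strict dominance is the
  simplest model reproducing the observed self-incompatible /
  mostly-cross-compatible pattern; with 6 alleles ~78% of random pairs are
  compatible.
- **Pod set**: Binomial(20, p) per replicate with `p_compat = 0.75` for
  compatible crosses and `p_leak = 0.10` for incompatible ones. Leakage
  stands in for partial self-compatibility (the moderately self-compatible
  genotypes in the printed tables) without modelling S-allele loss.
- **Pseudo-pods**: drawn from the flowers that did not set a pod, at
  `p_pseudo_incompat = 0.35` vs `p_pseudo_compat = 0.05` — mechanically
  higher where pod set is low, matching the elevated pseudo-pod set of
  selfs. The trial gives no quantitative pseudo-pod mechanism; this binomial
  leakage model is an assumption, echoed in the truth output so tests never
  treat it as biology.
- **Traits**: each genotype carries additive values drawn around baselines
  matching the printed tables' magnitudes (e.g. pod weight 150 g, brix
  12 °Bx, outturn 75%). An F1 hybrid entity's value is the parental mean
  inflated by `1 + dominance_gain` (defaults 0.10–0.25 by trait); a cross's
  expected trait is the mid-parent of its two entities, inflated again only
  when the cross is compatible and non-self. Peeled nut weight is derived as
  unpeeled × outturn/100, keeping the weight ordering invariant.
- **Noise**: multiplicative, applied per measured pod with CV `env_cv`
  (gamma deviates, mean exactly 1); a replicate's trait record is the mean
  over the pods it harvested (1 floor so selfs stay defined). This mirrors
  how the trial measures traits — instruments read individual pods/nuts and
  the cross value is their average — and it makes precision scale with pod
  number, so compatible crosses are measured more precisely than selfs.
  With `env_cv = 0` expectations are exact and recovered MPH equals
  100 · dominance gain to machine precision.
- **Randomness**: one stream per (seed, cross label, replicate) via hashed
  seed sequences, so growing a design never perturbs existing records.

What passing simulator-based tests shows — and what it does not: the
pipeline's estimators are consistent with the generator's additive+dominance
truth under binomial sampling. Real trials add flowering asynchrony, pollen
viability variation, pollinator effects beyond replicate identity, spatial
and year effects, and non-multiplicative measurement error; none of these
are modelled, so recovery in simulation does not certify field accuracy.

## Numerical choices and degenerate inputs

Zero pollinated flowers → undefined percentage (never 0). GLM statistic
clipped at 0 against IRLS rounding; p = 1 when the statistic is 0. PCA on
fewer than 3 crosses, clustering with k > n, and single-cluster description
raise errors. Checksummed fixtures fail loudly on corruption. The packaged
tables keep one printed decimal; acceptance comparisons are exact equality
on those values.

## Problem sizes

Tests and the acceptance script run trials of 30–40 genotypes with 25–140
single crosses and up to 15 double crosses (60 flowers per cross), 1000-run
null calibrations for the GLM contrast and the ANOVA, and 200–400-example
property sweeps; these sizes give stable verdicts for every check while the
whole suite stays fast.

## Known limitations

- Heterosis estimates carry no standard errors or tests (the trial reports
  point values only); no combining-ability (GCA/SCA) decomposition.
- The pedigree grammar is exactly 2 or 4 IDs; free-text pedigree history is
  out of scope.
- Trait directions are fixed larger-is-better for the scored traits.
- Cluster memberships are method-sensitive (retention %, linkage, k rule);
  only the workflow, not the trial's exact partitions, is reproduced.
- No multi-locus SI, pollen-tube growth, or orchard spatial layout in the
  generator.
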