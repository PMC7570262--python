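# Methods

## The accounting model

A buried packet experiment observes, per packet, the partition of sown
seeds at collection into three classes: expended (split coat, radicle,
or empty hull — the seed germinated or decayed), retained (intact), and
unrecovered (the bookkeeping remainder `seeds_sown − expended −
retained`). A subset of retained seeds enters a tetrazolium assay and
each assayed seed is scored stained (live) or unstained (dead).

All derived quantities are functions of pooled counts:

- the seed bank of a group is its total sown seeds (100%);
- the expended pool F and retained pool C are proportions of the seed
  bank; unrecovered seeds close the partition and are excluded from
  every rate denominator;
- the staining rate among assayed seeds, D/(D+E), is applied to all of
  C when a survival-relevant quantity is needed, because the assay is a
  random subsample of the retained pool;
- decayed (A) and germinated (B) seeds cannot be told apart at spring
  collection, so the live pool G = B + D and dead pool H = A + E are
  reported as intervals `[D, D+F]` and `[E, E+F]`; flow tables display
  the equal split A = B = F/2, tagged as a display convention and never
  used in estimation.

Sankey flow export conserves mass at every internal node to 1e-9 and is
property-tested over randomly generated valid pool summaries.

## Survival and its aggregation

Seed bank survival of a group is `p_l × p_s` with `p_l` = retained /
recovered and `p_s` = stained / assayed, computed from counts pooled
over the group's packets. The elementary analysis cell is the stratum
species × cohort × microhabitat × burial duration; coarser summaries
are unweighted means of stratum survival values. This mean-of-products
convention is the headline because it commutes with the way
cross-species and cross-microhabitat summaries are usually quoted
(e.g. mean(5.6, 1.0) = 3.3); the pooled alternative
`mean(p_l) × mean(p_s)` is exposed separately (`product_of_means`) and
differs in general — the test suite contains a worked demonstration.
Whether field reports use packet-weighted or unweighted means is rarely
stated; the unweighted choice reproduces every cross-checkable printed
summary we calibrate against, but it remains a convention, recorded
here.

Rounding is half-up at report time only (two-decimal float noise below
1e-10 is squashed first so that 4.95-like means round up); proportions
are carried at full precision internally.

Between-year decline is `(s₁ − s₂)/s₁ × 100`, undefined at `s₁ = 0`.
Computed from one-decimal rounded inputs it can differ from a value
computed on unrounded data by up to ~0.3 percentage points at these
magnitudes; comparisons against published declines use that tolerance.

Confidence intervals for survival (a product of two dependent binomial
proportions) have no exact textbook form; `bootstrap_survival_ci`
provides a seeded percentile bootstrap over packets (default 2000
resamples) as an explicit extension of the point estimator.

## Inference

Rank-based tests are used for survival comparisons because
location-level survival values are bounded, zero-inflated and
non-normal (a Shapiro–Wilk screen gates the reporting path). The
Mann–Whitney U statistic follows the rank-sum-minus-offset convention
(midranks under ties); p-values come from exact enumeration when the
combined sample is ≤ 12 with no ties, else from a tie- and
continuity-corrected normal approximation; the convention and path are
recorded in every result. Kruskal–Wallis uses the tie-corrected H
against chi-squared with k−1 df. Dunn's post-hoc z statistics use
pooled midranks with the standard tie term; the multiplicity adjustment
(none / Bonferroni / Holm, default Bonferroni) is recorded in the
output. The exact Mann–Whitney path is verified against an independent
brute-force permutation oracle, and both tests' null rejection rates
are checked against the nominal level by simulation.

Retention and staining are modelled with quasibinomial logit GLMs. The
retention model takes merged-location retained proportions as the
response, weighted by seeds recovered at that location (packets of the
same cohort collected at the same microhabitat × plot location are
merged first — an explicit operation, since a location is one
observational unit); the staining model takes unweighted seed-level
stain presence. Fitting is IRLS to a relative deviance change below
1e-10 (cap 100 iterations, with the deviance trace attached to any
convergence failure); dispersion is Pearson chi-squared over residual
df; quasi-separation is flagged, not fatal. Type III tests drop one
term at a time from the full factorial while keeping all others, which
is only well defined under non-treatment contrasts, so factor coding is
fixed to sum-to-zero; each term's F is the scaled deviance difference
over the full-model dispersion. The fit and the Type III table are
cross-checked against an independent engine (statsmodels) to 1e-6.
Plot is not a blocking factor (blocks are incomplete in this design),
and when dispersion exceeds 2 the table carries a caveat that
p-values are approximate — quasi-likelihood scaling absorbs but does
not remove extra-binomial variation.

## The simulator

Each sown seed starts live with probability `initial_viability`
(default 1: pre-burial viability is unmeasured in the emulated design,
so sown seeds are treated as live) and evolves per season: live intact
seeds are expended with `p_expend[s]`, die in place with `p_die[s]`, or
persist; dead intact seeds are expended with `p_expend_dead[s]`,
defaulting to the live rate (seed-coat decay treated as
viability-blind). Assays subsample retained seeds per packet at
`assay_fraction` (default 0.5 in the shipped scenario — assays in
these experiments use a subset of the retained pool); stain outcomes
are Bernoulli in sensitivity/specificity (defaults 1.0). Collection
years are realized as distinct packets buried once and exhumed after
one or two seasons, split in even halves within each microhabitat
third; plots are assigned round-robin (9 per site by default) and
individual locations can be marked lost to mimic field attrition.

Randomness uses one root seed with per-stratum substreams keyed by a
CRC of the stratum labels, so adding or removing a stratum never
perturbs another stratum's draws; identical seeds give bit-identical
packet tables.

Closed-form pool probabilities (retained, retained-live, staining rate,
survival) follow from the hazards by season-wise recursion, and
`scenario_from_pools` inverts them exactly: two seasons of (retained,
staining) targets determine the season hazards. A *rising* staining
rate between years cannot occur under viability-blind decay — the live
fraction of the retained pool can only fall — so the inversion
switches to selective dead-seed decay (faster expenditure of dead
intact seeds, no additional in-place death) in that case; infeasible
target orderings (retention increasing over time, retained-live above
viability) raise errors naming the violated constraint.

### Default calibration

The shipped scenario reproduces the published allocation (rare
species: 90 packets × 18 seeds + 180 × 9; common species: 90 × 14 +
180 × 2; thirds across control/runoff/shade, halves across two
collection years) and pins stratum pools to the reported percentages:
year-1 retention/staining of 32.7%/49.0% (rare) and 82.7%/31.1%
(common) with no microhabitat effect (none was detected in year 1);
year-2 staining of 62.3% (rare) and 11.4% (common) independent of
microhabitat, with microhabitat acting through retention, back-computed
as survival/staining from the reported species × microhabitat
second-year survival values (rare 5.6/9.6/14.0%, common 1.0/0.3/5.3%
for control/runoff/shade). The two cohorts share one calibration —
real cohorts differed, but no per-cohort pool values are available to
separate them. The default loses no seeds to non-recovery.

What the simulator deliberately omits: granivory and seed movement,
fungal-infection dynamics, weather covariates, cohort effects, and
packet-level overdispersion beyond binomial sampling. Passing tests
therefore demonstrate the correctness of the accounting, estimation and
inference machinery under the declared generating model — not that
field data meet those assumptions (real retention data, for instance,
are overdispersed relative to binomial, which is exactly why the
quasibinomial model is used on data).

## Validation harness and problem sizes

`parameter_recovery_study` re-simulates a scenario (replicate r uses
root seed `seed + r`), pools counts per stratum × duration, and flags
any stratum whose mean (p_l, p_s, survival) estimate deviates from the
closed-form truth by more than 3 SD/√replicates; below 10 replicates
flags are suppressed as meaningless. The shipped checks run 200
replicates of the full 540-packet scenario; the estimators are exact
conditional binomial proportions under the generating model, so no
stratum flags. Monte-Carlo checks of test levels use 5000 null
replicates at group size 25; exact-vs-oracle equivalence enumerates
all tie-free two-sample instances up to combined size 10; flow
conservation is checked on 1000 random valid pool summaries. These
sizes were chosen so every check is decisive at its stated tolerance
while the whole suite stays quick to run.

## Known limitations

- Type III tests assume the full factorial is estimable; empty design
  cells silently reduce the model rank (the rank is reported as
  `df_model`).
- The equal A/B display split in Sankey output is a visualization
  convention; downstream consumers must not read it as an estimate.
- The bootstrap interval undercovers for strata with very few assayed
  seeds (e.g. 2-seeds-per-packet cohorts), as any resampling interval
  does at tiny n.
- `scenario_from_pools` currently requires `initial_viability = 1`;
  scenarios with partial initial viability must specify hazards
  directly.
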