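# seedfate

Seed-fate accounting and seed bank survival analysis for buried seed
packet experiments.

Buried seed packets ("seed bags") are the standard way to measure how
long seeds of annual plants survive in soil: packets of individually
celled seeds are buried in known microhabitats, exhumed after one or
more growing seasons, and each seed is scored as *expended* (germinated
or decayed — indistinguishable at spring collection) or *retained*
(intact). A subset of retained seeds is tested for viability with a
tetrazolium staining assay. `seedfate` implements the full analysis
chain for such experiments — data model, fate-pool accounting,
survival estimation, and inference — together with a calibrated
multistate simulator so the whole pipeline is testable end to end
without field data.

The statistic at the core is **seed bank survival**

```
survival = p_l × p_s
```

where `p_l` is the proportion of recovered seeds that were retained
(intact) and `p_s` is the seed staining rate — the stained fraction of
assayed retained seeds, used as the viability estimate. Survival is
computed per elementary stratum (species × cohort × microhabitat ×
burial duration) from pooled counts and then averaged unweighted across
strata; the alternative pooled path `mean(p_l) × mean(p_s)` is also
reported because the two differ whenever retention and viability covary
across strata.

Around the survival statistic the package provides:

- **Fate-pool accounting** (`seedfate.pool_accounting`): partitions the
  seed bank (100%) into the expended pool F (decayed A + germinated B),
  the retained pool C, and the assayed live/dead split D/E; exports
  proportionally exact, mass-conserving Sankey flow tables (JSON/CSV).
  Live (G = B + D) and dead (H = A + E) pools are reported as intervals
  because A and B are not separately observable.
- **Inference** (`seedfate.rank_tests`, `seedfate.glm`): Mann–Whitney U
  (exact enumeration for small tie-free samples), Kruskal–Wallis with
  Dunn's post-hoc z tests, a Shapiro–Wilk screen, and a quasibinomial
  logit GLM fit by IRLS with Type III analysis-of-deviance F tests under
  sum-to-zero contrasts — the model used for packet-level retention
  proportions (weighted by seeds recovered) and seed-level stain
  outcomes.
- **Simulation** (`seedfate.synthetic_data`): a per-seed multistate
  model (live intact / dead intact / expended) with per-season,
  per-stratum hazards, closed-form pool probabilities, exact inversion
  from target pool percentages, and a parameter-recovery harness.

## Worked example

Simulate the default experiment — 540 packets / 4860 seeds across two
*Eriophyllum* species, two seed cohorts, three microhabitats (shade and
runoff zones of a photovoltaic panel plus open-ground control) and two
burial durations, calibrated to published pool percentages — then
estimate and aggregate survival:

```python
import seedfate as sf
from seedfate.presets import default_scenario

records = sf.simulate_experiment(default_scenario(rng_seed=42))
ests = sf.stratum_survival(records)

by_year = sf.aggregate_survival(ests, over=["cohort", "microhabitat", "species"])
for e in by_year:
    print(f"year {e.group['burial_seasons']}: survival {e.survival_pct:.1f}% "
          f"(mean of {e.n_strata} strata)")

micro = sf.aggregate_survival(
    [e for e in ests if e.group["burial_seasons"] == 2], over=["cohort", "species"])
for e in micro:
    print(f"year 2, {e.group['microhabitat']}: {e.survival_pct:.1f}%")

print(f"decline in control: {sf.survival_decline(18.9, 3.3):.1f}%")
```

```
year 1: survival 19.9% (mean of 12 strata)
year 2: survival 5.9% (mean of 12 strata)
year 2, control: 3.0%
year 2, runoff: 5.7%
year 2, shade: 8.8%
decline in control: 82.5%
```

Survival drops sharply in the second season, and shade microhabitats
retain noticeably more live seed than control or runoff — second-year
shade survival here is roughly triple the control value, driven by
elevated retention under panels rather than by staining-rate
differences (the scenario's generating model holds viability constant
across microhabitats).

The same pipeline runs from the shell:

```
seedfate report --seed 42 --out results/
seedfate simulate --seed 1 --out packets.csv
seedfate analyze --input packets.csv --out results/
seedfate recover --replicates 200 --seed 0 --out results/
```

`report` writes the packet table, pool summary, survival table, Sankey
flows, deviance tables, rank-test results and a manifest recording the
seed and config hash; identical configs reproduce identical numbers.

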