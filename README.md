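# troopnet

Social-network analysis of focal-sampling interaction records from a
primate troop: directed, weighted grooming and aggression networks,
alpha-tuned weighted network metrics, stepwise knockout simulations, and
the resampling / rank-based statistics needed to compare age-sex classes
and to quantify how excluding an entire age class (juveniles) distorts
the apparent network structure.  A synthetic troop generator with
plantable class-structured effects makes every stage testable without
field data.

## What it does

- **Network construction** (`troopnet.data_model`) — merges interrupted
  grooming bouts (pauses ≤ 30 s, same dyad and direction), then builds
  directed networks whose edge weights are hourly rates: grooming
  seconds/hour and aggressive acts/hour.  Three rate denominators are
  supported (`dyad_hours` default, `actor_hours`, `total_hours`).
- **Metrics** (`troopnet.metrics`) — binary degree / in- / out-degree,
  in/out-strength, generalized (alpha-tuned) degree, weighted
  betweenness with edge cost `(1/w)**alpha` (alpha = 0.5 default, raw
  counts, tolerance-based tie handling), weighted local clustering on the
  symmetrised network, density, Freeman degree centralization and mean
  clustering.
- **Knockout engine** (`troopnet.knockout`) — exhaustive targeted
  removals (every size-r subset of a target class), random control
  removals (500 iterations with exhaustive fallback whenever
  C(n, r) < budget, avoiding pseudoreplication), and class-effect
  removals that track per-class mean betweenness/clustering; plus
  betweenness rank-change tables.
- **Resampling** (`troopnet.permutation`) — selective node permutation
  (all C(10, 5) = 252 subset means per class) and class-mean bootstraps.
- **Statistics** (`troopnet.stats`) — Kruskal–Wallis, a from-scratch
  Scheirer–Ray–Hare rank-based two-way factorial test, Mann–Whitney U,
  stacked-regression slope comparison, Welch t on bootstrap
  distributions, and Levene/Shapiro–Wilk diagnostics.
- **Synthetic troops** (`troopnet.synthetic`) — Poisson dyadic
  interaction counts with lognormal bout durations at class-pair rates;
  an `EffectProfile` of multipliers plants the qualitative field pattern
  (juveniles groom many partners briefly and receive frequent aggression,
  adults initiate aggression, females dominate grooming, adult males
  avoid juveniles, juvenile–juvenile interaction is rare).
- **Pipeline + CLI** (`troopnet.pipeline`, `troopnet.cli`) — aims 1–3
  end-to-end with CSV/JSON/GraphML artifacts and optional plots.

## CLI

```bash
troopnet simulate --out data/ --seed 1          # synthetic roster/effort/events
troopnet build    --data data/ --out nets/      # edge lists + GraphML
troopnet metrics  --data data/ --out tables/    # node + global metric tables
troopnet aim1     --data data/ --out results/   # juvenile vs adult comparison
troopnet aim2     --data data/ --out results/   # knockout K-W / factorial tables
troopnet aim3     --data data/ --out results/   # class-effect slopes, ranks, bootstraps
troopnet all      --data data/ --out results/ --plots
```

Any analysis parameter can come from a YAML/JSON config
(`--config cfg.yaml`; keys mirror `troopnet.pipeline.AnalysisConfig`),
with flags taking precedence.  Every report directory includes
`run_metadata.json` with the config hash and seed.

### File dialects

- `roster.csv`: `id,sex,age_class,is_study_subject`
- `effort.csv`: `id,hours`
- `events.csv`: `actor,recipient,behaviour,start_time_s,duration_s`
  (duration empty for aggression)
- network exports: `source,target,weight` CSV and GraphML

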