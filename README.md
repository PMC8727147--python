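# virodiscover

Analysis pipeline for **virus-discovery dynamics in wild mammal hosts**:
given a table of host–virus association records with discovery dates
(VIRION-style), it asks whether current viral-richness estimates are stable
enough to support comparative ecological inference, or whether they are
still being actively rearranged by uneven discovery effort.

Intended users: disease ecologists and biostatisticians working with
host–pathogen association databases who need to quantify how sensitive
their richness-based inferences are to historical sampling bias.

## What it computes

Let `y_t` be the number of novel viruses discovered in a host taxon in year
`t`. The pipeline provides:

1. **Discovery-rate trends** — a penalized-spline count regression
   `log E[y_t] = f(t)` (Poisson, or negative-binomial when the Pearson
   dispersion of the Poisson fit exceeds 1.5), with years classified as
   *increasing* / *decreasing* / *none* according to whether the pointwise
   95% CI of `f'(t)` excludes zero. A taxon whose inventory is approaching
   completeness must eventually show a terminal *decreasing* period.
2. **Rank-stability curves** — Spearman's ρ between per-taxon viral
   richness at each historical year and at the 2018 reference, over a fixed
   taxon universe (taxa with ≥ 1 virus by the reference year; zeros
   backfilled). Steep decline toward the present means discovery effort has
   been actively reordering which taxa look virus-rich.
3. **Snapshot regressions** — at 5-year snapshots 1990–2020, a
   negative-binomial GLM of order-level viral richness (PCR/isolation
   evidence only) on `log(species richness)`, adjusting for
   `log(1 + citations)`, asking when the positive richness–richness
   association becomes detectable in the accumulating record.
4. **A synthetic discovery process** — orders with heavy-tailed per-species
   "true" viromes sampled under configurable effort curves and
   order-targeted effort shocks, with a ground-truth ledger, so the whole
   pipeline is testable without any external database.

## Worked example

```bash
python analysis/01_simulate.py        # synthetic VIRION-like world, seed 1
python analysis/02_ingest_filter.py   # -> results/pairs.csv
python analysis/03_discovery_trends.py
python analysis/04_rank_stability.py
python analysis/05_snapshot_glm.py
```

`02` prints (seed 1):

```
28935 records parsed, 0 rejected
23091 records after filters (resolved, wild, <= 2018)
6224 unique host-virus pairs (5530 with PCR/isolation evidence)
```

i.e. of ~29k raw reports, deduplication and the standard filters (resolved
virus names, wild hosts, records through 2018) leave 6224 unique host–virus
pairs — the unit of all downstream analysis. `03` then reports, per order,
the significant trend periods, e.g.

```
Chiroptera      [negative_binomial] ... 1997-2007 increasing; 2008-2018 none
Rodentia        [poisson          ] 1930-2018 increasing
```

— discovery is flat-or-accelerating everywhere; no terminal decreasing
period, so no evidence any order's inventory is nearing its asymptote. `04`
prints the stability summary: the all-species curve falls to ρ ≈ 0.40 by
2001 while order-level totals stay ≈ 0.90, and the shock-targeted order
(the bat analogue) has the lowest within-order ρ at 2010 (≈ 0.80) — a
decade of intensified surveillance rearranged its species ranking more than
any other order's. `05` prints the snapshot sweep:

```
2005: slope(log S) = -0.028 [-0.291, +0.235]  -> not detected
2015: slope(log S) = +0.163 [+0.055, +0.271]  -> POSITIVE
```

— the positive species-richness/viral-richness association is only
detectable in late snapshots, so an analysis run a decade earlier would
have drawn a different conclusion from the same underlying world.

The same operations are available programmatically
(`virodiscover.fit_trend`, `stability_curve`, `snapshot_sweep`,
`simulate`, …) and through a thin CLI (`virodiscover --help`).

## Acceptance script

`scripts/acceptance.py` re-runs the pipeline from scratch on the synthetic
world — simulation, ingest/filter/dedup, order-level trend fits with period
classification, the all-species stability curve, and the snapshot-GLM
sweep — and writes its JSON result file:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `src/virodiscover/` — library: `ingest`, `series`, `trends`,
  `stability`, `snapshot`, `simulate`, `cli`
- `analysis/` — numbered narrative drivers writing to `results/`
- `tests/` — unit, property and end-to-end behavioural tests
- `docs/methods.md` — models, assumptions, numerical choices, limitations
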