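# mtshazard

Chemical health-hazard ranking and scoring with the
Mahalanobis–Taguchi System (MTS).

Regulators and occupational-health practitioners face thousands of
chemicals with heterogeneous Globally Harmonized System (GHS) hazard
classifications and need a defensible way to pick the high-priority ones.
Most chemical ranking and scoring (CRS) schemes either use only the single
most severe endpoint or add endpoint scores as if they were independent —
under- or over-counting hazards that are correlated (oral and dermal acute
toxicity, skin and eye irritation, ...). `mtshazard` ranks chemicals by a
multivariate anomaly score that uses all ten health endpoints *and* their
correlation structure.

## Method

1. **Quantification.** Each GHS category is mapped to points:
   Category *n* → 100/*n* (so Category 1 = 100, ..., Category 5 = 20),
   Not Classified = 10, Classification Not Possible = 30 (a data gap is
   not evidence of safety, so it sits near Category 3), Not Applicable = 1.
   The three acute-inhalation routes (gas / vapor / dust-and-mist) are
   merged into their most conservative value first, leaving ten variables.
2. **Unit space.** A reference group of relatively low-hazard chemicals is
   selected: no Category 1 or 2 on any endpoint and a total score ≤ 280
   points. Its per-variable means *m*, standard deviations *s* and
   correlation matrix *R* define the Mahalanobis space.
3. **Scoring.** Every chemical gets a scaled Mahalanobis distance

   MD = zᵀ R⁻¹ z / k,   z_i = (x_i − m_i)/s_i,

   over the k usable variables. Small MD = similar to the low-hazard
   group; large MD = anomalous, i.e. hazardous. The mean MD over the unit
   space members is exactly (n−1)/n.
4. **Grading.** MDs are cut into k = 4 ordered grades by equal-interval,
   quantile, Jenks natural-breaks (exact dynamic program) or
   geometric-interval classification.
5. **Comparison & validation.** Pearson correlation and Cohen's kappa
   (unweighted / linear / quadratic) against external CRS scores such as
   EURAM or CHEMS (ingested as opaque numeric columns), and true/false
   positive proportions against a regulatory chemical list.

A latent-Gaussian synthetic-data generator (`mtshazard.synthetic_data`)
produces GHS tables with controllable inter-endpoint correlation, data-gap
rates and planted high-hazard chemicals, so the whole pipeline is testable
without any external dataset.

## Worked example

```python
from mtshazard import (SimulationConfig, generate, quantify, quantify_all,
                       select_normal_group, fit_reference, score_all,
                       classify, fixture_flutolanil, top_n)

# The canonical low-hazard worked example: nine Not Classified (10 points
# each) plus one Classification Not Possible (30 points) -> 120 points,
# inside the normal-group criteria.
quantify(fixture_flutolanil()).total        # 120.0

cfg = SimulationConfig(n_chemicals=1000, n_planted_hazards=5, seed=42)
records, truth = generate(cfg)
scores = quantify_all(records)
members = select_normal_group(scores, records)   # 737 low-hazard chemicals
by = {s.cas: s for s in scores}
ref = fit_reference([by[c] for c in members])
results = score_all(scores, ref)
for r in top_n(results, 5):
    print(r.rank, r.cas, round(r.md, 2))
```

prints the five planted hazards at the top of the ranking:

```
1 800997-17-7 87.15
2 800995-15-5 65.78
3 800999-19-9 63.24
4 800998-18-8 52.77
5 800996-16-6 51.3
```

Grading the MDs with Jenks natural breaks (`classify(..., "jenks", 4)`)
puts 881 / 114 / 4 / 1 chemicals in grades 1–4 with breaks at
(8.46, 51.30, 87.15): almost everything resembles the low-hazard
reference, and the top grades isolate the planted hazards. The mean MD
over the 737 unit-space members is 0.99864 = (737−1)/737, the exact MTS
identity.

The same pipeline is available from the shell:

```bash
mtshazard simulate --n 3000 --seed 42 --out ghs.csv
mtshazard quantify --input ghs.csv --out scores.csv
mtshazard unit-space --input ghs.csv --out ref.json
mtshazard score --input ghs.csv --reference ref.json --out md.csv
mtshazard grade --scores md.csv --method jenks --k 4 --out grades.csv
mtshazard run --config pipeline.yaml     # everything, with a manifest
```

## Layout

| Module | Contents |
| --- | --- |
| `mtshazard.ghs_io` | category model, CSV/JSON I/O, inhalation merge, quantification |
| `mtshazard.mts_core` | normal-group selection, unit-space fit, scaled MD, ranking |
| `mtshazard.grading` | the four class-interval methods (exact Fisher–Jenks DP) |
| `mtshazard.agreement` | Pearson, weighted kappa, regulatory validation, group CIs |
| `mtshazard.synthetic_data` | latent-Gaussian GHS table generator, literature-profile fixtures |
| `mtshazard.cli` | `mtshazard` command with per-stage subcommands and `run` |

See `docs/methods.md` for the modeling assumptions, parameter defaults and
known limitations.
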