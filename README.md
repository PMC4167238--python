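# schoolcontacts

Analysis tools for high-resolution face-to-face contact networks measured
with wearable proximity sensors in school settings, in the SocioPatterns
"tij" format: one record per 20-second window in which a pair of badges was
in face-to-face range.  The package targets the questions such deployments
raise for social science and epidemic modelling: how strongly does the
class structure shape mixing, is there gender homophily once the population
imbalance is controlled for, how stable are individual contact patterns
from day to day and from year to year, and how coarse a population
representation still suffices to model epidemic spread.

## What it computes

* **Contact events and aggregated networks.**  Records at 20-s resolution
  are merged into contact events (a >20-s silence interrupts a contact);
  over any window this yields a weighted graph with edge weight
  w_ij = cumulative contact seconds, event count n_ij, node degree k_i and
  strength s_i = Σ_j w_ij, together with duration/degree/weight
  distributions and their squared coefficients of variation (CV²), plus a
  discrete power-law tail fit (MLE with KS-minimizing x_min).
* **Contact matrices.**  Class×class (and class×gender) mixing matrices in
  six modes: total durations T_XY, total contacts N_XY, per-capita variants
  τ_XY = 2T_XX/n_X on the diagonal and T_XY/n_X off it (likewise n̄_XY),
  edge counts E_XY and edge densities ρ_XY = E_XY/E_max.  Matrices are
  compared with the entrywise cosine similarity (1 iff proportional, 0 iff
  disjoint support), with an off-diagonal-only scope as a robustness check.
* **Gender homophily.**  Per-node same-gender preference index h_i,
  gendered edge shares, weight-threshold robustness, and a matched
  Erdős–Rényi null ensemble (same N, E, gender labels; edges uniform).
* **Longitudinal stability.**  Activity time series, cumulative growth
  curves of contact time and distinct partners, and the per-node
  neighborhood cosine similarity σ_i between two windows,
  σ_i = Σ_j w_ij¹w_ij² / √(Σ_j (w_ij¹)² Σ_j (w_ij²)²),
  benchmarked against six null models (uniform edge placement, class-pair
  edge placement, Maslov–Sneppen degree-preserving rewiring globally or per
  class pair, and weight shuffling globally or per class pair).
* **SI spreading.**  A susceptible–infected process on the temporal stream
  (per-record Bernoulli transmission, synchronous 20-s slots) and on
  class-level / class×gender-level mixing surrogates, to test which
  population resolution reproduces the spread.
* **Synthetic school generator.**  Multi-day streams emulating a five-class
  deployment (sizes 31/35/38/35/41 with the published gender counts),
  ~91.5% intra-class contacts with a two-group class substructure,
  heavy-tailed durations and inter-event gaps, a break/lunch activity
  profile, and a persistence parameter π controlling day-to-day
  neighborhood stability.  Everything downstream is testable without the
  original data.

## Worked example

```python
import schoolcontacts as sc

ds = sc.generate(sc.SchoolConfig(), seed=42)       # 7 synthetic school days
net = sc.aggregate(ds.stream, ds.roster)           # whole-study network
print(len(ds.stream), len(sc.records_to_events(ds.stream)))
print(sc.graph_statistics(net))
print(sc.contact_matrix(net, "rho").data.round(3))

days = [sc.aggregate(ds.stream, ds.roster, window=w) for w in sc.day_windows(7)]
print(sc.pooled_daypair_similarities(days)["sigma"].mean())

ens = sc.er_null_ensemble(133, 47, 2220, n_real=1000, seed=42)
print(100 * ens.mean("mm"), 100 * ens.mean("ff"), 100 * ens.mean("male_pref"))
```

prints (seed 42):

```
16634 9076
{'n_nodes': 180, 'n_edges': 1574, 'density': 0.098, 'clustering': 0.258,
 'transitivity': 0.252, 'avg_shortest_path': 2.315}
       MP*1   MP*2     PC    PC*   PSI*
MP*1  0.417  0.053  0.013  0.010  0.010
MP*2  0.053  0.383  0.008  0.008  0.015
PC    0.013  0.008  0.398  0.043  0.050
PC*   0.010  0.008  0.043  0.378  0.043
PSI*  0.010  0.015  0.050  0.043  0.379
0.370
54.6 6.7 73.8
```

The edge-density matrix shows the strong class assortativity (dense
diagonal, a faint two-group substructure linking {MP\*1, MP\*2} and
{PC, PC\*, PSI\*}); the mean day-pair neighborhood cosine of 0.37 says a
student keeps a substantial but partial share of their partners from one
day to the next; and the null ensemble gives the gender edge shares and
male preference index expected from the 133/47 gender imbalance alone —
the baseline against which empirical homophily must be judged.

A command-line interface mirrors the library:

```bash
schoolcontacts generate --seed 1 --days 7 --out data/year_a
schoolcontacts analyze --tij data/year_a/contacts.tij --roster data/year_a/roster.tsv --out out/
schoolcontacts compare-years --a data/year_a --b data/year_b --classes "PC,PC*,PSI*"
```

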