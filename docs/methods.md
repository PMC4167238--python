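# Methods

This note records the models, conventions and numerical choices behind the
package, in the order the analysis runs.

## Contact streams and events

The unit of observation is a 20-second proximity record `(t, i, j)`: the
badges of i and j exchanged radio packets during the 20-s window indexed by
t.  A *contact event* is a maximal run of records for a pair at gaps of at
most 20 s; the first silent window interrupts the contact.  Conventions:

* A single isolated record is a contact of duration 20 s; an event spanning
  records t_first..t_last has duration t_last − t_first + 20.  Total event
  duration per pair is therefore exactly 20 s × its record count, an
  invariant the tests assert on every generated stream.
* Pairs are stored canonically with i < j lexicographically; node ids are
  opaque strings.
* Windowing assigns *records* (not events) to half-open windows
  [start, end), so an event spanning a window boundary is split at slot
  granularity and per-window duration totals stay additive.  Records
  outside all windows are dropped and counted.
* Timestamps are study-relative seconds; days are [d·86400, (d+1)·86400)
  and the morning/afternoon cut defaults to 13:00 (configurable).

## Aggregated networks and statistics

Over a window, nodes are *all* roster individuals (contact-free students
remain as isolates), edges carry weight w_ij (cumulative seconds) and count
n_ij (events).  Conventions where a choice was open:

* Density uses the full roster N: 2E/(N(N−1)).
* Clustering is the mean local clustering over nodes of degree ≥ 2
  (degree-0/1 nodes have no triangle fraction; they are excluded rather
  than counted as 0).  Transitivity is reported alongside, since summary
  statistics of this kind are ambiguous between the two readings.
* Average shortest path length is computed on the largest connected
  component with unweighted edges.
* Inter-contact gaps are computed per node within a single day, after
  merging the node's overlapping contact intervals into busy periods
  (simultaneous contacts with two partners are one busy period, not a
  negative gap).  Overnight gaps are excluded: out-of-school contacts were
  never observable, so cross-day gaps would measure the school schedule,
  not behavior.
* The power-law tail fit is a discrete maximum-likelihood estimate,
  α̂ = 1 + n/Σ ln(x/(x_min−½)), with x_min chosen to minimize the KS
  distance between the empirical tail and the Hurwitz-zeta model CDF, and
  a minimum tail size of 50.  The KS distance is returned so poor fits
  (e.g. geometric data) are visible.

## Contact matrices

Six modes over groups (classes, or class×gender): totals T_XY and N_XY
(symmetric, diagonal counts each intra-group pair once), edge counts E_XY
and densities ρ_XY = E_XY/E_max with E_max = n_X n_Y off-diagonal and
n_X(n_X−1)/2 on it, and per-capita τ_XY and n̄_XY.  The per-capita diagonal
uses τ_XX = 2T_XX/n_X: a contact between two members of X contributes its
full duration to *each* participant's personal tally.  An optional divisor
yields average-daily variants.  Entries with zero capacity (groups of size
≤ 1 on the diagonal) are reported as missing (NaN) in density and
per-capita modes rather than as 0.

Matrix similarity is the plain cosine over entry vectors — the only
standard choice that is 1 exactly for proportional matrices and 0 exactly
for disjoint supports.  The diagonal is included by default; the
off-diagonal scope is the robustness variant that removes the dominant
diagonal.  An all-zero matrix in scope raises rather than returning a
conventional value.

## Gender homophily

The same-gender preference index h_i is edge-based (unweighted), matching
its definition as a fraction of edges; a weighted variant would conflate
partner choice with contact duration.  Zero-degree nodes are excluded with
their count reported (no 0/0 convention).  Weight thresholds are inclusive
(≥) on the 20-s grid.

The null ensemble places E edges uniformly among the C(N,2) pairs with the
empirical gender labels fixed.  Closed forms under this null — M–M edge
share C(n_M,2)/C(N,2), male preference (n_M−1)/(N−1) — serve as
law-of-large-numbers checks on the simulated ensemble; Monte-Carlo standard
errors accompany every ensemble mean.

## Day-to-day stability and null models

The per-node neighborhood cosine σ_i between two windows uses the weighted
neighbor vectors; scoped variants zero out-of-scope neighbors *before*
normalization (restriction, not post-hoc masking).  Nodes with zero scoped
strength in either window are excluded and counted, so distribution sizes
are auditable: pooled per-class counts equal (day pairs) × (members with
defined σ).

Six randomization schemes benchmark the observed similarities.  All carry
each edge's (weight, count) attributes together, so the weight multiset is
conserved globally — and per class pair for the class-pair variants; the
rewiring schemes additionally conserve every node's degree (within each
class-pair subgraph for the pair variant).  Numerical choices: double-edge
swaps target 10 successful swaps per edge with proposals rejected if they
would create a self-loop or multi-edge (attempts capped at 20× the
target); subgraphs with fewer than 2 edges are left unchanged and logged;
in the random-placement schemes the weight multiset is carried onto the
new edges in random order so the weighted cosine remains comparable.
Realizations default to 1,000, configurable downward.

## SI spreading and population representations

The temporal SI process scans records in time order with synchronous
20-s-slot updates: each record between an infected and a susceptible
transmits with probability β, and a node infected in slot t transmits only
in later slots.  At β = 1 the infected set therefore equals reachability
by paths with strictly increasing record times, which an independent
forward-scan oracle verifies in the tests.  Seeding is uniform over nodes
unless fixed; nights are contact-free gaps.

The mixing surrogates run discrete-time SI over group compartments with
per-step infection probability 1 − exp(−β Σ_Y c_XY I_Y/n_Y), where c_XY is
the per-capita contact-event rate per 20-s step estimated from the stream
(the n̄ matrix divided by the number of in-school slots, so the time axes
are comparable).  The comparison across representations (temporal,
class-level, class×gender-level) reports mean prevalence curves with 5–95%
Monte-Carlo bands, time-to-half-prevalence and final sizes at matched β;
with gender-blind mixing the two compartmental resolutions are
statistically indistinguishable, and a homophily effect in the data
separates them.

## The synthetic generator

The generator produces the study conditions every downstream stage is
tested against.  Per day, each pair is *active* with probability
proportional to its mixing-tier weight (same class / same class-group /
cross-group, defaults 1 : 0.04 : 0.010487, solved so the implied
intra-class contact share is 91.5% for the default five-class roster);
active pairs draw 1 + Poisson events, durations iid from a bounded
discrete power law on the 20-s grid (exponent 2.5, cap 1 h — giving a mean
event duration near 40 s and CV² well above 1), with first starts sampled
from the activity profile (break and lunch peaks) and subsequent within-day
gaps from a bounded power law with exponent 1.8.  The empirical
inter-contact tail is only known qualitatively ("broad, exponent below
2"), so 1.8 is an explicit assumption, configurable.

Two mechanisms give day-to-day structure:

* **Pair persistence π** (default 0.75): each day a pair keeps its previous
  activity state with probability π and is re-drawn at its stationary rate
  otherwise.  This is exactly stationary in the marginals, reduces to
  independent days at π = 0 and a frozen contact set at π = 1, and is
  monotone in the day-pair neighborhood cosine.  Cross-class pairs use
  π × 0.3, making intra-class neighborhoods the more stable ones.  The
  default was calibrated once so the all-scope day-pair cosine lands
  mid-way in the 0.3–0.45 band reported for such deployments (~0.37).
* **Static pair affinity** (lognormal, mean 1, shape 0.75): a stable
  relationship intensity multiplying each active pair's event count.  This
  induces day-to-day *weight* correlation on persistent edges — without
  it, weight-shuffling null models would be statistically indistinguishable
  from the data, and the observed ordering (empirical > weight shuffles >
  degree-preserving rewiring > uniform placement) could not emerge.
  Durations stay iid, so the configured duration marginal is unaffected.

Remaining defaults: 650 expected active pairs per day and 2 expected
events per active pair give ~9,000 events per 7-day week — the same order
as, though below, a real deployment's ~20,000, keeping the default test
suite fast while leaving every statistic well-resolved; gender-blind mixing
by default (a homophily knob exists for power studies); an optional
exam-afternoon rate reduction, off by default.

What the generator does *not* emulate: spatial structure inside the school,
individual-level activity heterogeneity beyond pair affinity, correlations
between a pair's duration draws, or calendar effects beyond the optional
exam afternoon.  Passing tests therefore demonstrate correctness of the
analysis machinery under realistic marginals and persistence structure, not
fidelity of the generator to any particular real school.

## Problem sizes used in tests

The default test dataset is one 7-day generated week (~16,000 records);
marginal-recovery checks use a 14-day stream (~20,000 events); null-model
benchmarks in tests use 5–30 realizations on 3-day datasets, and the
ensemble checks against published null values use the full 1,000
realizations (seconds of runtime).  The acceptance script runs only the
1,000-realization ensemble.
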