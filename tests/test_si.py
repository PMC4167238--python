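"""SI spreading: temporal dynamics, mixing surrogates, representation tests."""

from dataclasses import replace
from itertools import product

import numpy as np
import pandas as pd
import pytest

import schoolcontacts as sc
from schoolcontacts.si import contact_rate_matrix

from conftest import make_roster, make_stream


def time_respecting_reachable(stream, source):
    """Independent oracle: nodes reachable via records with strictly
    increasing times, by forward scanning (equivalent to BFS in time)."""
    reached = {source: -np.inf}
    for t, i, j in stream[["t", "i", "j"]].itertuples(index=False):
        if i in reached and reached[i] < t and j not in reached:
            reached[j] = t
        elif j in reached and reached[j] < t and i not in reached:
            reached[i] = t
    return set(reached)


@pytest.fixture
def chain_roster():
    return make_roster([("a", "X", "M"), ("b", "X", "F"), ("c", "Y", "M")])


class TestTemporalSI:
    def test_beta_zero_only_seed(self, chain_roster):
        stream = make_stream([(0, "a", "b"), (20, "b", "c")])
        cfg = sc.SIConfig(beta=0.0, n_runs=5, seed=1, seed_node="a")
        traj = sc.run_si_temporal(stream, chain_roster, cfg)
        assert (traj.final_sizes() == 1).all()

    def test_temporal_path_respected(self, chain_roster):
        cfg = sc.SIConfig(beta=1.0, n_runs=1, seed=1, seed_node="a")
        forward = make_stream([(0, "a", "b"), (20, "b", "c")])
        traj = sc.run_si_temporal(forward, chain_roster, cfg)
        assert traj.final_sizes()[0] == 3
        backward = make_stream([(0, "b", "c"), (20, "a", "b")])
        traj = sc.run_si_temporal(backward, chain_roster, cfg)
        times = traj.infection_times[0]
        assert np.isnan(times["c"]) and times["b"] == 20

    def test_same_slot_no_relay(self, chain_roster):
        # both records in the same 20-s slot: infection cannot hop twice
        stream = make_stream([(0, "a", "b"), (0, "b", "c")])
        cfg = sc.SIConfig(beta=1.0, n_runs=1, seed=0, seed_node="a")
        traj = sc.run_si_temporal(stream, chain_roster, cfg)
        assert traj.final_sizes()[0] == 2

    def test_empty_stream_trivial(self, chain_roster):
        stream = make_stream([(0, "a", "b")]).iloc[:0]
        cfg = sc.SIConfig(beta=1.0, n_runs=3, seed=0)
        traj = sc.run_si_temporal(stream, chain_roster, cfg)
        assert (traj.final_sizes() == 1).all()

    def test_beta_one_equals_reachability_oracle(self, default_dataset):
        """Deterministic SI at beta = 1 infects exactly the set reachable by
        time-respecting paths, for several seed nodes."""
        ds = default_dataset
        stream = ds.stream[ds.stream["t"] < 86400].reset_index(drop=True)
        for seed_node in ds.roster.index[[0, 50, 120]]:
            cfg = sc.SIConfig(beta=1.0, n_runs=1, seed=0, seed_node=seed_node)
            traj = sc.run_si_temporal(stream, ds.roster, cfg)
            infected = set(traj.infection_times.index[traj.infection_times[0].notna()])
            assert infected == time_respecting_reachable(stream, seed_node)

    def test_final_size_matches_exhaustive_enumeration(self, chain_roster):
        """3-node toy stream at beta = 0.1: the final-size distribution from
        Monte Carlo matches exact enumeration over per-record outcomes."""
        records = [(0, "a", "b"), (20, "a", "b"), (40, "b", "c"), (60, "a", "c")]
        stream = make_stream(records)
        beta = 0.1
        # exact enumeration: each record transmits iff a Bernoulli(beta)
        # fires and its earlier endpoint was infected strictly before its slot
        size_prob = {1: 0.0, 2: 0.0, 3: 0.0}
        for outcome in product([True, False], repeat=len(records)):
            p = 1.0
            for fired in outcome:
                p *= beta if fired else 1 - beta
            t_inf = {"a": -np.inf}
            for (t, i, j), fired in zip(records, outcome):
                if not fired:
                    continue
                if t_inf.get(i, np.inf) < t and t < t_inf.get(j, np.inf):
                    t_inf[j] = t
                elif t_inf.get(j, np.inf) < t and t < t_inf.get(i, np.inf):
                    t_inf[i] = t
            size_prob[len(t_inf)] += p
        cfg = sc.SIConfig(beta=beta, n_runs=40_000, seed=8, seed_node="a")
        traj = sc.run_si_temporal(stream, chain_roster, cfg)
        sizes = traj.final_sizes()
        for size, prob in size_prob.items():
            mc = (sizes == size).mean()
            se = np.sqrt(prob * (1 - prob) / len(sizes))
            assert abs(mc - prob) < 4 * se + 1e-12, size

    def test_prevalence_monotone(self, default_dataset):
        ds = default_dataset
        stream = ds.stream[ds.stream["t"] < 86400].reset_index(drop=True)
        cfg = sc.SIConfig(beta=0.05, n_runs=10, seed=2)
        traj = sc.run_si_temporal(stream, ds.roster, cfg)
        prev = traj.prevalence(np.arange(0, 86400, 3600))
        assert (np.diff(prev["mean"]) >= 0).all()
        assert prev["mean"].iloc[-1] <= 1.0


class TestMixingSI:
    def test_zero_rates_no_spread(self):
        rates = pd.DataFrame([[0.0]], index=["X"], columns=["X"])
        cfg = sc.SIConfig(beta=1.0, n_runs=5, seed=0)
        traj = sc.run_si_mixing(rates, {"X": 10}, cfg, n_steps=100, seed_group="X")
        assert (traj.final_sizes() == 1).all()

    def test_disconnected_groups(self):
        rates = pd.DataFrame([[5.0, 0.0], [0.0, 5.0]], index=["X", "Y"], columns=["X", "Y"])
        cfg = sc.SIConfig(beta=1.0, n_runs=5, seed=1)
        traj = sc.run_si_mixing(rates, {"X": 5, "Y": 5}, cfg, n_steps=50, seed_group="X")
        by_group = traj.infection_times.notna().groupby(traj.groups).sum()
        assert (by_group.loc["Y"] == 0).all()
        assert (by_group.loc["X"] == 5).all()

    def test_rate_matrix_from_stream(self, default_dataset):
        rates, sizes, n_slots = contact_rate_matrix(default_dataset.stream, default_dataset.roster)
        assert list(rates.index) == sorted(sizes)
        assert n_slots > 0
        # total expected events recovered: sum_X n_X * sum_Y c_XY * slots
        # double-counts intra-class events once per participant
        n_events = len(sc.records_to_events(default_dataset.stream))
        total = 0.0
        for x in rates.index:
            total += sizes[x] * rates.loc[x].sum()
        assert total * n_slots == pytest.approx(2 * n_events, rel=1e-6)

    def test_class_vs_class_gender_equivalent_when_gender_blind(self, default_dataset):
        """On gender-blind data the class-level and class x gender surrogates
        produce statistically indistinguishable prevalence curves."""
        ds = default_dataset
        stream = ds.stream[ds.stream["t"] < 2 * 86400].reset_index(drop=True)
        grid = np.linspace(0, 2 * 86400, 25)
        curves = {}
        for by_gender, name in ((False, "class"), (True, "class_gender")):
            rates, sizes, n_slots = contact_rate_matrix(stream, ds.roster, by_gender=by_gender)
            cfg = sc.SIConfig(beta=0.4, n_runs=150, seed=5)
            traj = sc.run_si_mixing(rates, sizes, cfg, n_steps=n_slots)
            # mixing surrogate time axis: in-school slots; rescale to grid
            frac = traj.prevalence(np.linspace(0, n_slots * 20, 25))
            curves[name] = frac
        a, b = curves["class"], curves["class_gender"]
        # the two mean curves stay within each other's 5-95% MC bands
        inside = ((a["mean"] >= b["q05"]) & (a["mean"] <= b["q95"])).mean()
        assert inside > 0.9

    def test_gender_homophily_separates_representations(self):
        """With a strong homophily knob the class x gender surrogate deviates
        from the class-level one."""
        cfg = replace(sc.SchoolConfig(), n_days=2, gender_homophily=0.9)
        ds = sc.generate(cfg, seed=17)
        rates_c, sizes_c, n_slots = contact_rate_matrix(ds.stream, ds.roster, by_gender=False)
        rates_g, sizes_g, _ = contact_rate_matrix(ds.stream, ds.roster, by_gender=True)
        si_cfg = sc.SIConfig(beta=0.4, n_runs=150, seed=5)
        # seed in a female sub-group: spread differs when mixing is homophilous
        pc_f = sc.run_si_mixing(rates_g, sizes_g, si_cfg, n_steps=n_slots, seed_group="PC/F")
        pc = sc.run_si_mixing(rates_c, sizes_c, si_cfg, n_steps=n_slots, seed_group="PC")
        fa = pc_f.final_sizes() / pc_f.n_nodes
        fb = pc.final_sizes() / pc.n_nodes
        se = np.sqrt(fa.var(ddof=1) / len(fa) + fb.var(ddof=1) / len(fb))
        assert abs(fa.mean() - fb.mean()) > 3 * se


class TestCompareRepresentations:
    def test_beta_zero_all_flat(self, default_dataset):
        ds = default_dataset
        stream = ds.stream[ds.stream["t"] < 86400].reset_index(drop=True)
        cfg = sc.SIConfig(beta=0.0, n_runs=5, seed=0)
        table = sc.compare_representations(stream, ds.roster, cfg)
        assert set(table["representation"]) == {
            "temporal",
            "class_mixing",
            "class_gender_mixing",
        }
        for name, summary in table.attrs["summaries"].items():
            assert summary["final_size_mean"] == 1.0, name

    def test_output_contract(self, default_dataset):
        ds = default_dataset
        stream = ds.stream[ds.stream["t"] < 86400].reset_index(drop=True)
        cfg = sc.SIConfig(beta=0.01, n_runs=5, seed=1)
        table = sc.compare_representations(stream, ds.roster, cfg)
        assert {"t", "mean", "q05", "q95", "representation"} <= set(table.columns)
        assert (table["q05"] <= table["q95"]).all()
        for summary in table.attrs["summaries"].values():
            assert 1.0 <= summary["final_size_mean"] <= summary["n_nodes"]
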