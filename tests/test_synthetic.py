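"""The synthetic school generator: determinism, marginals, persistence."""

from dataclasses import replace
from math import comb

import numpy as np
import pandas as pd
import pytest

import schoolcontacts as sc
from schoolcontacts.stream_io import ConfigurationError


class TestConfig:
    def test_default_roster_matches_study_composition(self):
        roster = sc.build_roster(sc.SchoolConfig().classes)
        sizes = roster.groupby("class").size()
        assert sizes.tolist() == [31, 35, 38, 35, 41]
        assert (roster["gender"] == "M").sum() == 133
        assert (roster["gender"] == "F").sum() == 47

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            sc.SchoolConfig(persistence=1.5)
        with pytest.raises(ConfigurationError):
            sc.SchoolConfig(w_same=-1.0)
        with pytest.raises(ConfigurationError):
            sc.SchoolConfig(classes=(("X", 0, 0),))

    def test_yaml_roundtrip(self, tmp_path):
        cfg = replace(sc.SchoolConfig(), n_days=3, persistence=0.5)
        cfg.to_yaml(tmp_path / "cfg.yaml")
        assert sc.SchoolConfig.from_yaml(tmp_path / "cfg.yaml") == cfg

    def test_zero_total_rate_rejected(self):
        cfg = sc.SchoolConfig(w_same=0.0, w_group=0.0, w_cross=0.0)
        with pytest.raises(ConfigurationError):
            sc.generate(cfg, seed=1)


class TestImpliedIntraclassFraction:
    def test_cross_weight_zero(self):
        cfg = sc.SchoolConfig(
            classes=(("A", 1, 1), ("B", 1, 1)), class_groups=(("A",), ("B",)),
            w_group=0.0, w_cross=0.0,
        )
        assert sc.implied_intraclass_fraction(cfg) == 1.0

    def test_equal_weights_symmetry(self):
        n = 5
        cfg = sc.SchoolConfig(
            classes=(("A", n, 0), ("B", n, 0)), class_groups=(("A", "B"),),
            w_same=1.0, w_group=1.0, w_cross=1.0,
        )
        expected = 2 * comb(n, 2) / comb(2 * n, 2)
        assert sc.implied_intraclass_fraction(cfg) == pytest.approx(expected)

    def test_default_config_targets_intraclass_share(self):
        assert sc.implied_intraclass_fraction(sc.SchoolConfig()) == pytest.approx(
            0.915, abs=0.0005
        )

    def test_calibrate_cross_weight(self):
        cfg = sc.calibrate_cross_weight(sc.SchoolConfig(w_cross=1.0), 0.9)
        assert sc.implied_intraclass_fraction(cfg) == pytest.approx(0.9, abs=1e-9)


class TestGenerate:
    def test_seed_determinism(self):
        cfg = replace(sc.SchoolConfig(), n_days=2)
        a = sc.generate(cfg, seed=5)
        b = sc.generate(cfg, seed=5)
        pd.testing.assert_frame_equal(a.stream, b.stream)
        c = sc.generate(cfg, seed=6)
        assert not a.stream.equals(c.stream)

    def test_stream_is_valid_and_within_school_hours(self, default_dataset):
        ds = default_dataset
        sc.stream_io.validate_stream(ds.stream)  # no duplicates, on-grid, canonical
        day_t = ds.stream["t"] % 86400
        assert (day_t >= ds.config.school_start).all()
        assert (day_t < ds.config.school_end).all()

    def test_all_intraclass_when_cross_weights_zero(self):
        cfg = replace(sc.SchoolConfig(), n_days=2, w_group=0.0, w_cross=0.0)
        ds = sc.generate(cfg, seed=2)
        cls = ds.roster["class"]
        assert (cls.loc[ds.stream["i"]].to_numpy() == cls.loc[ds.stream["j"]].to_numpy()).all()

    def test_full_persistence_keeps_neighborhoods(self):
        """pi = 1 re-activates the same pairs every day; with the duration
        randomness removed, every active node's day-pair cosine is 1."""
        cfg = replace(
            sc.SchoolConfig(),
            n_days=2,
            persistence=1.0,
            cross_class_persistence_factor=1.0,
            duration_cap_slots=1,  # all durations 20 s
            mean_events_per_pair=1.0,
            intercontact_cap_slots=1,
        )
        ds = sc.generate(cfg, seed=3)
        nets = [sc.aggregate(ds.stream, ds.roster, window=w) for w in sc.day_windows(2)]
        sim = sc.neighborhood_similarity(nets[0], nets[1])
        assert len(sim) > 0
        assert np.allclose(sim["sigma"], 1.0)

    def test_intraclass_share_matches_implied_expectation(self):
        """Measured intra-class contact share within +/-2 pp of the
        pair-type expectation at >= 10,000 contacts."""
        cfg = replace(sc.SchoolConfig(), n_days=14)
        ds = sc.generate(cfg, seed=11)
        events = sc.records_to_events(ds.stream)
        assert len(events) >= 10_000
        cls = ds.roster["class"]
        same = cls.loc[events["i"]].to_numpy() == cls.loc[events["j"]].to_numpy()
        implied = sc.implied_intraclass_fraction(cfg)
        assert same.mean() == pytest.approx(implied, abs=0.02)

    def test_duration_marginal_matches_configured_law(self):
        """KS distance between generated durations (in slots) and the
        configured bounded discrete power law, at n ~ 10^4."""
        cfg = replace(sc.SchoolConfig(), n_days=14)
        ds = sc.generate(cfg, seed=13)
        slots = (sc.records_to_events(ds.stream)["duration"] // 20).to_numpy()
        assert slots.size >= 10_000
        k = np.arange(1, cfg.duration_cap_slots + 1)
        pmf = k ** -cfg.duration_exponent
        pmf = pmf / pmf.sum()
        model_cdf = np.cumsum(pmf)
        emp_cdf = np.searchsorted(np.sort(slots), k, side="right") / slots.size
        ks = np.max(np.abs(emp_cdf - model_cdf))
        assert ks < 0.02

    def test_persistence_monotonically_increases_similarity(self):
        """Mean day-pair neighborhood cosine similarity increases with pi
        (averaged over a fixed seed set at each grid point)."""
        means = []
        for pi in (0.0, 0.4, 0.8):
            vals = []
            for seed in (1, 2, 3):
                cfg = replace(sc.SchoolConfig(), n_days=4, persistence=pi)
                ds = sc.generate(cfg, seed=seed)
                nets = [
                    sc.aggregate(ds.stream, ds.roster, window=w) for w in sc.day_windows(4)
                ]
                vals.append(sc.pooled_daypair_similarities(nets)["sigma"].mean())
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_default_similarity_in_study_band(self, default_dataset, day_networks):
        """Default persistence produces day-to-day neighborhood similarities
        in the 0.3-0.45 band reported for real school deployments."""
        mean = sc.pooled_daypair_similarities(day_networks)["sigma"].mean()
        assert 0.3 <= mean <= 0.45

    def test_lunch_peak_in_activity_profile(self, default_dataset):
        """The hourly activity maximum falls in a configured peak window."""
        day1 = default_dataset.stream[default_dataset.stream["t"] < 86400]
        series = sc.activity_series(day1, 3600)
        peak_hour = series.idxmax() // 3600
        assert peak_hour in (10, 12, 13, 15)  # break or lunch hours

    def test_exam_afternoon_quieter(self):
        cfg = replace(sc.SchoolConfig(), n_days=3, exam_day=1)
        ds = sc.generate(cfg, seed=9)
        t = ds.stream["t"]
        day = t // 86400
        afternoon = (t % 86400) >= 13 * 3600
        exam_pm = ((day == 1) & afternoon).sum()
        other_pm = ((day == 0) & afternoon).sum()
        assert exam_pm < 0.5 * other_pm

    def test_gender_homophily_knob(self):
        cfg = replace(sc.SchoolConfig(), n_days=3, gender_homophily=0.6)
        ds = sc.generate(cfg, seed=4)
        net = sc.aggregate(ds.stream, ds.roster)
        pref = sc.same_gender_preference(net)
        base = sc.generate(replace(cfg, gender_homophily=0.0), seed=4)
        pref0 = sc.same_gender_preference(sc.aggregate(base.stream, base.roster))
        assert pref.mean("M") > pref0.mean("M")
        assert pref.mean("F") > pref0.mean("F")
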