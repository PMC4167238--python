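import pandas as pd
import pytest

import schoolcontacts as sc


def make_stream(records):
    """Build a validated stream from (t, i, j) tuples."""
    df = pd.DataFrame(records, columns=["t", "i", "j"])
    df["i"] = df["i"].astype(str)
    df["j"] = df["j"].astype(str)
    return sc.stream_io.validate_stream(df)


def make_roster(entries):
    """Build a roster from (id, class, gender) tuples."""
    df = pd.DataFrame(entries, columns=["id", "class", "gender"])
    return df.set_index("id")


@pytest.fixture
def tiny_roster():
    return make_roster(
        [
            ("a", "X", "M"),
            ("b", "X", "M"),
            ("c", "X", "F"),
            ("d", "Y", "F"),
            ("e", "Y", "M"),
        ]
    )


@pytest.fixture(scope="session")
def default_dataset():
    """Default synthetic dataset: the emulated study conditions, fixed seed."""
    return sc.generate(sc.SchoolConfig(), seed=7)


@pytest.fixture(scope="session")
def day_networks(default_dataset):
    ds = default_dataset
    return [
        sc.aggregate(ds.stream, ds.roster, window=w)
        for w in sc.day_windows(ds.config.n_days)
    ]


@pytest.fixture(scope="session")
def whole_network(default_dataset):
    return sc.aggregate(default_dataset.stream, default_dataset.roster)
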