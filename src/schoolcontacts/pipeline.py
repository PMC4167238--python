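"""End-to-end orchestration: full single-dataset analysis and year comparison.

``run_full_analysis`` drives every stage over one dataset (read from tij +
roster files or generated synthetically) and writes CSV/JSON artifacts with
a manifest recording the provenance (module, window, scheme, seed) of each.
``compare_years`` contrasts two datasets on their shared classes through
the cosine similarity of the duration (T), contact-count (N) and
edge-density (rho) contact matrices.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import homophily, longitudinal, nulls, si, stream_io, synthetic
from .matrices import MODES, contact_matrix, gender_block_matrix, matrix_similarity
from .network import (
    AggregatedNetwork,
    aggregate,
    contact_duration_distribution,
    degree_distribution,
    graph_statistics,
    inter_contact_distribution,
    weight_distribution,
)
from .stream_io import DAY_SECONDS, ConfigurationError, day_windows

logger = logging.getLogger("schoolcontacts")


@dataclass
class RunConfig:
    """One input source (files or synthetic), plus stage settings."""

    tij_path: str | None = None
    roster_path: str | None = None
    synthetic_config: synthetic.SchoolConfig | None = None
    n_days: int | None = None  # inferred from the stream when None
    null_schemes: Sequence[str] = nulls.SCHEMES
    null_realizations: int = 100
    weight_thresholds: Sequence[int] = (120, 300)  # 2 and 5 minutes
    si_config: si.SIConfig | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        from_files = self.tij_path is not None and self.roster_path is not None
        if from_files == (self.synthetic_config is not None):
            raise ConfigurationError(
                "exactly one input source required: (tij_path, roster_path) or synthetic_config"
            )

    def load(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        if self.synthetic_config is not None:
            ds = synthetic.generate(self.synthetic_config, seed=self.seed)
            return ds.stream, ds.roster
        stream = stream_io.read_tij(self.tij_path)
        roster = stream_io.read_roster(self.roster_path)
        stream_io.check_roster_covers(stream, roster)
        return stream, roster


class _Manifest:
    def __init__(self, out_dir: Path):
        self.out_dir = out_dir
        self.entries: list[dict] = []

    def add(self, name: str, module: str, **provenance) -> Path:
        path = self.out_dir / name
        self.entries.append({"artifact": name, "module": module, **provenance})
        return path

    def write(self, config_info: dict) -> None:
        payload = {"config": config_info, "artifacts": self.entries}
        (self.out_dir / "manifest.json").write_text(json.dumps(payload, indent=2, default=str))


def run_full_analysis(config: RunConfig, out_dir: str | Path) -> Path:
    """Run every analysis stage and write artifacts + manifest to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out)
    stream, roster = config.load()

    n_days = config.n_days
    if n_days is None:
        n_days = int(stream["t"].max() // DAY_SECONDS) + 1 if len(stream) else 1
    windows = {"whole": None, **{w.label: w for w in day_windows(n_days)}}

    # aggregated networks and per-window matrices (all six modes)
    networks: dict[str, AggregatedNetwork] = {}
    for label, window in windows.items():
        net = aggregate(stream, roster, window=window)
        networks[label] = net
        stream_io.write_edge_list(
            net, manifest.add(f"network_{label}.tsv", "aggregate_network", window=label)
        )
        for mode in MODES:
            m = contact_matrix(net, mode=mode, n_days=n_days if label == "whole" else None)
            stream_io.write_matrix_csv(
                m,
                manifest.add(
                    f"matrix_{label}_{mode}.csv", "contact_matrices", window=label, mode=mode
                ),
            )
    whole = networks["whole"]
    day_nets = [networks[w.label] for w in day_windows(n_days)]

    # global statistics and distributions
    stats = graph_statistics(whole)
    stats["n_contacts"] = int(sum(d["count"] for _, _, d in whole.graph.edges(data=True)))
    stats["total_duration_s"] = whole.total_weight()
    dur = contact_duration_distribution(stream)
    inter = inter_contact_distribution(stream)
    stats["contact_duration_mean"] = dur.mean
    stats["contact_duration_cv2"] = dur.cv2
    stats["intercontact_cv2"] = inter.cv2
    if whole.n_edges:
        stats["weight_cv2"] = weight_distribution(whole).cv2
        stats["degree_cv2"] = degree_distribution(whole).cv2
    manifest.add("global_statistics.json", "aggregate_network", window="whole")
    (out / "global_statistics.json").write_text(json.dumps(stats, indent=2))
    for summary, name in ((dur, "contact_durations"), (inter, "inter_contact_durations")):
        summary.survival().to_csv(
            manifest.add(f"dist_{name}.csv", "aggregate_network", window="whole"), index=False
        )

    # activity series and growth curves
    for wlen, name in ((3600, "hourly"), (600, "10min")):
        longitudinal.activity_series(stream, wlen).to_csv(
            manifest.add(f"activity_{name}.csv", "longitudinal", window="whole")
        )
    longitudinal.growth_curves(stream, roster).to_csv(
        manifest.add("growth_curves.csv", "longitudinal", window="whole")
    )

    # gender homophily
    gender = gender_block_matrix(whole, mode="rho")
    stream_io.write_matrix_csv(
        gender, manifest.add("matrix_whole_gender_rho.csv", "contact_matrices", mode="rho")
    )
    pref = homophily.same_gender_preference(whole)
    pref.summary().to_csv(
        manifest.add("gender_preference_summary.csv", "gender_homophily"), index=False
    )
    frac = homophily.gender_edge_fractions(whole)
    roster_counts = roster["gender"].value_counts()
    ens = homophily.er_null_ensemble(
        int(roster_counts.get("M", 0)),
        int(roster_counts.get("F", 0)),
        whole.n_edges,
        n_real=config.null_realizations,
        seed=config.seed,
    )
    hom = {
        "edge_fractions": {"mm": frac.mm, "ff": frac.ff, "mf": frac.mf},
        "er_null": json.loads(ens.summary().to_json(orient="records")),
        "n_zero_degree": pref.n_zero_degree,
    }
    for thr in config.weight_thresholds:
        tf = homophily.gender_edge_fractions(homophily.threshold_network(whole, thr))
        hom[f"edge_fractions_min_{thr}s"] = {"mm": tf.mm, "ff": tf.ff, "mf": tf.mf}
    manifest.add("gender_homophily.json", "gender_homophily", seed=config.seed)
    (out / "gender_homophily.json").write_text(json.dumps(hom, indent=2))

    # longitudinal similarity + null benchmark
    if len(day_nets) >= 2:
        longitudinal.daypair_similarity_summary(day_nets).to_csv(
            manifest.add("daypair_similarity_by_class.csv", "longitudinal"), index=False
        )
        bench = nulls.benchmark_all_schemes(
            day_nets,
            n_real=config.null_realizations,
            seed=config.seed,
            schemes=config.null_schemes,
        )
        bench.to_csv(
            manifest.add(
                "null_similarity_benchmark.csv",
                "null_models",
                seed=config.seed,
                n_real=config.null_realizations,
            ),
            index=False,
        )
    else:
        logger.info("skipping day-pair similarity: fewer than 2 days")
        manifest.entries.append({"artifact": None, "module": "longitudinal", "skipped": "single day"})

    # SI comparison (optional)
    if config.si_config is not None:
        cmp = si.compare_representations(stream, roster, config.si_config)
        cmp.to_csv(
            manifest.add("si_representations.csv", "si_spread", seed=config.si_config.seed),
            index=False,
        )
        (out / "si_summaries.json").write_text(json.dumps(cmp.attrs["summaries"], indent=2))
        manifest.add("si_summaries.json", "si_spread", seed=config.si_config.seed)

    manifest.write(
        {
            "seed": config.seed,
            "n_days": n_days,
            "source": "synthetic" if config.synthetic_config else config.tij_path,
        }
    )
    return out


# ---------------------------------------------------------------------------
# year comparison
# ---------------------------------------------------------------------------


@dataclass
class YearComparisonReport:
    shared_classes: list[str]
    similarities: dict[str, float]  # mode -> cosine similarity
    stats_a: dict
    stats_b: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(m, v) for m, v in self.similarities.items()], columns=["mode", "similarity"]
        )


def _restrict_to_classes(
    stream: pd.DataFrame, roster: pd.DataFrame, classes: Sequence[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    keep = roster[roster["class"].isin(classes)]
    ids = set(keep.index)
    mask = stream["i"].isin(ids) & stream["j"].isin(ids)
    return stream[mask].reset_index(drop=True), keep


def compare_years(
    dataset_a: tuple[pd.DataFrame, pd.DataFrame],
    dataset_b: tuple[pd.DataFrame, pd.DataFrame],
    shared_classes: Sequence[str] | None = None,
    modes: Sequence[str] = ("T", "N", "rho"),
) -> YearComparisonReport:
    """Cross-dataset contact-matrix similarity over the class intersection.

    Each dataset is a (stream, roster) pair.  Matrices are computed on the
    streams restricted to the shared classes, then compared entrywise with
    the cosine similarity for each requested mode.
    """
    (stream_a, roster_a), (stream_b, roster_b) = dataset_a, dataset_b
    if shared_classes is None:
        shared_classes = sorted(
            set(roster_a["class"].unique()) & set(roster_b["class"].unique())
        )
    shared_classes = list(shared_classes)
    if not shared_classes:
        raise ConfigurationError("no shared classes between the two datasets")
    sims: dict[str, float] = {}
    nets = []
    for stream, roster in ((stream_a, roster_a), (stream_b, roster_b)):
        sub_stream, sub_roster = _restrict_to_classes(stream, roster, shared_classes)
        nets.append(aggregate(sub_stream, sub_roster))
    for mode in modes:
        ma = contact_matrix(nets[0], mode=mode).restrict(shared_classes)
        mb = contact_matrix(nets[1], mode=mode).restrict(shared_classes)
        sims[mode] = matrix_similarity(ma, mb)
    return YearComparisonReport(
        shared_classes=shared_classes,
        similarities=sims,
        stats_a=graph_statistics(nets[0]),
        stats_b=graph_statistics(nets[1]),
    )
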