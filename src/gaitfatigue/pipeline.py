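"""End-to-end orchestration: simulate, segment, featurize, label, classify.

A run executes the two-phase workflow on one cohort.  Phase 1 segments
every bout into gait cycles, builds the normalized 43-feature matrix, and
compares the six classifiers under the configured partition protocol.
Phase 2 takes the best model by F1, ranks features by random-forest
importance, and evaluates the feature-reduction and sensor-ablation grids.
All stage outputs are written as CSV/JSON under the run directory and
indexed by a manifest; a fixed master seed makes the whole run, including
the written files, reproducible bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .features import (FEATURE_NAMES, assemble_dataset, class_distribution,
                       normalize_dataset)
from .io import write_json
from .models import (ModelSpec, PartitionSpec, compare_models, rank_features,
                     reduce_and_eval, sensor_ablation, train_eval)
from .preprocess import FilterSpec, segment_bout
from .synthetic import SimulationConfig, simulate_cohort

__all__ = ["RunConfig", "RunManifest", "run_end_to_end", "segment_cohort",
           "build_feature_matrix"]


@dataclass
class RunConfig:
    """Everything needed to reproduce a full run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    filter: FilterSpec = field(default_factory=FilterSpec)
    partition: PartitionSpec = field(default_factory=PartitionSpec)
    models: tuple[str, ...] = ("RF", "ANN", "SVM", "DT", "KNN", "LR")
    k_list: tuple[int, ...] = (25, 16, 13, 11, 8)
    subsets: tuple[str, ...] = ("all", "l5s1+foot", "l5s1", "foot")
    normalize: bool = True
    outdir: str = "runs/run0"
    seed: int = 0

    def __post_init__(self) -> None:
        # the master seed fans out to simulation and partitioning
        self.simulation = dataclasses.replace(self.simulation, seed=self.seed)
        self.partition = dataclasses.replace(self.partition, seed=self.seed)

    def to_dict(self) -> dict:
        return {
            "simulation": self.simulation.to_dict(),
            "filter": dataclasses.asdict(self.filter),
            "partition": dataclasses.asdict(self.partition),
            "models": list(self.models),
            "k_list": list(self.k_list),
            "subsets": list(self.subsets),
            "normalize": self.normalize,
            "outdir": self.outdir,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "simulation" in d:
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        if "filter" in d:
            d["filter"] = FilterSpec(**d["filter"])
        if "partition" in d:
            d["partition"] = PartitionSpec(**d["partition"])
        for key in ("models", "k_list", "subsets"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path: Path | str) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") \
            else json.loads(text)
        return cls.from_dict(data or {})

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance record of a completed run."""

    config_hash: str
    version: str
    outputs: dict[str, str] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def segment_cohort(ds, filter_spec: FilterSpec | None = None):
    """Segment every bout of a cohort.

    Yields (participant, bout, filtered recording, windows) and collects
    event/window tables as a side product via the returned generator's
    ``.tables`` attribute — use :func:`build_feature_matrix` for the
    common case.
    """
    for pid, bout, rec in ds.bouts():
        events, windows, filtered = segment_bout(rec, filter_spec)
        yield pid, bout, filtered, events, windows


def build_feature_matrix(ds, filter_spec: FilterSpec | None = None,
                         normalize: bool = True):
    """Segment, featurize and (optionally) baseline-normalize a cohort.

    Returns (feature matrix, events table, windows table, references).
    """
    segmented = []
    event_rows = []
    window_rows = []
    for pid, bout, filtered, events, windows in segment_cohort(ds, filter_spec):
        segmented.append((pid, bout, filtered, windows))
        for t in events.times:
            event_rows.append({"participant": pid, "bout": bout,
                               "time_s": float(t)})
        for w in windows:
            window_rows.append({"participant": pid, "bout": bout,
                                "cycle": w.cycle, "start_s": w.start_s,
                                "end_s": w.end_s})
    matrix = assemble_dataset(segmented, ds.labels)
    refs = None
    if normalize:
        matrix, refs = normalize_dataset(matrix)
    return (matrix, pd.DataFrame(event_rows), pd.DataFrame(window_rows), refs)


def run_end_to_end(config: RunConfig) -> RunManifest:
    """Execute the full two-phase pipeline and write all artefacts."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config.hash(), version=__version__)

    def _save_df(df: pd.DataFrame, name: str) -> None:
        df.to_csv(outdir / name, index=False)
        manifest.outputs[name.removesuffix(".csv")] = name

    write_json(config.to_dict(), outdir / "config.json")
    manifest.outputs["config"] = "config.json"

    # stage 1: simulation
    ds = simulate_cohort(config.simulation)
    _save_df(ds.labels, "labels.csv")
    manifest.counts["participants"] = config.simulation.n_participants
    manifest.counts["bouts"] = (config.simulation.n_participants
                                * config.simulation.bouts_per_participant)

    # stage 2-3: segmentation + features + normalization
    try:
        matrix, events, windows, _ = build_feature_matrix(
            ds, config.filter, normalize=config.normalize)
    except Exception as exc:
        raise RuntimeError(f"stage segmentation/features failed: {exc}") from exc
    _save_df(events, "events.csv")
    _save_df(windows, "windows.csv")
    _save_df(matrix, "features.csv")
    _save_df(class_distribution(matrix).reset_index(
        names="fatigue_class"), "class_distribution.csv")
    manifest.counts["heel_strikes"] = len(events)
    manifest.counts["cycles"] = len(matrix)

    # stage 4: model comparison
    y = matrix["fatigue_class"].to_numpy()
    if len(pd.unique(y)) < 2:
        msg = "single fatigue class present; skipping model training"
        warnings.warn(msg)
        manifest.warnings.append(msg)
        write_json(manifest.to_dict(), outdir / "manifest.json")
        return manifest
    X = matrix[list(FEATURE_NAMES)].to_numpy()
    specs = [ModelSpec(alg, seed=config.seed) for alg in config.models]
    try:
        table, results = compare_models(specs, X, y, config.partition)
    except Exception as exc:
        raise RuntimeError(f"stage model comparison failed: {exc}") from exc
    _save_df(table, "model_comparison.csv")
    write_json({alg: {"metrics": rep.to_dict(), "confusion": cm.tolist()}
                for alg, (rep, cm, _) in results.items()},
               outdir / "model_reports.json")
    manifest.outputs["model_reports"] = "model_reports.json"

    # stage 5 (phase 2): importance ranking on RF, reduction + ablation on
    # the best model by F1
    best_alg = table.iloc[0]["model"]
    best_spec = ModelSpec(best_alg, seed=config.seed)
    if "RF" in results:
        rf_model = results["RF"][2]
    else:
        _, _, rf_model = train_eval(ModelSpec("RF", seed=config.seed),
                                    X, y, config.partition)
    try:
        ranking = rank_features(rf_model)
        _save_df(pd.DataFrame({
            "feature_index": ranking.order,
            "feature": list(ranking.names),
            "importance": ranking.importances,
            "cumulative": ranking.cumulative,
        }), "importance.csv")
        k_list = tuple(k for k in config.k_list if k <= X.shape[1])
        reduction, _ = reduce_and_eval(X, y, ranking, config.partition,
                                       spec=best_spec, k_list=k_list)
        reduction.insert(0, "model", best_alg)
        _save_df(reduction, "reduction.csv")
        subsets = {name: sites for name, sites in
                   dict(all=("foot", "l5s1", "emg"), **{
                       "l5s1+foot": ("foot", "l5s1"),
                       "l5s1": ("l5s1",), "foot": ("foot",)}).items()
                   if name in config.subsets}
        ablation, _ = sensor_ablation(X, y, config.partition, spec=best_spec,
                                      subsets=subsets)
        ablation.insert(0, "model", best_alg)
        _save_df(ablation, "ablation.csv")
    except Exception as exc:
        raise RuntimeError(f"stage feature/sensor reduction failed: {exc}") from exc

    write_json(manifest.to_dict(), outdir / "manifest.json")
    return manifest
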