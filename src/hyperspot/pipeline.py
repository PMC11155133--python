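"""End-to-end orchestration: data -> preprocess -> hypergraph -> train -> segment
-> evaluate -> markers, with a reproducibility manifest.

A run is configured by a nested dict (usually loaded from YAML)::

    input:            # omit to generate synthetic data instead
      path: data_dir
      format: csv     # csv | mtx_dir | h5ad
      label_key: layer        # h5ad only
    synthetic:        # overrides for the synthetic generator
      n_spots: 800
    train:            # TrainConfig overrides
      gamma: 1.0
    n_clusters: 4
    assigner: leiden  # leiden | dec
    seed: 0
    output_dir: runs/demo

Every stochastic stage draws its seed deterministically from the master seed
plus the stage name, so a re-run with the same config and seed reproduces the
label file and loss traces.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import Partition, dec_partition, leiden_with_target_k
from .datasets import SpatialExpressionDataset, load_dataset
from .exceptions import ConfigError
from .hypergraph import build_hypergraph
from .markers import rank_marker_genes
from .metrics import evaluate_partition
from .model import init_params
from .preprocess import preprocess
from .synthetic import SyntheticSpec, generate
from .training import TrainConfig, fit, pretrain
from .utils import stage_seed

__all__ = ["RunManifest", "RunResult", "run_pipeline", "load_config"]


@dataclass
class RunManifest:
    """Reproducibility record written at the end of a run."""

    config: dict
    seed: int
    version: str
    input_checksums: dict[str, str]
    timings: dict[str, float]
    outputs: dict[str, str]
    ablation: dict[str, float]
    complete: bool = True

    def write(self, path: Path) -> None:
        tmp = path.with_suffix(".tmp")
        tmp.write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))
        tmp.replace(path)  # atomic on POSIX


@dataclass
class RunResult:
    """In-memory outputs of a pipeline run."""

    manifest: RunManifest
    dataset: SpatialExpressionDataset
    embedding: np.ndarray
    partition: Partition
    metrics: dict
    loss_trace: pd.DataFrame
    markers: object = None
    cluster_state: object = None


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ConfigError(f"config {path} did not parse to a mapping")
    return cfg


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _get_dataset(config: dict, seed: int) -> tuple[SpatialExpressionDataset, dict[str, str]]:
    if "input" in config and config["input"]:
        inp = dict(config["input"])
        path = Path(inp["path"])
        ds = load_dataset(path, format=inp.get("format", "csv"), label_key=inp.get("label_key"))
        sums = {}
        if path.is_file():
            sums[str(path)] = _checksum(path)
        else:
            for f in sorted(path.iterdir()):
                if f.is_file():
                    sums[str(f)] = _checksum(f)
        return ds, sums
    syn = dict(config.get("synthetic", {}))
    syn.setdefault("seed", stage_seed(seed, "synthetic"))
    spec = SyntheticSpec(**syn)
    return generate(spec), {"synthetic_spec": json.dumps(dataclasses.asdict(spec))}


def run_pipeline(
    config: dict | str | Path,
    output_dir: str | Path | None = None,
    seed: int | None = None,
) -> RunResult:
    """Execute the full pipeline and write all artifacts to ``output_dir``."""
    if not isinstance(config, dict):
        config = load_config(config)
    config = dict(config)
    if seed is not None:
        config["seed"] = int(seed)
    master_seed = int(config.get("seed", 0))
    out = Path(output_dir or config.get("output_dir", "hyperspot_run"))
    out.mkdir(parents=True, exist_ok=True)

    train_overrides = dict(config.get("train", {}))
    tc = TrainConfig(seed=master_seed, **train_overrides)
    assigner = config.get("assigner", "leiden")
    if assigner not in ("leiden", "dec"):
        raise ConfigError(f"unknown assigner {assigner!r}")

    timings: dict[str, float] = {}

    def _timed(name):
        class _T:
            def __enter__(self_):
                self_.t0 = time.perf_counter()

            def __exit__(self_, *exc):
                timings[name] = round(time.perf_counter() - self_.t0, 3)

        return _T()

    with _timed("data"):
        ds_raw, checksums = _get_dataset(config, master_seed)
    with _timed("preprocess"):
        ds, feats = preprocess(
            ds_raw,
            min_spots=tc.min_spots,
            n_components=tc.pca_components,
            seed=stage_seed(master_seed, "pca"),
        )
    with _timed("hypergraph"):
        _, A = build_hypergraph(ds.S, k=tc.k)
    with _timed("pretrain"):
        params = init_params(
            feats.n_features,
            hidden_f=tc.hidden_f,
            d_f=tc.d_f,
            hidden_g=tc.hidden_g,
            d_g=tc.d_g,
            seed=stage_seed(master_seed, "init"),
        )
        pre_trace = pretrain(params, feats.values, A, ds.S, tc)
    with _timed("fit"):
        emb, state, fit_trace = fit(params, feats.values, A, ds.S, tc)
    with _timed("segment"):
        n_clusters = int(config.get("n_clusters", tc.n_centroids))
        if assigner == "leiden":
            part = leiden_with_target_k(
                emb.H, n_clusters, seed=stage_seed(master_seed, "leiden"), k=tc.k
            )
        else:
            part = dec_partition(state.Q)
    with _timed("evaluate"):
        report = evaluate_partition(part, ds.S, G=ds.labels, k=tc.k)
    with _timed("markers"):
        markers = rank_marker_genes(ds, part, top_n=int(config.get("top_n_markers", 200)))

    # ---- artifacts -------------------------------------------------------
    emb_df = pd.DataFrame(
        emb.H, index=ds.spot_ids, columns=[f"dim_{i}" for i in range(emb.H.shape[1])]
    )
    emb_df.to_csv(out / "embedding.csv")
    pd.DataFrame(
        {"label": part.assignments}, index=ds.spot_ids
    ).to_csv(out / "labels.csv")
    trace = pd.concat(
        [pre_trace.to_frame().assign(stage="pretrain"), fit_trace.to_frame().assign(stage="fit")],
        ignore_index=True,
    )
    trace.to_csv(out / "loss_trace.csv", index=False)
    metrics = report.to_dict()
    metrics["n_clusters"] = part.n_clusters
    metrics["matched_target"] = bool(part.matched_target)
    (out / "metrics.json").write_text(json.dumps(metrics, indent=2))
    markers.to_frame().to_csv(out / "markers.tsv", sep="\t", index=False)
    (out / "config.yaml").write_text(yaml.safe_dump(config))

    manifest = RunManifest(
        config=config,
        seed=master_seed,
        version=__version__,
        input_checksums=checksums,
        timings=timings,
        outputs={
            name: str(out / name)
            for name in (
                "embedding.csv",
                "labels.csv",
                "loss_trace.csv",
                "metrics.json",
                "markers.tsv",
                "config.yaml",
            )
        },
        ablation={"lambda": tc.lam, "gamma": tc.gamma},
    )
    manifest.outputs["manifest.json"] = str(out / "manifest.json")
    manifest.write(out / "manifest.json")

    return RunResult(
        manifest=manifest,
        dataset=ds,
        embedding=emb.H,
        partition=part,
        metrics=metrics,
        loss_trace=trace,
        markers=markers,
        cluster_state=state,
    )
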