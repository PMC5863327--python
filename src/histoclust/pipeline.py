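"""Experiment orchestration: one run, the full grid, and parameter sweeps.

A run is load/generate -> optional per-image cluster quantization ->
stratified split -> build -> train -> (optional SVM head) -> evaluate,
with CSV/PNG/JSON artifacts and a manifest that reproduces the run
bit-for-bit.  The grid covers the three cluster arms (original image,
K-Means, Mean-Shift) x three models x two decision heads; sweeps vary the
cluster size K, the Mean-Shift bandwidth, or the (TS, ID) factorization.

One global seed fans out into deterministic per-stage seeds (data
generation, split, weight init, batching/dropout) so a single knob fixes
the whole run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .clustering import ClusterParams, quantize_dataset
from .data import (
    LabeledDataset,
    SyntheticParams,
    generate_synthetic_dataset,
    load_image_directory,
    stratified_split,
)
from .heads import (
    EpochHistory,
    SvmHead,
    TrainConfig,
    evaluate,
    fit_svm_head,
    train_hinge,
    train_softmax,
)
from .metrics import MetricReport
from .models import ModelSpec, build_model
from .layers import Network

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "stage_seeds",
    "run_experiment",
    "run_grid",
    "sweep",
    "TABLE3_TS_ID",
]

# the published (TS, ID) sweep configurations for the stacked-LSTM model
TABLE3_TS_ID = ((24, 128), (32, 96), (48, 64), (64, 48), (96, 32), (128, 24))

_STAGES = ("generate", "split", "init", "train", "cluster")


def stage_seeds(seed: int) -> dict[str, int]:
    """Fan one global seed out into independent per-stage seeds (< 2^31)."""
    state = np.random.SeedSequence(seed).generate_state(len(_STAGES))
    return {name: int(s % (2**31)) for name, s in zip(_STAGES, state)}


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything one experiment needs; exactly one data source."""

    synthetic: SyntheticParams | None = None
    data_dir: str | None = None
    layout: str = "flat"
    magnification: str | None = None
    cluster: ClusterParams | None = None  # None = original-image (OI) arm
    model: ModelSpec = ModelSpec(model_id=1)
    train: TrainConfig = TrainConfig(epochs=50)
    test_fraction: float = 0.30
    end_to_end_hinge: bool = False
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.data_dir is None):
            raise ValueError("exactly one of synthetic params or data_dir is required")

    def to_jsonable(self) -> dict:
        def convert(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (tuple, list)):
                return [convert(v) for v in obj]
            if isinstance(obj, (np.integer, np.floating)):
                return obj.item()
            return obj

        return convert(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_jsonable(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    report: MetricReport
    history: EpochHistory
    net: Network
    head: object  # "softmax" or SvmHead
    train_report: MetricReport
    artifacts: dict[str, Path]


def _load_data(cfg: ExperimentConfig, seeds: dict[str, int]) -> LabeledDataset:
    if cfg.synthetic is not None:
        params = replace(cfg.synthetic, seed=seeds["generate"])
        return generate_synthetic_dataset(params)
    return load_image_directory(cfg.data_dir, layout=cfg.layout,
                                magnification=cfg.magnification)


def _versions() -> dict[str, str]:
    import sklearn

    from . import __version__

    return {"histoclust": __version__, "numpy": np.__version__,
            "sklearn": sklearn.__version__}


def run_experiment(cfg: ExperimentConfig) -> ExperimentResult:
    """Execute one configured experiment end to end."""
    seeds = stage_seeds(cfg.seed)
    artifacts: dict[str, Path] = {}
    t0 = time.perf_counter()

    ds = _load_data(cfg, seeds)
    logger.info("stage=data n=%d malignant=%d benign=%d",
                len(ds), ds.n_malignant, ds.n_benign)

    if cfg.cluster is not None:
        tc = time.perf_counter()
        cl = replace(cfg.cluster, seed=seeds["cluster"])
        ds = LabeledDataset(quantize_dataset(ds.images, cl), ds.labels,
                            ds.magnification_tag)
        logger.info("stage=cluster method=%s elapsed=%.1fs",
                    cl.method, time.perf_counter() - tc)

    train_ds, test_ds = stratified_split(ds, cfg.test_fraction, seed=seeds["split"])
    logger.info("stage=split train=%d test=%d", len(train_ds), len(test_ds))

    spec = replace(cfg.model, seed=seeds["init"])
    net = build_model(spec)
    train_cfg = replace(cfg.train, seed=seeds["train"])

    tt = time.perf_counter()
    if cfg.end_to_end_hinge and spec.decision == "svm":
        net, history = train_hinge(net, train_ds, test_ds, train_cfg)
        head: object = "softmax"  # margin sign == argmax of the two scores
    else:
        net, history = train_softmax(net, train_ds, test_ds, train_cfg)
        head = "softmax"
    if spec.decision == "svm" and not cfg.end_to_end_hinge:
        head = fit_svm_head(net, train_ds, c=train_cfg.svm_c)
    logger.info("stage=train epochs=%d elapsed=%.1fs",
                train_cfg.epochs, time.perf_counter() - tt)

    _, train_report = evaluate(net, train_ds, head=head)
    _, test_report = evaluate(net, test_ds, head=head)
    logger.info("stage=evaluate test_acc=%.2f%% mcc=%.3f",
                test_report.accuracy_pct, test_report.mcc)

    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        h = cfg.config_hash()
        if len(history):
            artifacts["history"] = history.to_csv(out / f"history_{h}.csv")
            artifacts["curves"] = history.plot(out / f"curves_{h}.png")
        metrics_path = out / f"metrics_{h}.csv"
        _write_metrics_rows([_result_row(cfg, test_report)], metrics_path)
        artifacts["metrics"] = metrics_path
        weights = out / f"weights_{h}.npz"
        net.save_weights(weights)
        artifacts["weights"] = weights
        manifest = {
            "config": cfg.to_jsonable(),
            "config_hash": h,
            "seed": cfg.seed,
            "stage_seeds": seeds,
            "versions": _versions(),
            "elapsed_s": round(time.perf_counter() - t0, 2),
        }
        mpath = out / f"manifest_{h}.json"
        mpath.write_text(json.dumps(manifest, indent=2))
        artifacts["manifest"] = mpath

    return ExperimentResult(cfg, test_report, history, net, head,
                            train_report, artifacts)


def _result_row(cfg: ExperimentConfig, rep: MetricReport) -> dict:
    cluster = "oi" if cfg.cluster is None else cfg.cluster.method
    row = {
        "dataset": (cfg.magnification or "synthetic"),
        "cluster": cluster,
        "model": cfg.model.model_id,
        "decision": cfg.model.decision,
        "config_hash": cfg.config_hash(),
    }
    row.update({k: round(v, 4) for k, v in rep.as_dict().items()})
    return row


def _write_metrics_rows(rows: list[dict], path: Path) -> Path:
    import pandas as pd

    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def run_grid(base: ExperimentConfig, models=(1, 2, 3), ts: int = 64, id_dim: int = 48,
             ts3: int = 32, id3: int = 16):
    """The full experimental grid: {OI, KM, MS} x models x {softmax, svm}.

    The dataset is loaded once and quantized once per cluster arm; each
    (arm, model) pair is trained once under softmax and evaluated under
    both decision heads, yielding 2 rows per training and
    6 x len(models) rows in total.  Returns a pandas DataFrame.
    """
    import pandas as pd

    seeds = stage_seeds(base.seed)
    raw = _load_data(base, seeds)
    arms = [None,
            ClusterParams(method="km", k=8),
            ClusterParams(method="ms", bandwidth=0.2)]
    rows = []
    for cluster in arms:
        if cluster is None:
            ds = raw
        else:
            cl = replace(cluster, seed=seeds["cluster"])
            ds = LabeledDataset(quantize_dataset(raw.images, cl), raw.labels,
                                raw.magnification_tag)
        train_ds, test_ds = stratified_split(ds, base.test_fraction,
                                             seed=seeds["split"])
        for model_id in models:
            spec = ModelSpec(
                model_id=model_id,
                ts=None if model_id == 1 else (ts if model_id == 2 else ts3),
                id_dim=None if model_id == 1 else (id_dim if model_id == 2 else id3),
                decision="softmax",
                seed=seeds["init"],
            )
            cfg = replace(base, cluster=cluster, model=spec, out_dir=None)
            net = build_model(spec)
            net, _ = train_softmax(net, train_ds, test_ds,
                                   replace(base.train, seed=seeds["train"]))
            _, rep = evaluate(net, test_ds)
            rows.append(_result_row(cfg, rep))
            svm_cfg = replace(cfg, model=replace(spec, decision="svm"))
            head = fit_svm_head(net, train_ds, c=base.train.svm_c)
            _, svm_rep = evaluate(net, test_ds, head=head)
            rows.append(_result_row(svm_cfg, svm_rep))
    df = pd.DataFrame(rows)
    if base.out_dir is not None:
        out = Path(base.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "grid_metrics.csv", index=False)
    return df


def sweep(base: ExperimentConfig, axis: str, values=None):
    """Sweep one published axis: K in {8,16,24}, BW in {0.2,0.4,0.6},
    or the (TS, ID) factorizations of the stacked-LSTM model.

    Returns a DataFrame with one metric row per value; the ts_id axis also
    carries the trainable-parameter count per configuration.
    """
    import pandas as pd

    defaults = {"k": (8, 16, 24), "bw": (0.2, 0.4, 0.6), "ts_id": TABLE3_TS_ID}
    if axis not in defaults:
        raise ValueError(f"axis must be one of {sorted(defaults)}, got {axis!r}")
    values = tuple(values) if values is not None else defaults[axis]
    if not values:
        raise ValueError("sweep axis values must be non-empty")

    rows = []
    for value in values:
        if axis == "k":
            cfg = replace(base, cluster=ClusterParams(method="km", k=int(value)),
                          out_dir=None)
        elif axis == "bw":
            cfg = replace(base, cluster=ClusterParams(method="ms",
                                                      bandwidth=float(value)),
                          out_dir=None)
        else:
            ts, id_dim = value
            cfg = replace(base, model=replace(base.model, model_id=2,
                                              ts=int(ts), id_dim=int(id_dim)),
                          out_dir=None)
        res = run_experiment(cfg)
        row = _result_row(cfg, res.report)
        row["axis"] = axis
        row["value"] = str(value)
        if axis == "ts_id":
            row["parameters"] = res.net.count_parameters()
        rows.append(row)
    df = pd.DataFrame(rows)
    if base.out_dir is not None:
        out = Path(base.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / f"sweep_{axis}.csv", index=False)
    return df
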