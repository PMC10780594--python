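"""End-to-end orchestration: data -> clean -> segment -> encode -> train
-> evaluate, from one config.

The pipeline splits at the *recording* level before any fitted artifact is
built: codebooks see only training-side sub-sequences, feature scalers and
classifiers only training-side rows.  Every run records its parameters,
seeds and per-stage wall times, and is reproducible from (config, seed)
for the classical encoders (the deep encoders are reproducible within
floating-point accumulation order).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import codebook as cb_mod
from . import deep as deep_mod
from .classify import (
    EvalReport, LabeledDataset, SplitSpec, check_no_leakage, holdout_split,
    make_report, train_linear_svm, train_random_forest,
)
from .features import feature_frame
from .recordings import DatasetManifest, Recording, channel_names, load_dataset
from .synthetic import GeneratorConfig, generate_dataset
from .windowing import segment_subsequences, segment_windows, subsequence_matrix

logger = logging.getLogger(__name__)

ENCODERS = ("handcrafted", "codebook_llc", "cnn", "lstm")
CLASSIFIERS = ("svm", "rf", "none")


@dataclass
class PipelineConfig:
    """One experiment: data source, encoder, classifier and split."""

    data: GeneratorConfig | str | Path          # generator config or manifest
    encoder: str = "handcrafted"
    classifier: str = "rf"
    split: SplitSpec = field(default_factory=SplitSpec)
    window_length: int = 128
    window_overlap: float = 0.5
    codebook_w: int = 64
    codebook_l: int = 8
    codebook_k: int = 32
    codebook_restarts: int = 10
    llc_knn: int = 5
    llc_lambda: float = 0.01
    pooling: str = "average"
    #: granularity of one LLC descriptor: "window" pools the sub-sequences
    #: inside each classification window (the windowing used everywhere
    #: else); "recording" pools a whole recording into one descriptor
    codebook_unit: str = "window"
    deep_epochs: int = 27
    lstm_segment_length: int = 200
    out_dir: str | Path | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.encoder not in ENCODERS:
            raise ValueError(f"unknown encoder {self.encoder!r}")
        if self.classifier not in CLASSIFIERS:
            raise ValueError(f"unknown classifier {self.classifier!r}")
        deep = self.encoder in ("cnn", "lstm")
        if deep and self.classifier != "none":
            raise ValueError(
                f"encoder {self.encoder!r} carries its own softmax head; "
                f"set classifier='none' (got {self.classifier!r})"
            )
        if not deep and self.classifier == "none":
            raise ValueError(f"encoder {self.encoder!r} needs a classifier")


@dataclass
class PipelineResult:
    report: EvalReport
    config: PipelineConfig
    timings: dict[str, float] = field(default_factory=dict)
    codebook_training_ids: list[str] = field(default_factory=list)
    artifacts: dict = field(default_factory=dict)
    history: object = None


def _load_recordings(cfg: PipelineConfig) -> list[Recording]:
    if isinstance(cfg.data, GeneratorConfig):
        recs, _ = generate_dataset(cfg.data)
        from .recordings import clean_recording
        return [clean_recording(r) for r in recs]
    manifest = DatasetManifest.load(cfg.data)
    recs, log = load_dataset(manifest, root=Path(cfg.data).parent)
    if log.rejections:
        logger.warning("%d recording(s) rejected during load", len(log.rejections))
    return recs


def _recording_split(recs: list[Recording], split: SplitSpec):
    """Stratified recording-level split; returns (train_recs, test_recs)."""
    ids = np.array([r.recording_id for r in recs])
    labels = np.array([r.label for r in recs])
    subjects = np.array([r.subject_id for r in recs])
    ds = LabeledDataset(
        X=np.zeros((len(recs), 1)), y=labels, subjects=subjects, groups=ids
    )
    tr, te = holdout_split(ds, split)
    check_no_leakage(ids, tr, te, "recording")
    return [recs[i] for i in tr], [recs[i] for i in te]


def _make_classifier(cfg: PipelineConfig):
    if cfg.classifier == "svm":
        return lambda X, y: train_linear_svm(X, y, seed=cfg.seed)
    return lambda X, y: train_random_forest(X, y, seed=cfg.seed)


def handcrafted_dataset(
    recs: list[Recording], w: int = 128, overlap: float = 0.5
) -> LabeledDataset:
    """Window every recording and extract fused handcrafted features."""
    windows = [win for r in recs for win in segment_windows(r, w, overlap)]
    names = channel_names(recs[0].schema)
    df = feature_frame(windows, names)
    X = df.drop(columns=["label", "subject"]).to_numpy()
    groups = np.array([w.source_index[0] for w in windows])
    return LabeledDataset(
        X=X, y=df["label"].to_numpy(), subjects=df["subject"].to_numpy(),
        groups=groups,
    )


def build_sensor_codebooks(
    train_recs: list[Recording], cfg: PipelineConfig
) -> list[cb_mod.Codebook]:
    """One codebook per sensor, trained only on the given recordings."""
    sensors = list(train_recs[0].schema.keys())
    books = []
    for si, sensor in enumerate(sensors):
        subseqs = [
            s for r in train_recs
            for s in segment_subsequences(r, sensor, cfg.codebook_w, cfg.codebook_l)
        ]
        books.append(
            cb_mod.build_codebook(
                subsequence_matrix(subseqs),
                k=cfg.codebook_k,
                n_restarts=cfg.codebook_restarts,
                seed=cfg.seed + si,
                sensor_name=sensor,
                w=cfg.codebook_w,
                l=cfg.codebook_l,
            )
        )
    return books


def codebook_dataset(
    recs: list[Recording], books: list[cb_mod.Codebook], cfg: PipelineConfig
) -> LabeledDataset:
    """Pooled LLC descriptors, one per recording or per window.

    ``cfg.codebook_unit == "recording"`` pools each whole recording into a
    single descriptor; ``"window"`` first cuts the usual classification
    windows and pools the sub-sequences within each, so the codebook
    pipeline classifies the same units as the handcrafted one.
    """
    if cfg.codebook_unit == "recording":
        descs = [
            cb_mod.encode_sequence(
                r, books, pooling=cfg.pooling, knn=cfg.llc_knn,
                lam=cfg.llc_lambda,
            )
            for r in recs
        ]
        return LabeledDataset(
            X=np.stack([d.values for d in descs]),
            y=np.array([d.label for d in descs]),
            subjects=np.array([d.subject_id for d in descs]),
            groups=np.array([d.recording_id for d in descs]),
        )
    X, y, subjects, groups = [], [], [], []
    for r in recs:
        names = r.channel_names
        sensor_cols = {
            b.sensor_name: [i for i, c in enumerate(names)
                            if c.startswith(b.sensor_name + "_")]
            for b in books
        }
        for win in segment_windows(r, cfg.window_length, cfg.window_overlap):
            parts = []
            for b in books:
                axes = win.samples[:, sensor_cols[b.sensor_name]]
                subs = np.stack([
                    np.concatenate([axes[s:s + b.w, 0], axes[s:s + b.w, 1],
                                    axes[s:s + b.w, 2]])
                    for s in range(0, win.samples.shape[0] - b.w + 1, b.l)
                ])
                codes = cb_mod.encode_subsequences(
                    subs, b, knn=cfg.llc_knn, lam=cfg.llc_lambda
                )
                if cfg.pooling == "average":
                    parts.append(codes.mean(axis=0))
                elif cfg.pooling == "sum":
                    parts.append(codes.sum(axis=0))
                else:
                    parts.append(codes.max(axis=0))
            X.append(np.concatenate(parts))
            y.append(win.label)
            subjects.append(win.subject_id)
            groups.append(win.source_index[0])
    return LabeledDataset(X=np.stack(X), y=np.array(y),
                          subjects=np.array(subjects), groups=np.array(groups))


def _deep_windows(recs, cfg: PipelineConfig):
    """Raw tensors + integer labels for the deep encoders.

    CNN: 50%-overlapped windows of the full channel matrix, shaped
    (N, T, C, 1).  LSTM: 50%-overlapped segments of the first sensor's
    three axes, shaped (N, T, 3).  Inputs are later standardized with
    training-side statistics.
    """
    classes = sorted({r.label for r in recs})
    cls_idx = {c: i for i, c in enumerate(classes)}
    X, y, groups = [], [], []
    if cfg.encoder == "cnn":
        for r in recs:
            for win in segment_windows(r, cfg.window_length,
                                       cfg.window_overlap):
                X.append(win.samples[:, :, None])
                y.append(cls_idx[win.label])
                groups.append(win.source_index[0])
    else:
        seg = cfg.lstm_segment_length
        sensor = next(iter(recs[0].schema))
        for r in recs:
            length = min(seg, r.n_samples)
            if length < seg:
                logger.warning(
                    "recording %s shorter than LSTM segment %d; using %d",
                    r.recording_id, seg, length,
                )
            axes = r.sensor(sensor)
            step = max(1, length // 2)
            for start in range(0, r.n_samples - length + 1, step):
                X.append(axes[start:start + length])
                y.append(cls_idx[r.label])
                groups.append(r.recording_id)
    return np.stack(X), np.array(y), np.array(groups), classes


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute the configured chain and return its evaluation report.

    Stage failures propagate with the stage name prefixed, and partial
    artifacts (when ``out_dir`` is set) are left on disk for debugging.
    """
    cfg.validate()
    timings: dict[str, float] = {}
    result_artifacts: dict = {}
    out_dir = Path(cfg.out_dir) if cfg.out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    def timed(stage: str):
        class _T:
            def __enter__(self_):
                self_.t0 = time.perf_counter()

            def __exit__(self_, exc_type, exc, tb):
                timings[stage] = time.perf_counter() - self_.t0
                if exc is not None:
                    logger.error("stage %r failed: %s", stage, exc)
        return _T()

    with timed("load"):
        recs = _load_recordings(cfg)
    with timed("split"):
        train_recs, test_recs = _recording_split(recs, cfg.split)
    train_ids = [r.recording_id for r in train_recs]

    cb_train_ids: list[str] = []
    if cfg.encoder == "handcrafted":
        with timed("encode"):
            ds_train = handcrafted_dataset(train_recs, cfg.window_length,
                                           cfg.window_overlap)
            ds_test = handcrafted_dataset(test_recs, cfg.window_length,
                                          cfg.window_overlap)
        with timed("train"):
            clf = _make_classifier(cfg)(ds_train.X, ds_train.y)
        with timed("evaluate"):
            pred = clf.predict(ds_test.X)
            report = make_report(ds_test.y, pred, np.unique(ds_train.y),
                                 len(ds_train.y), cfg.split)
        if out_dir is not None:
            feature_frame(
                [w for r in train_recs for w in segment_windows(
                    r, cfg.window_length, cfg.window_overlap)],
                channel_names(train_recs[0].schema),
            ).to_csv(out_dir / "features_train.csv", index=False)
    elif cfg.encoder == "codebook_llc":
        with timed("codebook"):
            books = build_sensor_codebooks(train_recs, cfg)
            cb_train_ids = train_ids
        with timed("encode"):
            ds_train = codebook_dataset(train_recs, books, cfg)
            ds_test = codebook_dataset(test_recs, books, cfg)
        with timed("train"):
            clf = _make_classifier(cfg)(ds_train.X, ds_train.y)
        with timed("evaluate"):
            pred = clf.predict(ds_test.X)
            report = make_report(ds_test.y, pred, np.unique(ds_train.y),
                                 len(ds_train.y), cfg.split)
        if out_dir is not None:
            for b in books:
                b.save(out_dir / f"codebook_{b.sensor_name}.txt")
        result_artifacts["codebooks"] = books
    else:                                           # cnn / lstm
        with timed("encode"):
            Xtr, ytr, gtr, classes = _deep_windows(train_recs, cfg)
            Xte, yte, _, _ = _deep_windows(test_recs, cfg)
            # per-channel standardization over all training windows and
            # time steps (training-side statistics only)
            mu = Xtr.mean(axis=(0, 1), keepdims=True)
            sd = Xtr.std(axis=(0, 1), keepdims=True)
            sd[sd == 0] = 1.0
            Xtr = (Xtr - mu) / sd
            Xte = (Xte - mu) / sd
        with timed("train"):
            if cfg.encoder == "cnn":
                model = deep_mod.build_cnn(deep_mod.CNNConfig(
                    input_shape=Xtr.shape[1:], n_classes=len(classes),
                    epochs=cfg.deep_epochs, seed=cfg.seed,
                ))
            else:
                model = deep_mod.build_lstm(deep_mod.LSTMConfig(
                    segment_time_size=Xtr.shape[1], n_features=Xtr.shape[2],
                    n_classes=len(classes), epochs=cfg.deep_epochs,
                    seed=cfg.seed,
                ))
            history = model_history = deep_mod.train_deep(
                model, Xtr, ytr, groups=gtr, seed=cfg.seed
            )
        with timed("evaluate"):
            pred_idx = deep_mod.predict_classes(model, Xte)
            classes_arr = np.array(classes)
            report = make_report(classes_arr[yte], classes_arr[pred_idx],
                                 classes_arr, len(ytr), cfg.split)
        result_artifacts["model"] = model
        result_artifacts["history"] = model_history

    if out_dir is not None:
        (out_dir / "report.json").write_text(json.dumps(report.to_dict(), indent=2))
        np.savetxt(out_dir / "confusion.csv", report.confusion,
                   fmt="%d", delimiter=",",
                   header=",".join(report.classes))
        run_log = {
            "encoder": cfg.encoder,
            "classifier": cfg.classifier,
            "seed": cfg.seed,
            "window_length": cfg.window_length,
            "window_overlap": cfg.window_overlap,
            "codebook": {"w": cfg.codebook_w, "l": cfg.codebook_l,
                         "k": cfg.codebook_k,
                         "n_restarts": cfg.codebook_restarts},
            "llc": {"knn": cfg.llc_knn, "lambda": cfg.llc_lambda,
                    "pooling": cfg.pooling},
            "split": asdict(cfg.split),
            "timings_s": timings,
            "n_train_recordings": len(train_recs),
            "n_test_recordings": len(test_recs),
        }
        (out_dir / "run_log.json").write_text(json.dumps(run_log, indent=2))

    return PipelineResult(
        report=report, config=cfg, timings=timings,
        codebook_training_ids=cb_train_ids, artifacts=result_artifacts,
        history=result_artifacts.get("history"),
    )


def compare_encoders(configs: list[PipelineConfig]) -> pd.DataFrame:
    """Run several pipelines on the same data/split and tabulate accuracy.

    All configs must share the same data source and split seed so the
    comparison is apples-to-apples.
    """
    if not configs:
        raise ValueError("no configs given")
    ref = configs[0]
    for c in configs[1:]:
        if repr(c.data) != repr(ref.data) or c.split.seed != ref.split.seed:
            raise ValueError("configs must share data source and split seed")
    rows = []
    for c in configs:
        res = run_pipeline(c)
        rows.append({
            "encoder": c.encoder,
            "classifier": c.classifier,
            "accuracy": res.report.accuracy,
            "n_train": res.report.n_train,
            "n_test": res.report.n_test,
            "encode_time_s": res.timings.get("encode", float("nan"))
                             + res.timings.get("codebook", 0.0),
            "train_time_s": res.timings.get("train", float("nan")),
        })
    return pd.DataFrame(rows)
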