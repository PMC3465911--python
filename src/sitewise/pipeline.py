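"""Experiment orchestration: single- and multi-source runs under each CV scheme.

A run takes per-recording feature sources, builds a split plan, and inside
every fold selects prototypes from the *training* recordings only, projects
train and test into the dissimilarity space, fits the tree ensemble, and
accumulates the fold confusion matrices.  The summed matrix is scored by
prediction accuracy and by the Bayesian test of independence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, cvschemes, dissim
from .cohort import CohortIndex, build_cohort
from .indeptest import (
    ConfusionMatrix,
    MonteCarloConfig,
    accuracy,
    confusion_from_predictions,
    log_bayes_factor,
    sum_confusions,
)

__all__ = [
    "SourceSpec",
    "ExperimentConfig",
    "ExperimentData",
    "ResultRow",
    "run_single_source",
    "run_multi_source",
    "write_report",
]

_SCHEMES = {
    "recording_kfold": lambda cohort, cfg: cvschemes.recording_kfold(
        cohort, k=cfg.k, seed=cfg.split_seed
    ),
    "subject_kfold": lambda cohort, cfg: cvschemes.subject_kfold(
        cohort, k=cfg.k, seed=cfg.split_seed
    ),
    "leave_one_site_out": lambda cohort, cfg: cvschemes.leave_one_site_out(
        cohort, seed=cfg.split_seed
    ),
}


@dataclass
class SourceSpec:
    name: str
    distance: str = "euclidean"
    p: int = 40


@dataclass
class ExperimentConfig:
    scheme: str = "recording_kfold"
    k: int = 10
    split_seed: int = 0
    proto_seed: int = 0
    classifier: classify.ClassifierSpec = field(default_factory=classify.ClassifierSpec)
    mc: MonteCarloConfig = field(default_factory=MonteCarloConfig)
    prototypes: str = "per_fold"  # "per_fold" (leakage-free) | "global"

    def __post_init__(self) -> None:
        if self.scheme not in _SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}; known: {sorted(_SCHEMES)}")
        if self.prototypes not in ("per_fold", "global"):
            raise ValueError("prototypes must be 'per_fold' or 'global'")


@dataclass
class ExperimentData:
    """Cohort plus named per-recording feature sources (rows align with recordings)."""

    cohort: CohortIndex
    sources: dict  # name -> (n_recordings, d) array

    def __post_init__(self) -> None:
        n = self.cohort.n_recordings
        for name, X in self.sources.items():
            X = np.asarray(X, dtype=float)
            if X.shape[0] != n:
                raise ValueError(f"source {name!r} has {X.shape[0]} rows; cohort has {n}")
            self.sources[name] = X

    @classmethod
    def from_synthetic(cls, dataset, name: str = "synthetic") -> "ExperimentData":
        return cls(cohort=dataset.cohort, sources={name: dataset.features})

    @classmethod
    def from_directory(cls, path) -> "ExperimentData":
        """Load cohort.csv plus every *.tsv feature table (keyed by recording_id)."""
        path = Path(path)
        cohort = build_cohort(pd.read_csv(path / "cohort.csv"))
        order = [r.recording_id for r in cohort.recordings]
        sources = {}
        for tsv in sorted(path.glob("*.tsv")):
            df = pd.read_csv(tsv, sep="\t", index_col="recording_id")
            sources[tsv.stem] = df.loc[order].to_numpy(dtype=float)
        if not sources:
            raise ValueError(f"no feature TSVs found in {path}")
        return cls(cohort=cohort, sources=sources)


@dataclass
class ResultRow:
    label: str
    scheme: str
    log_b10: float
    t_star: int
    pa_aggregate: float
    pa_mean_folds: float
    tp: int
    tn: int
    fp: int
    fn: int
    fold_matrices: list
    prototype_audit: dict  # fold -> {source -> train recording_ids used as prototypes}
    details: dict = field(default_factory=dict)

    @property
    def confusion(self) -> ConfusionMatrix:
        return ConfusionMatrix.from_counts(self.tp, self.tn, self.fp, self.fn)

    def as_table_row(self) -> dict:
        return {
            "Data": self.label,
            "log(B10)": round(self.log_b10, 2),
            "PA": round(self.pa_aggregate, 2),
            "TP": self.tp,
            "TN": self.tn,
            "FP": self.fp,
            "FN": self.fn,
        }


def _fold_features(data, specs, train_idx, test_idx, config, global_protos):
    """Project one fold's train/test rows for each source and concatenate."""
    train_blocks, test_blocks, audit = [], [], {}
    for si, spec in enumerate(specs):
        X = data.sources[spec.name]
        d = dissim.get_distance(spec.distance)
        if config.prototypes == "global":
            proto_rows = global_protos[spec.name]
        else:
            train_objs = [X[i] for i in train_idx]
            ps = dissim.fft_select(
                train_objs, d, min(spec.p, len(train_objs)), seed=config.proto_seed + si
            )
            proto_rows = [train_idx[i] for i in ps.indices]
        audit[spec.name] = [data.cohort.recordings[i].recording_id for i in proto_rows]
        dmap = dissim.DissimilarityMap(prototypes=[X[i] for i in proto_rows], distance=d)
        train_blocks.append(dissim.project_all([X[i] for i in train_idx], dmap))
        test_blocks.append(dissim.project_all([X[i] for i in test_idx], dmap))
    return np.hstack(train_blocks), np.hstack(test_blocks), audit


def _run(data: ExperimentData, specs, label: str, config: ExperimentConfig) -> ResultRow:
    for spec in specs:
        if spec.name not in data.sources:
            raise ValueError(f"unknown source {spec.name!r}; have {sorted(data.sources)}")
        if spec.p > data.cohort.n_recordings:
            raise ValueError(f"p={spec.p} exceeds dataset size for source {spec.name!r}")
    plan = _SCHEMES[config.scheme](data.cohort, config)
    cvschemes.validate_plan(plan, data.cohort)
    row_of = {r.recording_id: i for i, r in enumerate(data.cohort.recordings)}
    labels = data.cohort.recording_labels()

    global_protos = {}
    if config.prototypes == "global":
        for si, spec in enumerate(specs):
            X = data.sources[spec.name]
            ps = dissim.fft_select(
                list(X), dissim.get_distance(spec.distance), spec.p, seed=config.proto_seed + si
            )
            global_protos[spec.name] = ps.indices

    fold_cms, fold_accs, audit_all = [], [], {}
    for f in plan.folds:
        train_idx = [row_of[i] for i in f.train]
        test_idx = [row_of[i] for i in f.test]
        Xtr, Xte, audit = _fold_features(data, specs, train_idx, test_idx, config, global_protos)
        audit_all[f.fold] = audit
        model = classify.train(Xtr, labels[train_idx], config.classifier)
        pred = classify.predict(model, Xte)
        cm = confusion_from_predictions(labels[test_idx], pred, c=data.cohort.n_classes)
        fold_cms.append(cm)
        fold_accs.append(accuracy(cm))
    total = sum_confusions(fold_cms)
    bf = log_bayes_factor(total, config.mc)
    (tn, fp), (fn, tp) = total.y
    return ResultRow(
        label=label,
        scheme=config.scheme,
        log_b10=bf.log_b10,
        t_star=bf.t_star,
        pa_aggregate=accuracy(total),
        pa_mean_folds=float(np.mean(fold_accs)),
        tp=int(tp),
        tn=int(tn),
        fp=int(fp),
        fn=int(fn),
        fold_matrices=[cm.y.tolist() for cm in fold_cms],
        prototype_audit=audit_all,
        details={
            "split_seed": config.split_seed,
            "proto_seed": config.proto_seed,
            "classifier": config.classifier.to_dict(),
            "M": config.mc.M,
            "mc_seed": config.mc.seed,
            "prototypes": config.prototypes,
        },
    )


def run_single_source(data: ExperimentData, source, config: ExperimentConfig) -> ResultRow:
    """Run one CV experiment on a single feature source."""
    spec = source if isinstance(source, SourceSpec) else SourceSpec(name=str(source))
    return _run(data, [spec], spec.name, config)


def run_multi_source(data: ExperimentData, sources, config: ExperimentConfig) -> ResultRow:
    """Concatenate per-source dissimilarity vectors (in declared order)."""
    specs = [s if isinstance(s, SourceSpec) else SourceSpec(name=str(s)) for s in sources]
    if len(specs) < 2:
        raise ValueError("multi-source run needs at least 2 sources")
    label = "+".join(s.name for s in specs)
    return _run(data, specs, label, config)


def write_report(rows, path) -> None:
    """TSV table plus a JSON sidecar from which every cell can be re-derived."""
    rows = list(rows)
    if not rows:
        raise ValueError("no result rows to write")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([r.as_table_row() for r in rows]).to_csv(path, sep="\t", index=False)
    sidecar = {
        "rows": [
            {
                "label": r.label,
                "scheme": r.scheme,
                "log_b10": r.log_b10,
                "t_star": r.t_star,
                "pa_aggregate": r.pa_aggregate,
                "pa_mean_folds": r.pa_mean_folds,
                "confusion": {"TP": r.tp, "TN": r.tn, "FP": r.fp, "FN": r.fn},
                "fold_matrices": r.fold_matrices,
                "prototype_audit": r.prototype_audit,
                "details": r.details,
            }
            for r in rows
        ]
    }
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)
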