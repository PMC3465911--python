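"""Cross-validation schemes respecting none, one or both batch levels.

Three estimation processes for clustered cohorts:

* ``recording_kfold`` — standard stratified k-fold on recordings.  Subjects
  (and sites) may straddle train and test; this is the biased baseline.
* ``subject_kfold`` — stratified k-fold on *subjects*; training uses all
  recordings of the training subjects while each test subject contributes
  exactly one randomly chosen recording, removing within-test dependence.
* ``leave_one_site_out`` — one fold per site; the held-out site's subjects
  form the test set (one recording each), removing both batch levels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .cohort import CohortIndex

__all__ = [
    "FoldSplit",
    "SplitPlan",
    "recording_kfold",
    "subject_kfold",
    "leave_one_site_out",
    "validate_plan",
]


@dataclass
class FoldSplit:
    fold: int
    train: list  # recording_ids
    test: list  # recording_ids


@dataclass
class SplitPlan:
    scheme: str
    k: int | None
    seed: int
    folds: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = {
            "scheme": self.scheme,
            "k": self.k,
            "seed": self.seed,
            "metadata": self.metadata,
            "folds": [{"fold": f.fold, "train": f.train, "test": f.test} for f in self.folds],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "SplitPlan":
        try:
            payload = json.loads(text_or_path)
        except (ValueError, TypeError):
            with open(text_or_path) as fh:
                payload = json.load(fh)
        return cls(
            scheme=payload["scheme"],
            k=payload["k"],
            seed=payload["seed"],
            metadata=payload.get("metadata", {}),
            folds=[FoldSplit(f["fold"], f["train"], f["test"]) for f in payload["folds"]],
        )


def _check_class_counts(labels, k, unit):
    labels = np.asarray(labels)
    for cls in np.unique(labels):
        count = int((labels == cls).sum())
        if count < k:
            raise ValueError(
                f"class {cls} has only {count} {unit}; cannot build {k} stratified folds"
            )


def recording_kfold(cohort: CohortIndex, k: int = 10, seed: int = 0) -> SplitPlan:
    """Stratified k-fold over recordings (ignores batch structure)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    labels = cohort.recording_labels()
    _check_class_counts(labels, k, "recordings")
    ids = [r.recording_id for r in cohort.recordings]
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = [
        FoldSplit(fold=i, train=[ids[j] for j in tr], test=[ids[j] for j in te])
        for i, (tr, te) in enumerate(skf.split(np.zeros(len(ids)), labels))
    ]
    return SplitPlan(scheme="recording_kfold", k=k, seed=seed, folds=folds)


def _one_recording_per_subject(cohort, subject_ids, rng):
    picks = []
    for s in subject_ids:
        idxs = cohort.recordings_of_subject(s)
        picks.append(cohort.recordings[idxs[int(rng.integers(len(idxs)))]].recording_id)
    return picks


def subject_kfold(cohort: CohortIndex, k: int = 10, seed: int = 0) -> SplitPlan:
    """Stratified k-fold over subjects; one test recording per test subject.

    Subjects are stratified by class label.  The per-subject test recording
    is sampled once when the plan is built, so the plan fully determines
    every later experiment.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    subj_labels = np.array([cohort.class_of_subject(s) for s in cohort.subjects])
    _check_class_counts(subj_labels, k, "subjects")
    rng = np.random.default_rng(seed)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for i, (tr, te) in enumerate(skf.split(np.zeros(len(cohort.subjects)), subj_labels)):
        train_subjects = [cohort.subjects[j] for j in tr]
        test_subjects = [cohort.subjects[j] for j in te]
        train = [
            cohort.recordings[idx].recording_id
            for s in train_subjects
            for idx in cohort.recordings_of_subject(s)
        ]
        test = _one_recording_per_subject(cohort, test_subjects, rng)
        folds.append(FoldSplit(fold=i, train=train, test=test))
    return SplitPlan(
        scheme="subject_kfold",
        k=k,
        seed=seed,
        folds=folds,
        metadata={"stratified_by_class": True},
    )


def leave_one_site_out(cohort: CohortIndex, seed: int = 0) -> SplitPlan:
    """One fold per site; train on the other sites, test on the held-out one."""
    if cohort.n_sites < 2:
        raise ValueError("leave-one-site-out needs at least 2 sites")
    rng = np.random.default_rng(seed)
    folds = []
    for i, site in enumerate(cohort.sites):
        test_subjects = [s for s in cohort.subjects if cohort.site_of_subject(s) == site]
        train = [r.recording_id for r in cohort.recordings if r.site_id != site]
        test = _one_recording_per_subject(cohort, test_subjects, rng)
        folds.append(FoldSplit(fold=i, train=train, test=test))
    return SplitPlan(scheme="leave_one_site_out", k=None, seed=seed, folds=folds)


def validate_plan(plan: SplitPlan, cohort: CohortIndex) -> None:
    """Audit scheme invariants; raises AssertionError on violation."""
    rec_by_id = {r.recording_id: r for r in cohort.recordings}
    for f in plan.folds:
        train, test = set(f.train), set(f.test)
        assert train and test, f"fold {f.fold}: empty side"
        assert not train & test, f"fold {f.fold}: train/test overlap"
        if plan.scheme in ("subject_kfold", "leave_one_site_out"):
            tr_subj = {rec_by_id[i].subject_id for i in train}
            te_subj = [rec_by_id[i].subject_id for i in test]
            assert not tr_subj & set(te_subj), f"fold {f.fold}: subject leakage"
            assert len(te_subj) == len(set(te_subj)), f"fold {f.fold}: >1 test recording/subject"
        if plan.scheme == "leave_one_site_out":
            tr_sites = {rec_by_id[i].site_id for i in train}
            te_sites = {rec_by_id[i].site_id for i in test}
            assert not tr_sites & te_sites, f"fold {f.fold}: site leakage"
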