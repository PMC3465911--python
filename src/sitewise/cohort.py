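"""Recording/subject/site hierarchy, class labels and batch-effect encoding.

A cohort is a two-level clustered sample: each recording belongs to exactly
one subject, each subject to exactly one acquisition site, and the diagnostic
class label is a property of the subject (constant across all of their
recordings).  The batch structure (site membership and subject identity) is
what classifier evaluation has to respect in order not to leak information
between train and test sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RecordingRecord",
    "CohortIndex",
    "build_cohort",
    "encode_batch",
    "batch_design_matrix",
    "zscore_columns",
]

REQUIRED_COLUMNS = ("recording_id", "subject_id", "site_id", "class_label")


@dataclass(frozen=True)
class RecordingRecord:
    """One recording (e.g. one resting-state run or one structural scan)."""

    recording_id: str
    subject_id: str
    site_id: str
    class_label: int
    sources: dict = field(default_factory=dict)


@dataclass
class CohortIndex:
    """Validated roster of recordings, subjects and sites.

    Roster order is first-appearance order in the input table, which fixes
    the positions used by :func:`encode_batch` deterministically.
    """

    recordings: list  # list[RecordingRecord]
    sites: list  # ordered site roster, size S
    subjects: list  # ordered subject roster, size N
    n_classes: int = 2

    def __post_init__(self) -> None:
        self._site_pos = {s: i for i, s in enumerate(self.sites)}
        self._subject_pos = {s: i for i, s in enumerate(self.subjects)}
        self._subject_site = {}
        self._subject_class = {}
        self._subject_recordings = {}
        for idx, rec in enumerate(self.recordings):
            self._subject_site.setdefault(rec.subject_id, rec.site_id)
            self._subject_class.setdefault(rec.subject_id, rec.class_label)
            self._subject_recordings.setdefault(rec.subject_id, []).append(idx)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_recordings(self) -> int:
        return len(self.recordings)

    def site_position(self, site_id: str) -> int:
        return self._site_pos[site_id]

    def subject_position(self, subject_id: str) -> int:
        return self._subject_pos[subject_id]

    def site_of_subject(self, subject_id: str) -> str:
        return self._subject_site[subject_id]

    def class_of_subject(self, subject_id: str) -> int:
        return self._subject_class[subject_id]

    def recordings_of_subject(self, subject_id: str) -> list:
        """Indices into ``recordings`` for one subject."""
        return list(self._subject_recordings[subject_id])

    def recording_labels(self) -> np.ndarray:
        return np.array([r.class_label for r in self.recordings], dtype=int)

    def counts_table(self) -> pd.DataFrame:
        """Per-site × per-class subject counts, with row/column margins."""
        rows = [
            {"site_id": self.site_of_subject(s), "class_label": self.class_of_subject(s)}
            for s in self.subjects
        ]
        df = pd.DataFrame(rows)
        table = df.groupby(["site_id", "class_label"]).size().unstack(fill_value=0)
        table = table.reindex(index=self.sites, fill_value=0)
        table["All"] = table.sum(axis=1)
        return table

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "recording_id": [r.recording_id for r in self.recordings],
                "subject_id": [r.subject_id for r in self.recordings],
                "site_id": [r.site_id for r in self.recordings],
                "class_label": [r.class_label for r in self.recordings],
            }
        )


def build_cohort(table: pd.DataFrame, n_classes: int = 2) -> CohortIndex:
    """Build and validate a :class:`CohortIndex` from a tabular description.

    Parameters
    ----------
    table
        DataFrame (or convertible) with columns ``recording_id``,
        ``subject_id``, ``site_id``, ``class_label``.
    n_classes
        Number of diagnostic classes; labels must lie in ``{0..n_classes-1}``.

    Raises
    ------
    ValueError
        On duplicate recording ids, a subject listed under two sites, a
        subject with inconsistent class labels, or out-of-range labels.
    """
    df = pd.DataFrame(table)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    if len(df) == 0:
        raise ValueError("cohort table is empty")

    rec_ids = df["recording_id"].astype(str)
    dup = rec_ids[rec_ids.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate recording_id values: {sorted(set(dup))}")

    labels = df["class_label"].astype(int)
    if ((labels < 0) | (labels >= n_classes)).any():
        raise ValueError(f"class labels must be in 0..{n_classes - 1}")

    by_subject = df.groupby("subject_id", sort=False)
    bad_site = by_subject["site_id"].nunique()
    bad_site = bad_site[bad_site > 1]
    if len(bad_site):
        raise ValueError(f"subjects listed under multiple sites: {list(bad_site.index)}")
    bad_cls = by_subject["class_label"].nunique()
    bad_cls = bad_cls[bad_cls > 1]
    if len(bad_cls):
        raise ValueError(f"subjects with inconsistent class labels: {list(bad_cls.index)}")

    recordings = [
        RecordingRecord(
            recording_id=str(r.recording_id),
            subject_id=str(r.subject_id),
            site_id=str(r.site_id),
            class_label=int(r.class_label),
        )
        for r in df.itertuples(index=False)
    ]
    sites = list(dict.fromkeys(r.site_id for r in recordings))
    subjects = list(dict.fromkeys(r.subject_id for r in recordings))
    return CohortIndex(recordings=recordings, sites=sites, subjects=subjects, n_classes=n_classes)


def encode_batch(recording: RecordingRecord, cohort: CohortIndex) -> np.ndarray:
    """Two-level batch-effect indicator vector for one recording.

    Returns a binary vector of length ``S + N`` (site block first) with
    exactly two ones: one at the recording's site position and one at
    ``S +`` the subject's roster position.  The encoding depends only on
    (site, subject), so all recordings of a subject share one vector.
    """
    try:
        i = cohort.site_position(recording.site_id)
        j = cohort.subject_position(recording.subject_id)
    except KeyError as exc:
        raise ValueError(f"unknown site or subject: {exc}") from exc
    vec = np.zeros(cohort.n_sites + cohort.n_subjects, dtype=np.int8)
    vec[i] = 1
    vec[cohort.n_sites + j] = 1
    return vec


def batch_design_matrix(cohort: CohortIndex) -> np.ndarray:
    """Stack of :func:`encode_batch` vectors, one row per recording."""
    return np.vstack([encode_batch(r, cohort) for r in cohort.recordings])


def zscore_columns(table) -> np.ndarray:
    """Z-score each column using the population (divide-by-n) deviation.

    Constant columns map to all-zeros rather than NaN.  Non-numeric input
    is rejected.
    """
    X = np.asarray(table, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] < 1:
        raise ValueError("need at least one row")
    if not np.isfinite(X).all():
        raise ValueError("non-numeric or non-finite cells in table")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # population convention
    out = np.zeros_like(X)
    nz = sd > 0
    out[:, nz] = (X[:, nz] - mean[nz]) / sd[nz]
    return out
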