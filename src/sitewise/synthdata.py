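"""Seeded generator of multi-site, multi-recording datasets.

The generator emulates the structure of pooled multi-site clinical cohorts
(unbalanced two-class labels, ~8 sites, 1..k recordings per subject) with a
Gaussian additive random-effects model.  For recording r of subject j
(class y_j) at site s the feature vector is

    x_r = delta * y_j * u + u_s + v_j + eps_r

with a constant (or sparse) class shift delta, site effect
u_s ~ N(0, sigma_site^2 I), subject effect v_j ~ N(0, sigma_subj^2 I) and
recording noise eps_r ~ N(0, sigma_eps^2 I).  Class labels are drawn
per-site with a configurable prevalence, so site–class confounding can be
dialled in directly.  Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortIndex, build_cohort

__all__ = ["SyntheticConfig", "SyntheticDataset", "generate", "generate_volumes", "write_dataset"]


@dataclass
class SyntheticConfig:
    n_sites: int = 8
    subjects_per_site: int = 30
    prevalence: object = 0.38  # scalar or per-site sequence of P(class 1)
    k_max: int = 3  # recordings per subject uniform on 1..k_max
    n_features: int = 40
    class_effect: float = 0.0  # delta, mean shift of class 1
    site_sd: float = 1.0
    subject_sd: float = 0.5
    noise_sd: float = 1.0
    sparse_fraction: float | None = None  # if set, delta applies to this fraction of features
    seed: int = 0

    def __post_init__(self) -> None:
        prev = np.broadcast_to(np.asarray(self.prevalence, dtype=float), (self.n_sites,))
        if ((prev < 0) | (prev > 1)).any():
            raise ValueError("prevalences must lie in [0, 1]")
        if min(self.site_sd, self.subject_sd, self.noise_sd) < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.k_max < 1:
            raise ValueError("k_max must be >= 1")
        if self.n_sites < 1 or self.subjects_per_site < 1 or self.n_features < 1:
            raise ValueError("sites, subjects and features must be positive")
        self._prev = prev


@dataclass
class SyntheticDataset:
    cohort: CohortIndex
    features: np.ndarray  # rows follow cohort.recordings order
    site_effects: dict  # site_id -> u_s
    subject_effects: dict  # subject_id -> v_j
    config: SyntheticConfig = field(repr=False, default=None)


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Draw a full synthetic dataset from the random-effects model."""
    rng = np.random.default_rng(config.seed)
    d = config.n_features
    shift = np.ones(d)
    if config.sparse_fraction is not None:
        k = max(1, int(round(config.sparse_fraction * d)))
        shift = np.zeros(d)
        shift[rng.choice(d, size=k, replace=False)] = 1.0

    rows = []
    site_effects = {}
    subject_effects = {}
    feats = []
    for s in range(config.n_sites):
        site_id = f"site{s:02d}"
        u_s = rng.normal(0.0, config.site_sd, size=d)
        site_effects[site_id] = u_s
        for j in range(config.subjects_per_site):
            subject_id = f"{site_id}_subj{j:03d}"
            y_j = int(rng.random() < config._prev[s])
            v_j = rng.normal(0.0, config.subject_sd, size=d)
            subject_effects[subject_id] = v_j
            base = config.class_effect * y_j * shift + u_s + v_j
            n_rec = int(rng.integers(1, config.k_max + 1))
            for r in range(n_rec):
                rows.append(
                    {
                        "recording_id": f"{subject_id}_rec{r}",
                        "subject_id": subject_id,
                        "site_id": site_id,
                        "class_label": y_j,
                    }
                )
                feats.append(base + rng.normal(0.0, config.noise_sd, size=d))
    cohort = build_cohort(pd.DataFrame(rows))
    return SyntheticDataset(
        cohort=cohort,
        features=np.vstack(feats),
        site_effects=site_effects,
        subject_effects=subject_effects,
        config=config,
    )


def generate_volumes(config: SyntheticConfig, shape) -> list:
    """Per-recording 3D volumes embedding the feature model.

    The features of :func:`generate` (same seed) are scattered into
    ``n_features`` designated voxels (chosen from the seed, fixed across
    recordings, ordered by row-major scan position); background voxels are
    zero.  Masking the volumes at any positive threshold and flattening
    recovers the feature matrix exactly.
    """
    shape = tuple(int(s) for s in shape)
    n_vox = int(np.prod(shape))
    if n_vox < config.n_features:
        raise ValueError(f"shape {shape} holds {n_vox} voxels < {config.n_features} features")
    dataset = generate(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5C3A]))
    voxels = np.sort(rng.choice(n_vox, size=config.n_features, replace=False))
    vols = []
    for row in dataset.features:
        v = np.zeros(n_vox)
        v[voxels] = row
        vols.append(v.reshape(shape))
    return vols


def write_dataset(dataset: SyntheticDataset, out_dir, source_name: str = "synthetic") -> None:
    """Write cohort CSV and a feature TSV in the formats the pipeline reads."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset.cohort.to_table().to_csv(out / "cohort.csv", index=False)
    df = pd.DataFrame(
        dataset.features,
        index=pd.Index([r.recording_id for r in dataset.cohort.recordings], name="recording_id"),
    )
    df.to_csv(out / f"{source_name}.tsv", sep="\t")
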