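import numpy as np
import pandas as pd
import pytest

from sitewise import SyntheticConfig, build_cohort, generate

# Per-site (controls, patients) subject counts of an 8-site reference cohort
# with 62%/38% class unbalance, 932 subjects in total.
SITE_COUNTS = {
    "PKGU": (146, 99),
    "BHBU": (21, 5),
    "KKI": (48, 46),
    "NIMP": (26, 22),
    "NYU": (132, 121),
    "OHSU": (73, 38),
    "UPIT": (89, 8),
    "WUSL": (40, 18),
}


@pytest.fixture(scope="session")
def eight_site_cohort():
    """Cohort reproducing the reference per-site/per-class subject counts."""
    rows = []
    n = 0
    for site, (controls, patients) in SITE_COUNTS.items():
        for label, count in ((0, controls), (1, patients)):
            for _ in range(count):
                sid = f"s{n:04d}"
                rows.append(
                    {
                        "recording_id": f"{sid}_r0",
                        "subject_id": sid,
                        "site_id": site,
                        "class_label": label,
                    }
                )
                n += 1
    return build_cohort(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def small_dataset():
    """Small multi-site dataset with a clear class signal, for pipeline tests."""
    cfg = SyntheticConfig(
        n_sites=4,
        subjects_per_site=10,
        prevalence=0.4,
        k_max=2,
        n_features=20,
        class_effect=3.0,
        site_sd=0.5,
        subject_sd=0.5,
        noise_sd=1.0,
        seed=11,
    )
    return generate(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
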