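import numpy as np
import pandas as pd
import pytest

from sftdx.expression import ExpressionSet
from sftdx.synthetic import (
    ExpressionTruth,
    SampleBlock,
    SetLayout,
    quota_ihc_cohort,
    simulate_multiplatform_cohort,
)


def make_eset(values, set_id="s1", platform="generic", histotypes=None, sites=None,
              features=None):
    """Small in-memory expression set for unit tests."""
    values = np.asarray(values, dtype=float)
    n_feat, n_samp = values.shape
    features = features or [f"G{i}" for i in range(n_feat)]
    samples = [f"{set_id}_c{j}" for j in range(n_samp)]
    ann = pd.DataFrame(
        {
            "set_id": set_id,
            "platform": platform,
            "histotype": histotypes or ["SFT"] * n_samp,
            "site": sites or ["meningeal"] * n_samp,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    matrix = pd.DataFrame(values, index=features, columns=samples)
    return ExpressionSet(matrix=matrix, set_id=set_id, platform=platform, annotations=ann)


@pytest.fixture(scope="session")
def quota_cohort():
    """The deterministic IHC cohort with the published joint marker counts."""
    return quota_ihc_cohort()


def two_set_truth(noise_sd=0.0, offsets=None, target_shift=0.0, n_hk=5, seed=0,
                  hk_noise=None):
    """Minimal two-set truth: target shifted between SFT and synovial sarcoma."""
    base = 6.0
    return ExpressionTruth(
        per_histotype_log2_mean={
            "SFT": base + target_shift, "HPC": base + target_shift,
            "meningioma": base, "synovial_sarcoma": base,
        },
        batch_offsets=offsets or {"A": 0.0, "B": 0.0},
        housekeeping_ids=[f"HK{i:04d}" for i in range(1, n_hk + 1)],
        noise_sd=noise_sd,
        housekeeping_noise_sd=hk_noise,
        seed=seed,
    )


def two_set_layouts(platform_a="affymetrix_u133a", platform_b="cdna_array",
                    n_background=8, n=3):
    B = SampleBlock
    blocks = [B("SFT", "meningeal", n), B("synovial_sarcoma", "extrameningeal", n)]
    return [
        SetLayout("A", platform_a, list(blocks), n_background),
        SetLayout("B", platform_b, list(blocks), n_background),
    ]


@pytest.fixture()
def small_cohort_sets():
    truth = two_set_truth(noise_sd=0.2, offsets={"A": 0.0, "B": 1.5},
                          target_shift=1.0, seed=11)
    sets, annots = simulate_multiplatform_cohort(truth, two_set_layouts())
    return truth, sets, annots
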