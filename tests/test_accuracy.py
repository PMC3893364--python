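import numpy as np
import pandas as pd
import pytest

from sftdx.accuracy import (
    CohortSelector,
    CombinedRule,
    ContingencyTable,
    MENINGEAL_HPC,
    MENINGEAL_SFT,
    MENINGIOMAS,
    SYNOVIAL_SARCOMAS,
    build_contingency,
    call_marker,
    combine_markers,
    compare_paired_sensitivity,
    diagnostic_metrics,
    validate_cohort,
)
from sftdx.synthetic import default_ihc_truth, simulate_ihc_cohort


# ---------------------------------------------------------------------------
# marker calls
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "percent,status,band",
    [
        (0, "negative", "none"),
        (4, "negative", "none"),
        (5, "positive", "low"),
        (10, "positive", "low"),
        (11, "positive", "intermediate"),
        (50, "positive", "intermediate"),
        (51, "positive", "high"),
        (100, "positive", "high"),
    ],
)
def test_call_marker_band_boundaries(percent, status, band):
    call = call_marker(percent)
    assert (call.status, call.band) == (status, band)


def test_call_marker_range_check():
    for bad in (-1, 101):
        with pytest.raises(ValueError, match="out of range"):
            call_marker(bad)


# ---------------------------------------------------------------------------
# contingency tables from the published quota cohort
# ---------------------------------------------------------------------------

def test_sft_aldh1_contingency(quota_cohort):
    t = build_contingency(quota_cohort, "ALDH1", MENINGEAL_SFT, MENINGIOMAS)
    assert (t.tp, t.fn, t.fp, t.tn) == (21, 4, 2, 161)


def test_sft_and_rule_contingency(quota_cohort):
    t = build_contingency(quota_cohort, CombinedRule("and"), MENINGEAL_SFT, MENINGIOMAS)
    assert (t.tp, t.fn) == (20, 5)
    assert (t.fp, t.tn) == (0, 163)


def test_hpc_and_rule_positives(quota_cohort):
    t = build_contingency(quota_cohort, CombinedRule("and"), MENINGEAL_HPC, MENINGIOMAS)
    assert t.tp == 34


def test_or_rule_counts(quota_cohort):
    derived = combine_markers(quota_cohort, CombinedRule("or"))
    sft = derived[derived["histotype"] == "SFT"]
    hpc = derived[derived["histotype"] == "HPC"]
    assert int(sft["positive"].sum()) == 24
    assert int(hpc["positive"].sum()) == 54


def test_selector_validation(quota_cohort):
    with pytest.raises(ValueError, match="overlap"):
        build_contingency(quota_cohort, "ALDH1", MENINGEAL_SFT,
                          CohortSelector("everything", ("SFT", "meningioma")))
    with pytest.raises(ValueError, match="reference"):
        build_contingency(quota_cohort, "ALDH1", MENINGEAL_SFT,
                          CohortSelector("none", ("meningioma",), site="extrameningeal"))
    with pytest.raises(ValueError, match="absent"):
        build_contingency(quota_cohort, "EMA", MENINGEAL_SFT, MENINGIOMAS)


def test_missing_marker_samples_excluded(quota_cohort):
    trimmed = quota_cohort[
        ~((quota_cohort["marker"] == "CD34")
          & (quota_cohort["sample_id"] == "sft_000"))
    ]
    t = build_contingency(trimmed, "CD34", MENINGEAL_SFT, MENINGIOMAS)
    assert t.n_excluded == 1
    assert t.tp + t.fn == 24
    with pytest.raises(ValueError, match="missing"):
        combine_markers(trimmed, CombinedRule("and"))


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def test_published_metric_values():
    m = diagnostic_metrics(ContingencyTable(21, 4, 2, 161, "SFT", "men", "ALDH1"))
    assert np.isclose(100 * m.se, 84.0)
    assert round(100 * m.sp, 1) == 98.8
    assert round(100 * m.ppv, 1) == 91.3
    assert round(100 * m.npv, 1) == 97.6
    m = diagnostic_metrics(ContingencyTable(23, 2, 8, 155, "SFT", "men", "CD34"))
    assert np.isclose(100 * m.se, 92.0)
    assert round(100 * m.sp, 1) == 95.1
    assert round(100 * m.ppv, 1) == 74.2
    assert round(100 * m.npv, 1) == 98.7


def test_perfect_marker_metrics():
    m = diagnostic_metrics(ContingencyTable(10, 0, 0, 20, "d", "r", "perfect"))
    assert (m.se, m.sp, m.ppv, m.npv) == (1.0, 1.0, 1.0, 1.0)
    for ci in (m.ci_se, m.ci_sp, m.ci_ppv, m.ci_npv):
        assert ci[0] <= 1.0 <= ci[1] + 1e-12


def test_undefined_predictive_values_flagged():
    m = diagnostic_metrics(ContingencyTable(0, 10, 0, 20, "d", "r", "dead"))
    assert m.ppv is None and m.ci_ppv is None
    assert any("PPV undefined" in n for n in m.notes)
    with pytest.raises(ValueError, match="margin"):
        diagnostic_metrics(ContingencyTable(0, 0, 5, 5, "d", "r", "m"))


def test_ci_methods_contain_point_estimate_and_cp_wider():
    rng = np.random.default_rng(0)
    for _ in range(20):
        tp, fn = int(rng.integers(0, 30)), int(rng.integers(0, 30))
        if tp + fn == 0:
            continue
        t = ContingencyTable(tp, fn, int(rng.integers(0, 10)) + 1,
                             int(rng.integers(0, 100)) + 1, "d", "r", "m")
        wilson = diagnostic_metrics(t, ci_method="wilson")
        cp = diagnostic_metrics(t, ci_method="clopper_pearson")
        for m in (wilson, cp):
            assert m.ci_se[0] - 1e-12 <= m.se <= m.ci_se[1] + 1e-12
            assert m.ci_sp[0] - 1e-12 <= m.sp <= m.ci_sp[1] + 1e-12
        assert (cp.ci_se[1] - cp.ci_se[0]) >= (wilson.ci_se[1] - wilson.ci_se[0]) - 1e-9


def test_combined_rule_dominance_on_stochastic_cohorts():
    """OR can only gain sensitivity; AND can only gain specificity."""
    for seed in range(5):
        cohort = simulate_ihc_cohort(default_ihc_truth(seed=seed))
        for disease in (MENINGEAL_SFT, MENINGEAL_HPC):
            per_marker = {
                m: diagnostic_metrics(build_contingency(cohort, m, disease, MENINGIOMAS))
                for m in ("ALDH1", "CD34")
            }
            or_m = diagnostic_metrics(
                build_contingency(cohort, CombinedRule("or"), disease, MENINGIOMAS))
            and_m = diagnostic_metrics(
                build_contingency(cohort, CombinedRule("and"), disease, MENINGIOMAS))
            assert or_m.se >= max(m.se for m in per_marker.values()) - 1e-12
            assert and_m.sp >= max(m.sp for m in per_marker.values()) - 1e-12


def test_combined_band_conventions(quota_cohort):
    both = combine_markers(quota_cohort, CombinedRule("and"))
    any_ = combine_markers(quota_cohort, CombinedRule("or"))
    sample = "sft_000"  # ALDH1 low (7%), CD34 intermediate (30%)
    assert both.loc[sample, "band"] == "low"
    assert any_.loc[sample, "band"] == "intermediate"
    neg = both[~both["positive"]]
    assert (neg["band"] == "none").all()


# ---------------------------------------------------------------------------
# paired sensitivity
# ---------------------------------------------------------------------------

def _paired_cohort(statuses):
    """statuses: list of (aldh1_positive, cd34_positive) for disease samples."""
    rows = []
    for i, (a, c) in enumerate(statuses):
        sid = f"s{i}"
        rows.append((sid, "SFT", "meningeal", "ALDH1", 30 if a else 0))
        rows.append((sid, "SFT", "meningeal", "CD34", 30 if c else 0))
    return pd.DataFrame(rows, columns=["sample_id", "histotype", "site",
                                       "marker", "percent_stained"])


def test_mcnemar_exact_binomial():
    # b=5 discordant one way, c=0: p = 2 * (1/2)^5 = 0.0625 exactly
    cohort = _paired_cohort([(True, False)] * 5 + [(True, True)] * 4)
    r = compare_paired_sensitivity(cohort, "ALDH1", "CD34", MENINGEAL_SFT)
    assert (r.b, r.c) == (5, 0)
    assert np.isclose(r.p_value, 0.0625, atol=1e-12)


def test_mcnemar_symmetric_discordance():
    cohort = _paired_cohort([(True, False)] * 3 + [(False, True)] * 3)
    r = compare_paired_sensitivity(cohort, "ALDH1", "CD34", MENINGEAL_SFT)
    assert r.p_value == 1.0


def test_mcnemar_no_discordance_flagged():
    cohort = _paired_cohort([(True, True)] * 4 + [(False, False)] * 2)
    r = compare_paired_sensitivity(cohort, "ALDH1", "CD34", MENINGEAL_SFT)
    assert r.p_value == 1.0
    assert r.note == "no discordant pairs"


# ---------------------------------------------------------------------------
# cohort validation
# ---------------------------------------------------------------------------

def test_cohort_validation_errors(quota_cohort):
    with pytest.raises(ValueError, match="empty"):
        validate_cohort(quota_cohort.iloc[0:0])
    dup = pd.concat([quota_cohort, quota_cohort.iloc[[0]]])
    with pytest.raises(ValueError, match="duplicate"):
        validate_cohort(dup)
    bad = quota_cohort.copy()
    bad.loc[bad.index[0], "percent_stained"] = 150
    with pytest.raises(ValueError, match="out of"):
        validate_cohort(bad)
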