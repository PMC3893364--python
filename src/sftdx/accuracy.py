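"""IHC marker scoring, contingency tables and diagnostic accuracy.

A marker is called positive when cytoplasmic staining covers 5% or more of the
tumour cells; positives are banded semi-quantitatively (low 5-10%,
intermediate 11-50%, high >50%).  From binary calls the module builds 2x2
contingency tables of a disease group against a reference group (by default
meningiomas only — the clinically relevant differential, not "everything
else"), computes sensitivity / specificity / predictive values with Wilson or
Clopper-Pearson 95% intervals, evaluates combined-marker rules (AND / OR over
ALDH1 and CD34), and compares paired marker sensitivities with the exact
McNemar test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.contingency_tables import mcnemar
from statsmodels.stats.proportion import proportion_confint

logger = logging.getLogger(__name__)

POSITIVITY_THRESHOLD = 5  # percent stained cells
BANDS = ("none", "low", "intermediate", "high")
MARKERS = ("ALDH1", "CD34")

COHORT_COLUMNS = ["sample_id", "histotype", "site", "marker", "percent_stained"]


@dataclass(frozen=True)
class MarkerCall:
    status: str  # "negative" | "positive"
    band: str    # "none" | "low" | "intermediate" | "high"

    def __post_init__(self) -> None:
        if (self.status == "negative") != (self.band == "none"):
            raise ValueError("negative calls must have band 'none' and vice versa")


def call_marker(percent_stained: int | float) -> MarkerCall:
    """Binary call plus semi-quantitative band for a percent-stained value.

    <5 negative; 5-10 low; 11-50 intermediate; >50 high.
    """
    p = float(percent_stained)
    if not 0 <= p <= 100:
        raise ValueError(f"percent stained out of range: {percent_stained}")
    if p < POSITIVITY_THRESHOLD:
        return MarkerCall("negative", "none")
    if p <= 10:
        return MarkerCall("positive", "low")
    if p <= 50:
        return MarkerCall("positive", "intermediate")
    return MarkerCall("positive", "high")


def validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format cohort table (one row per sample x marker)."""
    missing = set(COHORT_COLUMNS) - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table lacks columns: {sorted(missing)}")
    if cohort.empty:
        raise ValueError("empty cohort")
    if cohort.duplicated(subset=["sample_id", "marker"]).any():
        raise ValueError("cohort holds duplicate sample x marker rows")
    bad = ~cohort["percent_stained"].between(0, 100)
    if bad.any():
        raise ValueError(
            f"percent_stained out of [0,100] for samples "
            f"{cohort.loc[bad, 'sample_id'].tolist()[:5]}"
        )
    return cohort


def read_cohort_csv(path) -> pd.DataFrame:
    return validate_cohort(pd.read_csv(path))


def _calls_wide(cohort: pd.DataFrame) -> pd.DataFrame:
    """Pivot to one row per sample with per-marker status/band columns."""
    wide = cohort.pivot(index="sample_id", columns="marker", values="percent_stained")
    meta = cohort.drop_duplicates("sample_id").set_index("sample_id")[["histotype", "site"]]
    return wide.join(meta)


_BAND_ORDER = {b: i for i, b in enumerate(BANDS)}


@dataclass(frozen=True)
class CombinedRule:
    """AND / OR combination of marker positivity."""

    op: str  # "and" | "or"
    markers: tuple[str, ...] = MARKERS

    def __post_init__(self) -> None:
        if self.op not in ("and", "or"):
            raise ValueError("rule op must be 'and' or 'or'")

    @property
    def label(self) -> str:
        return (" & " if self.op == "and" else " | ").join(self.markers)


def combine_markers(cohort: pd.DataFrame, rule: CombinedRule) -> pd.DataFrame:
    """Derive a combined-marker call per sample.

    AND is positive iff every marker is positive (band = min of the member
    bands); OR is positive iff any marker is (band = max).  Bands of combined
    calls are informational only — diagnosis uses the binary status.
    """
    wide = _calls_wide(validate_cohort(cohort))
    for m in rule.markers:
        if m not in wide.columns or wide[m].isna().any():
            missing = wide.index[wide[m].isna()].tolist()[:5] if m in wide.columns else "all"
            raise ValueError(f"marker {m!r} missing for samples: {missing}")
    calls = {m: wide[m].map(call_marker) for m in rule.markers}
    status = pd.DataFrame({m: c.map(lambda x: x.status == "positive") for m, c in calls.items()})
    positive = status.all(axis=1) if rule.op == "and" else status.any(axis=1)
    band_idx = pd.DataFrame({m: c.map(lambda x: _BAND_ORDER[x.band]) for m, c in calls.items()})
    agg = band_idx.min(axis=1) if rule.op == "and" else band_idx.max(axis=1)
    bands = [BANDS[i] if pos else "none" for i, pos in zip(agg, positive)]
    return pd.DataFrame(
        {
            "histotype": wide["histotype"],
            "site": wide["site"],
            "positive": positive,
            "band": bands,
        },
        index=wide.index,
    )


@dataclass(frozen=True)
class CohortSelector:
    """Histotype (and optionally site) filter over cohort samples."""

    label: str
    histotypes: tuple[str, ...]
    site: str | None = None

    def mask(self, frame: pd.DataFrame) -> pd.Series:
        m = frame["histotype"].isin(self.histotypes)
        if self.site is not None:
            m &= frame["site"] == self.site
        return m


MENINGEAL_SFT = CohortSelector("meningeal SFT", ("SFT",), site="meningeal")
MENINGEAL_HPC = CohortSelector("meningeal HPC", ("HPC",), site="meningeal")
MENINGIOMAS = CohortSelector("meningiomas", ("meningioma",))
SYNOVIAL_SARCOMAS = CohortSelector("synovial sarcomas", ("synovial_sarcoma",))


@dataclass
class ContingencyTable:
    tp: int
    fn: int
    fp: int
    tn: int
    disease_group: str
    reference_group: str
    marker: str
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("contingency counts must be non-negative")


def _sample_positivity(cohort: pd.DataFrame, marker_or_rule) -> pd.DataFrame:
    if isinstance(marker_or_rule, CombinedRule):
        return combine_markers(cohort, marker_or_rule), marker_or_rule.label
    marker = str(marker_or_rule)
    sub = cohort.loc[cohort["marker"] == marker]
    if sub.empty:
        raise ValueError(f"marker {marker!r} absent from cohort")
    calls = sub["percent_stained"].map(lambda p: call_marker(p).status == "positive")
    frame = pd.DataFrame(
        {
            "histotype": sub["histotype"].to_numpy(),
            "site": sub["site"].to_numpy(),
            "positive": calls.to_numpy(),
        },
        index=sub["sample_id"],
    )
    return frame, marker


def build_contingency(
    cohort: pd.DataFrame,
    marker_or_rule,
    disease: CohortSelector,
    reference: CohortSelector = MENINGIOMAS,
) -> ContingencyTable:
    """2x2 counts of a marker (or combined rule) for disease vs reference.

    Samples matched by *both* selectors indicate mis-specified groups and are
    rejected.  Samples lacking the marker are excluded and counted.
    """
    validate_cohort(cohort)
    frame, label = _sample_positivity(cohort, marker_or_rule)
    dmask, rmask = disease.mask(frame), reference.mask(frame)
    if (dmask & rmask).any():
        raise ValueError("disease and reference selections overlap")
    if not dmask.any():
        raise ValueError(f"no samples match disease selector {disease.label!r}")
    if not rmask.any():
        raise ValueError(f"no samples match reference selector {reference.label!r}")
    # samples present in the cohort but missing this marker
    all_ids = set(cohort["sample_id"])
    n_excluded = len(all_ids - set(frame.index))
    if n_excluded:
        logger.info("%d samples lack marker %s and were excluded", n_excluded, label)
    d, r = frame.loc[dmask, "positive"], frame.loc[rmask, "positive"]
    return ContingencyTable(
        tp=int(d.sum()), fn=int((~d).sum()),
        fp=int(r.sum()), tn=int((~r).sum()),
        disease_group=disease.label, reference_group=reference.label,
        marker=label, n_excluded=n_excluded,
    )


@dataclass
class DiagnosticAccuracy:
    se: float
    sp: float
    ppv: float | None
    npv: float | None
    ci_se: tuple[float, float]
    ci_sp: tuple[float, float]
    ci_ppv: tuple[float, float] | None
    ci_npv: tuple[float, float] | None
    ci_method: str
    table: ContingencyTable
    notes: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "marker": self.table.marker,
            "disease": self.table.disease_group,
            "reference": self.table.reference_group,
            "tp": self.table.tp, "fn": self.table.fn,
            "fp": self.table.fp, "tn": self.table.tn,
            "se": self.se, "sp": self.sp, "ppv": self.ppv, "npv": self.npv,
            "ci_se": self.ci_se, "ci_sp": self.ci_sp,
            "ci_ppv": self.ci_ppv, "ci_npv": self.ci_npv,
            "ci_method": self.ci_method,
            "notes": self.notes,
        }


def _ci(count: int, nobs: int, method: str) -> tuple[float, float]:
    sm_method = {"wilson": "wilson", "clopper_pearson": "beta"}[method]
    lo, hi = proportion_confint(count, nobs, alpha=0.05, method=sm_method)
    return float(lo), float(hi)


def diagnostic_metrics(table: ContingencyTable, ci_method: str = "wilson") -> DiagnosticAccuracy:
    """SE/SP/PPV/NPV point estimates with 95% CIs.

    Predictive values are left undefined (None, with a note) when their
    denominator is empty — e.g. a marker that never fires has no PPV.
    """
    if ci_method not in ("wilson", "clopper_pearson"):
        raise ValueError(f"unknown ci_method {ci_method!r}")
    npos, nneg = table.tp + table.fn, table.fp + table.tn
    if npos == 0 or nneg == 0:
        raise ValueError("contingency table has an empty margin")
    notes: list[str] = []
    se, sp = table.tp / npos, table.tn / nneg
    ntest_pos, ntest_neg = table.tp + table.fp, table.tn + table.fn
    if ntest_pos:
        ppv, ci_ppv = table.tp / ntest_pos, _ci(table.tp, ntest_pos, ci_method)
    else:
        ppv, ci_ppv = None, None
        notes.append("PPV undefined: no test-positive samples")
    if ntest_neg:
        npv, ci_npv = table.tn / ntest_neg, _ci(table.tn, ntest_neg, ci_method)
    else:
        npv, ci_npv = None, None
        notes.append("NPV undefined: no test-negative samples")
    return DiagnosticAccuracy(
        se=se, sp=sp, ppv=ppv, npv=npv,
        ci_se=_ci(table.tp, npos, ci_method),
        ci_sp=_ci(table.tn, nneg, ci_method),
        ci_ppv=ci_ppv, ci_npv=ci_npv,
        ci_method=ci_method, table=table, notes=notes,
    )


@dataclass
class PairedSensitivityResult:
    p_value: float
    b: int  # marker_a positive / marker_b negative
    c: int  # marker_a negative / marker_b positive
    note: str = ""


def compare_paired_sensitivity(
    cohort: pd.DataFrame,
    marker_a: str,
    marker_b: str,
    disease: CohortSelector,
) -> PairedSensitivityResult:
    """Exact McNemar comparison of two markers' sensitivity on paired calls.

    Two-sided binomial test on the discordant pairs (b = A+/B-, c = A-/B+)
    among disease samples; with no discordance the markers are
    indistinguishable and p = 1 by convention.
    """
    wide = _calls_wide(validate_cohort(cohort))
    sub = wide.loc[CohortSelector(disease.label, disease.histotypes, disease.site).mask(wide)]
    for m in (marker_a, marker_b):
        if m not in sub.columns or sub[m].isna().any():
            raise ValueError(f"marker {m!r} not called on every disease sample")
    pos_a = sub[marker_a].map(lambda p: call_marker(p).status == "positive")
    pos_b = sub[marker_b].map(lambda p: call_marker(p).status == "positive")
    b = int((pos_a & ~pos_b).sum())
    c = int((~pos_a & pos_b).sum())
    if b + c == 0:
        return PairedSensitivityResult(1.0, 0, 0, note="no discordant pairs")
    both = int((pos_a & pos_b).sum())
    neither = int((~pos_a & ~pos_b).sum())
    res = mcnemar([[both, b], [c, neither]], exact=True)
    return PairedSensitivityResult(float(res.pvalue), b, c)
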