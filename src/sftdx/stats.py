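"""Group comparisons of the target gene on the integrated data.

Compares log2 expression of a single gene between histotype groups on the
DWD-merged matrix: Welch t-test (pooled-variance Student variant available),
Mann-Whitney U, and the fold change 2^(mean_a - mean_b) — the ratio of
geometric means, the natural fold-change dialect for log2 data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dwd import MergedExpressionSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GroupSelector:
    """Sample filter: histotype membership, optionally restricted by site."""

    label: str
    histotypes: tuple[str, ...]
    site: str | None = None

    def mask(self, annotations: pd.DataFrame) -> np.ndarray:
        m = annotations["histotype"].isin(self.histotypes).to_numpy()
        if self.site is not None:
            m &= (annotations["site"] == self.site).to_numpy()
        return m


SFT_HPC = GroupSelector("SFT/HPC", ("SFT", "HPC"))
MENINGIOMA = GroupSelector("meningioma", ("meningioma",))
SYNOVIAL = GroupSelector("synovial_sarcoma", ("synovial_sarcoma",))


@dataclass
class ComparisonResult:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_log2_a: float
    mean_log2_b: float
    fold_change: float
    p_ttest: float
    p_mannwhitney: float
    stratum: str = "all"

    def as_dict(self) -> dict:
        return asdict(self)


def compare_groups(
    merged: MergedExpressionSet,
    gene: str,
    group_a: GroupSelector,
    group_b: GroupSelector,
    stratum: str = "all",
    ttest_variant: str = "welch",
) -> ComparisonResult:
    """Two-group comparison of one gene's log2 expression.

    Welch's unequal-variance t-test by default (``ttest_variant="student"``
    for the pooled-variance form); two-sided Mann-Whitney U (exact when both
    samples are small and tie-free, otherwise normal approximation with tie
    correction); fold change 2^(mean_a - mean_b).
    """
    if gene not in merged.matrix.index:
        raise KeyError(f"gene {gene!r} absent from merged matrix")
    values = merged.matrix.loc[gene]
    a = values[group_a.mask(merged.annotations)].to_numpy(dtype=float)
    b = values[group_b.mask(merged.annotations)].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"groups need >=2 samples each (got {len(a)} {group_a.label!r}, "
            f"{len(b)} {group_b.label!r})"
        )
    t = sps.ttest_ind(a, b, equal_var=(ttest_variant == "student"))
    mw = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    return ComparisonResult(
        group_a=group_a.label,
        group_b=group_b.label,
        n_a=len(a),
        n_b=len(b),
        mean_log2_a=mean_a,
        mean_log2_b=mean_b,
        fold_change=float(2.0 ** (mean_a - mean_b)),
        p_ttest=float(t.pvalue),
        p_mannwhitney=float(mw.pvalue),
        stratum=stratum,
    )


#: the histotype contrasts reported for the target gene
STANDARD_PAIRS: tuple[tuple[GroupSelector, GroupSelector], ...] = (
    (SFT_HPC, MENINGIOMA),
    (SFT_HPC, SYNOVIAL),
    (GroupSelector("SFT", ("SFT",)), GroupSelector("HPC", ("HPC",))),
)


@dataclass
class StratifiedReport:
    comparisons: list[ComparisonResult]
    skipped: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([c.as_dict() for c in self.comparisons])


def site_stratified_report(merged: MergedExpressionSet, gene: str) -> StratifiedReport:
    """All-samples and meningeal-only histotype contrasts, plus the
    meningeal-vs-extrameningeal contrast within SFT/HPC.

    A contrast whose stratum is emptied by filtering is skipped and logged,
    not errored: real compendia rarely cover every stratum.
    """
    comparisons: list[ComparisonResult] = []
    skipped: list[str] = []

    def attempt(a: GroupSelector, b: GroupSelector, stratum: str) -> None:
        try:
            comparisons.append(compare_groups(merged, gene, a, b, stratum=stratum))
        except ValueError as err:
            msg = f"{stratum}: {a.label} vs {b.label} skipped ({err})"
            skipped.append(msg)
            logger.info(msg)

    def meningeal(g: GroupSelector) -> GroupSelector:
        # synovial sarcomas are extrameningeal by nature: the meningeal
        # stratum restricts meningeal tumour groups but keeps them whole
        if "synovial_sarcoma" in g.histotypes:
            return g
        return GroupSelector(g.label, g.histotypes, site="meningeal")

    for a, b in STANDARD_PAIRS:
        attempt(a, b, "all")
    for a, b in STANDARD_PAIRS:
        attempt(meningeal(a), meningeal(b), "meningeal")
    attempt(
        GroupSelector("SFT/HPC meningeal", ("SFT", "HPC"), site="meningeal"),
        GroupSelector("SFT/HPC extrameningeal", ("SFT", "HPC"), site="extrameningeal"),
        "within-SFT/HPC",
    )
    return StratifiedReport(comparisons=comparisons, skipped=skipped)
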