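"""Stability scoring and selection of housekeeping anchor genes.

Batch integration is anchored on genes whose expression is stable both within
and across studies.  For each candidate gene the statistic is the *inter-set
variance of intra-set variances*: compute the unbiased sample variance of the
gene's log2 values within each set, then the variance of those per-set
variances across sets.  A gene that is similarly (un)variable in every study
scores low; the lowest-scoring fraction of candidates is retained.

The retained fraction defaults to 354/451 — the published funnel that keeps
354 of 451 mapped candidates.  The cut-off is a configuration knob because the
underlying rule ("defined by the distribution of variability measurements") is
not a formula; an alternative median + 1 MAD rule is provided.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionSet

logger = logging.getLogger(__name__)

#: default fraction of candidates retained (the 451 -> 354 funnel)
DEFAULT_RETAINED_FRACTION = 354.0 / 451.0


@dataclass(frozen=True)
class StabilityScore:
    """Per-gene stability statistic across sets."""

    gene_id: str
    intra_set_variances: dict[str, float]
    inter_set_variance: float

    @property
    def mean_intra_variance(self) -> float:
        return float(np.mean(list(self.intra_set_variances.values())))


@dataclass
class AnchorGeneSet:
    """Housekeeping genes plus the target gene that anchor DWD integration."""

    housekeeping_ids: list[str]
    target_gene_id: str

    def __post_init__(self) -> None:
        deduped = list(dict.fromkeys(self.housekeeping_ids))
        if len(deduped) != len(self.housekeeping_ids):
            logger.warning(
                "anchor set: %d duplicate housekeeping ids removed",
                len(self.housekeeping_ids) - len(deduped),
            )
            self.housekeeping_ids = deduped
        if self.target_gene_id in self.housekeeping_ids:
            raise ValueError(
                f"target gene {self.target_gene_id!r} also listed as housekeeping"
            )
        if not self.housekeeping_ids:
            logger.warning("anchor set holds only the target gene; integration will "
                           "be driven by a single feature")

    @property
    def gene_ids(self) -> list[str]:
        """All anchor genes: housekeeping plus the target (last)."""
        return [*self.housekeeping_ids, self.target_gene_id]

    def __len__(self) -> int:
        return len(self.housekeeping_ids) + 1


def score_stability(
    sets: list[ExpressionSet], candidates: list[str]
) -> list[StabilityScore]:
    """Score each candidate gene's cross-set expression stability.

    Every candidate must be present in every set (run
    :func:`sftdx.probes.intersect_gene_universe` first) and every set must
    have at least two samples.
    """
    if len(sets) == 1:
        logger.warning("single set: inter-set variance is 0 for every gene (degenerate)")
    for s in sets:
        if s.n_samples < 2:
            raise ValueError(f"set {s.set_id!r} has <2 samples; variance undefined")
        missing = set(candidates) - set(s.matrix.index)
        if missing:
            raise ValueError(
                f"candidates absent from set {s.set_id!r}: {sorted(missing)[:5]}"
            )
    per_set = {
        s.set_id: s.matrix.loc[candidates].var(axis=1, ddof=1) for s in sets
    }
    intra = pd.DataFrame(per_set)  # genes x sets
    inter = intra.var(axis=1, ddof=1) if intra.shape[1] > 1 else pd.Series(0.0, index=intra.index)
    return [
        StabilityScore(
            gene_id=g,
            intra_set_variances={sid: float(intra.at[g, sid]) for sid in intra.columns},
            inter_set_variance=float(inter[g]),
        )
        for g in candidates
    ]


def select_housekeeping(
    scores: list[StabilityScore],
    retained_fraction: float = DEFAULT_RETAINED_FRACTION,
) -> list[str]:
    """Retain the ``floor(fraction * n)`` most stable candidate genes.

    Ranking is by inter-set variance, with boundary ties broken by smaller
    mean intra-set variance and then gene id, so selection is deterministic
    and monotone in the fraction.
    """
    if not scores:
        raise ValueError("no stability scores supplied")
    if not 0 < retained_fraction <= 1:
        raise ValueError("retained_fraction must be in (0, 1]")
    k = math.floor(retained_fraction * len(scores))
    ranked = sorted(
        scores,
        key=lambda s: (s.inter_set_variance, s.mean_intra_variance, s.gene_id),
    )
    return [s.gene_id for s in ranked[:k]]


def select_housekeeping_mad(scores: list[StabilityScore]) -> list[str]:
    """Alternative rule: retain genes with inter-set variance below
    median + 1 MAD of the score distribution."""
    if not scores:
        raise ValueError("no stability scores supplied")
    v = np.array([s.inter_set_variance for s in scores])
    cut = np.median(v) + np.median(np.abs(v - np.median(v)))
    keep = sorted(
        (s for s in scores if s.inter_set_variance <= cut),
        key=lambda s: (s.inter_set_variance, s.mean_intra_variance, s.gene_id),
    )
    return [s.gene_id for s in keep]


def build_anchor_set(housekeeping: list[str], target_gene_id: str) -> AnchorGeneSet:
    """Anchor genes = selected housekeeping genes plus the target gene.

    The target is carried through integration (so its expression is adjusted
    consistently) but flagged apart so stability reports exclude it.
    """
    return AnchorGeneSet(housekeeping_ids=list(housekeeping), target_gene_id=target_gene_id)


def write_stability_report(
    scores: list[StabilityScore], selected: list[str], path
) -> None:
    sel = set(selected)
    rows = []
    for s in scores:
        row = {"gene_id": s.gene_id}
        row.update({f"var_{k}": v for k, v in s.intra_set_variances.items()})
        row["inter_set_variance"] = s.inter_set_variance
        row["selected"] = s.gene_id in sel
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")
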