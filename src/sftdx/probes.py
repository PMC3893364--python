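"""Collapse probe-level matrices to one row per EntrezGene.

Cross-platform integration requires a common gene universe.  Probes are mapped
to EntrezGene identifiers; where several probes represent one gene, the
redundancy rules are:

1. On Affymetrix platforms, restrict candidates to the best available probe-set
   extension class, preferring ``_at`` over ``s_at`` over every other
   extension (``_at`` probe sets are the most gene-specific by design).
2. Among the remaining candidates keep the probe with the highest unbiased
   sample variance of its log2 values in that data set; exact-variance ties
   break lexicographically by probe id so collapsing is deterministic.

On non-Affymetrix platforms (e.g. spotted cDNA arrays, where extensions do not
exist) the variance rule alone decides.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .expression import AFFYMETRIX_PLATFORMS, ExpressionSet

logger = logging.getLogger(__name__)

EXTENSIONS = ("_at", "s_at", "other", "na")
# lower = preferred; "na" (non-Affymetrix) never competes on extension
EXTENSION_RANK = {"_at": 0, "s_at": 1, "other": 2, "na": 0}


@dataclass(frozen=True)
class ProbeAnnotation:
    """One probe-to-gene mapping row."""

    probe_id: str
    entrez_gene_id: str
    platform: str
    extension: str = "na"

    def __post_init__(self) -> None:
        if self.extension not in EXTENSIONS:
            raise ValueError(f"unknown extension {self.extension!r}")
        if self.platform not in AFFYMETRIX_PLATFORMS and self.extension != "na":
            raise ValueError(
                f"probe {self.probe_id}: extension must be 'na' on platform {self.platform}"
            )


def annotations_to_frame(annots: list[ProbeAnnotation]) -> pd.DataFrame:
    df = pd.DataFrame([a.__dict__ for a in annots])
    dup = df.duplicated(subset=["probe_id", "platform"])
    if dup.any():
        raise ValueError(
            "duplicate probe annotations (a probe may map to only one gene): "
            f"{df.loc[dup, 'probe_id'].tolist()[:5]}"
        )
    return df.set_index("probe_id")


def read_probe_annotations(path: str | Path) -> list[ProbeAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    annots = [
        ProbeAnnotation(r.probe_id, r.entrez_gene_id, r.platform, r.extension)
        for r in df.itertuples(index=False)
    ]
    annotations_to_frame(annots)  # duplicate check
    return annots


def write_probe_annotations(annots: list[ProbeAnnotation], path: str | Path) -> None:
    pd.DataFrame([a.__dict__ for a in annots]).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


@dataclass
class GeneExpressionSet(ExpressionSet):
    """Expression set keyed by gene id, with probe provenance.

    ``provenance`` maps gene_id -> {"probe_id": winner, "n_candidates": k}.
    """


def collapse_probes(eset: ExpressionSet, annots: list[ProbeAnnotation]) -> GeneExpressionSet:
    """Collapse a probe-level set to one row per EntrezGene.

    Unannotated or unmappable probes are dropped with a logged warning and
    counted in the provenance under the ``"_dropped"`` key.
    """
    if eset.n_samples < 2:
        raise ValueError("collapse_probes needs >=2 samples for variance to be defined")
    adf = annotations_to_frame([a for a in annots if a.platform == eset.platform])

    probe_ids = eset.matrix.index
    known = probe_ids.isin(adf.index)
    n_dropped = int((~known).sum())
    if n_dropped:
        logger.warning(
            "set %s: dropping %d unannotated probes (e.g. %s)",
            eset.set_id, n_dropped, list(probe_ids[~known][:3]),
        )
    matrix = eset.matrix.loc[known]
    info = adf.loc[matrix.index]
    mappable = info["entrez_gene_id"].notna() & (info["entrez_gene_id"] != "")
    n_dropped += int((~mappable).sum())
    matrix, info = matrix.loc[mappable.to_numpy()], info.loc[mappable.to_numpy()]

    variances = matrix.var(axis=1, ddof=1)
    is_affy = eset.platform in AFFYMETRIX_PLATFORMS

    table = pd.DataFrame(
        {
            "gene": info["entrez_gene_id"].to_numpy(),
            "ext_rank": info["extension"].map(EXTENSION_RANK).to_numpy() if is_affy else 0,
            "variance": variances.to_numpy(),
            "probe_id": matrix.index.to_numpy(),
        }
    )
    # extension class first, then highest variance, then probe id
    table = table.sort_values(
        ["gene", "ext_rank", "variance", "probe_id"],
        ascending=[True, True, False, True],
        kind="stable",
    )
    winners = table.groupby("gene", sort=True).first()
    n_cands = table.groupby("gene", sort=True).size()

    out = matrix.loc[winners["probe_id"]]
    out.index = winners.index.rename("entrez_gene_id")
    provenance = {
        g: {"probe_id": row["probe_id"], "n_candidates": int(n_cands[g])}
        for g, row in winners.iterrows()
    }
    provenance["_dropped"] = n_dropped
    return GeneExpressionSet(
        matrix=out,
        set_id=eset.set_id,
        platform=eset.platform,
        annotations=eset.annotations,
        is_log2=eset.is_log2,
        provenance=provenance,
    )


def write_provenance_tsv(gset: GeneExpressionSet, path: str | Path) -> None:
    rows = [
        {"gene_id": g, "chosen_probe": v["probe_id"], "n_candidates": v["n_candidates"]}
        for g, v in gset.provenance.items()
        if g != "_dropped"
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


class RequiredGeneMissing(ValueError):
    """A gene required for the analysis is absent from at least one set."""


def intersect_gene_universe(
    sets: list[ExpressionSet], required: list[str] | None = None
) -> list[str]:
    """Genes present in every set, sorted; raises if a required gene is absent.

    ``required`` names the genes without which the analysis cannot proceed
    (typically the target gene); the error identifies the offending set.
    """
    if len(sets) < 2:
        raise ValueError("need >=2 sets to intersect")
    for gene in required or []:
        for s in sets:
            if gene not in s.matrix.index:
                raise RequiredGeneMissing(
                    f"required gene {gene!r} is absent from set {s.set_id!r}"
                )
    common = set(sets[0].matrix.index)
    for s in sets[1:]:
        common &= set(s.matrix.index)
    return sorted(common)
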