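"""Expression-set container and tab-delimited I/O.

An :class:`ExpressionSet` is one study's log2 expression matrix (features in
rows, samples in columns) together with its set identifier, array platform and
per-sample annotations (histotype, anatomical site).  All downstream stages —
quantile normalization, probe collapsing, housekeeping selection and DWD batch
integration — consume and produce this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

HISTOTYPES = ("SFT", "HPC", "meningioma", "synovial_sarcoma")
SITES = ("meningeal", "extrameningeal")

PLATFORMS = ("affymetrix_u133a", "affymetrix_u133plus2", "cdna_array", "generic")
AFFYMETRIX_PLATFORMS = ("affymetrix_u133a", "affymetrix_u133plus2")


@dataclass
class ExpressionSet:
    """Log2 expression matrix for one study plus sample annotations.

    Parameters
    ----------
    matrix
        Features x samples, index = probe or gene identifiers, columns =
        sample identifiers, values on log2 scale when ``is_log2`` is True.
    set_id
        Study / batch identifier.
    platform
        One of ``PLATFORMS``.
    annotations
        One row per sample (index = sample id) with at least columns
        ``histotype`` and ``site``; a ``set_id`` column is added if absent.
    is_log2
        Whether values are already log2-transformed.
    """

    matrix: pd.DataFrame
    set_id: str
    platform: str
    annotations: pd.DataFrame
    is_log2: bool = True
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise ValueError(
                f"unknown platform {self.platform!r}; expected one of {PLATFORMS}"
            )
        if self.matrix.isna().any().any():
            raise ValueError(f"set {self.set_id!r}: matrix contains missing values")
        if "set_id" not in self.annotations.columns:
            self.annotations = self.annotations.assign(set_id=self.set_id)
        missing = set(self.matrix.columns) - set(self.annotations.index)
        if missing:
            raise ValueError(
                f"set {self.set_id!r}: samples without annotations: {sorted(missing)[:5]}"
            )
        # keep annotations aligned to matrix columns
        self.annotations = self.annotations.loc[list(self.matrix.columns)]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    @property
    def feature_ids(self) -> pd.Index:
        return self.matrix.index

    def copy_with(self, **kwargs) -> "ExpressionSet":
        return replace(self, **kwargs)


def read_expression_tsv(
    path: str | Path,
    annotations: pd.DataFrame,
    set_id: str,
    platform: str,
    is_log2: bool = True,
) -> ExpressionSet:
    """Read a matrix TSV (first column = feature id, one column per sample)."""
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    ann = annotations.loc[annotations["set_id"] == set_id] if "set_id" in annotations else annotations
    return ExpressionSet(matrix=matrix, set_id=set_id, platform=platform,
                         annotations=ann, is_log2=is_log2)


def write_expression_tsv(eset: ExpressionSet, path: str | Path) -> None:
    eset.matrix.to_csv(path, sep="\t", index_label="feature_id", lineterminator="\n")


def read_sample_annotations(path: str | Path) -> pd.DataFrame:
    """Read the sample-annotation TSV (sample_id, set_id, platform, histotype, site)."""
    ann = pd.read_csv(path, sep="\t", index_col="sample_id", dtype=str)
    bad = set(ann["histotype"]) - set(HISTOTYPES)
    if bad:
        raise ValueError(f"unknown histotype labels: {sorted(bad)}")
    return ann


def write_sample_annotations(ann: pd.DataFrame, path: str | Path) -> None:
    ann.to_csv(path, sep="\t", index_label="sample_id", lineterminator="\n")
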