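"""Within-set quantile normalization of processed log2 matrices.

Each study's matrix is normalized so that every sample (column) shares one
empirical distribution: the rank-wise mean of the sorted columns.  Ties within
a column receive the mean of the reference values spanning their tied ranks
(the common "ties = average" dialect).  Quantile normalization is applied
per set, before probe collapsing and DWD; it equalizes within-set sample
distributions but deliberately leaves between-set offsets in place for the
batch-integration stage to remove.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .expression import ExpressionSet

# values above this on a matrix flagged log2 are taken as evidence the data
# are really on the linear scale (log2 microarray intensities top out ~16)
LINEAR_SCALE_THRESHOLD = 30.0


def ensure_log2(eset: ExpressionSet, threshold: float = LINEAR_SCALE_THRESHOLD) -> ExpressionSet:
    """Guarantee log2 scale: apply log2(x + 1) to linear-scale input.

    Raises if the set is flagged log2 but contains values exceeding
    ``threshold`` (a mis-declared linear-scale matrix), or if a declared
    linear-scale matrix holds negative values (log undefined).
    """
    if eset.is_log2:
        if (eset.matrix.to_numpy() > threshold).any():
            raise ValueError(
                f"set {eset.set_id!r} is flagged log2 but holds values > {threshold}; "
                "likely linear-scale data"
            )
        return eset
    if (eset.matrix.to_numpy() < 0).any():
        raise ValueError(f"set {eset.set_id!r}: negative values on declared linear scale")
    return eset.copy_with(matrix=np.log2(eset.matrix + 1.0), is_log2=True)


def quantile_normalize(eset: ExpressionSet) -> ExpressionSet:
    """Force every column of the set onto the mean empirical distribution.

    After the transform all columns have identical sorted value vectors —
    the across-column mean of per-rank values — while each column's internal
    rank order is preserved.
    """
    if not eset.is_log2:
        raise ValueError("quantile_normalize expects log2 data; call ensure_log2 first")
    X = eset.matrix.to_numpy(dtype=float)
    if X.shape[1] < 1:
        raise ValueError("matrix has no samples")
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        vals = np.empty_like(reference)
        vals[order] = reference
        # tied input values receive the mean of the reference values
        # spanning their tied ranks
        tied = pd.DataFrame({"v": col, "q": vals})
        out[:, j] = tied.groupby("v")["q"].transform("mean").to_numpy()
    matrix = pd.DataFrame(out, index=eset.matrix.index, columns=eset.matrix.columns)
    return eset.copy_with(matrix=matrix)
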