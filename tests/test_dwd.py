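import numpy as np
import pandas as pd
import pytest

from sftdx.dwd import (
    MergedExpressionSet,
    adjust_batch_pair,
    fit_dwd,
    merge_all,
    pca_batch_check,
)
from sftdx.housekeeping import build_anchor_set

from conftest import make_eset


def _merged(values, set_id, genes=None):
    eset = make_eset(np.asarray(values, dtype=float), set_id=set_id,
                     features=genes)
    return MergedExpressionSet(matrix=eset.matrix, annotations=eset.annotations)


# ---------------------------------------------------------------------------
# fit_dwd
# ---------------------------------------------------------------------------

def test_one_dimensional_classes_give_unit_weight():
    X = np.array([[-1.0, -1.0, 1.0, 1.0]])
    labels = np.array(["a", "a", "b", "b"])
    d = fit_dwd(X, labels)
    assert abs(abs(d.weights[0]) - 1.0) < 1e-8
    pa = d.per_batch_mean_projection["a"]
    pb = d.per_batch_mean_projection["b"]
    assert np.isclose(pa + pb, 0.0, atol=1e-6)  # symmetric about the midpoint


def test_separating_axis_dominates_noise_axis():
    rng = np.random.default_rng(0)
    n = 10
    X = np.vstack([
        np.concatenate([np.full(n, -2.0), np.full(n, 2.0)]) + rng.normal(0, 0.05, 2 * n),
        rng.normal(0, 0.05, 2 * n),
    ])
    labels = np.array(["a"] * n + ["b"] * n)
    d = fit_dwd(X, labels)
    assert abs(d.weights[0]) > 0.99
    assert d.converged


def test_duplicating_samples_leaves_direction_unchanged():
    rng = np.random.default_rng(1)
    X = rng.normal(0, 1, (3, 12)) + np.outer([1.0, 0.5, -0.5],
                                             np.repeat([1.0, -1.0], 6))
    labels = np.array(["a"] * 6 + ["b"] * 6)
    d1 = fit_dwd(X, labels, penalty=5.0)
    d2 = fit_dwd(np.hstack([X, X]), np.concatenate([labels, labels]), penalty=5.0)
    sign = np.sign(d1.weights @ d2.weights)
    np.testing.assert_allclose(d1.weights, sign * d2.weights, atol=1e-5)


def test_unit_norm_invariant_over_random_instances():
    rng = np.random.default_rng(2)
    for _ in range(8):
        n, d = int(rng.integers(6, 24)), int(rng.integers(1, 6))
        X = rng.normal(0, 1, (d, n))
        labels = np.array(["a"] * (n // 2) + ["b"] * (n - n // 2))
        fit = fit_dwd(X, labels)
        assert abs(np.linalg.norm(fit.weights) - 1.0) < 1e-8


def test_single_class_rejected():
    with pytest.raises(ValueError, match="two batch labels"):
        fit_dwd(np.zeros((2, 4)), ["a", "a", "a", "a"])
    with pytest.raises(ValueError, match="fewer than 2"):
        fit_dwd(np.zeros((2, 4)), ["a", "a", "a", "b"])


# ---------------------------------------------------------------------------
# adjustment and merging
# ---------------------------------------------------------------------------

def test_identical_batches_need_no_shift():
    rng = np.random.default_rng(3)
    base = rng.normal(8, 1, (4, 6))
    a, b = _merged(base, "A"), _merged(base, "B")
    d = fit_dwd(np.hstack([a.matrix, b.matrix]), ["A"] * 6 + ["B"] * 6)
    out = adjust_batch_pair(a, b, d)
    assert out.adjustment_log[-1]["shift_magnitude"] < 1e-6
    np.testing.assert_allclose(out.matrix.to_numpy(), np.hstack([base, base]),
                               atol=1e-6)


def test_pure_offset_removed_exactly():
    # at zero within-batch noise the DWD direction aligns with the offset
    # vector, so the midpoint translation removes the offset in closed form
    rng = np.random.default_rng(4)
    point = rng.normal(8, 1, (5, 1))
    eps = 1e-9 * rng.standard_normal((5, 8))
    base = np.tile(point, (1, 8)) + eps
    delta = 2.5
    a, b = _merged(base, "A"), _merged(base + delta, "B")
    d = fit_dwd(np.hstack([a.matrix, b.matrix]), ["A"] * 8 + ["B"] * 8)
    out = adjust_batch_pair(a, b, d)
    X = out.matrix.to_numpy()
    mean_a, mean_b = X[:, :8].mean(axis=1), X[:, 8:].mean(axis=1)
    np.testing.assert_allclose(mean_a, mean_b, atol=1e-6)
    # within-batch centered structure untouched (exactly: a pure translation)
    np.testing.assert_allclose(
        X[:, :8] - X[:, :8].mean(axis=1, keepdims=True),
        base - base.mean(axis=1, keepdims=True), atol=1e-12)


def test_noisy_offset_mean_gap_along_direction_closed():
    # with real within-batch noise the translation closes the batch-mean gap
    # along the fitted direction and changes nothing orthogonal to it
    rng = np.random.default_rng(14)
    base = rng.normal(8, 1, (5, 8))
    a, b = _merged(base, "A"), _merged(base + 2.5, "B")
    d = fit_dwd(np.hstack([a.matrix, b.matrix]), ["A"] * 8 + ["B"] * 8)
    out = adjust_batch_pair(a, b, d)
    X = out.matrix.to_numpy()
    gap = X[:, :8].mean(axis=1) - X[:, 8:].mean(axis=1)
    assert abs(gap @ d.weights) < 1e-9
    orth_before = (base + 2.5) - np.outer(d.weights, d.weights @ (base + 2.5))
    orth_after = X[:, 8:] - np.outer(d.weights, d.weights @ X[:, 8:])
    np.testing.assert_allclose(orth_after, orth_before, atol=1e-9)


def test_histotype_labels_do_not_drive_adjustment():
    rng = np.random.default_rng(5)
    base = rng.normal(8, 1, (4, 6))
    a = _merged(base, "A")
    b1 = _merged(base + 1.0, "B")
    b2 = _merged(base + 1.0, "B")
    b2.annotations = b2.annotations.assign(
        histotype=rng.permutation(b2.annotations["histotype"].to_numpy()))
    d = fit_dwd(np.hstack([a.matrix, b1.matrix]), ["A"] * 6 + ["B"] * 6)
    out1 = adjust_batch_pair(a, b1, d)
    out2 = adjust_batch_pair(a, b2, d)
    np.testing.assert_allclose(out1.matrix.to_numpy(), out2.matrix.to_numpy())


def _zero_noise_sets(offsets, genes=6, n=5):
    rng = np.random.default_rng(6)
    base = rng.normal(8, 1, (genes, 1))
    sets = []
    for sid, off in offsets.items():
        values = np.tile(base, (1, n)) + off + rng.normal(0, 1e-12, (genes, n))
        sets.append(make_eset(values, set_id=sid,
                              features=[f"HK{i}" for i in range(genes - 1)] + ["T"]))
    return sets


def test_merge_all_step_count_and_log():
    sets = _zero_noise_sets({"A": 0.0, "B": 1.0})
    anchor = build_anchor_set([f"HK{i}" for i in range(5)], "T")
    merged = merge_all(sets, anchor)
    assert len(merged.adjustment_log) == 1
    sets5 = _zero_noise_sets({"A": 0.0, "B": 1.0, "C": -2.0, "D": 3.0, "E": 0.5})
    merged5 = merge_all(sets5, anchor)
    assert len(merged5.adjustment_log) == 4
    assert merged5.n_samples == 25


def test_zero_noise_offsets_telescope_away():
    sets = _zero_noise_sets({"A": 0.0, "B": 2.0, "C": -3.5, "D": 4.0})
    anchor = build_anchor_set([f"HK{i}" for i in range(5)], "T")
    merged = merge_all(sets, anchor)
    means = merged.matrix.T.groupby(merged.annotations["set_id"]).mean()
    for g in merged.matrix.index:
        assert means[g].max() - means[g].min() < 1e-6


def test_explicit_merge_order_and_validation():
    sets = _zero_noise_sets({"A": 0.0, "B": 1.0, "C": 2.0})
    anchor = build_anchor_set([f"HK{i}" for i in range(5)], "T")
    merged = merge_all(sets, anchor, order=["C", "A", "B"])
    assert merged.adjustment_log[0]["adjusted_batch"] == "A"
    with pytest.raises(ValueError, match="every set id"):
        merge_all(sets, anchor, order=["C", "A"])
    with pytest.raises(ValueError, match="anchor genes"):
        merge_all(sets, build_anchor_set(["NOPE"], "T"), order=["C", "A", "B"])


def test_gene_universe_mismatch_rejected():
    a = _merged(np.zeros((2, 3)), "A", genes=["G1", "G2"])
    b = _merged(np.zeros((2, 3)), "B", genes=["G1", "G3"])
    d = fit_dwd(np.random.default_rng(0).normal(0, 1, (2, 6)),
                ["A"] * 3 + ["B"] * 3)
    with pytest.raises(ValueError, match="mismatch"):
        adjust_batch_pair(a, b, d)


# ---------------------------------------------------------------------------
# PCA batch check
# ---------------------------------------------------------------------------

def test_silhouette_high_before_and_low_after_adjustment():
    rng = np.random.default_rng(7)
    base = rng.normal(8, 1, (10, 1))
    sets = []
    for sid, off in {"A": 0.0, "B": 4.0}.items():
        values = np.tile(base, (1, 8)) + off + rng.normal(0, 0.2, (10, 8))
        sets.append(make_eset(values, set_id=sid,
                              features=[f"HK{i}" for i in range(9)] + ["T"]))
    anchor = build_anchor_set([f"HK{i}" for i in range(9)], "T")
    before = merge_all(sets, anchor, skip_adjustment=True)
    after = merge_all(sets, anchor)
    rep_before = pca_batch_check(before)
    rep_after = pca_batch_check(after)
    assert rep_before.silhouette > 0.8 and rep_before.mixed is False
    assert rep_after.silhouette < 0.25 and rep_after.mixed is True


def test_single_batch_mixing_not_applicable():
    m = _merged(np.random.default_rng(8).normal(0, 1, (4, 6)), "A")
    rep = pca_batch_check(m)
    assert rep.silhouette is None and rep.mixed is None


def test_pca_needs_enough_samples():
    m = _merged(np.random.default_rng(9).normal(0, 1, (4, 2)), "A")
    with pytest.raises(ValueError, match="samples"):
        pca_batch_check(m)
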