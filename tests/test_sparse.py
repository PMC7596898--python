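"""Dictionary construction and the L1 coding / minimum-residual classifier.

Independent oracles: an exact basis-pursuit linear program (scipy linprog)
and exhaustive support enumeration with least-squares refits.
"""

import numpy as np
import pytest
from scipy.optimize import linprog

import sparsebci as sb
from sparsebci.csp import FeatureVector


def bp_linprog(A, y):
    """Exact basis pursuit min ||x||_1 s.t. Ax = y as a linear program."""
    m, N = A.shape
    res = linprog(
        np.ones(2 * N), A_eq=np.hstack([A, -A]), b_eq=y,
        bounds=[(0, None)] * (2 * N), method="highs",
    )
    assert res.status == 0
    return res.x[:N] - res.x[N:], res.x.sum()


def identity_dictionary():
    return sb.Dictionary(np.eye(4), [1, 1, 2, 2])


# ---------------------------------------------------------------------------
# dictionary construction
# ---------------------------------------------------------------------------


def test_dictionary_grouping_and_normalization(rng):
    feats = [FeatureVector(rng.normal(size=32), 2) for _ in range(140)]
    feats += [FeatureVector(rng.normal(size=32), 1) for _ in range(140)]
    d = sb.build_dictionary(feats)
    assert d.A.shape == (32, 280)
    assert list(d.column_classes[:140]) == [1] * 140
    assert list(d.column_classes[140:]) == [2] * 140
    np.testing.assert_allclose(np.linalg.norm(d.A, axis=0), 1.0, atol=1e-12)


def test_dictionary_minimal_and_missing_class(rng):
    d = sb.build_dictionary([FeatureVector([1.0, 2.0], 1), FeatureVector([3.0, 1.0], 2)])
    assert d.A.shape == (2, 2)
    with pytest.raises(ValueError):
        sb.build_dictionary([FeatureVector([1.0, 2.0], None)])


# ---------------------------------------------------------------------------
# L1 solving
# ---------------------------------------------------------------------------


def test_training_atom_recovers_itself_exactly():
    d = identity_dictionary()
    code = sb.solve_l1(d, np.array([0.0, 1.0, 0.0, 0.0]), epsilon=0.0)
    np.testing.assert_array_equal(code.x_hat, [0, 1, 0, 0])
    np.testing.assert_allclose(code.residuals, [0.0, 1.0], atol=1e-12)
    assert code.predicted_class == 1


def test_class2_span_vector():
    d = identity_dictionary()
    code = sb.solve_l1(d, np.array([0.0, 0.0, 0.6, 0.8]), epsilon=0.0)
    np.testing.assert_allclose(code.x_hat, [0, 0, 0.6, 0.8], atol=1e-10)
    np.testing.assert_allclose(code.residuals, [1.0, 0.0], atol=1e-10)
    assert code.predicted_class == 2


def test_zero_input_gives_zero_code():
    d = identity_dictionary()
    code = sb.solve_l1(d, np.zeros(4), epsilon=0.0)
    assert np.all(code.x_hat == 0)
    assert code.l1_norm == 0.0


def test_dimension_mismatch_rejected():
    with pytest.raises(ValueError):
        sb.solve_l1(identity_dictionary(), np.ones(3))


@pytest.mark.parametrize("eps", [1e-8, 0.05])
def test_objective_matches_linprog_oracle(rng, eps):
    """On small random dictionaries the solver's L1 objective matches the
    exact LP solution of the equality-constrained problem (for loose eps the
    solver may only do better)."""
    for _ in range(10):
        A = rng.normal(size=(6, 14))
        A /= np.linalg.norm(A, axis=0)
        supp = rng.choice(14, 2, replace=False)
        x0 = np.zeros(14)
        x0[supp] = rng.normal(size=2) + np.sign(rng.normal(size=2))
        y = A @ x0
        d = sb.Dictionary(A, [1] * 7 + [2] * 7)
        code = sb.solve_l1(d, y, epsilon=eps)
        _, lp_obj = bp_linprog(A, y)
        assert code.l1_norm <= lp_obj + 1e-4
        if eps <= 1e-8:
            assert abs(code.l1_norm - lp_obj) < 1e-4


def test_delta_partition_sums_to_code(rng):
    A = rng.normal(size=(6, 12))
    A /= np.linalg.norm(A, axis=0)
    d = sb.Dictionary(A, [1] * 6 + [2] * 6)
    y = rng.normal(size=6)
    code = sb.solve_l1(d, y)
    parts = [np.where(d.column_classes == c, code.x_hat, 0.0) for c in d.classes]
    np.testing.assert_array_equal(sum(parts), code.x_hat)


def test_homogeneity_in_y(rng):
    A = rng.normal(size=(6, 12))
    A /= np.linalg.norm(A, axis=0)
    d = sb.Dictionary(A, [1] * 6 + [2] * 6)
    y = rng.normal(size=6)
    c = 3.7
    code1 = sb.solve_l1(d, y, epsilon=0.01)
    code2 = sb.solve_l1(d, c * y, epsilon=0.01 * c)
    np.testing.assert_allclose(code2.x_hat, c * code1.x_hat, atol=1e-5)
    assert code1.predicted_class == code2.predicted_class


def test_sparsity_monotone_in_epsilon(rng):
    A = rng.normal(size=(8, 16))
    A /= np.linalg.norm(A, axis=0)
    d = sb.Dictionary(A, [1] * 8 + [2] * 8)
    y = rng.normal(size=8)
    l1 = [sb.solve_l1(d, y, epsilon=e).l1_norm for e in (0.5, 0.1, 0.01, 1e-6)]
    for a, b in zip(l1, l1[1:]):
        assert b >= a - 1e-6  # tighter constraint never loosens the L1 norm


# ---------------------------------------------------------------------------
# classification and code matrices
# ---------------------------------------------------------------------------


def test_training_atoms_self_classify(rng):
    X = rng.normal(size=(20, 8))
    feats = [FeatureVector(v, 1 + (i % 2)) for i, v in enumerate(X)]
    d = sb.build_dictionary(feats)
    out = sb.classify_src(d, feats)
    assert all(p == f.label for (p, _), f in zip(out, feats))


def test_empty_test_list():
    assert sb.classify_src(identity_dictionary(), []) == []
    assert sb.sparse_features(identity_dictionary(), []).shape == (0, 4)


def test_src_accuracy_on_separated_gaussians(rng):
    """Well-separated (orthogonal) class means: held-out SRC accuracy should
    be high.  Antipodal means would not qualify — signed sparse coding
    reconstructs them equally well with either class's atoms."""
    m = 8
    mu1 = np.array([2.0, 0.0] * (m // 2))
    mu2 = np.array([0.0, 2.0] * (m // 2))
    train = [FeatureVector(mu1 + 0.5 * rng.normal(size=m), 1) for _ in range(50)]
    train += [FeatureVector(mu2 + 0.5 * rng.normal(size=m), 2) for _ in range(50)]
    test = [FeatureVector(mu1 + 0.5 * rng.normal(size=m), 1) for _ in range(50)]
    test += [FeatureVector(mu2 + 0.5 * rng.normal(size=m), 2) for _ in range(50)]
    d = sb.build_dictionary(train)
    out = sb.classify_src(d, test)
    acc = np.mean([p == f.label for (p, _), f in zip(out, test)])
    assert acc >= 0.9


def test_sparse_feature_matrix_shape_and_identity_rows():
    d = identity_dictionary()
    feats = [FeatureVector(row, None) for row in np.eye(4)]
    codes = sb.sparse_features(d, feats, epsilon=0.0)
    np.testing.assert_allclose(codes, np.eye(4), atol=1e-10)


def test_leave_one_out_masks_own_column(rng):
    X = rng.normal(size=(10, 6))
    feats = [FeatureVector(v, 1 + (i % 2)) for i, v in enumerate(X)]
    d = sb.build_dictionary(feats)
    from sparsebci.evaluation import _atom_columns

    cols = _atom_columns([f.label for f in feats])
    codes = sb.sparse_features(d, feats, exclude_columns=cols)
    assert codes.shape == (10, 10)
    for s, c in enumerate(cols):
        assert codes[s, c] == 0.0
    # without masking, each atom codes itself perfectly instead
    codes_self = sb.sparse_features(d, feats, epsilon=1e-10)
    for s, c in enumerate(cols):
        assert abs(codes_self[s, c]) > 0.9
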