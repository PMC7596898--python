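"""CSP fitting against analytic and library oracles; feature contracts."""

import warnings

import numpy as np
import pytest

import sparsebci as sb
from sparsebci.io import Epoch, EpochSet


def epoch_with_cov(C, label, fs=100.0):
    """Epoch whose sample second-moment matrix is exactly C (up to scale)."""
    Q = np.array([[1, 1, -1, -1], [1, -1, 1, -1]], float)  # orthogonal rows
    L = np.linalg.cholesky(C)
    return Epoch(L @ Q, label, fs)


@pytest.fixture()
def analytic_pair():
    return EpochSet(
        [epoch_with_cov(np.diag([4.0, 1.0]), 1), epoch_with_cov(np.diag([1.0, 4.0]), 2)],
        100.0,
    )


def test_analytic_eigenvalues(analytic_pair):
    # trace-normalized covariances diag(.8,.2) and diag(.2,.8): the
    # generalized eigenvalues of (C1, C1+C2) are exactly 0.8 and 0.2
    m = sb.fit_csp(analytic_pair, 2)
    np.testing.assert_allclose(m.eigenvalues, [0.8, 0.2], atol=1e-6)


def test_joint_diagonalization_and_normalization(analytic_pair):
    m = sb.fit_csp(analytic_pair, 2)
    C1 = np.diag([4.0, 1.0]) / 5.0
    C2 = np.diag([1.0, 4.0]) / 5.0
    W = m.filters
    D1, D2 = W @ C1 @ W.T, W @ C2 @ W.T
    assert abs(D1[0, 1]) < 1e-6 and abs(D2[0, 1]) < 1e-6
    np.testing.assert_allclose(np.diag(D1 + D2), 1.0, atol=1e-8)
    # per-filter class-1 and class-2 fractions pair to one
    np.testing.assert_allclose(np.diag(D1) + np.diag(D2), 1.0, atol=1e-8)


def test_symmetric_classes_give_half_eigenvalues(rng):
    epochs = [
        Epoch(rng.normal(size=(4, 200)), 1 + (i % 2), 100.0) for i in range(40)
    ]
    m = sb.fit_csp(EpochSet(epochs, 100.0), 4)
    assert np.all(np.abs(m.eigenvalues - 0.5) < 0.12)


def test_single_class_rejected(rng):
    epochs = [Epoch(rng.normal(size=(3, 100)), 1, 100.0) for _ in range(4)]
    with pytest.raises(ValueError, match="two classes"):
        sb.fit_csp(EpochSet(epochs, 100.0), 2)


def test_cross_check_against_mne(high_snr_epochs):
    """Independent oracle: mne's CSP fitted on the same epochs yields the
    same filter directions (up to sign and ordering)."""
    mne = pytest.importorskip("mne")
    es, _ = high_snr_epochs
    ours = sb.fit_csp(es, 4)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mcsp = mne.decoding.CSP(
            n_components=4, norm_trace=True, transform_into="csp_space",
            component_order="mutual_info",
        )
        mcsp.fit(es.to_array(), es.labels)
    W_m = mcsp.filters_[:4]
    for w in ours.filters:
        cos = np.abs(W_m @ w) / (np.linalg.norm(W_m, axis=1) * np.linalg.norm(w))
        assert cos.max() > 0.99


def test_feature_normalization_identity(high_snr_epochs):
    es, _ = high_snr_epochs
    m = sb.fit_csp(es, 6)
    f = sb.csp_features(m, es.epochs[0])
    assert abs(np.exp(f.values).sum() - 1.0) < 1e-10
    assert f.label == es.epochs[0].label


def test_rank_one_epoch_maximizes_matching_feature(high_snr_epochs):
    es, _ = high_snr_epochs
    m = sb.fit_csp(es, 4)
    # signal living entirely along filter 0's pattern direction
    pattern = m.patterns[:, 0]
    data = np.outer(pattern, np.sin(2 * np.pi * 10 * np.arange(300) / 100.0))
    f = sb.csp_features(m, Epoch(data, 1, 100.0))
    assert np.argmax(f.values) == 0


def test_degenerate_epoch_rejected(high_snr_epochs):
    es, _ = high_snr_epochs
    m = sb.fit_csp(es, 4)
    with pytest.raises(ValueError, match="degenerate"):
        sb.csp_features(m, Epoch(np.zeros((es.n_channels, 300)), 1, 100.0))


def test_scale_invariance(high_snr_epochs):
    es, _ = high_snr_epochs
    scaled = EpochSet([Epoch(7.5 * e.data, e.label, e.fs) for e in es.epochs], es.fs)
    m1, m2 = sb.fit_csp(es, 4), sb.fit_csp(scaled, 4)
    np.testing.assert_allclose(np.abs(m1.filters), np.abs(m2.filters), atol=1e-8)
    f1 = sb.csp_features(m1, es.epochs[0])
    f2 = sb.csp_features(m2, scaled.epochs[0])
    np.testing.assert_allclose(f1.values, f2.values, atol=1e-8)


def test_filter_cap_when_channels_below_request(high_snr_epochs):
    es, _ = high_snr_epochs  # 10 channels
    m = sb.fit_csp(es, 32)
    assert m.n_filters == 10
    assert m.fitted_channels == 10


def test_planted_direction_recovery(high_snr_epochs):
    es, truth = high_snr_epochs
    m = sb.fit_csp(es, 4)
    report = sb.ground_truth_check(m, truth)
    assert report["max_abs_cos"] >= 0.95


def test_feature_matrix_full_width_at_32_channels():
    # with >= 32 channels the requested 32 filters are all kept, so the
    # feature matrix of a 280-trial set is 280 x 32
    rec, _ = sb.generate(sb.SimConfig(n_channels=32, n_trials_per_class=140, seed=3))
    es = sb.bandpass(sb.segment_epochs(rec, 3.0), 8, 15)
    m = sb.fit_csp(es, 32)
    X, y = sb.feature_matrix(m, es)
    assert X.shape == (280, 32)
    assert sorted(np.unique(y)) == [1, 2]
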