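"""RDM construction: correlation metric, decoding metric, PCA summary."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import correlation_rdm_oracle
from neurorsa.containers import LayerActivations, SpatialPatterns, TrialTensor
from neurorsa.rdm import (
    correlation_rdm,
    decoding_rdm,
    decoding_rdm_timeseries,
    layer_rdms,
    restrict_to_top_voxels,
    summary_rdm,
    summary_vectors,
)


# -- correlation metric ---------------------------------------------------

def test_identical_patterns_have_zero_dissimilarity():
    X = np.vstack([np.arange(5.0)] * 2 + [np.arange(5.0)[::-1]])
    rdm = correlation_rdm(X)
    assert rdm.get(0, 1) == pytest.approx(0.0, abs=1e-12)


def test_anticorrelated_patterns_have_dissimilarity_two():
    x = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
    X = np.vstack([x, -x, np.arange(5.0)])
    assert correlation_rdm(X).get(0, 1) == pytest.approx(2.0, abs=1e-12)


def test_correlation_rdm_matches_rank_oracle_on_random_fixtures(rng):
    for _ in range(20):
        X = rng.standard_normal((6, 5))
        got = correlation_rdm(X).values
        want = correlation_rdm_oracle(X)
        np.testing.assert_allclose(got, want, atol=1e-12)


def test_correlation_rdm_matches_oracle_with_ties(rng):
    X = rng.integers(0, 3, size=(4, 5)).astype(float)  # many ties
    X[0] = [0, 1, 2, 2, 1]
    np.testing.assert_allclose(correlation_rdm(X).values,
                               correlation_rdm_oracle(X), atol=1e-12)


def test_constant_pattern_flagged_missing_not_zeroed(caplog):
    X = np.vstack([np.full(4, 2.0), np.arange(4.0), np.arange(4.0)[::-1]])
    with caplog.at_level(logging.WARNING):
        rdm = correlation_rdm(X)
    assert np.isnan(rdm.get(0, 1)) and np.isnan(rdm.get(0, 2))
    assert np.isfinite(rdm.get(1, 2))
    assert "undefined" in caplog.text


@settings(deadline=None, max_examples=20, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_correlation_rdm_invariant_to_monotone_feature_transform(seed):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((5, 7))
    warped = np.exp(3.0 * X)  # strictly monotone per-entry transform
    np.testing.assert_allclose(correlation_rdm(X).values,
                               correlation_rdm(warped).values, atol=1e-9)


def test_correlation_rdm_rejects_degenerate_inputs():
    with pytest.raises(ValueError):
        correlation_rdm(np.zeros((2, 5)))
    with pytest.raises(ValueError):
        correlation_rdm(np.zeros((4, 1)))


# -- decoding metric ------------------------------------------------------

def _two_condition_trials(rng, m=30, sensors=6, separation=0.0):
    a = rng.standard_normal((m, sensors)) + separation
    b = rng.standard_normal((m, sensors)) - separation
    data = np.stack([a, b])[:, :, :, None]
    return TrialTensor(data, np.array([0.0]))


def test_separable_conditions_decode_perfectly(rng):
    trials = _two_condition_trials(rng, separation=50.0)
    rdm = decoding_rdm(trials, 0.0, k=5, n_reps=3, seed=0)
    assert rdm.values[0] == 100.0
    assert rdm.metric == "decoding_accuracy_percent"


def test_fast_engine_equals_sklearn_engine(rng):
    trials = _two_condition_trials(rng, separation=0.3)
    fast = decoding_rdm(trials, 0.0, k=5, n_reps=5, seed=3, engine="fast")
    skl = decoding_rdm(trials, 0.0, k=5, n_reps=5, seed=3, engine="sklearn")
    np.testing.assert_array_equal(fast.values, skl.values)


def test_insufficient_pseudo_trials_rejected(rng):
    trials = _two_condition_trials(rng, m=8)
    with pytest.raises(ValueError, match="fewer than 2 pseudo-trials"):
        decoding_rdm(trials, 0.0, k=5)


def test_surplus_trials_dropped_with_log(rng, caplog):
    trials = _two_condition_trials(rng, m=32)  # 32 % 5 = 2 dropped
    with caplog.at_level(logging.INFO, logger="neurorsa.rdm"):
        decoding_rdm(trials, 0.0, k=5, n_reps=2, seed=0)
    assert "surplus trials" in caplog.text


def test_decoding_seed_reproducible_and_variance_shrinks_with_reps(rng):
    trials = _two_condition_trials(rng, separation=0.25)
    a = decoding_rdm(trials, 0.0, k=5, n_reps=10, seed=9).values
    b = decoding_rdm(trials, 0.0, k=5, n_reps=10, seed=9).values
    np.testing.assert_array_equal(a, b)
    accs10 = [decoding_rdm(trials, 0.0, k=5, n_reps=10, seed=s).values[0]
              for s in range(12)]
    accs100 = [decoding_rdm(trials, 0.0, k=5, n_reps=100, seed=s).values[0]
               for s in range(12)]
    assert np.std(accs100) < np.std(accs10)


def test_timeseries_yields_one_rdm_per_timepoint(rng):
    m, sensors, T = 10, 4, 5
    data = rng.standard_normal((3, m, sensors, T))
    trials = TrialTensor(data, np.arange(T, dtype=float) * 10.0)
    times, rdms = decoding_rdm_timeseries(trials, k=5, n_reps=2, seed=1)
    assert len(rdms) == T and times.size == T
    assert all(r.values.size == 3 for r in rdms)


def test_timeseries_worker_count_does_not_change_results(rng):
    data = rng.standard_normal((3, 10, 4, 3))
    trials = TrialTensor(data, np.arange(3.0))
    _, serial = decoding_rdm_timeseries(trials, k=5, n_reps=2, seed=4,
                                        n_jobs=1)
    _, parallel = decoding_rdm_timeseries(trials, k=5, n_reps=2, seed=4,
                                          n_jobs=2)
    for a, b in zip(serial, parallel):
        np.testing.assert_array_equal(a.values, b.values)


# -- layer and summary RDMs ----------------------------------------------

def test_layer_rdms_match_oracle_and_duplicated_layer_identical(rng):
    m1 = rng.standard_normal((5, 6))
    acts = LayerActivations([(1, m1), (2, m1.copy()), (3, rng.standard_normal((5, 6)))])
    rdms = layer_rdms(acts)
    assert len(rdms) == 3
    np.testing.assert_array_equal(rdms[0].values, rdms[1].values)
    np.testing.assert_allclose(rdms[2].values, correlation_rdm_oracle(acts.layers[2][1]),
                               atol=1e-12)


def test_pca_scores_match_eigendecomposition_oracle():
    # rank-2 toy matrix, 4 conditions x 3 units
    M = np.array([[1.0, 2.0, 0.0],
                  [2.0, 4.0, 1.0],
                  [3.0, 6.0, 0.0],
                  [4.0, 8.0, 1.0]])
    scores = summary_vectors(LayerActivations([(1, M)]), normalize=False)
    Xc = M - M.mean(axis=0)
    cov = Xc.T @ Xc / 1.0
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][:3]
    oracle = Xc @ evecs[:, order]
    # align oracle component signs to the package's convention
    for c in range(oracle.shape[1]):
        load = evecs[:, order[c]]
        if load[np.argmax(np.abs(load))] < 0:
            oracle[:, c] *= -1
    np.testing.assert_allclose(scores, oracle, atol=1e-10)


def test_summary_vector_width_is_conditions_minus_one_per_layer(rng):
    acts = LayerActivations([(l, rng.standard_normal((10, 30 + 5 * l)))
                             for l in range(1, 4)])
    vecs = summary_vectors(acts)
    assert vecs.shape == (10, 9 * 3)


def test_layer_with_few_units_zero_padded(rng):
    acts = LayerActivations([(1, rng.standard_normal((10, 4)))])
    vecs = summary_vectors(acts)
    assert vecs.shape == (10, 9)
    assert np.all(vecs[:, 4:] == 0.0)


def test_single_layer_summary_equals_its_pca_score_rdm(rng):
    acts = LayerActivations([(1, rng.standard_normal((8, 12)))])
    np.testing.assert_array_equal(
        summary_rdm(acts).values,
        correlation_rdm(summary_vectors(acts)).values)


def test_summary_rdm_invariant_to_rescaling_single_layer(rng):
    mats = [rng.standard_normal((8, 12)) for _ in range(3)]
    acts = LayerActivations(list(enumerate(mats, start=1)))
    scaled = LayerActivations([(1, mats[0] * 37.0), (2, mats[1]), (3, mats[2])])
    np.testing.assert_allclose(summary_rdm(acts).values,
                               summary_rdm(scaled).values, atol=1e-9)


# -- voxel restriction ----------------------------------------------------

def test_restrict_to_top_voxels_keeps_largest_statistics(rng):
    pat = SpatialPatterns(rng.standard_normal((4, 5)),
                          np.array(list("abcde")))
    kept = restrict_to_top_voxels(pat, np.array([3.0, 1.0, 4.0, 1.0, 5.0]), 2)
    assert list(kept.voxel_ids) == ["c", "e"]  # stats 4 and 5
    np.testing.assert_array_equal(kept.data, pat.data[:, [2, 4]])


def test_restrict_to_top_voxels_identity_and_validation(rng):
    pat = SpatialPatterns(rng.standard_normal((4, 5)), np.arange(5))
    same = restrict_to_top_voxels(pat, np.arange(5.0), 5)
    np.testing.assert_array_equal(same.data, pat.data)
    with pytest.raises(ValueError):
        restrict_to_top_voxels(pat, np.arange(5.0), 0)
    with pytest.raises(ValueError):
        restrict_to_top_voxels(pat, np.arange(5.0), 6)


def test_restrict_breaks_ties_by_voxel_order(rng):
    pat = SpatialPatterns(rng.standard_normal((4, 4)), np.arange(4))
    kept = restrict_to_top_voxels(pat, np.array([1.0, 1.0, 1.0, 1.0]), 2)
    assert list(kept.voxel_ids) == [0, 1]
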