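"""Construction of representational dissimilarity matrices (RDMs).

Three routes into the common condensed-RDM data model:

* correlation RDMs (1 minus Spearman's R) from condition-by-feature
  pattern matrices — the metric used for voxel patterns and model-layer
  activations;
* decoding RDMs (pairwise cross-validated linear-SVM accuracy, in
  percent) from trial-resolved sensor recordings — the metric used for
  time-resolved MEG analysis;
* a PCA-balanced summary RDM concatenating per-layer principal-component
  scores so that layers with wildly different unit counts contribute
  equal-width feature blocks.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.stats import rankdata
from sklearn.decomposition import PCA
from sklearn.svm import SVC

try:  # fast path: direct libsvm binding (same solver SVC wraps)
    from sklearn.svm import _libsvm as _libsvm_backend

    _libsvm_backend.set_verbosity_wrap(0)
except ImportError:  # pragma: no cover
    _libsvm_backend = None

from .containers import (
    RDM,
    LayerActivations,
    SpatialPatterns,
    TrialTensor,
    condensed_length,
)

__all__ = [
    "correlation_rdm",
    "decoding_rdm",
    "decoding_rdm_timeseries",
    "layer_rdms",
    "summary_rdm",
    "summary_vectors",
    "restrict_to_top_voxels",
]

logger = logging.getLogger(__name__)


def _as_pattern_matrix(patterns) -> np.ndarray:
    if isinstance(patterns, SpatialPatterns):
        return patterns.data
    return np.asarray(patterns, dtype=float)


def correlation_rdm(patterns, condition_labels: list[str] | None = None) -> RDM:
    """Correlation-distance RDM: 1 minus Spearman's R per condition pair.

    Parameters
    ----------
    patterns
        (conditions, features) matrix or :class:`SpatialPatterns`.
        Needs >= 3 conditions and >= 2 features.

    Notes
    -----
    Ranks use average-rank tie handling.  A condition whose feature vector
    is constant has undefined rank correlation with every other condition;
    the affected entries are stored as NaN and their count is logged —
    they are never silently zeroed.
    """
    X = _as_pattern_matrix(patterns)
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 conditions for an RDM")
    if p < 2:
        raise ValueError("need at least 2 features")
    ranks = rankdata(X, axis=1)  # average ranks for ties
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    sd = np.sqrt((centered**2).sum(axis=1))
    constant = sd == 0
    sd_safe = np.where(constant, 1.0, sd)
    corr = (centered @ centered.T) / np.outer(sd_safe, sd_safe)
    np.clip(corr, -1.0, 1.0, out=corr)
    dissim = 1.0 - corr
    if constant.any():
        dissim[constant, :] = np.nan
        dissim[:, constant] = np.nan
    iu = np.triu_indices(n, k=1)
    values = dissim[iu]
    n_missing = int(np.isnan(values).sum())
    if n_missing:
        logger.warning(
            "correlation_rdm: %d/%d entries undefined (constant pattern "
            "vectors) and stored as missing", n_missing, values.size,
        )
    return RDM(values, metric="correlation_distance",
               condition_labels=condition_labels)


def _pseudo_trials(cond_data: np.ndarray, k: int, rng: np.random.Generator
                   ) -> np.ndarray:
    """Randomly assign M trials to L = M // k groups of k and average.

    Surplus trials (M mod k) are dropped uniformly at random per call.
    Returns (L, sensors).
    """
    m = cond_data.shape[0]
    L = m // k
    perm = rng.permutation(m)[: L * k]
    return cond_data[perm].reshape(L, k, -1).mean(axis=1)


def _fit_linear_svm_fast(X: np.ndarray, y: np.ndarray, C: float
                         ) -> tuple[np.ndarray, float]:
    """Linear SVM weight vector and bias via the libsvm binding.

    With training labels ordered zeros-then-ones the decision value
    ``w @ x + b`` is positive for class 0 (libsvm orients the decision
    toward the first label it encounters); the caller accounts for
    that.  Identical solution to ``SVC(kernel='linear')``, which wraps
    the same solver, minus the per-call validation overhead.
    """
    out = _libsvm_backend.fit(X, y, svm_type=0, kernel="linear", C=C)
    support_vectors, dual_coef, intercept = out[1], out[3], out[4]
    return dual_coef[0] @ support_vectors, float(intercept[0])


def _pair_accuracy(a: np.ndarray, b: np.ndarray, C: float,
                   clf=None) -> float:
    """Leave-one-pseudo-trial-out CV accuracy for one condition pair.

    ``a`` and ``b`` are (L, sensors) pseudo-trial arrays; fold ``f`` holds
    out the f-th pseudo-trial of each condition and trains on the rest.
    """
    L = a.shape[0]
    labels = np.r_[np.zeros(L - 1), np.ones(L - 1)]
    correct = 0
    for f in range(L):
        keep = np.arange(L) != f
        X = np.ascontiguousarray(np.vstack([a[keep], b[keep]]))
        if clf is None:
            w, bias = _fit_linear_svm_fast(X, labels, C)
            # decision > 0 -> class 0 (see _fit_linear_svm_fast)
            correct += int(a[f] @ w + bias > 0)
            correct += int(b[f] @ w + bias <= 0)
        else:
            clf.fit(X, labels)
            pred = clf.predict(np.vstack([a[f], b[f]]))
            correct += int(pred[0] == 0) + int(pred[1] == 1)
    return correct / (2 * L)


def decoding_rdm(trials: TrialTensor, t_ms: float, k: int = 5,
                 n_reps: int = 100, seed: int | np.random.Generator = 0,
                 C: float = 1.0, engine: str = "fast") -> RDM:
    """Pairwise decoding-accuracy RDM at one timepoint.

    For every condition pair, the M trials at time ``t_ms`` are
    sub-averaged into ``L = M // k`` pseudo-trials by random assignment,
    a linear maximum-margin classifier (SVM, fixed C) is cross-validated
    leave-one-pseudo-trial-out over the L folds, and the procedure is
    repeated ``n_reps`` times with fresh random assignments.  The RDM
    entry is the mean test accuracy in percent (chance = 50).

    ``engine="fast"`` calls the libsvm solver directly;
    ``engine="sklearn"`` goes through :class:`sklearn.svm.SVC`.  Both
    yield identical accuracies (same solver); the fast path skips
    per-call input validation, which dominates at these problem sizes.

    Raises if fewer than two pseudo-trials can be formed (only one fold).
    """
    m = trials.n_trials
    if m // k < 2:
        raise ValueError(
            f"M={m} trials with k={k} leave fewer than 2 pseudo-trials; "
            "cross-validation needs at least 2 folds")
    if m % k:
        logger.info("decoding_rdm: %d surplus trials (M=%d, k=%d) dropped "
                    "at random per repetition", m % k, m, k)
    n = trials.n_conditions
    if n < 2:
        raise ValueError("need at least 2 conditions")
    rng = np.random.default_rng(seed)
    ti = trials.time_index(t_ms)
    data_t = trials.data[:, :, :, ti]  # (conditions, trials, sensors)
    use_fast = engine == "fast" and _libsvm_backend is not None
    clf = None if use_fast else SVC(kernel="linear", C=C)
    acc = np.zeros(condensed_length(n))
    for _ in range(n_reps):
        pseudo = [_pseudo_trials(data_t[c], k, rng) for c in range(n)]
        idx = 0
        for i in range(n):
            for j in range(i + 1, n):
                acc[idx] += _pair_accuracy(pseudo[i], pseudo[j], C, clf)
                idx += 1
    acc = acc / n_reps * 100.0
    return RDM(acc, metric="decoding_accuracy_percent")


def decoding_rdm_timeseries(trials: TrialTensor, k: int = 5,
                            n_reps: int = 100,
                            seed: int | np.random.Generator = 0,
                            times_ms: np.ndarray | None = None,
                            n_jobs: int = 1, engine: str = "fast"
                            ) -> tuple[np.ndarray, list[RDM]]:
    """One decoding RDM per timepoint.

    Each timepoint gets an independent child random stream spawned from
    ``seed``, so results are reproducible and independent of the worker
    count (``n_jobs`` parallelises over timepoints via joblib).
    Returns ``(times_ms, [RDM, ...])`` in time order.
    """
    if times_ms is None:
        times_ms = trials.times_ms
    times_ms = np.asarray(times_ms, dtype=float)
    ss = np.random.SeedSequence(
        seed if isinstance(seed, (int, np.integer)) else seed.integers(2**31))
    children = ss.spawn(times_ms.size)
    if n_jobs == 1:
        rdms = [decoding_rdm(trials, t, k=k, n_reps=n_reps,
                             seed=np.random.default_rng(cs), engine=engine)
                for t, cs in zip(times_ms, children)]
    else:
        from joblib import Parallel, delayed
        rdms = Parallel(n_jobs=n_jobs)(
            delayed(decoding_rdm)(trials, t, k=k, n_reps=n_reps,
                                  seed=np.random.default_rng(cs),
                                  engine=engine)
            for t, cs in zip(times_ms, children))
    return times_ms, rdms


def layer_rdms(acts: LayerActivations) -> list[RDM]:
    """Correlation RDM per model layer, in layer order."""
    return [correlation_rdm(mat) for _, mat in acts.layers]


def _fix_component_signs(components: np.ndarray) -> np.ndarray:
    """Flip each component so its largest-magnitude loading is positive."""
    flip = np.sign(components[np.argmax(np.abs(components), axis=0),
                              np.arange(components.shape[1])])
    flip[flip == 0] = 1.0
    return flip


def summary_vectors(acts: LayerActivations, normalize: bool = True
                    ) -> np.ndarray:
    """PCA-balanced per-condition summary vectors concatenated across layers.

    Each layer's (conditions, units) matrix is centred per unit and
    reduced by PCA to ``n_conditions - 1`` component scores per condition
    (the maximal rank after centring), making every layer contribute an
    equal-width block regardless of its unit count.  A layer with fewer
    units than that retains ``min(units, n_conditions - 1)`` components
    and is zero-padded to fixed width.  Component signs are fixed so the
    largest-magnitude loading of each component is positive.

    With ``normalize`` (default) each layer's score block is scaled to
    unit Frobenius norm, so no layer dominates the concatenation by raw
    activation amplitude — the point of the balancing — and the summary
    is invariant to rescaling any single layer by a positive constant.
    Within-layer variance ordering is preserved (no whitening).

    Returns (conditions, (n_conditions - 1) * n_layers).
    """
    n = acts.n_conditions
    if n < 3:
        raise ValueError("need at least 3 conditions")
    width = n - 1
    blocks = []
    for _, mat in acts.layers:
        n_comp = min(width, mat.shape[1])
        pca = PCA(n_components=n_comp, svd_solver="full")
        scores = pca.fit_transform(mat)
        flip = _fix_component_signs(pca.components_.T)
        scores = scores * flip
        if normalize:
            norm = np.linalg.norm(scores)
            if norm > 0:
                scores = scores / norm
        if n_comp < width:
            scores = np.pad(scores, ((0, 0), (0, width - n_comp)))
        blocks.append(scores)
    return np.concatenate(blocks, axis=1)


def summary_rdm(acts: LayerActivations) -> RDM:
    """Single whole-model RDM from the PCA-balanced summary vectors."""
    return correlation_rdm(summary_vectors(acts))


def restrict_to_top_voxels(patterns: SpatialPatterns,
                           grand_average: np.ndarray,
                           n: int) -> SpatialPatterns:
    """Keep the ``n`` voxels with the largest grand-average statistic.

    Emulates the functional ROI restriction to the most strongly
    activated voxels in a grand-average contrast.  Ties are broken by
    voxel id order (stable sort), so the result is deterministic.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    ga = np.asarray(grand_average, dtype=float)
    if ga.size != patterns.n_voxels:
        raise ValueError("grand_average length must match voxel count")
    if n > patterns.n_voxels:
        raise ValueError("n exceeds voxel count")
    order = np.argsort(-ga, kind="stable")[:n]
    order = np.sort(order)  # preserve original voxel order among the kept
    return SpatialPatterns(patterns.data[:, order], patterns.voxel_ids[order])
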