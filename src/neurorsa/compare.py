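"""Comparing model RDMs with brain RDMs and summarising the result.

The primitive is Spearman's correlation between the condensed
(lower-triangle, diagonal excluded) halves of two RDMs.  On top of it:
similarity time courses against time-resolved decoding RDMs, peak and
onset latencies, the layer-number-vs-peak-latency hierarchy statistic,
hierarchy contrasts between models, model-difference time courses, and
ROI layer profiles.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.stats import spearmanr

from .containers import RDM, HierarchyResult, SimilarityTimeCourse

__all__ = [
    "compare_rdms",
    "timecourse",
    "stack_timecourses",
    "peak_latency",
    "onset_latency",
    "hierarchy_statistic",
    "hierarchy_contrast",
    "model_difference_timecourse",
    "roi_layer_profile",
]

logger = logging.getLogger(__name__)


def compare_rdms(a: RDM, b: RDM) -> float:
    """Spearman's R between two RDMs' condensed entries.

    Pairs missing (NaN) in either RDM are excluded pairwise; with fewer
    than 3 valid pairs the correlation is undefined and NaN is returned
    (logged, never silently zeroed).
    """
    if a.values.size != b.values.size:
        raise ValueError("RDMs must have the same number of conditions")
    valid = np.isfinite(a.values) & np.isfinite(b.values)
    if valid.sum() < 3:
        logger.warning("compare_rdms: only %d valid pairs; similarity "
                       "undefined", int(valid.sum()))
        return float("nan")
    r = spearmanr(a.values[valid], b.values[valid]).statistic
    return float(r)


def timecourse(times_ms: np.ndarray, meg_rdms: list[RDM], model_rdm: RDM,
               label: str = "") -> SimilarityTimeCourse:
    """Similarity of one subject's time-resolved RDMs to a model RDM."""
    times_ms = np.asarray(times_ms, dtype=float)
    if len(meg_rdms) != times_ms.size:
        raise ValueError("one RDM per timepoint required")
    vals = np.array([compare_rdms(r, model_rdm) for r in meg_rdms])
    return SimilarityTimeCourse(times_ms, vals[None, :], label=label)


def stack_timecourses(tcs: list[SimilarityTimeCourse]) -> SimilarityTimeCourse:
    """Stack single-subject time courses into one multi-subject course."""
    t0 = tcs[0].times_ms
    for tc in tcs[1:]:
        if not np.array_equal(tc.times_ms, t0):
            raise ValueError("time axes differ")
    return SimilarityTimeCourse(t0, np.vstack([tc.values for tc in tcs]),
                                label=tcs[0].label)


def peak_latency(tc: SimilarityTimeCourse,
                 window_ms: tuple[float, float] = (0.0, 1000.0)
                 ) -> np.ndarray:
    """Per-subject time of the maximal similarity within a window.

    The default window is post-stimulus (0-1000 ms): pre-stimulus peaks
    are noise.  Ties resolve to the earliest timepoint.  A subject with
    no finite value in the window gets NaN.
    """
    lo, hi = window_ms
    sel = (tc.times_ms >= lo) & (tc.times_ms <= hi)
    if not sel.any():
        raise ValueError("window does not intersect the epoch")
    t_win = tc.times_ms[sel]
    v_win = tc.values[:, sel]
    out = np.full(tc.n_subjects, np.nan)
    for s in range(tc.n_subjects):
        v = v_win[s]
        if np.isfinite(v).any():
            v = np.where(np.isfinite(v), v, -np.inf)
            out[s] = t_win[int(np.argmax(v))]  # argmax: earliest tie wins
    return out


def onset_latency(tc: SimilarityTimeCourse, significant_mask: np.ndarray,
                  onset_ms: float = 0.0) -> float:
    """First timepoint of the earliest significant cluster after stimulus onset.

    ``significant_mask`` is a per-timepoint boolean (from cluster-based
    inference on the group time course).  Returns NaN (and logs) when no
    post-onset timepoint is significant.
    """
    mask = np.asarray(significant_mask, dtype=bool)
    if mask.size != tc.times_ms.size:
        raise ValueError("mask length must match the time axis")
    idx = np.flatnonzero(mask & (tc.times_ms >= onset_ms))
    if idx.size == 0:
        logger.warning("onset_latency: no significant post-onset timepoint")
        return float("nan")
    return float(tc.times_ms[idx[0]])


def _spearman_layer(latencies: np.ndarray, layer_index: np.ndarray) -> float:
    valid = np.isfinite(latencies)
    if valid.sum() < 2:
        return float("nan")
    return float(spearmanr(layer_index[valid], latencies[valid]).statistic)


def hierarchy_statistic(peak_latencies: np.ndarray,
                        layer_index: np.ndarray | None = None,
                        n_perm: int = 10_000, seed: int = 0,
                        tail: str = "two-sided",
                        exhaustive: bool = False) -> HierarchyResult:
    """Layer-number vs peak-latency association across subjects.

    ``peak_latencies`` is (subjects, layers) in ms.  Per subject, the
    Spearman correlation between layer index and that subject's peak
    latencies is computed (undefined latencies excluded pairwise;
    subjects with fewer than 2 valid layers are dropped and logged).
    The group statistic is the mean of per-subject R; its p-value comes
    from a sign-permutation test on the per-subject Rs.  The result
    also carries ``subject_mean_R``, the Spearman correlation between
    layer index and the subject-averaged latencies (the statistic a
    subject-average latency plot displays; far less noisy because
    latency jitter averages out before ranking).
    """
    from .inference import sign_permutation_test

    lat = np.atleast_2d(np.asarray(peak_latencies, dtype=float))
    n_sub, n_layers = lat.shape
    if n_layers < 2:
        raise ValueError("need at least 2 layers")
    if layer_index is None:
        layer_index = np.arange(1, n_layers + 1, dtype=float)
    rs = np.array([_spearman_layer(lat[s], layer_index) for s in range(n_sub)])
    dropped = int(np.isnan(rs).sum())
    if dropped:
        logger.warning("hierarchy_statistic: %d subject(s) dropped "
                       "(fewer than 2 valid layers)", dropped)
    rs = rs[np.isfinite(rs)]
    with np.errstate(invalid="ignore"):
        mean_lat = np.nanmean(lat, axis=0)
    subject_mean_R = _spearman_layer(mean_lat, np.asarray(layer_index, float))
    if rs.size < 2:
        logger.warning("hierarchy_statistic: %d valid subject(s); "
                       "group p-value undefined", rs.size)
        group = float(rs.mean()) if rs.size else float("nan")
        return HierarchyResult(rs, group, float("nan"), subject_mean_R)
    p = sign_permutation_test(rs[:, None], n_perm=n_perm, seed=seed,
                              tail=tail, exhaustive=exhaustive)[0]
    return HierarchyResult(rs, float(rs.mean()), float(p), subject_mean_R)


def hierarchy_contrast(a: HierarchyResult, b: HierarchyResult,
                       n_perm: int = 10_000, seed: int = 0,
                       tail: str = "two-sided",
                       exhaustive: bool = False) -> tuple[float, float]:
    """Group difference of hierarchy statistics between two models.

    Per-subject R differences (paired by subject order) are summarised
    by their mean ``delta_R`` with a sign-permutation p-value.
    Returns ``(delta_R, p)``.
    """
    from .inference import sign_permutation_test

    ra, rb = a.per_subject_R, b.per_subject_R
    if ra.size != rb.size:
        raise ValueError("hierarchy results must pair the same subjects")
    diff = ra - rb
    p = sign_permutation_test(diff[:, None], n_perm=n_perm, seed=seed,
                              tail=tail, exhaustive=exhaustive)[0]
    return float(diff.mean()), float(p)


def model_difference_timecourse(a: SimilarityTimeCourse,
                                b: SimilarityTimeCourse,
                                label: str = "") -> SimilarityTimeCourse:
    """Per-subject subtraction of two similarity time courses (a - b)."""
    if not np.array_equal(a.times_ms, b.times_ms):
        raise ValueError("time axes differ")
    if a.n_subjects != b.n_subjects:
        raise ValueError("subject counts differ")
    return SimilarityTimeCourse(
        a.times_ms.copy(), a.values - b.values,
        label=label or f"{a.label}-minus-{b.label}",
        bounded=False)  # differences may leave [-1, 1]


def roi_layer_profile(roi_rdm: RDM, layer_rdm_list: list[RDM],
                      layer_index: np.ndarray | None = None
                      ) -> tuple[np.ndarray, float]:
    """Similarity of an ROI RDM to each model layer, plus its layer trend.

    Returns ``(per_layer_similarity, R)`` where ``R`` is the Spearman
    correlation of layer number with similarity — non-zero values
    indicate a hierarchical relationship between the ROI and the model.
    """
    sims = np.array([compare_rdms(roi_rdm, lr) for lr in layer_rdm_list])
    if layer_index is None:
        layer_index = np.arange(1, len(layer_rdm_list) + 1, dtype=float)
    valid = np.isfinite(sims)
    r = (float(spearmanr(layer_index[valid], sims[valid]).statistic)
         if valid.sum() >= 2 else float("nan"))
    return sims, r
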