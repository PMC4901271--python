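"""Occlusion-based receptive-field estimation for model units.

Works with any *extractor*: a pure callable mapping an image batch
(n, H, W[, C]) to per-unit activations (n, n_units).  The unit's
empirical receptive field is estimated by sliding (or randomly
sampling) small gray occluders over its most strongly activating
images, recording the activation drop per occluder position
(discrepancy map), re-centring each map on its peak and averaging.
A selectivity region is obtained by weighting a feature map with the
RF at every location and thresholding the summed contribution map at a
fraction (default 50%) of its maximum.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import fftconvolve

__all__ = [
    "top_k_images",
    "discrepancy_map",
    "receptive_field",
    "selectivity_region",
]


def _activations(extractor, images: np.ndarray, unit: int) -> np.ndarray:
    acts = np.asarray(extractor(images), dtype=float)
    if acts.ndim == 1:
        acts = acts[:, None]
    return acts[:, unit]


def top_k_images(extractor, images: np.ndarray, unit: int, K: int = 25
                 ) -> np.ndarray:
    """Indices of the K most strongly activating images, strongest first.

    Ties break by image index (stable ordering).
    """
    if K < 1:
        raise ValueError("K must be positive")
    acts = _activations(extractor, images, unit)
    order = np.argsort(-acts, kind="stable")
    return order[: min(K, acts.size)]


def _occluder_positions(h: int, w: int, size: int, stride: int | None,
                        n_samples: int | None, rng) -> np.ndarray:
    max_r, max_c = h - size, w - size
    if stride is not None:
        rr = np.arange(0, max_r + 1, stride)
        cc = np.arange(0, max_c + 1, stride)
        return np.array([(r, c) for r in rr for c in cc])
    if n_samples is None:
        raise ValueError("provide stride or n_samples")
    rows = rng.integers(0, max_r + 1, size=n_samples)
    cols = rng.integers(0, max_c + 1, size=n_samples)
    return np.column_stack([rows, cols])


def discrepancy_map(extractor, image: np.ndarray, unit: int,
                    occluder_size: int = 8, stride: int | None = None,
                    n_samples: int | None = None, seed: int = 0,
                    fill: float = 0.5, batch_size: int = 256) -> np.ndarray:
    """Per-pixel activation drop when the image is occluded at that pixel.

    A gray square occluder (``fill`` value, default mid-gray) is placed
    at grid positions (``stride``) or at ``n_samples`` random positions.
    For each position the discrepancy is the unit's original activation
    minus its activation on the occluded image; each pixel of the map
    averages the discrepancies of all occluders covering it (pixels
    never covered stay 0).  Extractor failures propagate annotated with
    the occluder position.
    """
    image = np.asarray(image, dtype=float)
    h, w = image.shape[:2]
    if occluder_size > min(h, w):
        raise ValueError("occluder does not fit in the image")
    rng = np.random.default_rng(seed)
    positions = _occluder_positions(h, w, occluder_size, stride, n_samples, rng)
    orig = float(_activations(extractor, image[None], unit)[0])
    total = np.zeros((h, w))
    cover = np.zeros((h, w))
    for start in range(0, len(positions), batch_size):
        chunk = positions[start:start + batch_size]
        batch = np.repeat(image[None], len(chunk), axis=0)
        for b, (r, c) in enumerate(chunk):
            batch[b, r:r + occluder_size, c:c + occluder_size] = fill
        try:
            acts = _activations(extractor, batch, unit)
        except Exception as exc:  # annotate with position context
            raise RuntimeError(
                f"extractor failed on occluders at positions "
                f"{chunk.tolist()}") from exc
        for (r, c), a in zip(chunk, acts):
            total[r:r + occluder_size, c:c + occluder_size] += orig - a
            cover[r:r + occluder_size, c:c + occluder_size] += 1
    with np.errstate(invalid="ignore"):
        out = np.where(cover > 0, total / np.maximum(cover, 1), 0.0)
    if not np.all(np.isfinite(out)):
        raise ValueError("non-finite discrepancy values")
    return out


def _recenter(m: np.ndarray) -> np.ndarray:
    """Translate a map so its peak sits at the array centre.

    Peak ties resolve to the first position in scan (row-major) order.
    Values shifted in from outside are zero.
    """
    h, w = m.shape
    pr, pc = np.unravel_index(int(np.argmax(m)), m.shape)
    dr, dc = h // 2 - pr, w // 2 - pc
    out = np.zeros_like(m)
    src_r = slice(max(0, -dr), min(h, h - dr))
    src_c = slice(max(0, -dc), min(w, w - dc))
    dst_r = slice(max(0, dr), min(h, h + dr))
    dst_c = slice(max(0, dc), min(w, w + dc))
    out[dst_r, dst_c] = m[src_r, src_c]
    return out


def receptive_field(maps: list[np.ndarray]) -> np.ndarray:
    """Average of discrepancy maps after re-centring each on its peak."""
    if not maps:
        raise ValueError("no discrepancy maps")
    shapes = {m.shape for m in maps}
    if len(shapes) != 1:
        raise ValueError("discrepancy maps must share a shape")
    return np.mean([_recenter(np.asarray(m, dtype=float)) for m in maps],
                   axis=0)


def selectivity_region(feature_map: np.ndarray, rf: np.ndarray,
                       threshold_frac: float = 0.5) -> np.ndarray:
    """Binary image region primarily driving a unit's response.

    The RF is placed at every location, weighted by the feature-map
    value there, and contributions are summed over all pixels — i.e.
    the feature map is convolved with the RF.  The result is
    thresholded at ``threshold_frac`` of its maximum (default 50%).
    """
    if not 0 < threshold_frac <= 1:
        raise ValueError("threshold_frac must be in (0, 1]")
    fm = np.asarray(feature_map, dtype=float)
    contrib = fftconvolve(fm, np.asarray(rf, dtype=float), mode="same")
    return contrib >= threshold_frac * contrib.max()
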