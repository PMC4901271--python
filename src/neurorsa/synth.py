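"""Synthetic inputs with the statistical structure the analysis assumes.

The generator emulates a visual-recognition RSA study: 118 image
conditions shown to 15 subjects, 306-sensor MEG epochs from -100 to
+1000 ms at 1 ms resolution with 30 trials per condition, 100-voxel ROI
activation patterns, and an 8-layer feed-forward model whose layers
carry a controllable latency and region gradient.

Shared latent geometry
----------------------
Each model layer ``l`` owns a latent condition-embedding matrix ``Z_l``
(conditions x d).  Model activations, MEG sensor patterns and fMRI voxel
patterns are all random linear images of the same ``Z_l`` plus i.i.d.
Gaussian noise, so decoding RDMs, voxel-pattern RDMs and model-layer
RDMs share per-layer representational geometry — the premise of the
whole analysis.  The layer's *target RDM* is the correlation RDM of
``Z_l`` itself.

In the MEG signal the layer geometries are mixed over time by Gaussian
temporal kernels centred at per-layer latencies; in fMRI they are mixed
per region by configurable weights (V1-like regions weight low layers,
IT-like regions weight high layers).

All randomness flows from one experiment seed through named
``numpy.random.SeedSequence`` substreams (layer, subject, stage), so the
same seed reproduces every fixture bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import convolve

from .containers import RDM, LayerActivations, SpatialPatterns, SurfaceMesh, TrialTensor
from .rdm import correlation_rdm

__all__ = [
    "GroundTruth",
    "make_ground_truth",
    "simulate_layer_activations",
    "simulate_meg_subject",
    "simulate_fmri_subject",
    "generate_noise_images",
    "build_toy_mesh",
    "DEFAULT_EPOCH_MS",
]

#: The study epoch: -100..+1000 ms at 1 ms steps (1101 timepoints).
DEFAULT_EPOCH_MS = np.arange(-100.0, 1001.0, 1.0)

_STAGE = {"latent": 0, "model": 1, "meg": 2, "fmri": 3, "images": 4}


def _stream(seed: int, stage: str, *keys: int) -> np.random.Generator:
    """Named substream: (experiment seed, stage, extra keys)."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed),
                               spawn_key=(_STAGE[stage], *map(int, keys))))


@dataclass
class GroundTruth:
    """Generative description of one synthetic experiment.

    Parameters
    ----------
    n_conditions, n_layers
        Study size; defaults follow the emulated design (118 images,
        8 model layers).
    layer_latency_ms
        Per-layer latency at which that layer's geometry peaks in the
        MEG signal.  Must lie inside the simulated epoch.
    layer_region_weights
        Mapping region name -> per-layer mixing weights in [0, 1]
        (sum <= 1 per region); the remainder of the variance budget is
        noise-only.
    hierarchy_sign
        +1 latencies increase with layer, -1 decrease, 0 constant
        (recorded for provenance; ``make_ground_truth`` applies it).
    signal_scale, noise_sd
        Amplitude of the condition-specific signal versus the i.i.d.
        Gaussian per-trial, per-sensor recording noise.  The default
        noise_sd=10 puts peak pairwise decoding around 80-90%, the band
        published sensor-level pairwise image-decoding curves peak in;
        recordings are far noisier than the pattern estimates below.
    fmri_noise_sd
        Noise on voxel pattern estimates (post-averaging, so much
        smaller than the per-trial sensor noise).
    model_noise_sd
        Optional noise on model-unit activations (0 = deterministic
        model, the realistic case).
    latent_dim
        Dimensionality d of the latent condition embeddings Z_l.
    kernel_width_ms
        FWHM of the Gaussian temporal kernel mixing the layer
        geometries into the MEG signal (matches the 20 ms
        smoothing-window scale of the emulated preprocessing).
    """

    n_conditions: int = 118
    n_layers: int = 8
    layer_latency_ms: np.ndarray = None
    layer_region_weights: dict[str, np.ndarray] = field(default_factory=dict)
    hierarchy_sign: int = +1
    signal_scale: float = 1.0
    noise_sd: float = 10.0
    fmri_noise_sd: float = 1.0
    model_noise_sd: float = 0.0
    latent_dim: int = 20
    kernel_width_ms: float = 20.0
    epoch_ms: np.ndarray = None
    seed: int = 0
    shared_latent: bool = False  # all layers share layer 1's geometry

    def __post_init__(self) -> None:
        if self.n_conditions < 3:
            raise ValueError("need at least 3 conditions (RDM degenerate below)")
        if self.epoch_ms is None:
            self.epoch_ms = DEFAULT_EPOCH_MS.copy()
        self.epoch_ms = np.asarray(self.epoch_ms, dtype=float)
        if self.layer_latency_ms is None:
            self.layer_latency_ms = 100.0 + 10.0 * np.arange(1, self.n_layers + 1)
        self.layer_latency_ms = np.asarray(self.layer_latency_ms, dtype=float)
        if self.layer_latency_ms.size != self.n_layers:
            raise ValueError("one latency per layer required")
        lo, hi = self.epoch_ms.min(), self.epoch_ms.max()
        if ((self.layer_latency_ms < lo) | (self.layer_latency_ms > hi)).any():
            raise ValueError("layer latencies must lie inside the epoch")
        for region, w in self.layer_region_weights.items():
            w = np.asarray(w, dtype=float)
            if w.size != self.n_layers:
                raise ValueError(f"region {region!r}: one weight per layer")
            if (w < 0).any() or (w > 1).any() or w.sum() > 1 + 1e-9:
                raise ValueError(f"region {region!r}: weights in [0,1], sum <= 1")
            self.layer_region_weights[region] = w

    # -- latent geometry ---------------------------------------------------
    def latent_embedding(self, layer: int) -> np.ndarray:
        """Latent condition embedding Z_l (conditions x d), deterministic.

        With ``shared_latent`` every layer returns layer 1's embedding
        (identical target RDMs across layers).
        """
        rng = _stream(self.seed, "latent", 1 if self.shared_latent else layer)
        return rng.standard_normal((self.n_conditions, self.latent_dim))

    def layer_target_rdm(self, layer: int) -> RDM:
        """The correlation RDM the layer's observations converge to."""
        return correlation_rdm(self.latent_embedding(layer))

    def temporal_kernels(self, times_ms: np.ndarray) -> np.ndarray:
        """(n_layers, n_times) Gaussian mixing weights, peak 1 at latency.

        ``kernel_width_ms`` is the FWHM of the Gaussian (the usual
        meaning of a kernel's width), i.e. sigma = width / 2.3548.
        """
        t = np.asarray(times_ms, dtype=float)[None, :]
        mu = self.layer_latency_ms[:, None]
        sigma = self.kernel_width_ms / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        return np.exp(-0.5 * ((t - mu) / sigma) ** 2)


def make_ground_truth(n_conditions: int = 118, n_layers: int = 8,
                      hierarchy_sign: int = +1,
                      base_latency_ms: float = 100.0,
                      latency_step_ms: float = 10.0,
                      **kwargs) -> GroundTruth:
    """Ground truth with latencies ``base + step*l`` ordered by ``hierarchy_sign``.

    ``hierarchy_sign=+1`` gives latencies increasing with layer number
    (the configuration the emulated study reports for a task-trained
    model), ``-1`` reverses the order (the untrained-architecture
    regime), ``0`` assigns every layer the mean latency.
    """
    lat = base_latency_ms + latency_step_ms * np.arange(1, n_layers + 1)
    if hierarchy_sign < 0:
        lat = lat[::-1].copy()
    elif hierarchy_sign == 0:
        lat = np.full(n_layers, lat.mean())
    return GroundTruth(n_conditions=n_conditions, n_layers=n_layers,
                       layer_latency_ms=lat, hierarchy_sign=hierarchy_sign,
                       **kwargs)


def _tile_embed(Z: np.ndarray, n_features: int, rng: np.random.Generator
                ) -> np.ndarray:
    """Map latent columns into feature space by tiling.

    Duplicating features is an affine transform of per-condition ranks,
    so pairwise Spearman correlations — hence the correlation RDM — are
    preserved exactly by whole tiles; a remainder below one tile width
    duplicates a random subset of latent dimensions (slight reweighting
    only).  With fewer features than latent dimensions a random subset
    of dimensions is used.
    """
    d = Z.shape[1]
    if n_features < d:
        return Z[:, rng.permutation(d)[:n_features]]
    m, r = divmod(n_features, d)
    cols = np.concatenate([np.tile(np.arange(d), m), rng.permutation(d)[:r]])
    return Z[:, cols]


def _orthonormal_embed(Z: np.ndarray, n_features: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Map latent columns into feature space by a random orthonormal map.

    Pairwise Euclidean distances (which drive linear decodability) are
    preserved exactly; the result is rescaled so the average per-feature
    signal variance stays at the latent level.
    """
    d = Z.shape[1]
    if n_features >= d:
        Q, _ = np.linalg.qr(rng.standard_normal((n_features, d)))
        return (Z @ Q.T) * np.sqrt(n_features / d)
    Q, _ = np.linalg.qr(rng.standard_normal((d, n_features)))
    return Z @ Q


def simulate_layer_activations(gt: GroundTruth,
                               units_per_layer: int | list[int] = 256
                               ) -> LayerActivations:
    """Per-layer condition-by-unit activations.

    Each layer's activations tile its latent embedding Z_l into unit
    space (a rank-preserving map, see :func:`_tile_embed`) plus
    ``model_noise_sd`` Gaussian noise — so the layer's correlation RDM
    approaches its target RDM as the noise vanishes (and equals it up
    to tiling-remainder reweighting at zero noise).  Successive layers
    use independent embeddings and are therefore representationally
    distinct.
    """
    if np.isscalar(units_per_layer):
        units_per_layer = [int(units_per_layer)] * gt.n_layers
    if len(units_per_layer) != gt.n_layers:
        raise ValueError("one unit count per layer required")
    if any(u < 2 for u in units_per_layer):
        raise ValueError("each layer needs at least 2 units")
    layers = []
    for l, u in zip(range(1, gt.n_layers + 1), units_per_layer):
        rng = _stream(gt.seed, "model", l)
        Z = gt.latent_embedding(l)
        A = gt.signal_scale * _tile_embed(Z, u, rng)
        if gt.model_noise_sd:
            A = A + gt.model_noise_sd * rng.standard_normal(
                (gt.n_conditions, u))
        layers.append((l, A))
    return LayerActivations(layers)


def simulate_meg_subject(gt: GroundTruth, subject: int = 0,
                         n_sensors: int = 306, n_trials: int = 30,
                         times_ms: np.ndarray | None = None,
                         smooth_window_ms: float = 20.0) -> TrialTensor:
    """Trial-resolved sensor recordings for one subject.

    The noiseless condition pattern at time t is
    ``sum_l w_l(t) * B_l[c]`` where ``B_l`` maps the layer's latent
    embedding into this subject's sensor space by a subject-specific
    random orthonormal map (distance-preserving, so linear decodability
    mirrors the latent geometry) and ``w_l`` is a Gaussian kernel
    centred at the layer's latency.  Each trial adds ``noise_sd``
    Gaussian noise per sensor and timepoint; emulating the sliding-
    window smoothing of the study's preprocessing, the noise is then
    box-averaged over ``smooth_window_ms`` along time (0 disables).
    The expected decoding-RDM similarity to layer l's RDM peaks at l's
    latency.  With ``signal_scale=0`` conditions are exchangeable and
    pairwise decoding sits at chance.
    """
    if times_ms is None:
        times_ms = gt.epoch_ms
    times_ms = np.asarray(times_ms, dtype=float)
    lo, hi = times_ms.min(), times_ms.max()
    if ((gt.layer_latency_ms < lo) | (gt.layer_latency_ms > hi)).any():
        raise ValueError("times_ms must cover all layer latencies")
    rng = _stream(gt.seed, "meg", subject)
    kern = gt.temporal_kernels(times_ms)  # (layers, times)
    signal = np.zeros((gt.n_conditions, n_sensors, times_ms.size))
    for l in range(1, gt.n_layers + 1):
        Z = gt.latent_embedding(l)
        B = gt.signal_scale * _orthonormal_embed(Z, n_sensors, rng)
        signal += B[:, :, None] * kern[l - 1][None, None, :]
    noise = gt.noise_sd * rng.standard_normal(
        (gt.n_conditions, n_trials, n_sensors, times_ms.size))
    if smooth_window_ms and times_ms.size > 1:
        from scipy.ndimage import uniform_filter1d

        dt = float(np.median(np.diff(times_ms)))
        width = max(1, int(round(smooth_window_ms / dt)))
        if width > 1:
            # rescale so noise_sd stays the per-sample SD regardless of
            # the time grid; smoothing only adds temporal correlation
            noise = uniform_filter1d(noise, size=width, axis=-1,
                                     mode="nearest") * np.sqrt(width)
    data = signal[:, None, :, :] + noise
    return TrialTensor(data, times_ms, subject_id=f"sub-{subject:02d}")


def simulate_fmri_subject(gt: GroundTruth, regions: list[str] | None = None,
                          n_voxels_per_region: int = 100, subject: int = 0,
                          ) -> dict[str, SpatialPatterns]:
    """Condition-by-voxel activation patterns per region for one subject.

    Each region's pattern is ``sum_l beta_l * (Z_l @ W_l)`` for the
    region's per-layer weights plus Gaussian voxel noise, so its RDM is a
    noisy mixture of the layer target RDMs.  Weights must be defined in
    ``gt.layer_region_weights`` for every requested region.
    """
    if n_voxels_per_region <= 0:
        raise ValueError("need at least one voxel per region")
    if regions is None:
        regions = list(gt.layer_region_weights)
    out: dict[str, SpatialPatterns] = {}
    for r_idx, region in enumerate(regions):
        if region not in gt.layer_region_weights:
            raise ValueError(f"no layer weights defined for region {region!r}")
        w = gt.layer_region_weights[region]
        rng = _stream(gt.seed, "fmri", subject, r_idx)
        pat = np.zeros((gt.n_conditions, n_voxels_per_region))
        for l in range(1, gt.n_layers + 1):
            if w[l - 1] == 0:
                continue
            pat += w[l - 1] * gt.signal_scale * _tile_embed(
                gt.latent_embedding(l), n_voxels_per_region, rng)
        pat += gt.fmri_noise_sd * rng.standard_normal(pat.shape)
        voxel_ids = np.array([f"{region}_{v:04d}" for v in range(n_voxels_per_region)])
        out[region] = SpatialPatterns(pat, voxel_ids)
    return out


def _gaussian_kernel_2d(size: int, sd: float) -> np.ndarray:
    """Normalized 2-D Gaussian filter of given support and SD (pixels)."""
    ax = np.arange(size) - (size - 1) / 2.0
    g = np.exp(-0.5 * (ax / sd) ** 2)
    k = np.outer(g, g)
    return k / k.sum()


def generate_noise_images(n: int, size: int = 256, n_channels: int = 3,
                          seed: int = 0, filter_size: int = 10,
                          filter_sd_px: float = 80.0) -> np.ndarray:
    """Structured noise images: smoothed uniform fields.

    Each channel and pixel is drawn independently from uniform [0, 1],
    then convolved with a 2-D Gaussian filter of support
    ``filter_size x filter_size`` and standard deviation
    ``filter_sd_px`` pixels (with that SD the kernel is nearly flat over
    its support, i.e. close to a box blur).  Reflective padding at the
    borders keeps edge statistics comparable to the interior.  The
    smoothing leaves small but perceptible spatial gradients: positive
    lag-1 spatial autocorrelation.

    ``filter_size=1`` degenerates to the identity (raw uniform field).
    Returns (n, size, size, n_channels) float array.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if size < filter_size:
        raise ValueError("image size must be at least the filter size")
    rng = _stream(seed, "images")
    raw = rng.uniform(0.0, 1.0, size=(n, size, size, n_channels))
    if filter_size <= 1:
        return raw
    kernel = _gaussian_kernel_2d(filter_size, filter_sd_px)
    out = np.empty_like(raw)
    for i in range(n):
        for c in range(n_channels):
            out[i, :, :, c] = convolve(raw[i, :, :, c], kernel, mode="reflect")
    return out


def build_toy_mesh(rows: int, cols: int, spacing_mm: float = 3.0) -> SurfaceMesh:
    """Flat triangulated grid mesh with known Euclidean geometry.

    ``rows x cols`` vertices spaced ``spacing_mm`` apart in the z=0
    plane; each unit cell is split into two triangles, giving
    ``2*(rows-1)*(cols-1)`` faces.  Vertex v maps to synthetic voxel v,
    so graph-geodesic and Euclidean predicates can be compared exactly.

    The second diagonal of each cell is added as a graph edge
    (``extra_edges``): a planar triangulation can carry only one
    diagonal per cell, and that arbitrary orientation choice makes
    graph distances anisotropic (e.g. one (2,2)-cell neighbour at
    2*sqrt(2) spacings, the mirrored one at 2+sqrt(2)).  With both
    diagonals the lattice graph is direction-unbiased and disk
    membership at radius 3x the spacing coincides with the flat
    surface's true geodesic (Euclidean) disks.
    """
    if rows < 2 or cols < 2:
        raise ValueError("need at least a 2x2 grid")
    if spacing_mm <= 0:
        raise ValueError("spacing must be positive")
    jj, ii = np.meshgrid(np.arange(cols), np.arange(rows))
    coords = np.column_stack([
        jj.ravel() * spacing_mm, ii.ravel() * spacing_mm,
        np.zeros(rows * cols)])
    faces = []
    anti_diagonals = []
    for r in range(rows - 1):
        for c in range(cols - 1):
            v00 = r * cols + c
            v01, v10, v11 = v00 + 1, v00 + cols, v00 + cols + 1
            faces.append((v00, v01, v11))
            faces.append((v00, v11, v10))
            anti_diagonals.append((v01, v10))
    return SurfaceMesh(coords, np.asarray(faces), np.arange(rows * cols),
                       extra_edges=np.asarray(anti_diagonals))
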