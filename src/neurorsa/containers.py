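"""Core data containers shared across the package.

All pairwise dissimilarities are stored in *condensed* form: a vector of
length ``n*(n-1)/2`` over condition pairs ``(i, j)`` with ``i < j`` in
lexicographic order (the same convention as
:func:`scipy.spatial.distance.squareform`).  The diagonal of a
representational dissimilarity matrix is undefined and never stored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RDM",
    "TrialTensor",
    "SpatialPatterns",
    "LayerActivations",
    "SurfaceMesh",
    "SearchlightDisk",
    "SimilarityTimeCourse",
    "HierarchyResult",
    "ClusterResult",
    "condensed_length",
    "n_conditions_from_condensed",
    "pair_index",
]

#: Valid dissimilarity metrics and their value bounds (NaN = missing entry).
METRIC_BOUNDS = {
    "correlation_distance": (0.0, 2.0),
    "decoding_accuracy_percent": (0.0, 100.0),
}


def condensed_length(n: int) -> int:
    """Number of condition pairs for ``n`` conditions."""
    return n * (n - 1) // 2


def n_conditions_from_condensed(m: int) -> int:
    """Invert ``n*(n-1)/2 = m``; raises if ``m`` is not a valid pair count."""
    n = int(round((1 + np.sqrt(1 + 8 * m)) / 2))
    if condensed_length(n) != m:
        raise ValueError(f"{m} is not a valid condensed length")
    return n


def pair_index(i: int, j: int, n: int) -> int:
    """Index of pair (i, j), i < j, in the condensed vector for n conditions."""
    if not 0 <= i < j < n:
        raise ValueError(f"invalid pair ({i}, {j}) for n={n}")
    return n * i - i * (i + 1) // 2 + (j - i - 1)


@dataclass
class RDM:
    """Condensed representational dissimilarity matrix.

    Parameters
    ----------
    values
        Condensed dissimilarities, length ``n*(n-1)/2``, pairs in
        lexicographic ``i < j`` order.  ``NaN`` marks a missing entry
        (e.g. a pair whose rank correlation was undefined).
    metric
        ``"correlation_distance"`` (bounded [0, 2]) or
        ``"decoding_accuracy_percent"`` (bounded [0, 100]).
    condition_labels
        Optional condition names, length ``n``.
    """

    values: np.ndarray
    metric: str
    condition_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("condensed RDM values must be 1-D")
        if self.metric not in METRIC_BOUNDS:
            raise ValueError(f"unknown metric {self.metric!r}")
        n = n_conditions_from_condensed(self.values.size)
        if self.condition_labels is not None and len(self.condition_labels) != n:
            raise ValueError("condition_labels length must match n_conditions")
        lo, hi = METRIC_BOUNDS[self.metric]
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < lo - 1e-9 or finite.max() > hi + 1e-9):
            raise ValueError(
                f"{self.metric} values outside [{lo}, {hi}]: "
                f"range ({finite.min()}, {finite.max()})"
            )

    @property
    def n_conditions(self) -> int:
        return n_conditions_from_condensed(self.values.size)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def to_square(self) -> np.ndarray:
        """Symmetric square form with NaN on the (undefined) diagonal."""
        n = self.n_conditions
        sq = np.full((n, n), np.nan)
        iu = np.triu_indices(n, k=1)
        sq[iu] = self.values
        sq[(iu[1], iu[0])] = self.values
        return sq

    @classmethod
    def from_square(cls, square: np.ndarray, metric: str,
                    condition_labels: list[str] | None = None) -> "RDM":
        square = np.asarray(square, dtype=float)
        if square.ndim != 2 or square.shape[0] != square.shape[1]:
            raise ValueError("square RDM must be a square matrix")
        off = ~np.eye(square.shape[0], dtype=bool)
        sym = np.isclose(square, square.T, equal_nan=True) | ~off
        if not sym.all():
            raise ValueError("square RDM must be symmetric off the diagonal")
        iu = np.triu_indices(square.shape[0], k=1)
        return cls(square[iu], metric=metric, condition_labels=condition_labels)

    def get(self, i: int, j: int) -> float:
        """Dissimilarity of conditions i and j (order irrelevant)."""
        if i == j:
            raise ValueError("diagonal entries are undefined")
        i, j = min(i, j), max(i, j)
        return float(self.values[pair_index(i, j, self.n_conditions)])


@dataclass
class TrialTensor:
    """Trial-resolved sensor recordings for one subject.

    ``data`` has shape (conditions, trials, sensors, timepoints);
    ``times_ms`` is the strictly increasing timepoint axis in milliseconds.
    """

    data: np.ndarray
    times_ms: np.ndarray
    subject_id: str = "subject"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("TrialTensor data must be 4-D "
                             "(conditions, trials, sensors, timepoints)")
        if self.data.shape[3] != self.times_ms.size:
            raise ValueError("time axis length mismatch")
        if self.data.shape[1] < 2:
            raise ValueError("need at least 2 trials per condition")
        if np.any(np.diff(self.times_ms) <= 0):
            raise ValueError("times_ms must be strictly increasing")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("TrialTensor contains non-finite values")

    @property
    def n_conditions(self) -> int:
        return self.data.shape[0]

    @property
    def n_trials(self) -> int:
        return self.data.shape[1]

    @property
    def n_sensors(self) -> int:
        return self.data.shape[2]

    def time_index(self, t_ms: float) -> int:
        """Index of the timepoint closest to ``t_ms``."""
        return int(np.argmin(np.abs(self.times_ms - t_ms)))


@dataclass
class SpatialPatterns:
    """Condition-wise spatial activation patterns (t-value-like, unitless).

    ``data`` has shape (conditions, voxels); ``voxel_ids`` are unique labels.
    """

    data: np.ndarray
    voxel_ids: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.voxel_ids = np.asarray(self.voxel_ids)
        if self.data.ndim != 2:
            raise ValueError("SpatialPatterns data must be 2-D (conditions, voxels)")
        if self.voxel_ids.size != self.data.shape[1]:
            raise ValueError("voxel_ids length mismatch")
        if len(set(self.voxel_ids.tolist())) != self.voxel_ids.size:
            raise ValueError("duplicate voxel ids")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("SpatialPatterns contains non-finite values")

    @property
    def n_conditions(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    def select_voxels(self, voxel_ids) -> "SpatialPatterns":
        """Subset (and reorder) columns by voxel id."""
        lookup = {v: k for k, v in enumerate(self.voxel_ids.tolist())}
        idx = [lookup[v] for v in voxel_ids]
        return SpatialPatterns(self.data[:, idx], np.asarray(voxel_ids))


@dataclass
class LayerActivations:
    """Ordered per-layer condition-by-unit activation matrices."""

    layers: list[tuple[int, np.ndarray]]

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("no layers")
        idx = [int(i) for i, _ in self.layers]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("layer indices must be strictly increasing")
        mats = [np.asarray(m, dtype=float) for _, m in self.layers]
        n_cond = {m.shape[0] for m in mats}
        if len(n_cond) != 1:
            raise ValueError("all layers must share the condition axis")
        self.layers = list(zip(idx, mats))

    @property
    def n_conditions(self) -> int:
        return self.layers[0][1].shape[0]

    @property
    def layer_indices(self) -> list[int]:
        return [i for i, _ in self.layers]

    @property
    def n_layers(self) -> int:
        return len(self.layers)


@dataclass
class SurfaceMesh:
    """Triangulated cortical surface with a vertex-to-voxel mapping.

    ``vertex_coords`` (n_vertices, 3) in mm; ``faces`` (n_faces, 3) vertex
    indices; ``vertex_to_voxel`` per-vertex voxel id, -1 meaning unmapped.

    ``extra_edges`` optionally adds graph edges beyond the face-derived
    ones.  Synthetic lattice fixtures use it for the second cell
    diagonal: a square lattice's natural neighbour graph is
    8-connected, and restricting the graph to one arbitrary diagonal
    orientation per cell (as a planar triangulation must) biases
    graph-geodesic distances anisotropically.  Meshes loaded from real
    surface files carry face edges only.
    """

    vertex_coords: np.ndarray
    faces: np.ndarray
    vertex_to_voxel: np.ndarray
    extra_edges: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertex_coords = np.asarray(self.vertex_coords, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        self.vertex_to_voxel = np.asarray(self.vertex_to_voxel, dtype=int)
        n = self.vertex_coords.shape[0]
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= n):
            raise ValueError("faces reference invalid vertices")
        if self.vertex_to_voxel.size != n:
            raise ValueError("vertex_to_voxel length mismatch")
        if self.extra_edges is not None:
            self.extra_edges = np.asarray(self.extra_edges, dtype=int)
            if self.extra_edges.size and (self.extra_edges.min() < 0
                                          or self.extra_edges.max() >= n):
                raise ValueError("extra_edges reference invalid vertices")

    @property
    def n_vertices(self) -> int:
        return self.vertex_coords.shape[0]

    def edges(self) -> np.ndarray:
        """Unique undirected mesh edges as an (n_edges, 2) index array."""
        f = self.faces
        e = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [0, 2]]])
        if self.extra_edges is not None and self.extra_edges.size:
            e = np.concatenate([e, self.extra_edges])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    def edge_lengths(self, edges: np.ndarray | None = None) -> np.ndarray:
        if edges is None:
            edges = self.edges()
        d = self.vertex_coords[edges[:, 0]] - self.vertex_coords[edges[:, 1]]
        lengths = np.linalg.norm(d, axis=1)
        if np.any(lengths <= 0):
            raise ValueError("mesh has zero-length edges")
        return lengths


@dataclass
class SearchlightDisk:
    """Voxels feeding the pattern analysis centred on one mesh vertex."""

    center_vertex: int
    member_voxels: np.ndarray

    def __post_init__(self) -> None:
        self.member_voxels = np.asarray(self.member_voxels, dtype=int)
        if self.member_voxels.size == 0:
            raise ValueError("empty searchlight disk")
        if np.unique(self.member_voxels).size != self.member_voxels.size:
            raise ValueError("voxel repeated within a disk")


@dataclass
class SimilarityTimeCourse:
    """Per-subject RDM-similarity values over time.

    ``values`` has shape (n_subjects, n_timepoints) of Spearman R in [-1, 1]
    (NaN = undefined); ``label`` names the model/layer being compared.
    ``bounded=False`` relaxes the [-1, 1] check for derived courses such
    as model differences.
    """

    times_ms: np.ndarray
    values: np.ndarray
    label: str = ""
    bounded: bool = True

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != self.times_ms.size:
            raise ValueError("time axis mismatch")
        finite = self.values[np.isfinite(self.values)]
        if self.bounded and finite.size and (
                finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("similarity values outside [-1, 1]")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]


@dataclass
class HierarchyResult:
    """Layer-number vs peak-latency association, per subject and at group level.

    ``group_R`` is the mean of per-subject Spearman Rs (the default
    group statistic, matching the per-subject sign-permutation test);
    ``subject_mean_R`` is the Spearman R between layer number and the
    subject-averaged latencies (the statistic a subject-average plot
    shows).  ``p_value`` refers to ``group_R``.
    """

    per_subject_R: np.ndarray
    group_R: float
    p_value: float
    subject_mean_R: float = float("nan")

    def __post_init__(self) -> None:
        self.per_subject_R = np.asarray(self.per_subject_R, dtype=float)
        finite = self.per_subject_R[np.isfinite(self.per_subject_R)]
        if finite.size and (np.abs(finite) > 1 + 1e-9).any():
            raise ValueError("Spearman R outside [-1, 1]")


@dataclass
class ClusterResult:
    """Outcome of cluster-extent-corrected sign-permutation inference.

    ``clusters`` is a list of dicts with keys ``members`` (point indices),
    ``extent`` (point count), ``p_corrected`` and ``significant``.
    """

    clusters: list[dict]
    cluster_def_p: float
    cluster_p: float
    bonferroni_factor: int
    point_p: np.ndarray = field(default=None)  # uncorrected per-point p
    null_max_extent: np.ndarray = field(default=None)

    @property
    def significant_mask_length(self) -> int | None:
        return None if self.point_p is None else self.point_p.size

    def significant_mask(self, n_points: int | None = None) -> np.ndarray:
        """Boolean mask of points inside significant clusters."""
        if n_points is None:
            if self.point_p is None:
                raise ValueError("n_points required")
            n_points = self.point_p.size
        mask = np.zeros(n_points, dtype=bool)
        for c in self.clusters:
            if c["significant"]:
                mask[np.asarray(c["members"], dtype=int)] = True
        return mask
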