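"""Surface-based searchlight construction and per-vertex RDMs.

A searchlight disk is the set of voxels mapped from all mesh vertices
less than a geodesic radius (default 9 mm, strict inequality) away from
a centre vertex.  Geodesic distances are approximated, as is standard
for mesh searchlights, by shortest paths along mesh edges weighted by
Euclidean edge length (Dijkstra), not exact polyhedral geodesics.
Voxels mapped from several in-range vertices enter a disk only once.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .containers import RDM, SearchlightDisk, SpatialPatterns, SurfaceMesh
from .rdm import correlation_rdm

__all__ = ["geodesic_distances", "build_disks", "searchlight_rdms",
           "searchlight_similarity_map"]

logger = logging.getLogger(__name__)


def _edge_graph(mesh: SurfaceMesh):
    edges = mesh.edges()
    lengths = mesh.edge_lengths(edges)
    n = mesh.n_vertices
    g = coo_matrix(
        (np.r_[lengths, lengths],
         (np.r_[edges[:, 0], edges[:, 1]], np.r_[edges[:, 1], edges[:, 0]])),
        shape=(n, n))
    return g.tocsr()


def geodesic_distances(mesh: SurfaceMesh, source: int,
                       cutoff_mm: float | None = None) -> dict[int, float]:
    """Graph-geodesic distances from ``source``, truncated at ``cutoff_mm``.

    Returns a mapping vertex -> distance for vertices within the cutoff
    (the source maps to 0.0).  An isolated source yields only itself.
    """
    graph = _edge_graph(mesh)
    limit = np.inf if cutoff_mm is None else float(cutoff_mm)
    dist = dijkstra(graph, indices=source, limit=limit)
    within = np.flatnonzero(np.isfinite(dist) & (dist <= limit))
    return {int(v): float(dist[v]) for v in within}


def build_disks(mesh: SurfaceMesh, radius_mm: float = 9.0
                ) -> list[SearchlightDisk]:
    """One geodesic searchlight disk per vertex.

    Member voxels are the deduplicated voxel ids of all vertices with
    geodesic distance strictly less than ``radius_mm`` from the centre,
    ordered by distance (centre first) with ties broken by vertex index.
    Vertices whose disk contains no mapped voxel are dropped and logged.
    """
    if radius_mm <= 0:
        raise ValueError("radius must be positive")
    graph = _edge_graph(mesh)
    dist = dijkstra(graph, limit=radius_mm)  # (n, n), inf beyond limit
    disks: list[SearchlightDisk] = []
    n_dropped = 0
    for v in range(mesh.n_vertices):
        d = dist[v]
        members = np.flatnonzero(d < radius_mm)  # strict: "less than r away"
        members = members[np.lexsort((members, d[members]))]
        voxels = mesh.vertex_to_voxel[members]
        voxels = voxels[voxels >= 0]
        # deduplicate keeping first (nearest) occurrence
        _, first = np.unique(voxels, return_index=True)
        voxels = voxels[np.sort(first)]
        if voxels.size == 0:
            n_dropped += 1
            continue
        disks.append(SearchlightDisk(center_vertex=v, member_voxels=voxels))
    if n_dropped:
        logger.warning("build_disks: %d vertices dropped (no mapped voxel "
                       "within radius)", n_dropped)
    return disks


def searchlight_rdms(disks: list[SearchlightDisk], patterns: SpatialPatterns,
                     voxel_id_of: dict[int, object] | None = None
                     ) -> dict[int, RDM]:
    """Correlation RDM per searchlight disk, keyed by centre vertex.

    ``voxel_id_of`` optionally maps integer disk voxel ids to the labels
    used in ``patterns.voxel_ids`` (identity by default).  Disks with a
    single voxel still yield an RDM when the single-feature rank
    correlation is defined; degenerate entries propagate as missing.
    """
    lookup = {v: k for k, v in enumerate(patterns.voxel_ids.tolist())}
    out: dict[int, RDM] = {}
    for disk in disks:
        ids = disk.member_voxels
        if voxel_id_of is not None:
            ids = [voxel_id_of[int(v)] for v in ids]
        cols = [lookup[v] for v in np.asarray(ids).tolist()]
        sub = patterns.data[:, cols]
        if sub.shape[1] < 2:
            logger.warning("searchlight_rdms: disk at vertex %d has < 2 "
                           "voxels; RDM undefined, flagged missing",
                           disk.center_vertex)
            out[disk.center_vertex] = RDM(
                np.full(patterns.n_conditions * (patterns.n_conditions - 1) // 2,
                        np.nan),
                metric="correlation_distance")
            continue
        out[disk.center_vertex] = correlation_rdm(sub)
    return out


def searchlight_similarity_map(disk_rdms: dict[int, RDM], model_rdm: RDM
                               ) -> dict[int, float]:
    """Per-vertex Spearman similarity between disk RDMs and a model RDM."""
    from .compare import compare_rdms
    return {v: compare_rdms(r, model_rdm) for v, r in disk_rdms.items()}
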