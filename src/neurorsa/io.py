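"""Reading and writing the package's on-disk formats.

HDF5 (via h5py) is the primary container for arrays (bit-exact
round-trips); plain-text exports (square CSV with empty diagonal cells,
OFF meshes, tidy CSVs, PNG images) serve interchange and inspection.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import (
    RDM,
    LayerActivations,
    SimilarityTimeCourse,
    SpatialPatterns,
    SurfaceMesh,
    TrialTensor,
)

__all__ = [
    "save_rdm_h5", "load_rdm_h5", "export_rdm_csv", "import_rdm_csv",
    "save_trial_tensor_h5", "load_trial_tensor_h5",
    "save_spatial_patterns_h5", "load_spatial_patterns_h5",
    "save_layer_activations_h5", "load_layer_activations_h5",
    "save_layer_activations_csv", "load_layer_activations_csv",
    "save_mesh_off", "load_mesh_off",
    "save_vertex_map_csv", "load_vertex_map_csv",
    "save_images_png", "timecourse_to_csv", "timecourse_from_csv",
    "write_manifest",
]


# -- RDM ------------------------------------------------------------------

def save_rdm_h5(rdm: RDM, path, group: str = "rdm") -> None:
    """HDF5 group {values, n_conditions, metric, labels}; bit-exact."""
    with h5py.File(path, "a") as f:
        if group in f:
            del f[group]
        g = f.create_group(group)
        g.create_dataset("values", data=rdm.values)
        g.attrs["n_conditions"] = rdm.n_conditions
        g.attrs["metric"] = rdm.metric
        if rdm.condition_labels is not None:
            g.create_dataset("labels",
                             data=np.array(rdm.condition_labels, dtype="S"))


def load_rdm_h5(path, group: str = "rdm") -> RDM:
    with h5py.File(path, "r") as f:
        g = f[group]
        labels = None
        if "labels" in g:
            labels = [s.decode() for s in g["labels"][()]]
        return RDM(g["values"][()], metric=g.attrs["metric"],
                   condition_labels=labels)


def export_rdm_csv(rdm: RDM, path) -> None:
    """Square CSV with empty diagonal cells (human-readable export)."""
    sq = rdm.to_square()
    n = rdm.n_conditions
    labels = rdm.condition_labels or [f"cond{i}" for i in range(n)]
    with open(path, "w") as fh:
        fh.write("," + ",".join(labels) + "\n")
        for i in range(n):
            cells = ["" if i == j or not np.isfinite(sq[i, j])
                     else repr(float(sq[i, j])) for j in range(n)]
            fh.write(labels[i] + "," + ",".join(cells) + "\n")


def import_rdm_csv(path, metric: str) -> RDM:
    df = pd.read_csv(path, index_col=0)
    sq = df.to_numpy(dtype=float)
    return RDM.from_square(sq, metric=metric,
                           condition_labels=list(df.columns))


# -- TrialTensor / SpatialPatterns / LayerActivations ---------------------

def save_trial_tensor_h5(t: TrialTensor, path, group: str = "trials") -> None:
    with h5py.File(path, "a") as f:
        if group in f:
            del f[group]
        g = f.create_group(group)
        g.create_dataset("data", data=t.data)
        g.create_dataset("times_ms", data=t.times_ms)
        g.attrs["subject_id"] = t.subject_id


def load_trial_tensor_h5(path, group: str = "trials") -> TrialTensor:
    with h5py.File(path, "r") as f:
        g = f[group]
        return TrialTensor(g["data"][()], g["times_ms"][()],
                           subject_id=str(g.attrs["subject_id"]))


def save_spatial_patterns_h5(p: SpatialPatterns, path,
                             group: str = "patterns") -> None:
    with h5py.File(path, "a") as f:
        if group in f:
            del f[group]
        g = f.create_group(group)
        g.create_dataset("data", data=p.data)
        g.create_dataset("labels",
                         data=np.array([str(v) for v in p.voxel_ids],
                                       dtype="S"))


def load_spatial_patterns_h5(path, group: str = "patterns") -> SpatialPatterns:
    with h5py.File(path, "r") as f:
        g = f[group]
        ids = np.array([s.decode() for s in g["labels"][()]])
        return SpatialPatterns(g["data"][()], ids)


def save_layer_activations_h5(acts: LayerActivations, path,
                              group: str = "layers") -> None:
    with h5py.File(path, "a") as f:
        if group in f:
            del f[group]
        g = f.create_group(group)
        for idx, mat in acts.layers:
            g.create_dataset(f"layer_{idx:03d}", data=mat)


def load_layer_activations_h5(path, group: str = "layers") -> LayerActivations:
    with h5py.File(path, "r") as f:
        g = f[group]
        layers = sorted((int(name.split("_")[1]), g[name][()]) for name in g)
        return LayerActivations(layers)


def save_layer_activations_csv(acts: LayerActivations, out_dir) -> list[Path]:
    """One ``layer_<idx>.csv`` (conditions x units, no header) per layer."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for idx, mat in acts.layers:
        p = out_dir / f"layer_{idx:03d}.csv"
        np.savetxt(p, mat, delimiter=",")
        paths.append(p)
    return paths


def load_layer_activations_csv(paths) -> LayerActivations:
    layers = []
    for p in paths:
        idx = int(Path(p).stem.split("_")[1])
        layers.append((idx, np.loadtxt(p, delimiter=",", ndmin=2)))
    return LayerActivations(sorted(layers))


# -- SurfaceMesh ----------------------------------------------------------

def save_mesh_off(mesh: SurfaceMesh, path) -> None:
    """OFF-style text file (vertex coordinates in mm, triangular faces)."""
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{mesh.n_vertices} {len(mesh.faces)} 0\n")
        for v in mesh.vertex_coords:
            fh.write(f"{float(v[0])!r} {float(v[1])!r} {float(v[2])!r}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def load_mesh_off(path, vertex_to_voxel: np.ndarray | None = None
                  ) -> SurfaceMesh:
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if lines[0] != "OFF":
        raise ValueError("not an OFF file")
    nv, nf, _ = (int(x) for x in lines[1].split())
    coords = np.array([[float(x) for x in ln.split()]
                       for ln in lines[2:2 + nv]])
    faces = np.array([[int(x) for x in ln.split()[1:4]]
                      for ln in lines[2 + nv:2 + nv + nf]], dtype=int
                     ).reshape(nf, 3)
    if vertex_to_voxel is None:
        vertex_to_voxel = np.arange(nv)
    return SurfaceMesh(coords, faces, vertex_to_voxel)


def save_vertex_map_csv(mesh: SurfaceMesh, path) -> None:
    pd.DataFrame({"vertex": np.arange(mesh.n_vertices),
                  "voxel": mesh.vertex_to_voxel}).to_csv(path, index=False)


def load_vertex_map_csv(path) -> np.ndarray:
    df = pd.read_csv(path).sort_values("vertex")
    return df["voxel"].to_numpy(dtype=int)


# -- images / time courses / manifests ------------------------------------

def save_images_png(images: np.ndarray, out_dir, prefix: str = "img"
                    ) -> list[Path]:
    """Write an (n, H, W[, C]) float [0, 1] stack as 8-bit PNGs."""
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, img in enumerate(images):
        arr = np.clip(np.asarray(img) * 255.0, 0, 255).astype(np.uint8)
        p = out_dir / f"{prefix}_{i:04d}.png"
        Image.fromarray(arr).save(p)
        paths.append(p)
    return paths


def timecourse_to_csv(tc: SimilarityTimeCourse, path) -> None:
    """Tidy CSV: one row per (subject, time_ms) with the similarity value."""
    n_sub, n_t = tc.values.shape
    df = pd.DataFrame({
        "subject": np.repeat(np.arange(n_sub), n_t),
        "time_ms": np.tile(tc.times_ms, n_sub),
        "value": tc.values.ravel(),
        "label": tc.label,
    })
    df.to_csv(path, index=False)


def timecourse_from_csv(path) -> SimilarityTimeCourse:
    df = pd.read_csv(path)
    times = np.sort(df["time_ms"].unique())
    subjects = np.sort(df["subject"].unique())
    piv = df.pivot(index="subject", columns="time_ms", values="value")
    piv = piv.loc[subjects, times]
    label = str(df["label"].iloc[0]) if "label" in df else ""
    return SimilarityTimeCourse(times, piv.to_numpy(), label=label,
                                bounded=False)


def write_manifest(path, config: dict, seed: int, extra: dict | None = None
                   ) -> None:
    """JSON run manifest: config hash, seed, package/library versions."""
    import hashlib
    import sklearn
    import scipy

    from . import __version__

    cfg_json = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "config": config,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": int(seed),
        "versions": {
            "neurorsa": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "sklearn": sklearn.__version__,
        },
    }
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
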