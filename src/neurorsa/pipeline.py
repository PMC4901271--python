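"""End-to-end experiment orchestration.

Three canned experiments mirror the analysis figures a study of this
kind reports:

* ``run_temporal_experiment`` — simulate MEG subjects, build decoding
  RDM time series, compare against model layer RDMs, extract peak
  latencies, test the layer-vs-latency hierarchy and run cluster-
  corrected group inference per layer;
* ``run_spatial_experiment`` — simulate voxel patterns on a surface
  mesh with model structure painted on a patch, run the geodesic
  searchlight and localize the model similarity maximum;
* ``run_model_comparison`` — compare two models' summary RDMs against
  the same MEG data and contrast the resulting time courses.

Every run can write a JSON manifest (config hash, seed, versions)
sufficient to reproduce its outputs bit-exactly.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import compare, inference, io, rdm, searchlight, synth

__all__ = ["RunConfig", "run_temporal_experiment", "run_spatial_experiment",
           "run_model_comparison"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters of a simulated experiment.

    Defaults are the emulated study's conditions: 118 images, 15
    subjects, 306 sensors, 30 trials, sub-averaging k=5 with 100
    repetitions, -100..1000 ms at 1 ms, 10,000 sign permutations,
    1,000 bootstraps, 9 mm searchlight radius.  Desk-scale runs pass
    smaller values explicitly.
    """

    seed: int = 0
    n_conditions: int = 118
    n_subjects: int = 15
    n_layers: int = 8
    n_sensors: int = 306
    n_trials: int = 30
    units_per_layer: int = 256
    k: int = 5
    n_reps: int = 100
    epoch_start_ms: float = -100.0
    epoch_stop_ms: float = 1000.0
    time_step_ms: float = 1.0
    hierarchy_sign: int = +1
    base_latency_ms: float = 100.0
    latency_step_ms: float = 10.0
    signal_scale: float = 1.0
    noise_sd: float = 10.0
    latent_dim: int = 20
    kernel_width_ms: float = 20.0
    searchlight_radius_mm: float = 9.0
    mesh_rows: int = 10
    mesh_cols: int = 10
    mesh_spacing_mm: float = 3.0
    n_perm: int = 10_000
    n_boot: int = 1_000
    cluster_def_p: float = 0.05
    cluster_p: float = 0.05
    bonferroni_factor: int | None = None  # default: one per layer map
    n_jobs: int = 1
    out_dir: str | None = None

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.epoch_start_ms, self.epoch_stop_ms + 1e-9,
                         self.time_step_ms)

    @classmethod
    def desk_scale(cls, seed: int = 0, hierarchy_sign: int = +1,
                   **overrides) -> "RunConfig":
        """Scaled reference configuration for recovery analyses.

        Sixteen conditions, 128 sensors, 8 repetitions of the
        sub-averaging, a 60-240 ms analysis grid at 10 ms — sizes
        chosen so a full 15-subject recovery run completes in minutes
        while keeping peak pairwise decoding in the realistic 70-90%
        band (see docs/methods.md).  Subject count, trials, k and the
        latency gradient stay at the study's values.
        """
        base = dict(
            seed=seed, n_conditions=16, n_subjects=15, n_layers=8,
            n_sensors=128, n_trials=30, units_per_layer=64, k=5, n_reps=8,
            epoch_start_ms=60.0, epoch_stop_ms=240.0, time_step_ms=10.0,
            hierarchy_sign=hierarchy_sign, base_latency_ms=100.0,
            latency_step_ms=10.0, latent_dim=20, n_perm=10_000)
        base.update(overrides)
        return cls(**base)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        valid = set(cls.__dataclass_fields__)
        unknown = set(raw) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


def _ground_truth(cfg: RunConfig) -> synth.GroundTruth:
    return synth.make_ground_truth(
        n_conditions=cfg.n_conditions, n_layers=cfg.n_layers,
        hierarchy_sign=cfg.hierarchy_sign,
        base_latency_ms=cfg.base_latency_ms,
        latency_step_ms=cfg.latency_step_ms,
        signal_scale=cfg.signal_scale, noise_sd=cfg.noise_sd,
        latent_dim=cfg.latent_dim, kernel_width_ms=cfg.kernel_width_ms,
        epoch_ms=cfg.times_ms, seed=cfg.seed)


def subject_layer_timecourses(cfg: RunConfig,
                              model_rdms: list | None = None,
                              gt: synth.GroundTruth | None = None
                              ) -> tuple[list, np.ndarray]:
    """Per-layer multi-subject similarity time courses for one experiment.

    Returns ``(timecourses, times_ms)`` where ``timecourses[l]`` stacks
    all subjects' similarity-to-layer-l time courses.
    """
    gt = gt or _ground_truth(cfg)
    if model_rdms is None:
        acts = synth.simulate_layer_activations(gt, cfg.units_per_layer)
        model_rdms = rdm.layer_rdms(acts)
    times = cfg.times_ms
    per_layer: list[list] = [[] for _ in model_rdms]
    for s in range(cfg.n_subjects):
        trials = synth.simulate_meg_subject(
            gt, subject=s, n_sensors=cfg.n_sensors, n_trials=cfg.n_trials,
            times_ms=times)
        _, meg_rdms = rdm.decoding_rdm_timeseries(
            trials, k=cfg.k, n_reps=cfg.n_reps,
            seed=int(np.random.SeedSequence(
                entropy=cfg.seed, spawn_key=(100, s)).generate_state(1)[0]
                     % 2**31),
            n_jobs=cfg.n_jobs)
        for li, mrdm in enumerate(model_rdms):
            per_layer[li].append(
                compare.timecourse(times, meg_rdms, mrdm,
                                   label=f"layer{li + 1}"))
        logger.info("temporal experiment: subject %d/%d done", s + 1,
                    cfg.n_subjects)
    return [compare.stack_timecourses(tcs) for tcs in per_layer], times


def run_temporal_experiment(cfg: RunConfig) -> dict:
    """Simulate, decode, compare and test the temporal hierarchy."""
    gt = _ground_truth(cfg)
    acts = synth.simulate_layer_activations(gt, cfg.units_per_layer)
    model_rdms = rdm.layer_rdms(acts)
    tcs, times = subject_layer_timecourses(cfg, model_rdms, gt)
    window = (max(0.0, times.min()), times.max())
    latencies = np.column_stack(
        [compare.peak_latency(tc, window_ms=window) for tc in tcs])
    hier = compare.hierarchy_statistic(latencies, n_perm=cfg.n_perm,
                                       seed=cfg.seed)
    bonf = cfg.bonferroni_factor or len(tcs)
    clusters = []
    onsets = []
    for tc in tcs:
        cr = inference.cluster_extent_correct(
            tc.values, cluster_def_p=cfg.cluster_def_p,
            cluster_p=cfg.cluster_p, n_perm=cfg.n_perm,
            bonferroni_factor=bonf, seed=cfg.seed, tail="greater")
        clusters.append(cr)
        onsets.append(compare.onset_latency(tc, cr.significant_mask()))
    latency_se = [inference.bootstrap_se(latencies[:, li], n_boot=cfg.n_boot,
                                         seed=cfg.seed + li)
                  for li in range(latencies.shape[1])]
    report = {
        "times_ms": times,
        "timecourses": tcs,
        "peak_latencies_ms": latencies,
        "peak_latency_se_ms": np.asarray(latency_se),
        "onset_latencies_ms": np.asarray(onsets),
        "hierarchy": hier,
        "clusters": clusters,
        "true_latencies_ms": gt.layer_latency_ms,
    }
    if cfg.out_dir:
        _write_temporal_outputs(cfg, report)
    return report


def _write_temporal_outputs(cfg: RunConfig, report: dict) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for li, tc in enumerate(report["timecourses"]):
        io.timecourse_to_csv(tc, out / f"timecourse_layer{li + 1}.csv")
    np.savetxt(out / "peak_latencies_ms.csv", report["peak_latencies_ms"],
               delimiter=",")
    hier = report["hierarchy"]
    io.write_manifest(out / "manifest.json", cfg.to_dict(), cfg.seed,
                      extra={"group_R": hier.group_R,
                             "p_value": hier.p_value})


def painted_patch_patterns(cfg: RunConfig, mesh, subject: int = 0,
                           layer: int | None = None,
                           gt: synth.GroundTruth | None = None):
    """Voxel patterns on a mesh with model structure painted on a patch.

    The "anterior" patch (vertices in the upper third of the grid's y
    range) carries the chosen layer's latent geometry; all other voxels
    are pure noise.  Returns ``(SpatialPatterns, patch_voxel_ids)``.
    """
    gt = gt or _ground_truth(cfg)
    layer = layer if layer is not None else gt.n_layers
    y = mesh.vertex_coords[:, 1]
    patch = np.flatnonzero(y > y.min() + 2.0 * (y.max() - y.min()) / 3.0)
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=(200, subject)))
    n_vox = mesh.n_vertices
    data = gt.fmri_noise_sd * rng.standard_normal((gt.n_conditions, n_vox))
    Z = gt.latent_embedding(layer)
    W = rng.standard_normal((gt.latent_dim, patch.size)) / np.sqrt(gt.latent_dim)
    data[:, patch] += gt.signal_scale * (Z @ W)
    from .containers import SpatialPatterns
    return SpatialPatterns(data, np.arange(n_vox)), patch


def run_spatial_experiment(cfg: RunConfig) -> dict:
    """Searchlight mapping with localization of painted model structure."""
    gt = _ground_truth(cfg)
    acts = synth.simulate_layer_activations(gt, cfg.units_per_layer)
    model_rdms = rdm.layer_rdms(acts)
    mesh = synth.build_toy_mesh(cfg.mesh_rows, cfg.mesh_cols,
                                cfg.mesh_spacing_mm)
    disks = searchlight.build_disks(mesh, cfg.searchlight_radius_mm)
    painted_layer = gt.n_layers
    subj_maps = []  # (subjects, layers, vertices)
    vertices = np.array([d.center_vertex for d in disks])
    patch = None
    for s in range(cfg.n_subjects):
        patterns, patch = painted_patch_patterns(cfg, mesh, subject=s,
                                                 layer=painted_layer, gt=gt)
        disk_rdms = searchlight.searchlight_rdms(disks, patterns)
        subj_maps.append(np.array(
            [[compare.compare_rdms(disk_rdms[v], mrdm) for v in vertices]
             for mrdm in model_rdms]))
    maps = np.array(subj_maps)  # (subjects, layers, vertices)
    group_map = np.nanmean(maps, axis=0)
    painted_map = group_map[painted_layer - 1]
    peak_vertex = int(vertices[int(np.nanargmax(painted_map))])
    report = {
        "mesh": mesh,
        "vertices": vertices,
        "maps": maps,
        "group_maps": group_map,
        "patch_vertices": patch,
        "painted_layer": painted_layer,
        "peak_vertex": peak_vertex,
        "peak_in_patch": bool(peak_vertex in set(patch.tolist())),
    }
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        import pandas as pd
        for li in range(group_map.shape[0]):
            pd.DataFrame({"vertex_id": vertices,
                          "value": group_map[li]}).to_csv(
                out / f"similarity_map_layer{li + 1}.csv", index=False)
        io.save_mesh_off(mesh, out / "mesh.off")
        io.save_vertex_map_csv(mesh, out / "vertex_to_voxel.csv")
        io.write_manifest(out / "manifest.json", cfg.to_dict(), cfg.seed,
                          extra={"peak_vertex": peak_vertex,
                                 "peak_in_patch": report["peak_in_patch"]})
    return report


def run_model_comparison(cfg: RunConfig, alt_seed_offset: int = 7919) -> dict:
    """Contrast two models' summary RDMs against the same MEG data.

    Model A shares the generator's latent geometry (a "trained" model);
    model B is built from an independent ground truth (same
    architecture, unrelated representations).  Their per-subject
    similarity time courses are subtracted and tested with two-sided
    cluster-corrected sign permutation; the divergence onset is the
    first timepoint of the earliest significant difference cluster.
    """
    gt = _ground_truth(cfg)
    acts_a = synth.simulate_layer_activations(gt, cfg.units_per_layer)
    gt_alt = _ground_truth(
        RunConfig(**{**cfg.to_dict(), "seed": cfg.seed + alt_seed_offset}))
    acts_b = synth.simulate_layer_activations(gt_alt, cfg.units_per_layer)
    rdm_a = rdm.summary_rdm(acts_a)
    rdm_b = rdm.summary_rdm(acts_b)
    # one decoding pass; both models are compared to the same MEG RDMs
    (tc_a, tc_b), times = subject_layer_timecourses(cfg, [rdm_a, rdm_b], gt)
    diff = compare.model_difference_timecourse(tc_a, tc_b, label="A-minus-B")
    cr = inference.cluster_extent_correct(
        diff.values, cluster_def_p=cfg.cluster_def_p, cluster_p=cfg.cluster_p,
        n_perm=cfg.n_perm, bonferroni_factor=cfg.bonferroni_factor or 1,
        seed=cfg.seed, tail="two-sided")
    divergence_ms = compare.onset_latency(diff, cr.significant_mask())
    report = {
        "times_ms": times,
        "timecourse_a": tc_a,
        "timecourse_b": tc_b,
        "difference": diff,
        "clusters": cr,
        "divergence_ms": divergence_ms,
    }
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.timecourse_to_csv(tc_a, out / "timecourse_model_a.csv")
        io.timecourse_to_csv(tc_b, out / "timecourse_model_b.csv")
        io.timecourse_to_csv(diff, out / "timecourse_difference.csv")
        io.write_manifest(out / "manifest.json", cfg.to_dict(), cfg.seed,
                          extra={"divergence_ms": divergence_ms})
    return report
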