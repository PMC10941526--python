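"""End-to-end orchestration: simulate -> vb -> smooth -> stats.

Each stage writes its artifacts under the run directory and is skipped on a
re-run when its outputs already exist, so deleting only the ``stats``
directory and re-running recomputes only the inference stage.  A manifest
captures the configuration, package version and all seeds; a failed stage
leaves a ``FAILED`` marker naming the stage and subject.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .geometry_io import (CohortTable, SubjectRecord, load_vertex_map,
                          save_cohort_csv, save_json, save_mesh,
                          save_vertex_map, save_volume)
from .group_inference import (TfceParams, design_from_cohort, permutation_fwe,
                              residualize_nuisance_map)
from .surface_smoothing import smooth_map, smoothing_matrix
from .synthetic_data import SimulationParams, synth_cohort
from .vb_core import vb_map


@dataclass(frozen=True)
class RunConfig:
    out_dir: str
    sim: SimulationParams = SimulationParams()
    min_neighbourhood: int = 3
    fwhm: float = 4.0                  # mm
    n_perm: int = 10_000
    alpha: float = 0.05
    n_hemispheres: int = 2
    tfce: TfceParams = TfceParams()
    seed: int = 0

    def validate(self):
        if self.sim.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        sim = SimulationParams(**{k: tuple(v) if isinstance(v, list) else v
                                  for k, v in raw.pop("sim", {}).items()})
        tfce = TfceParams(**raw.pop("tfce", {}))
        return cls(sim=sim, tfce=tfce, **raw)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_experiment(config: RunConfig) -> Path:
    """Execute every stage; returns the run directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()

    stage = "simulate"
    subject_id = ""
    try:
        cohort, labels = _stage_simulate(config, out)
        stage = "vb"
        vb_values = []
        for subj in cohort.subjects:
            subject_id = subj.subject_id
            vb_values.append(_stage_vb(config, out, subj))
        subject_id = ""
        stage = "smooth"
        smoothed = _stage_smooth(config, out, cohort, vb_values)
        stage = "stats"
        result = _stage_stats(config, out, cohort, smoothed)
    except Exception as exc:
        failed_marker.write_text(f"stage={stage} subject={subject_id}: {exc}\n")
        raise

    if result is None:  # stats stage previously completed; nothing to update
        return out
    save_json(out / "manifest.json", {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "n_permutations": result.n_permutations,
        "null_max_pos_quantiles": np.quantile(
            result.null_max_pos, [0.5, 0.95, 0.99]).tolist(),
    })
    return out


def _stage_simulate(config: RunConfig, out: Path):
    cohort, labels = synth_cohort(config.sim.with_(rng_seed=config.seed))
    mesh_path = out / "mesh.surf.gii"
    if not mesh_path.exists():
        save_mesh(mesh_path, cohort.subjects[0].mesh)
        rows = []
        for s in cohort.subjects:
            fpath = out / f"{s.subject_id}_features.nii.gz"
            mpath = out / f"{s.subject_id}_mask.nii.gz"
            save_volume(fpath, s.features.data, s.features.affine)
            save_volume(mpath, s.features.mask.astype(np.uint8), s.features.affine)
            rows.append({"subject_id": s.subject_id, "group": s.group,
                         "pma_at_scan": s.pma_at_scan, "sex": s.sex,
                         "mesh_path": str(mesh_path), "features_path": str(fpath),
                         "mask_path": str(mpath), "nuisance_path": ""})
        save_cohort_csv(out / "cohort.csv", rows)
        save_json(out / "ground_truth.json", {
            "effect_vertices": cohort.effect_vertices,
            "patch_labels": labels.labels,
            "seed": config.seed,
            "params": dataclasses.asdict(config.sim),
        })
    return cohort, labels


def _stage_vb(config: RunConfig, out: Path, subj: SubjectRecord) -> np.ndarray:
    path = out / f"{subj.subject_id}_vb.func.gii"
    if path.exists():
        return load_vertex_map(path)
    vbm = vb_map(subj, min_neighbourhood=config.min_neighbourhood)
    save_vertex_map(path, vbm.values, subj.mesh)
    save_vertex_map(out / f"{subj.subject_id}_vb_nsize.func.gii",
                    vbm.neighbourhood_sizes.astype(float), subj.mesh)
    # reload so fresh and resumed runs see identical (file-precision) values
    return load_vertex_map(path)


def _stage_smooth(config: RunConfig, out: Path, cohort: CohortTable,
                  vb_values: list[np.ndarray]) -> np.ndarray:
    mesh = cohort.subjects[0].mesh
    kernel = smoothing_matrix(mesh, config.fwhm)
    rows = []
    for subj, values in zip(cohort.subjects, vb_values):
        path = out / f"{subj.subject_id}_vb_smoothed.func.gii"
        if path.exists():
            rows.append(load_vertex_map(path))
            continue
        sm = smooth_map(mesh, values, config.fwhm, kernel=kernel)
        save_vertex_map(path, sm, mesh)
        rows.append(load_vertex_map(path))
    return np.vstack(rows)


def _stage_stats(config: RunConfig, out: Path, cohort: CohortTable,
                 maps: np.ndarray):
    stats_dir = out / "stats"
    if (stats_dir / "report.json").exists():
        return None
    stats_dir.mkdir(exist_ok=True)
    mesh = cohort.subjects[0].mesh
    nuisance = [s.nuisance_map for s in cohort.subjects]
    if all(nm is not None for nm in nuisance):
        maps = residualize_nuisance_map(maps, np.vstack(nuisance))
    X, contrast, _ = design_from_cohort(cohort)
    result = permutation_fwe(maps, X, contrast, mesh, n_perm=config.n_perm,
                             rng_seed=config.seed, tfce_params=config.tfce,
                             alpha=config.alpha,
                             n_hemispheres=config.n_hemispheres)
    for name, arr in [("tstat", result.t_map),
                      ("tfce_pos", result.tfce_pos),
                      ("tfce_neg", result.tfce_neg),
                      ("pfwe_pos", result.p_pos),
                      ("pfwe_neg", result.p_neg)]:
        save_vertex_map(stats_dir / f"{name}.func.gii", arr, mesh)

    sig_pos = result.significance_mask("pos")
    sig_neg = result.significance_mask("neg")
    report = {
        "n_subjects": len(cohort),
        "alpha_threshold": result.alpha_threshold,
        "n_permutations": result.n_permutations,
        "exhaustive": result.exhaustive,
        "n_significant_pos": int(sig_pos.sum()),
        "n_significant_neg": int(sig_neg.sum()),
        "n_missing_vertices": int(np.isnan(result.t_map).sum()),
    }
    gt_path = out / "ground_truth.json"
    if gt_path.exists() and cohort.effect_vertices is not None:
        truth = np.zeros(mesh.vertex_count, dtype=bool)
        truth[cohort.effect_vertices] = True
        tp = int((sig_pos & truth).sum())
        report["effect_sensitivity"] = tp / max(int(truth.sum()), 1)
        report["effect_false_discovery_proportion"] = (
            int((sig_pos & ~truth).sum()) / max(int(sig_pos.sum()), 1))
    save_json(stats_dir / "report.json", report)
    return result
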