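"""End-to-end pipeline: simulate → parcellate → stability → group → maps →
fingerprints → contrasts → PLS, with a checksummed output manifest.

Every run is reproducible from (config, seed): the resolved configuration is
written beside the outputs and the manifest lists each artifact with its
SHA-256 checksum, so a rerun can be verified bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io, maps, synthetic, task
from .parcellation import build_similarity, group_parcellation, spectral_parcellate
from .pls import BehavioralPLS
from .stability import (interhemispheric_similarity, select_k,
                        split_half_stability)

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Parameters of the full synthetic-data pipeline.

    Defaults follow the study conditions the analysis assumes: K candidates
    2..8 per hemisphere, 100 split-half repeats, tract-map thresholds
    0.001 (noise) / 0.5 (population fraction) / 0.01 (MPM binarization),
    5000 streamlines per seed voxel and 10,000 per subdivision, and 1000
    permutations/bootstraps for PLS.
    """

    # synthetic-data sizes
    n_subjects: int = 20
    n_per_hemisphere: int = 150
    k_true: int = 3
    n_targets: int = 500
    noise_scale: float = 0.005
    streams_per_voxel: int = synthetic.DEFAULT_STREAMS_PER_VOXEL
    total_streams: int = synthetic.DEFAULT_TOTAL_STREAMS
    n_tract_voxels: int = 1000
    n_atlas_parcels: int = 12
    n_behavior_subjects: int = 450
    p_brain: int = 7
    q_behavior: int = 2
    latent_strength: float = 0.2
    # analysis parameters
    k_min: int = 2
    k_max: int = 8
    n_repeats: int = 100
    noise_threshold: float = 0.001
    population_fraction: float = 0.5
    mpm_threshold: float = 0.01
    n_perm: int = 1000
    n_boot: int = 1000
    affinity: str = "shift"
    nmi_variant: str = "arithmetic"
    exclusion_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("noise_threshold", "population_fraction", "mpm_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 2 <= self.k_min < self.k_max:
            raise ValueError("need 2 <= k_min < k_max")
        if self.k_max > self.n_per_hemisphere:
            raise ValueError("k_max exceeds the per-hemisphere voxel count")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _atlas_labels(shape: tuple[int, ...], n_parcels: int) -> np.ndarray:
    """Partition a volume into contiguous equal-count parcels (synthetic atlas)."""
    n = int(np.prod(shape))
    flat = np.repeat(np.arange(1, n_parcels + 1), int(np.ceil(n / n_parcels)))[:n]
    return flat.reshape(shape)


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute every stage on synthetic data; returns the output manifest.

    Any stage failure aborts with the stage name attached, after writing the
    partial manifest collected so far.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "artifacts": {}, "results": {}}
    stage = "setup"

    def _register(name: str, path: Path) -> None:
        manifest["artifacts"][name] = {
            "path": str(path), "sha256": io.sha256_of(path)}

    try:
        stage = "simulate"
        geometry = synthetic.make_seed_geometry(config.n_per_hemisphere,
                                                rng_seed=config.seed)
        truth = synthetic.make_planted_truth(
            geometry, k_true=config.k_true, n_targets=config.n_targets,
            noise_scale=config.noise_scale, latent_strength=config.latent_strength,
            n_brain=config.p_brain, n_behavior=config.q_behavior)
        conns = synthetic.simulate_connectivity(
            geometry, truth, config.n_subjects,
            streams_per_voxel=config.streams_per_voxel, rng_seed=config.seed + 1)
        for s, conn in enumerate(conns):
            path = out / f"connectivity_subject{s:03d}.tsv"
            io.write_connectivity(conn, path)
            _register(f"connectivity/{s}", path)
        truth_path = out / "truth.json"
        io.write_json({"k_true": truth.k_true,
                       "labels_true": truth.labels_true,
                       "noise_scale": truth.noise_scale,
                       "latent_strength": truth.latent_strength}, truth_path)
        _register("truth", truth_path)

        stage = "parcellate"
        k_range = range(config.k_min, config.k_max + 1)
        hemi_conns = {h: [c.subset(geometry.indices(h)) for c in conns]
                      for h in ("left", "right")}

        stage = "stability"
        reports = {}
        for h in ("left", "right"):
            rep = split_half_stability(hemi_conns[h], k_range=k_range,
                                       n_repeats=config.n_repeats,
                                       rng_seed=config.seed + 2)
            interhemi = {}
            for k in k_range:
                parts = {
                    hh: group_parcellation(
                        [spectral_parcellate(build_similarity(c), k,
                                             rng_seed=config.seed + 3)
                         for c in hemi_conns[hh]], k,
                        rng_seed=config.seed + 4, hemisphere=hh)
                    for hh in ("left", "right")}
                interhemi[k] = interhemispheric_similarity(
                    parts["left"], parts["right"], geometry)
            rep.interhemispheric = pd.Series(interhemi, name="interhemispheric_nmi")
            select_k(rep)
            reports[h] = rep
            table = rep.table.copy()
            table["interhemispheric_nmi"] = rep.interhemispheric
            path = out / f"stability_{h}.tsv"
            io.write_table(table.reset_index(), path)
            _register(f"stability/{h}", path)
        selected = min(reports["left"].selected_k, reports["right"].selected_k)
        manifest["results"]["selected_k"] = {
            h: reports[h].selected_k for h in reports} | {"used": selected}
        stability_path = out / "stability.json"
        io.write_json({"selected_k": selected,
                       "flags": {h: reports[h].flag_reason for h in reports}},
                      stability_path)
        _register("stability/selected", stability_path)

        stage = "group"
        group_parcs, subject_parcs = {}, {}
        for h in ("left", "right"):
            subject_parcs[h] = [
                spectral_parcellate(build_similarity(c), selected,
                                    rng_seed=config.seed + 5, hemisphere=h,
                                    subject=str(s))
                for s, c in enumerate(hemi_conns[h])]
            group_parcs[h] = group_parcellation(subject_parcs[h], selected,
                                                rng_seed=config.seed + 6,
                                                hemisphere=h)
            idx = geometry.indices(h)
            tsv = out / f"group_parcellation_{h}.tsv"
            io.write_parcellation_tsv(group_parcs[h], idx, tsv)
            _register(f"group_parcellation/{h}/tsv", tsv)
            vol, affine = io.parcellation_to_volume(
                group_parcs[h].labels, geometry.voxel_coords[idx])
            nii = out / f"group_parcellation_{h}.nii.gz"
            io.write_volume(nii, vol, affine)
            _register(f"group_parcellation/{h}/nifti", nii)

        stage = "maps"
        prob = maps.probabilistic_map(subject_parcs["left"], group_parcs["left"])
        prob_path = out / "assignment_probability_left.tsv"
        io.write_table(pd.DataFrame(
            prob, columns=[f"subdivision_{i + 1}" for i in range(selected)]),
            prob_path)
        _register("maps/assignment_probability", prob_path)

        tract = synthetic.simulate_tract_counts(
            selected, config.n_tract_voxels, config.n_subjects,
            total_streams=config.total_streams, rng_seed=config.seed + 7)
        rel = np.stack([
            [maps.normalize_tract(tract[s, d],
                                  config.total_streams * synthetic.WAYPOINT_FACTOR,
                                  config.noise_threshold)
             for d in range(selected)] for s in range(config.n_subjects)])
        pop = np.stack([maps.population_map(rel[:, d], config.population_fraction)
                        for d in range(selected)])
        mpm = maps.max_probability_map(pop, config.mpm_threshold)
        for d in range(selected):
            path = out / f"population_map_subdivision{d + 1}.nii.gz"
            io.write_volume(path, pop[d])
            _register(f"maps/population/{d + 1}", path)
        mpm_path = out / "max_probability_map.nii.gz"
        io.write_volume(mpm_path, mpm.astype(np.int16))
        _register("maps/mpm", mpm_path)

        stage = "fingerprints"
        from .fingerprints import fingerprint, group_fingerprint, raw_strength

        atlas = _atlas_labels(tract.shape[2:], config.n_atlas_parcels)
        target_sizes = np.array([(atlas == t).sum()
                                 for t in range(1, config.n_atlas_parcels + 1)])
        sub_sizes = np.array([(group_parcs["left"].labels == c).sum()
                              for c in range(1, selected + 1)])
        tables = []
        for s in range(config.n_subjects):
            counts = np.array([
                [tract[s, d][atlas == t].sum()
                 for t in range(1, config.n_atlas_parcels + 1)]
                for d in range(selected)])
            raw = raw_strength(counts, sub_sizes, target_sizes,
                               config.total_streams)
            tables.append(fingerprint(raw))
        group_fp = group_fingerprint(tables)
        fp_path = out / "fingerprints.tsv"
        io.write_table(group_fp.to_tidy(), fp_path)
        _register("fingerprints", fp_path)

        stage = "contrasts"
        X, Y = synthetic.simulate_brain_behavior(
            config.n_behavior_subjects, config.p_brain, config.q_behavior,
            truth, rng_seed=config.seed + 8)
        roi_names = [f"roi{i + 1}" for i in range(config.p_brain)]
        roi_table = synthetic.simulate_roi_conditions(X, roi_names,
                                                      rng_seed=config.seed + 9)
        contrasts = task.build_contrasts(roi_table)
        contrasts_path = out / "contrasts.tsv"
        io.write_table(contrasts, contrasts_path)
        _register("contrasts", contrasts_path)
        wide = contrasts.pivot(index="subject", columns="roi", values="value")
        behavior = pd.DataFrame(Y, columns=["delay_discounting_auc",
                                            "flanker_score"][: config.q_behavior])
        stats = task.correlate_with_behavior(wide[roi_names], behavior,
                                             exclusion_sd=config.exclusion_sd)
        stats_path = out / "roi_behavior_correlations.tsv"
        io.write_table(stats, stats_path)
        _register("contrasts/correlations", stats_path)

        stage = "pls"
        est = BehavioralPLS(n_perm=config.n_perm, n_boot=config.n_boot,
                            random_state=config.seed + 10).fit(X, Y)
        res = est.result_
        pls_path = out / "pls.json"
        io.write_json({
            "singular_values": res.singular_values,
            "effect_sizes": res.effect_sizes,
            "perm_pvalues": res.perm_pvalues,
            "score_correlations": res.score_correlations,
            "score_correlation_ci": res.score_correlation_ci,
        }, pls_path)
        _register("pls/result", pls_path)
        weights = pd.DataFrame({
            "feature": roi_names + list(behavior.columns),
            "side": ["brain"] * config.p_brain + ["behavior"] * config.q_behavior,
        })
        for l in range(len(res.singular_values)):
            weights[f"weight_lv{l + 1}"] = np.concatenate(
                [res.brain_weights[:, l], res.behavior_weights[:, l]])
            weights[f"bootstrap_ratio_lv{l + 1}"] = np.concatenate(
                [res.bootstrap_ratios_brain[:, l],
                 res.bootstrap_ratios_behavior[:, l]])
        weights_path = out / "pls_weights.tsv"
        io.write_table(weights, weights_path)
        _register("pls/weights", weights_path)

        manifest["results"]["pls_effect_sizes"] = res.effect_sizes.tolist()
        manifest["results"]["pls_perm_pvalues"] = res.perm_pvalues.tolist()

    except Exception as exc:
        manifest["failed_stage"] = stage
        io.write_json(manifest, out / "manifest.json")
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    config_path = out / "config.json"
    io.write_json(config.to_dict(), config_path)
    _register("config", config_path)
    io.write_json(manifest, out / "manifest.json")
    return manifest
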