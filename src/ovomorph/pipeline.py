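"""End-to-end orchestration: simulate/segment/features/profile/groupstats
(and aggregation), with YAML configuration, seed fan-out and a run manifest.

A single global seed is fanned out to per-stage seeds through a counter-based
``numpy.random.SeedSequence`` scheme, so any stage can be re-run on its own
and still see the same stream.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as ovio
from .morphometry import extract_features, nc_ratio_summary
from .profile import MorphologyProfileModel
from .segmentation import CurationParams, curate, quantify_intensity, segment_cells, segment_nuclei, texture_infomeas
from .specs import MicromoldSpec, SceneSpec
from .synthetic import (
    jasp_population,
    lata_population,
    old_population,
    render_scene,
    sample_population,
    simulate_micromold,
    young_population,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "stage_seed"]

_POPULATIONS = {
    "young": young_population,
    "old": old_population,
    "lata": lata_population,
    "jasp": jasp_population,
}

_SCHEMA = {
    "seed": None,
    "simulate": {
        "groups": [{"population", "age", "treatment", "replicate", "n_cells", "n_scenes"}],
        "scene": {"image_shape", "pixel_size", "noise_sd", "poisson_noise", "confluency_fraction",
                  "background_level", "include_membrane"},
    },
    "segmentation": {
        "dna_channel": None,
        "cytoplasm_channel": None,
        "sigma": None,
        "curation": {"min_area_um2", "max_area_um2", "max_neighbors", "neighbor_radius_diameters"},
    },
    "profile": {"scaler", "n_factors", "communality_threshold", "embed_method", "k", "k_range",
                "cluster_space", "n_init"},
    "groupstats": {"groupby", "enrichment_method"},
    "aggregation": {
        "conditions": [{"name", "count_law", "count_mean", "grid", "well_diameter_um",
                        "well_pitch_um", "pixel_size", "particle_area_median", "particle_area_gsd"}],
        "bandwidth": None,
    },
}

_STAGES = ("simulate", "segment", "features", "profile", "groupstats", "aggregate")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    idx = _STAGES.index(stage)
    ss = np.random.SeedSequence(entropy=global_seed, spawn_key=(idx,))
    return int(ss.generate_state(1)[0] % (2**31))


def _check_section(cfg: dict) -> None:
    for key, val in cfg.items():
        if key not in _SCHEMA:
            raise ValueError(f"unknown config key '{key}'")
        spec = _SCHEMA[key]
        if spec is None or val is None:
            continue
        if isinstance(spec, set):
            if not isinstance(val, dict):
                raise ValueError(f"config section '{key}' must be a mapping")
            for k2 in val:
                if k2 not in spec:
                    raise ValueError(f"unknown config key '{key}.{k2}'")
        elif isinstance(spec, dict):
            if not isinstance(val, dict):
                raise ValueError(f"config section '{key}' must be a mapping")
            for k2, v2 in val.items():
                if k2 not in spec:
                    raise ValueError(f"unknown config key '{key}.{k2}'")
                inner = spec[k2]
                if isinstance(inner, set) and isinstance(v2, dict):
                    for k3 in v2:
                        if k3 not in inner:
                            raise ValueError(f"unknown config key '{key}.{k2}.{k3}'")
                elif isinstance(inner, list) and isinstance(v2, list):
                    for i, item in enumerate(v2):
                        for k3 in item:
                            if k3 not in inner[0]:
                                raise ValueError(f"unknown config key '{key}.{k2}[{i}].{k3}'")


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (YAML-backed)."""

    raw: dict

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        cfg = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(cfg)

    @classmethod
    def from_dict(cls, cfg: dict) -> "PipelineConfig":
        _check_section(cfg)
        if "simulate" in cfg and cfg["simulate"] is not None:
            groups = cfg["simulate"].get("groups") or []
            if not groups:
                raise ValueError("simulate.groups must list at least one group")
            for g in groups:
                pop = g.get("population")
                if pop not in _POPULATIONS:
                    raise ValueError(
                        f"unknown population '{pop}'; choose from {sorted(_POPULATIONS)}"
                    )
        return cls(raw=cfg)

    @property
    def seed(self) -> int:
        return int(self.raw.get("seed", 0))

    def section(self, name: str) -> dict:
        return dict(self.raw.get(name) or {})


@dataclass
class RunManifest:
    """Per-stage accounting: seeds, cell counts, output files and hashes."""

    global_seed: int
    stages: dict = field(default_factory=dict)
    started: float = field(default_factory=time.time)

    def record(self, stage: str, **info) -> None:
        self.stages[stage] = info

    def add_file(self, stage: str, path) -> None:
        path = Path(path)
        digest = hashlib.sha256(path.read_bytes()).hexdigest()[:16]
        self.stages.setdefault(stage, {}).setdefault("files", {})[path.name] = digest

    def validate_counts(self) -> None:
        """Cell counts must reconcile across stage boundaries."""
        seg = self.stages.get("segment")
        feat = self.stages.get("features")
        prof = self.stages.get("profile")
        if seg is not None:
            if seg["detected"] != seg["retained"] + seg["removed"]:
                raise ValueError("segment stage counts do not reconcile")
        if seg is not None and feat is not None:
            if feat["cells_in"] != seg["retained"]:
                raise ValueError("features stage input differs from curated cells")
            if feat["cells_out"] + feat["dropped"] != feat["cells_in"]:
                raise ValueError("features stage counts do not reconcile")
        if feat is not None and prof is not None:
            if prof["cells"] != feat["cells_out"]:
                raise ValueError("profile stage input differs from feature rows")

    def to_json(self, path) -> None:
        ovio.write_json(
            {"global_seed": self.global_seed, "stages": self.stages,
             "elapsed_s": round(time.time() - self.started, 2)},
            path,
        )


def run_pipeline(config: PipelineConfig, out_dir) -> RunManifest:
    """Execute the configured stages in order and write all outputs.

    With a ``simulate`` section, scenes are generated per group and carried
    through segmentation, feature extraction, profiling and group statistics;
    an ``aggregation`` section adds micromold simulation and particle
    counting. Fully reproducible for a fixed config and seed when the
    embedding method is deterministic.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.resolved.yaml").write_text(yaml.safe_dump(config.raw))
    manifest = RunManifest(global_seed=config.seed)

    sim_cfg = config.section("simulate")
    seg_cfg = config.section("segmentation")
    if sim_cfg:
        features = _run_imaging_stages(config, sim_cfg, seg_cfg, out, manifest)
    else:
        raise ValueError("config has no 'simulate' section; nothing to run")

    ovio.write_feature_matrix(features, out / "features.csv")
    manifest.add_file("features", out / "features.csv")

    # ------------------------------------------------------------------ profile
    prof_cfg = config.section("profile")
    k_range = prof_cfg.get("k_range", [2, 15])
    model = MorphologyProfileModel(
        features,
        scaler=prof_cfg.get("scaler", "minmax"),
        n_factors=int(prof_cfg.get("n_factors", 2)),
        communality_threshold=float(prof_cfg.get("communality_threshold", 0.5)),
        embed_method=prof_cfg.get("embed_method", "umap"),
        k=prof_cfg.get("k", "auto"),
        k_range=range(int(k_range[0]), int(k_range[1]) + 1),
        cluster_space=prof_cfg.get("cluster_space", "features"),
        n_init=int(prof_cfg.get("n_init", 10)),
    )
    results = model.fit(seed=stage_seed(config.seed, "profile"))
    manifest.record(
        "profile",
        cells=results.preprocessed.n_cells,
        n_features_in=len(results.preprocessed.data.columns),
        n_features_retained=results.selection.n_retained,
        k=results.k,
        seed=stage_seed(config.seed, "profile"),
    )
    cell_table = results.cell_table()
    cell_table.to_csv(out / "cells.csv", index=False)
    results.selection.communality.to_csv(out / "communality.csv")
    ovio.write_json(
        {"k": results.k, "inertia": results.clusters.inertia_curve,
         "silhouette": results.clusters.silhouette_curve},
        out / "k_diagnostics.json",
    )
    manifest.add_file("profile", out / "cells.csv")

    # --------------------------------------------------------------- groupstats
    gs_cfg = config.section("groupstats")
    groupby = gs_cfg.get("groupby", "age")
    from .groupstats import enrichment_correlation, fractional_abundance

    groups = cell_table[groupby].astype(str).to_numpy()
    profiles = fractional_abundance(results.labels, groups, k=results.k)
    corr = {}
    names = list(profiles)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            corr[f"{a}|{b}"] = enrichment_correlation(
                profiles[a], profiles[b], method=gs_cfg.get("enrichment_method", "cluster_fraction")
            )
    ovio.write_json(
        {
            "abundance": {g: p.fractions.tolist() for g, p in profiles.items()},
            "correlation": corr,
            "nc_summary_tests": {
                m: t for m, t in nc_ratio_summary(features, group_field=groupby)["tests"].items()
            } if len(names) == 2 else {},
        },
        out / "groupstats.json",
    )
    manifest.record("groupstats", groups=names, correlations=corr)
    manifest.add_file("groupstats", out / "groupstats.json")

    # -------------------------------------------------------------- aggregation
    agg_cfg = config.section("aggregation")
    if agg_cfg:
        _run_aggregation(config, agg_cfg, out, manifest)

    manifest.validate_counts()
    manifest.to_json(out / "manifest.json")
    return manifest


def _run_imaging_stages(config, sim_cfg, seg_cfg, out, manifest) -> "pd.DataFrame":
    sim_seed = stage_seed(config.seed, "simulate")
    scene_kwargs = dict(sim_cfg.get("scene") or {})
    if "image_shape" in scene_kwargs:
        scene_kwargs["image_shape"] = tuple(scene_kwargs["image_shape"])

    cur_cfg = seg_cfg.get("curation") or {}
    cur = CurationParams(**cur_cfg)
    dna_ch = seg_cfg.get("dna_channel", "dna")
    cyt_ch = seg_cfg.get("cytoplasm_channel", "actin")
    sigma = float(seg_cfg.get("sigma", 1.0))

    frames = []
    n_sim = n_det = n_ret = n_feat = n_drop = 0
    scene_i = 0
    for g in sim_cfg["groups"]:
        pop = _POPULATIONS[g["population"]]()
        for _ in range(int(g.get("n_scenes", 1))):
            scene_i += 1
            n_cells = int(g.get("n_cells", 40))
            params = sample_population(pop, n_cells, seed=sim_seed + scene_i)
            scene = SceneSpec(n_cells=n_cells, seed=sim_seed + scene_i, **scene_kwargs)
            image, truth = render_scene(params, scene)
            n_sim += len(truth)

            nuclei = segment_nuclei(image, dna_ch, sigma=sigma)
            cells = segment_cells(image, cyt_ch, nuclei, sigma=sigma)
            index, report = curate(nuclei, cells, cur)
            index.with_metadata(
                age=str(g.get("age", g["population"])),
                treatment=str(g.get("treatment", "vehicle")),
                replicate=str(g.get("replicate", scene_i)),
            )
            n_det += report.detected
            n_ret += report.retained

            intensity = quantify_intensity(image, index, ["actin", "vimentin"])
            intensity_nuc = quantify_intensity(image, index, ["dna"], compartment="nucleus")
            tex = {
                rec.cell_id: texture_infomeas(
                    image.channel("actin"), index.cells.labels == rec.cell_label
                )
                for rec in index.records
            }
            intensity = intensity.join(intensity_nuc)
            intensity["actin_infomeas"] = pd.Series(tex)
            fm = extract_features(index, index.nuclei, index.cells, intensity=intensity)
            fm.metadata["age"] = str(g.get("age", g["population"]))
            fm.metadata["treatment"] = str(g.get("treatment", "vehicle"))
            n_feat += fm.n_cells
            n_drop += fm.n_dropped
            frames.append(fm)

    manifest.record("simulate", cells=n_sim, seed=sim_seed, scenes=scene_i)
    manifest.record("segment", detected=n_det, retained=n_ret, removed=n_det - n_ret)
    manifest.record("features", cells_in=n_ret, cells_out=n_feat, dropped=n_drop)

    from .morphometry import FeatureMatrix

    merged = FeatureMatrix(
        features=pd.concat([f.features for f in frames], ignore_index=True),
        metadata=pd.concat([f.metadata for f in frames], ignore_index=True),
        catalog=frames[0].catalog,
        n_dropped=n_drop,
    )
    merged.metadata["cell_id"] = np.arange(merged.n_cells)
    return merged


def _run_aggregation(config, agg_cfg, out, manifest) -> None:
    from .aggregation import count_particles, detect_wells, particle_count_distribution, summarize_aggregation

    agg_seed = stage_seed(config.seed, "aggregate")
    counts = {}
    summaries = {}
    for i, cond in enumerate(agg_cfg.get("conditions") or []):
        spec = MicromoldSpec(
            grid=tuple(cond.get("grid", (9, 9))),
            count_law=cond.get("count_law", "poisson"),
            count_mean=float(cond.get("count_mean", 3.0)),
            well_diameter=float(cond.get("well_diameter_um", 400.0)),
            well_pitch=float(cond.get("well_pitch_um", 600.0)),
            pixel_size=float(cond.get("pixel_size", 3.3)),
            seed=agg_seed + i,
        )
        image, _, _ = simulate_micromold(spec)
        grid = detect_wells(image, spec.grid, spec.well_diameter, spec.well_pitch, mode="auto")
        table = count_particles(image, grid)
        name = cond["name"]
        counts[name] = table.counts_per_well()
        s = summarize_aggregation(table, grid)
        summaries[name] = {
            "n_visible_wells": s.n_visible_wells,
            "organoid_count": s.organoid_count,
            "aggregates_per_microwell": s.aggregates_per_microwell,
            "mean_organoid_area_um2": s.mean_organoid_area_um2,
        }
    if counts:
        curves = particle_count_distribution(counts, bandwidth=float(agg_cfg.get("bandwidth", 0.5)))
        curves.to_csv(out / "count_distributions.csv", index=False)
        ovio.write_json(summaries, out / "aggregation.json")
        manifest.record("aggregate", conditions=list(counts), seed=agg_seed)
        manifest.add_file("aggregate", out / "aggregation.json")
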