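"""End-to-end orchestration: phantom → (denoise) → fit → geometry → metrics → track.

A :class:`PipelineConfig` (typically loaded from YAML) toggles stages and
carries every stage's parameter block.  One global seed fans out to
per-stage seeds by stable hashing, so toggling one stage never changes
another stage's randomness.  Every run writes a resolved copy of its config
and a manifest with SHA-256 checksums of all outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .denoise import DenoiseParams, local_pca_denoise
from .geometry import build_geometry
from .microstructure import (
    aggregate_metrics,
    helix_angle,
    sheetlet_angle,
    tables_to_long,
    transmural_profile,
)
from .phantom import PhantomSpec, build_phantom, sample_cohort_specs
from .tensor import DiffusionTensorModel
from .tractography import TrackingParams, ha_tract_ratio, track, tract_mean_ha

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "stage_seed",
    "subject_metrics",
    "simulate_cohort_tables",
]

logger = logging.getLogger(__name__)

_STAGES = ("phantom", "denoise", "fit", "geometry", "metrics", "track")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


@dataclass
class PipelineConfig:
    """Resolved configuration of a full pipeline run.

    Unknown keys in the source mapping are rejected — a typo in a stage
    block should fail loudly, not silently fall back to a default.
    """

    out_dir: str = "cardiodti_run"
    rng_seed: int = 0
    log_level: str = "INFO"
    stages: dict = field(
        default_factory=lambda: {s: s != "denoise" for s in _STAGES}
    )
    phantom: dict = field(default_factory=dict)       # PhantomSpec overrides
    denoise: dict = field(default_factory=dict)       # DenoiseParams fields
    tracking: dict = field(default_factory=dict)      # TrackingParams fields
    geometry: dict = field(default_factory=dict)      # build_geometry options
    fit_method: str = "ols"

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stage toggles: {sorted(unknown)}")
        for name, params_cls in (("denoise", DenoiseParams), ("tracking", TrackingParams)):
            block = getattr(self, name)
            allowed = {f.name for f in dataclasses.fields(params_cls)}
            bad = set(block) - allowed
            if bad:
                raise ValueError(f"unknown keys in {name!r} block: {sorted(bad)}")
        allowed = {f.name for f in dataclasses.fields(PhantomSpec)}
        bad = set(self.phantom) - allowed - {"grid"}
        if bad:
            raise ValueError(f"unknown keys in 'phantom' block: {sorted(bad)}")
        # dependency checks before any stage executes
        st = self.stages
        if st.get("track") and not st.get("fit"):
            raise ValueError("tracking requires a fitted tensor: enable 'fit'")
        if st.get("metrics") and not (st.get("fit") and st.get("geometry")):
            raise ValueError("metrics require both 'fit' and 'geometry'")
        if st.get("fit") and not st.get("phantom"):
            raise ValueError("no input stage: enable 'phantom'")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        allowed = {f.name for f in dataclasses.fields(cls)}
        bad = set(mapping) - allowed
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        merged_stages = {s: s != "denoise" for s in _STAGES}
        merged_stages.update(mapping.get("stages", {}))
        kwargs = {k: v for k, v in mapping.items() if k != "stages"}
        return cls(stages=merged_stages, **kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(os.fspath(path)) as fh:
            mapping = yaml.safe_load(fh) or {}
        return cls.from_mapping(mapping)

    def to_mapping(self) -> dict:
        return dataclasses.asdict(self)

    def build_phantom_spec(self) -> PhantomSpec:
        over = dict(self.phantom)
        grid = over.pop("grid", None)
        if "rng_seed" not in over:
            over["rng_seed"] = stage_seed(self.rng_seed, "phantom")
        if "grid_shape" in over:
            over["grid_shape"] = tuple(over["grid_shape"])
        if "eigenvalues_true" in over:
            over["eigenvalues_true"] = tuple(over["eigenvalues_true"])
        if grid is not None:
            return PhantomSpec.for_grid(int(grid), **over)
        return PhantomSpec(**over)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in order; returns the manifest.

    A stage failure aborts with the failing stage named; outputs written by
    earlier stages are retained.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = os.fspath(config.out_dir)
    os.makedirs(out, exist_ok=True)
    with open(os.path.join(out, "resolved_config.yaml"), "w") as fh:
        yaml.safe_dump(config.to_mapping(), fh, sort_keys=True)

    outputs: list[str] = ["resolved_config.yaml"]
    state: dict = {}
    for stage in _STAGES:
        if not config.stages.get(stage, False):
            logger.info("stage %s disabled; skipping", stage)
            continue
        try:
            _run_stage(stage, config, state, out, outputs)
        except Exception as exc:  # noqa: BLE001 - abort naming the stage
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "outputs": {p: _sha256(os.path.join(out, p)) for p in sorted(outputs)},
        "stages_run": [s for s in _STAGES if config.stages.get(s)],
        "rng_seed": config.rng_seed,
    }
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _run_stage(stage, config, state, out, outputs):
    if stage == "phantom":
        spec = config.build_phantom_spec()
        dwi, gtab, truth = build_phantom(spec)
        state.update(dwi=dwi, gtab=gtab, truth=truth)
        dio.write_dwi(
            dwi, gtab,
            os.path.join(out, "dwi.nii.gz"),
            os.path.join(out, "dwi.bval"),
            os.path.join(out, "dwi.bvec"),
        )
        dio.write_maps(
            {
                "myocardium": truth.myocardium.astype(np.uint8),
                "cavity": truth.cavity.astype(np.uint8),
                "true_depth": truth.depth,
                "true_HA": truth.ha,
            },
            truth.affine, out,
            units={"true_depth": "fraction", "true_HA": "deg"},
            valid_ranges={"true_HA": (-90.0, 90.0)},
        )
        outputs += ["dwi.nii.gz", "dwi.bval", "dwi.bvec", "myocardium.nii.gz",
                    "cavity.nii.gz", "true_depth.nii.gz", "true_HA.nii.gz",
                    "maps_manifest.tsv"]
    elif stage == "denoise":
        params = DenoiseParams(**config.denoise)
        state["dwi"] = local_pca_denoise(
            state["dwi"], params, mask=state["truth"].myocardium
        )
        dio.write_dwi(
            state["dwi"], state["gtab"],
            os.path.join(out, "dwi_denoised.nii.gz"),
            os.path.join(out, "dwi.bval"),
            os.path.join(out, "dwi.bvec"),
        )
        outputs.append("dwi_denoised.nii.gz")
    elif stage == "fit":
        model = DiffusionTensorModel(
            state["dwi"], state["gtab"], mask=state["truth"].myocardium
        )
        fit = model.fit(method=config.fit_method)
        state["fit"] = fit
        dio.write_maps(
            fit.scalar_maps(), state["truth"].affine, out,
            units={"MD": "mm^2/s", "FA": "", "lambda1": "mm^2/s",
                   "lambda2": "mm^2/s", "lambda3": "mm^2/s"},
        )
        outputs += [f"{n}.nii.gz" for n in ("MD", "FA", "lambda1", "lambda2", "lambda3")]
    elif stage == "geometry":
        truth = state["truth"]
        geom = build_geometry(
            truth.myocardium, truth.cavity, truth.affine, **config.geometry
        )
        state["geom"] = geom
        dio.write_maps(
            {
                "depth": geom.depth,
                "layer_labels": geom.layer_labels.astype(np.int16),
                "region_labels": geom.region_labels.astype(np.int16),
                "aha_segments": geom.segment_ids.astype(np.int16),
            },
            truth.affine, out,
            units={"depth": "fraction"},
        )
        geom.profiles.to_csv(
            os.path.join(out, "wall_profiles.tsv"), sep="\t", index=False
        )
        outputs += ["depth.nii.gz", "layer_labels.nii.gz", "region_labels.nii.gz",
                    "aha_segments.nii.gz", "wall_profiles.tsv"]
    elif stage == "metrics":
        fit, geom = state["fit"], state["geom"]
        ha = helix_angle(fit.primary_eigenvector, geom.frames, geom.frame_valid)
        e2a = sheetlet_angle(
            fit.primary_eigenvector, fit.secondary_eigenvector,
            geom.frames, geom.frame_valid,
        )
        state["ha"], state["e2a"] = ha, e2a
        dio.write_maps(
            {"HA": ha, "absE2A": e2a}, geom.affine, out,
            units={"HA": "deg", "absE2A": "deg"},
        )
        prof = transmural_profile(ha, geom.depth, geom.region_labels)
        prof.to_csv(os.path.join(out, "transmural_profile.tsv"),
                    sep="\t", index=False)
        table = aggregate_metrics(
            fit.scalar_maps(), {"HA": ha, "absE2A": e2a}, geom
        )
        table.to_csv(os.path.join(out, "region_layer_table.tsv"),
                     sep="\t", index=False)
        state["table"], state["profile"] = table, prof
        outputs += ["HA.nii.gz", "absE2A.nii.gz", "transmural_profile.tsv",
                    "region_layer_table.tsv"]
    elif stage == "track":
        fit, truth = state["fit"], state["truth"]
        tp_kwargs = dict(config.tracking)
        if "rng_seed" not in tp_kwargs:
            tp_kwargs["rng_seed"] = stage_seed(config.rng_seed, "track")
        params = TrackingParams(**tp_kwargs)
        tg = track(
            fit.primary_eigenvector, fit.fa, truth.myocardium, truth.affine, params
        )
        if "ha" in state:
            tract_mean_ha(tg, state["ha"])
            ratio = ha_tract_ratio(tg, state["ha"], state["geom"].region_labels)
            ratio.to_csv(os.path.join(out, "ha_tract_ratio.tsv"),
                         sep="\t", index=False)
            outputs.append("ha_tract_ratio.tsv")
        tg.to_tck(os.path.join(out, "tracts.tck"))
        tg.tract_table().to_csv(os.path.join(out, "tracts.tsv"),
                                sep="\t", index=False)
        tg.save_summary(os.path.join(out, "tract_counts.json"))
        state["tractogram"] = tg
        outputs += ["tracts.tck", "tracts.tsv", "tract_counts.json"]


def subject_metrics(
    spec: PhantomSpec,
    denoise: bool = False,
    fit_method: str = "ols",
    geometry_options: dict | None = None,
):
    """Phantom → (denoise) → fit → geometry → metrics for one subject.

    Returns (region-layer table, transmural profile table).
    """
    dwi, gtab, truth = build_phantom(spec)
    if denoise:
        dwi = local_pca_denoise(dwi, DenoiseParams(), mask=truth.myocardium)
    fit = DiffusionTensorModel(dwi, gtab, mask=truth.myocardium).fit(method=fit_method)
    geom = build_geometry(
        truth.myocardium, truth.cavity, truth.affine, **(geometry_options or {})
    )
    ha = helix_angle(fit.primary_eigenvector, geom.frames, geom.frame_valid)
    e2a = sheetlet_angle(
        fit.primary_eigenvector, fit.secondary_eigenvector,
        geom.frames, geom.frame_valid,
    )
    table = aggregate_metrics(fit.scalar_maps(), {"HA": ha, "absE2A": e2a}, geom)
    profile = transmural_profile(ha, geom.depth, geom.region_labels)
    return table, profile


def simulate_cohort_tables(
    base_spec: PhantomSpec,
    n_subjects: int,
    rng_seed: int,
    region_scale: dict | None = None,
    label: str = "S",
    **cohort_kwargs,
) -> pd.DataFrame:
    """Simulate a cohort and return its long-format metric table.

    Subject specs come from :func:`cardiodti.phantom.sample_cohort_specs`
    (subject-level helix/diffusivity jitter, optional regional group
    effect); each subject runs the full phantom → fit → geometry → metrics
    chain.
    """
    specs = sample_cohort_specs(
        base_spec, n_subjects, rng_seed, region_scale=region_scale, **cohort_kwargs
    )
    tables = {}
    for i, spec in enumerate(specs):
        table, _ = subject_metrics(spec)
        tables[f"{label}{i:02d}"] = table
    return tables_to_long(tables)
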