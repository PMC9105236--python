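"""End-to-end wiring of the synthetic synapse-recovery experiment.

``run_pipeline`` executes generate → detect → cross-check → pair → density →
group comparison for two genotype groups of synthetic ROIs, writes every
artifact (volumes optional, punctae/calls CSV, density JSON, comparison
report) plus a manifest with SHA-256 checksums, and is fully deterministic
given its config.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import pairing, puncta, stats, synthetic


class PipelineError(RuntimeError):
    """A stage failed; carries the stage tag for error reporting."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


class RunConfig(BaseModel):
    """Resolved configuration of one pipeline run (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")

    demo: str = "synapse-recovery"
    seed: int = 0
    out_dir: Path = Path("synaptect-run")
    n_rois_per_group: int = 3
    group_densities: dict[str, float] = Field(
        default_factory=lambda: {"WT": 0.8523, "KO": 1.6625}
    )
    synapse_class: str = "excitatory"
    size_um: tuple[float, float, float] = (5.0, 5.0, 2.0)
    voxel_um: tuple[float, float, float] = (0.02, 0.02, 0.1)
    snr: float = 15.0
    distractor_density: float = 0.3
    artifact_density: float = 0.1
    detection_threshold: float = 5.0
    min_separation_nm: float = 100.0
    validation_radius_nm: float = 250.0
    pairing_threshold_nm: float = 300.0
    write_volumes: bool = False


def load_config(path: str | Path) -> RunConfig:
    payload = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig(**payload)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def analyze_roi(
    sted_pre, sted_post, conf_pre, conf_post, cfg: RunConfig
) -> pairing.SynapseCallSet:
    """Detect → cross-check → pair on one ROI's four volumes."""
    calls_inputs = {}
    for sted, conf in ((sted_pre, conf_pre), (sted_post, conf_post)):
        raw = puncta.detect_maxima(
            sted,
            min_intensity=cfg.detection_threshold,
            min_separation_nm=cfg.min_separation_nm,
        )
        validated = puncta.confocal_crosscheck(
            raw, conf, validation_radius_nm=cfg.validation_radius_nm
        )
        calls_inputs[sted.channel] = validated
    return pairing.pair_punctae(
        calls_inputs["pre"],
        calls_inputs["post"],
        threshold_nm=cfg.pairing_threshold_nm,
        synapse_class=cfg.synapse_class,
    )


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the synapse-recovery demo; returns the artifact manifest."""
    if cfg.demo != "synapse-recovery":
        raise PipelineError("config", f"unknown demo {cfg.demo!r}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    resolved = json.loads(cfg.model_dump_json())
    resolved.pop("out_dir")  # implied by the file's location; keeps manifests comparable
    (out / "config.yaml").write_text(yaml.safe_dump(resolved, sort_keys=False))

    densities: dict[str, list[float]] = {}
    files: list[Path] = [out / "config.yaml"]
    roi_volume = float(np.prod(cfg.size_um))
    for g_i, (group, density) in enumerate(sorted(cfg.group_densities.items())):
        densities[group] = []
        for r in range(cfg.n_rois_per_group):
            seed = cfg.seed + 1000 * g_i + r
            spec = synthetic.VolumeSpec(
                size_um=cfg.size_um,
                voxel_um=cfg.voxel_um,
                synapse_density=density,
                distractor_density_pre=cfg.distractor_density,
                distractor_density_post=cfg.distractor_density,
                sted_only_artifact_density=cfg.artifact_density,
                snr=cfg.snr,
                synapse_class=cfg.synapse_class,
                seed=seed,
            )
            try:
                vols = synthetic.generate_synapse_volume(spec)
            except ValueError as exc:
                raise PipelineError("simulate", str(exc)) from exc
            sted_pre, sted_post, conf_pre, conf_post, truth = vols
            try:
                calls = analyze_roi(sted_pre, sted_post, conf_pre, conf_post, cfg)
            except ValueError as exc:
                raise PipelineError("analyze", str(exc)) from exc
            dens = pairing.compute_density(calls, roi_volume)
            densities[group].append(dens.density_per_um3)
            tag = f"{group.lower()}_roi{r}"
            files.append(calls.to_csv(out / f"calls_{tag}.csv"))
            files.append(truth.to_csv(out / f"truth_{tag}.csv"))
            files.append(dens.to_json(out / f"density_{tag}.json"))
            if cfg.write_volumes:
                from .volume import write_tiff

                for v, name in zip(vols[:4], ("sted_pre", "sted_post", "conf_pre", "conf_post")):
                    files.append(write_tiff(v, out / f"{name}_{tag}.tif"))

    groups = sorted(densities)
    comparison = None
    if min(len(densities[g]) for g in groups) >= 3:
        try:
            cmp_result = stats.compare_groups(densities[groups[0]], densities[groups[1]])
        except ValueError as exc:
            raise PipelineError("stats", str(exc)) from exc
        comparison = {
            "test": cmp_result.test_used,
            "statistic": cmp_result.statistic,
            "df_or_u": cmp_result.df_or_u,
            "p_value": cmp_result.p_value,
            "report": cmp_result.report(),
        }
    report = {
        "groups": {g: densities[g] for g in groups},
        "group_means": {g: float(np.mean(densities[g])) for g in groups},
        "comparison": comparison,  # null when a group has < 3 ROIs
    }
    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2))
    files.append(report_path)

    manifest = {
        "demo": cfg.demo,
        "seed": cfg.seed,
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
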