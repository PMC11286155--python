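"""Run configuration, validation, seeds and provenance manifests.

A single YAML (or JSON) document configures every stage; unknown keys are
rejected so typos fail loudly.  An empty document yields the calibrated
reference configuration.  Each stage derives its own seed deterministically
from the single global seed, and a JSON manifest records the configuration
hash, seed and per-stage status for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import time
import zlib
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .anatomy import (
    DEFAULT_CURVE_SHAPE,
    CohortParams,
    SkullParams,
    SuturePatencySchedule,
    default_schedule,
)
from .fem import AgeMaterialModel
from .muscle import MuscleConstants


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SkullConfig(_Block):
    ax: float = Field(55.0, gt=0)
    ay: float = Field(70.0, gt=0)
    az: float = Field(50.0, gt=0)
    shell_thickness: float = Field(6.0, gt=0)
    face_height: float = Field(60.0, gt=0)
    face_width: float = Field(60.0, gt=0)
    face_depth: float = Field(6.0, gt=0)
    arch_radius: float = Field(4.0, gt=0)
    suture_width: float = Field(2.0, gt=0)
    voxel_pitch: float = Field(3.0, gt=0)
    facial_growth_exponent: float = Field(1.25, gt=0)


class CohortConfig(_Block):
    n: int = Field(51, ge=2)
    age_min: float = 0.0
    age_max: float = 48.0
    cv: float = Field(0.10, ge=0)


class AnatomyConfig(_Block):
    skull: SkullConfig = SkullConfig()
    cohort: CohortConfig = CohortConfig()


class MaterialsConfig(_Block):
    e_bone_base: float = Field(421.0, gt=0)
    e_joint_base: float = Field(30.0, gt=0)
    bone_rate: float = 125.0
    joint_rate: float = 100.0
    nu_bone: float = Field(0.22, gt=0, lt=0.5)
    nu_joint: float = Field(0.30, gt=0, lt=0.5)


class LoadingConfig(_Block):
    stress_factor: float = Field(37.0, gt=0)
    vectors_per_side: int = Field(3, ge=1)
    fascia_vectors_total: int = Field(6, ge=2)
    patch_radius_mm: float = Field(4.0, gt=0)
    with_fascia: bool = True


class PipelineConfig(_Block):
    ages: list[float] = Field(default_factory=lambda: [3, 6, 12, 24, 36, 48])
    modes: list[int] = Field(default_factory=lambda: [1, 2, 3])
    fascia_flags: list[bool] = Field(default_factory=lambda: [False, True])
    output_dir: str = "results"


class RunConfig(_Block):
    """Fully validated configuration; defaults reproduce the calibrated
    reference run."""

    anatomy: AnatomyConfig = AnatomyConfig()
    materials: MaterialsConfig = MaterialsConfig()
    loading: LoadingConfig = LoadingConfig()
    pipeline: PipelineConfig = PipelineConfig()
    seed: int = 0

    # -- adapters to the domain parameter objects -----------------------------

    def skull_params(self, age_months: float) -> SkullParams:
        s = self.anatomy.skull
        return SkullParams(
            age_months=age_months,
            ax=s.ax, ay=s.ay, az=s.az,
            shell_thickness=s.shell_thickness,
            face_height=s.face_height, face_width=s.face_width,
            face_depth=s.face_depth, arch_radius=s.arch_radius,
            suture_width=s.suture_width, voxel_pitch=s.voxel_pitch,
            facial_growth_exponent=s.facial_growth_exponent,
            seed=stage_seed(self.seed, "anatomy"),
        )

    def cohort_params(self) -> CohortParams:
        c = self.anatomy.cohort
        return CohortParams(
            n=c.n, age_range=(c.age_min, c.age_max), cv=c.cv,
            curve_shape=dict(DEFAULT_CURVE_SHAPE),
            seed=stage_seed(self.seed, "cohort"),
        )

    def material_model(self) -> AgeMaterialModel:
        m = self.materials
        return AgeMaterialModel(
            e_bone_base=m.e_bone_base, e_joint_base=m.e_joint_base,
            bone_rate=m.bone_rate, joint_rate=m.joint_rate,
            nu_bone=m.nu_bone, nu_joint=m.nu_joint,
        )

    def muscle_constants(self) -> MuscleConstants:
        ld = self.loading
        return MuscleConstants(
            stress_factor=ld.stress_factor,
            vectors_per_side=ld.vectors_per_side,
            fascia_vectors_total=ld.fascia_vectors_total,
        )

    def schedule(self) -> SuturePatencySchedule:
        return default_schedule()


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON configuration file.

    An empty file yields the full-default (reference) configuration.
    Unknown keys raise a validation error naming the offending key.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    return RunConfig.model_validate(data or {})


def dump_config(cfg: RunConfig, path: str | Path | None = None) -> str:
    text = yaml.safe_dump(cfg.model_dump(mode="json"), sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def config_hash(cfg: RunConfig) -> str:
    """Stable SHA-256 of the canonical JSON form of a configuration."""
    blob = json.dumps(cfg.model_dump(mode="json"), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed fan-out (kept below 2^31)."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2**31)


MANIFEST_SCHEMA = {
    "required": ["version", "config_hash", "seed", "stages", "created_unix"],
    "stage_required": ["name", "status"],
    "statuses": {"ok", "failed", "skipped"},
}


def validate_manifest(manifest: dict) -> None:
    for key in MANIFEST_SCHEMA["required"]:
        if key not in manifest:
            raise ValueError(f"manifest missing key {key!r}")
    for st in manifest["stages"]:
        for key in MANIFEST_SCHEMA["stage_required"]:
            if key not in st:
                raise ValueError(f"manifest stage missing key {key!r}")
        if st["status"] not in MANIFEST_SCHEMA["statuses"]:
            raise ValueError(f"unknown stage status {st['status']!r}")


def write_manifest(
    out_dir: str | Path,
    cfg: RunConfig,
    stages: list[dict],
    filename: str = "manifest.json",
) -> Path:
    """Write the JSON run manifest (config hash, seed, stage statuses)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "config_hash": config_hash(cfg),
        "seed": cfg.seed,
        "stages": stages,
        "created_unix": time.time(),
    }
    validate_manifest(manifest)
    path = out / filename
    path.write_text(json.dumps(manifest, indent=2))
    return path
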