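"""Scenario configuration files, validation, and run manifests.

Configs are YAML with a strict schema (unknown keys rejected, seed
mandatory): a top-level ``seed`` plus a ``scenarios`` list, each entry
naming a scenario and overriding condition switches, timepoints, replicate
counts, kinetic rates, or assay parameters. The reserved config name
``paper_panels`` resolves to the built-in panel library instead of a file.

Every run emits a :class:`RunManifest` (JSON) carrying the package version,
a hash of the fully resolved configuration, the master seed, and the output
files; re-running from a manifest reproduces the outputs byte-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import __version__
from .assays import IPParams, PrecipParams, QPCRParams, Scenario, SSPEParams
from .pathway import Condition, RateSet
from .scenarios import all_scenarios

__all__ = [
    "ScenarioConfig",
    "ConfigBundle",
    "load_config",
    "resolve_scenarios",
    "write_manifest",
    "read_manifest",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ConditionConfig(_Strict):
    ner_functional: bool = True
    donor: Literal["none", "heterologous", "homologous"] = "none"
    rad51_inhibited: bool = False
    proteasome_inhibited: bool = False
    ogg1_variant: Literal["K341", "R341"] = "K341"
    sprtn_deficient: bool = False


class RateConfig(_Strict):
    k63_rate: Optional[float] = None
    k48_rate: Optional[float] = None
    proteolysis_rate: Optional[float] = None
    ner_excision_rate: Optional[float] = None
    hr_rate: Optional[float] = None
    b02_factor: Optional[float] = None
    mg132_factor: Optional[float] = None
    k341r_ub_factor: Optional[float] = None


class QPCRConfig(_Strict):
    efficiency: Optional[float] = None
    ct_reference: Optional[float] = None
    ct_noise_sd: Optional[float] = None


class SSPEConfig(_Strict):
    cycles: Optional[int] = None
    gain: Optional[float] = None
    damaged_leak: Optional[float] = None


class PrecipConfig(_Strict):
    capture_prob: Optional[float] = None
    nonspecific_loss: Optional[float] = None
    proteolyzed_precipitates: Optional[bool] = None


class IPConfig(_Strict):
    capture_efficiency: Optional[float] = None
    background_rate: Optional[float] = None
    proteolyzed_retains_tags: Optional[bool] = None


class ScenarioConfig(_Strict):
    """One scenario entry of a config file (all overrides optional)."""

    scenario_id: str
    condition: ConditionConfig = Field(default_factory=ConditionConfig)
    timepoints: list[float] = [1.0]
    replicates: int = 3
    assays: list[Literal["sspe", "kcl_sds", "ip"]] = ["sspe", "kcl_sds", "ip"]
    ip_antibodies: list[Literal["pan_ub", "k48", "k63"]] = ["pan_ub"]
    rates: RateConfig = Field(default_factory=RateConfig)
    qpcr: QPCRConfig = Field(default_factory=QPCRConfig)
    sspe: SSPEConfig = Field(default_factory=SSPEConfig)
    precip: PrecipConfig = Field(default_factory=PrecipConfig)
    ip: IPConfig = Field(default_factory=IPConfig)
    n_molecules: int = 10_000
    propagation: Literal["gillespie", "exact"] = "gillespie"
    include_baseline: bool = True
    is_baseline_arm: bool = False
    seed_group: Optional[str] = None

    @field_validator("replicates", "n_molecules")
    @classmethod
    def _positive(cls, v: int) -> int:
        if v < 1:
            raise ValueError("must be >= 1")
        return v

    @field_validator("timepoints")
    @classmethod
    def _nonneg(cls, v: list[float]) -> list[float]:
        if any(t < 0 for t in v):
            raise ValueError("timepoints must be >= 0")
        return v

    def to_scenario(self) -> Scenario:
        def overlay(default_obj, cfg):
            over = {k: v for k, v in cfg.model_dump().items() if v is not None}
            return type(default_obj)(**{**asdict(default_obj), **over}) if over else default_obj

        # dataclasses with nested defaults
        rates = overlay(RateSet(), self.rates)
        qpcr = overlay(QPCRParams(), self.qpcr)
        sspe = overlay(SSPEParams(), self.sspe)
        precip = overlay(PrecipParams(), self.precip)
        ip = overlay(IPParams(), self.ip)
        return Scenario(
            scenario_id=self.scenario_id,
            condition=Condition(**self.condition.model_dump()),
            timepoints=tuple(self.timepoints),
            replicates=self.replicates,
            assays=tuple(self.assays),
            ip_antibodies=tuple(self.ip_antibodies),
            rates=rates,
            qpcr=qpcr,
            sspe=sspe,
            precip=precip,
            ip=ip,
            n_molecules=self.n_molecules,
            propagation=self.propagation,
            include_baseline=self.include_baseline,
            is_baseline_arm=self.is_baseline_arm,
            seed_group=self.seed_group,
        )


class ConfigBundle(_Strict):
    """A fully validated configuration: mandatory seed + scenario list."""

    seed: int
    scenarios: list[ScenarioConfig]

    @field_validator("seed")
    @classmethod
    def _seed_range(cls, v: int) -> int:
        if not (0 <= v < 2**31):
            raise ValueError("seed must lie in [0, 2**31)")
        return v

    def resolved(self) -> list[Scenario]:
        seen: set[str] = set()
        out = []
        for sc in self.scenarios:
            if sc.scenario_id in seen:
                raise ValueError(f"duplicate scenario_id {sc.scenario_id!r}")
            seen.add(sc.scenario_id)
            out.append(sc.to_scenario())
        return out

    def canonical_dict(self) -> dict:
        return self.model_dump(mode="json")


def load_config(path: str | Path, seed: int | None = None) -> ConfigBundle:
    """Load and validate a config file, or the built-in ``paper_panels`` set.

    ``seed`` overrides (or supplies, for the built-in set) the master seed.
    Validation errors name the offending key; a missing seed is an error —
    no implicit entropy is ever used.
    """
    if str(path) == "paper_panels":
        if seed is None:
            raise ValueError("seed is mandatory (pass --seed or a config seed)")
        scenarios = [
            _scenario_to_config(s) for s in all_scenarios()
        ]
        return ConfigBundle(seed=seed, scenarios=scenarios)
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"config file not found: {p}")
    raw = yaml.safe_load(p.read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping: {p}")
    if seed is not None:
        raw = {**raw, "seed": seed}
    if "seed" not in raw:
        raise ValueError("seed is mandatory (set it in the config or pass --seed)")
    return ConfigBundle.model_validate(raw)


def _scenario_to_config(s: Scenario) -> ScenarioConfig:
    return ScenarioConfig(
        scenario_id=s.scenario_id,
        condition=ConditionConfig(**asdict(s.condition)),
        timepoints=list(s.timepoints),
        replicates=s.replicates,
        assays=list(s.assays),
        ip_antibodies=list(s.ip_antibodies),
        rates=RateConfig(**asdict(s.rates)),
        qpcr=QPCRConfig(**asdict(s.qpcr)),
        sspe=SSPEConfig(**asdict(s.sspe)),
        precip=PrecipConfig(**asdict(s.precip)),
        ip=IPConfig(**{k: v for k, v in asdict(s.ip).items() if k != "antibody"}),
        n_molecules=s.n_molecules,
        propagation=s.propagation,
        include_baseline=s.include_baseline,
        is_baseline_arm=s.is_baseline_arm,
        seed_group=s.seed_group,
    )


def resolve_scenarios(bundle: ConfigBundle) -> list[Scenario]:
    return bundle.resolved()


def config_hash(bundle: ConfigBundle) -> str:
    blob = json.dumps(bundle.canonical_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def write_manifest(
    path: str | Path,
    bundle: ConfigBundle,
    command: str,
    outputs: list[str | Path],
) -> dict:
    """Emit the run manifest; sufficient to reproduce the run byte-identically."""
    manifest = {
        "package": "dpcrepair",
        "version": __version__,
        "command": command,
        "seed": bundle.seed,
        "config_hash": config_hash(bundle),
        "config": bundle.canonical_dict(),
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "outputs": [str(o) for o in outputs],
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def read_manifest(path: str | Path) -> tuple[ConfigBundle, dict]:
    """Load a manifest and revalidate its embedded configuration."""
    manifest = json.loads(Path(path).read_text())
    bundle = ConfigBundle.model_validate(manifest["config"])
    if config_hash(bundle) != manifest["config_hash"]:
        raise ValueError(f"manifest config hash mismatch: {path}")
    return bundle, manifest
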