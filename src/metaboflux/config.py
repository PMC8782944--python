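"""Run configuration: YAML in, validated and fully-resolved config out.

Defaults (alpha 0.05, |r| threshold 0.7, line broadening 0.3 Hz, bundled
reduced network, reference group = first group) are filled in and echoed to
the log so every run records its effective parameters.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .synthetic import DEFAULT_EFFECTS, EffectSpec, StudyDesign, default_design

logger = logging.getLogger(__name__)

DEFAULT_STAGES = ["simulate", "stats", "network", "fba"]


class ConfigError(ValueError):
    pass


@dataclass
class FBASettings:
    network: str | None = None  # None -> bundled reduced network
    reference_group: str = "sham"
    tissue: str = "maternal_heart"
    v_max: float = 10.0


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "results"
    alpha: float = 0.05
    threshold: float = 0.7
    lb_hz: float = 0.3
    table: str | None = None  # existing table CSV; otherwise simulate
    regions: str | None = None
    stages: list[str] = field(default_factory=lambda: list(DEFAULT_STAGES))
    design: dict = field(default_factory=dict)
    fba: FBASettings = field(default_factory=FBASettings)

    def resolved_design(self) -> StudyDesign:
        base = default_design(seed=self.seed)
        d = dict(self.design)
        tissues = d.get("tissues", base.tissues)
        effects = d.pop("effects", None)
        if effects is not None:
            effects = [EffectSpec(**e) for e in effects]
        else:
            # default effects are inert for tissues outside the design
            effects = [e for e in DEFAULT_EFFECTS if e.tissue in tissues]
        return StudyDesign(
            tissues=tissues,
            groups=d.get("groups", base.groups),
            n_per_group=d.get("n_per_group", base.n_per_group),
            seed=self.seed,
            baseline_means=d.get("baseline_means", base.baseline_means),
            cv=d.get("cv", base.cv),
            effects=effects,
        )

    def to_dict(self) -> dict:
        payload = asdict(self)
        payload["fba"] = asdict(self.fba)
        return payload

    def dump(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def validate_config(path) -> RunConfig:
    """Load, validate and resolve a YAML run configuration.

    All violations are aggregated into one error report.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    problems: list[str] = []
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        problems.append(f"unknown fields: {sorted(unknown)}")
    fba_raw = raw.pop("fba", {}) or {}
    if not isinstance(fba_raw, dict):
        problems.append("fba must be a mapping")
        fba_raw = {}
    fba_unknown = set(fba_raw) - set(FBASettings.__dataclass_fields__)
    if fba_unknown:
        problems.append(f"unknown fba fields: {sorted(fba_unknown)}")
        fba_raw = {k: v for k, v in fba_raw.items() if k not in fba_unknown}
    config = RunConfig(**{k: v for k, v in raw.items() if k in known},
                       fba=FBASettings(**fba_raw))

    if not 0 < config.alpha < 1:
        problems.append(f"alpha must be in (0, 1), got {config.alpha}")
    if not 0 < config.threshold <= 1:
        problems.append(f"threshold must be in (0, 1], got {config.threshold}")
    if config.lb_hz < 0:
        problems.append(f"lb_hz must be >= 0, got {config.lb_hz}")
    if config.fba.v_max <= 0:
        problems.append(f"fba.v_max must be > 0, got {config.fba.v_max}")
    bad_stages = set(config.stages) - set(DEFAULT_STAGES) - {"nmr"}
    if bad_stages:
        problems.append(f"unknown stages: {sorted(bad_stages)}")
    for name, value in (("table", config.table), ("regions", config.regions),
                        ("fba.network", config.fba.network)):
        if value is not None and not Path(value).exists():
            problems.append(f"{name} path does not exist: {value}")
    if config.table is None and "simulate" not in config.stages:
        problems.append("either a table path or the simulate stage is required")
    try:
        config.resolved_design()
    except Exception as exc:
        problems.append(f"invalid design: {exc}")
    if problems:
        raise ConfigError(f"{path}: " + "; ".join(problems))
    logger.info("resolved config: %s", config.to_dict())
    return config
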