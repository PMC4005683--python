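"""Declarative run configuration.

One YAML file drives a whole run. Either a ``simulation`` block (the
generator makes the inputs) or an ``inputs`` block (paths to existing
design/intensity tables plus a sample -> condition map) must be
present. All analysis thresholds live under ``thresholds`` with the
defaults used throughout the pipeline:

.. code-block:: yaml

    seed: 1
    simulation:
      n_genes: 500
      n_replicates: 3
      fraction_regulated_splicing: 0.1
      delta_psi: 0.3
    # inputs:
    #   design: design.tsv
    #   intensities: intensities.tsv
    #   conditions: {ctl_1: control, ctl_2: control, trt_1: treated, trt_2: treated}
    thresholds:
      expressed: 500      # fluorescence units, inclusive
      fc_min: 1.5
      alpha_gene: 0.05
      alpha_probeset: 0.01
      scale_target: 500
      trim: 0.02
      r_min: 0.7
      min_keep: 3
      probe_test_on: si   # 'si' (gene-normalized) or 'raw'
      equal_var: true
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .simulate import SimulationParams


class ConfigError(ValueError):
    """Raised when a run configuration is invalid."""


@dataclass
class Thresholds:
    expressed: float = 500.0
    fc_min: float = 1.5
    alpha_gene: float = 0.05
    alpha_probeset: float = 0.01
    scale_target: float = 500.0
    trim: float = 0.02
    r_min: float = 0.7
    min_keep: int = 3
    probe_test_on: str = "si"
    equal_var: bool = True

    def validate(self) -> None:
        if self.probe_test_on not in ("si", "raw"):
            raise ConfigError(f"probe_test_on must be 'si' or 'raw', got {self.probe_test_on!r}")
        for name in ("alpha_gene", "alpha_probeset"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ConfigError(f"{name} must be in (0, 1], got {v}")
        if self.fc_min < 1:
            raise ConfigError(f"fc_min must be >= 1, got {self.fc_min}")
        if not 0 <= self.trim < 0.5:
            raise ConfigError(f"trim must be in [0, 0.5), got {self.trim}")


@dataclass
class RunConfig:
    seed: int = 0
    simulation: SimulationParams | None = None
    design_path: Path | None = None
    intensities_path: Path | None = None
    conditions: dict[str, str] = field(default_factory=dict)
    thresholds: Thresholds = field(default_factory=Thresholds)

    def validate(self) -> None:
        self.thresholds.validate()
        if self.simulation is None and (
            self.design_path is None or self.intensities_path is None
        ):
            raise ConfigError(
                "config must provide either a 'simulation' block or "
                "'inputs' with design and intensities paths"
            )
        if self.simulation is None and not self.conditions:
            raise ConfigError("real-data runs need an inputs.conditions sample map")
        if self.simulation is not None:
            self.simulation.validate()

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        seed = int(data.get("seed", 0))
        sim = None
        if "simulation" in data:
            sim_kwargs = dict(data["simulation"] or {})
            sim_kwargs.setdefault("seed", seed)
            known = {f.name for f in dataclasses.fields(SimulationParams)}
            unknown = set(sim_kwargs) - known
            if unknown:
                raise ConfigError(f"unknown simulation keys: {sorted(unknown)}")
            if "probes_per_probeset" in sim_kwargs:
                sim_kwargs["probes_per_probeset"] = tuple(sim_kwargs["probes_per_probeset"])
            sim = SimulationParams(**sim_kwargs)
        inputs = data.get("inputs", {}) or {}
        thr_kwargs = dict(data.get("thresholds", {}) or {})
        known_thr = {f.name for f in dataclasses.fields(Thresholds)}
        unknown = set(thr_kwargs) - known_thr
        if unknown:
            raise ConfigError(f"unknown threshold keys: {sorted(unknown)}")
        cfg = cls(
            seed=seed,
            simulation=sim,
            design_path=Path(inputs["design"]) if "design" in inputs else None,
            intensities_path=Path(inputs["intensities"]) if "intensities" in inputs else None,
            conditions=dict(inputs.get("conditions", {}) or {}),
            thresholds=Thresholds(**thr_kwargs),
        )
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        out: dict = {"seed": self.seed, "thresholds": dataclasses.asdict(self.thresholds)}
        if self.simulation is not None:
            sim = dataclasses.asdict(self.simulation)
            sim["probes_per_probeset"] = list(sim["probes_per_probeset"])
            out["simulation"] = sim
        if self.design_path is not None:
            out["inputs"] = {
                "design": str(self.design_path),
                "intensities": str(self.intensities_path),
                "conditions": dict(self.conditions),
            }
        return out

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
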