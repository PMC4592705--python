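"""Run configuration: a YAML file naming the input, component map, ENM
parameters, deletion variants and PTC selection.

Component boundaries (which chains are L9, which chains form the outermost
L12 dimer, which L10 residues are its bound C-terminal segment) are not
derivable from coordinates and differ between deposited structures, so they
are always user-supplied selection strings, never hard-coded.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .enm import ENMParameters
from .errors import ConfigError
from .mass import DeletionSpec
from .structures import Selection

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    input: Path | None = None
    components: dict[str, str] = field(default_factory=dict)
    ptc: str | None = None
    deletions: list[dict] = field(default_factory=list)
    gamma: float = 1.0
    cutoff: float = 15.0
    temperature: float = 300.0
    n_modes: int | str = "all"
    outdir: Path = Path("ribomech_out")
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} must be a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**{k: v for k, v in raw.items() if k in known})
        if cfg.input is not None:
            cfg.input = Path(cfg.input)
            if not cfg.input.is_absolute():
                cfg.input = Path(path).parent / cfg.input
        cfg.outdir = Path(cfg.outdir)
        if not cfg.outdir.is_absolute():
            cfg.outdir = Path(path).parent / cfg.outdir
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.input is not None and not Path(self.input).exists():
            raise ConfigError(f"input file {self.input} does not exist")
        if self.gamma <= 0 or self.cutoff <= 0:
            raise ConfigError("gamma and cutoff must be positive")
        if self.n_modes != "all":
            try:
                self.n_modes = int(self.n_modes)
            except (TypeError, ValueError):
                raise ConfigError(f"n_modes must be an integer or 'all', got {self.n_modes!r}")
            if self.n_modes < 1:
                raise ConfigError("n_modes must be >= 1")
        for d in self.deletions:
            if not isinstance(d, dict) or "name" not in d:
                raise ConfigError(f"each deletion needs a 'name': {d!r}")
        for label, sel in self.components.items():
            Selection.from_string(str(sel))  # syntax check

    @property
    def enm_params(self) -> ENMParameters:
        return ENMParameters(gamma=self.gamma, cutoff=self.cutoff,
                             temperature=self.temperature)

    def component_selections(self) -> dict[str, Selection]:
        return {label: Selection.from_string(str(s)) for label, s in self.components.items()}

    def ptc_sel(self) -> Selection:
        if not self.ptc:
            raise ConfigError("config has no 'ptc' selection")
        return Selection.from_string(self.ptc)

    def deletion_specs(self) -> list[DeletionSpec]:
        specs = []
        for d in self.deletions:
            sels = tuple(Selection.from_string(str(s)) for s in d.get("selections", []))
            specs.append(DeletionSpec(d["name"], tuple(d.get("components", [])), sels))
        return specs

    def manifest(self, command: str) -> dict:
        import numpy
        import scipy

        from . import __version__

        return {
            "command": command,
            "config": {
                "input": str(self.input) if self.input else None,
                "components": self.components,
                "ptc": self.ptc,
                "deletions": self.deletions,
                "gamma": self.gamma,
                "cutoff": self.cutoff,
                "temperature": self.temperature,
                "n_modes": self.n_modes,
                "outdir": str(self.outdir),
                "seed": self.seed,
            },
            "versions": {
                "ribomech": __version__,
                "numpy": numpy.__version__,
                "scipy": scipy.__version__,
                "python": sys.version.split()[0],
            },
        }

    def write_manifest(self, command: str) -> Path:
        self.outdir.mkdir(parents=True, exist_ok=True)
        path = self.outdir / f"manifest_{command}.json"
        path.write_text(json.dumps(self.manifest(command), indent=2) + "\n")
        return path
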