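"""Layered run configuration.

A run is fully described by a :class:`RunConfig`: featurizer geometry,
network architecture, training settings and dataset assembly options.  It
loads from a single YAML file with ``section.key=value`` command-line
overrides; unknown keys are rejected, and every run writes its resolved
configuration, seed and code version into the output directory.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field, fields

from .network import NetworkConfig, TrainConfig


@dataclass(frozen=True)
class FeaturizerConfig:
    """Grid geometry for the site voxelizer."""

    edge_length: float = 30.0
    resolution: float = 1.0


@dataclass(frozen=True)
class RunConfig:
    featurizer: FeaturizerConfig = field(default_factory=FeaturizerConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    ratio: int = 1
    folds: int = 5

    # -- construction ---------------------------------------------------------
    _SECTIONS = {
        "featurizer": FeaturizerConfig,
        "network": NetworkConfig,
        "training": TrainConfig,
    }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        unknown = set(data) - {f.name for f in fields(cls)}
        if unknown:
            raise ValueError(f"unknown configuration sections: {sorted(unknown)}")
        kwargs = {}
        for name, sub_cls in cls._SECTIONS.items():
            if name in data:
                sub = dict(data.pop(name) or {})
                bad = set(sub) - {f.name for f in fields(sub_cls)}
                if bad:
                    raise ValueError(f"unknown {name} configuration keys: {sorted(bad)}")
                for k, v in sub.items():
                    if isinstance(v, list):
                        sub[k] = tuple(v)
                kwargs[name] = sub_cls(**sub)
        kwargs.update(data)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def with_overrides(self, overrides: list[str]) -> "RunConfig":
        """Apply ``section.key=value`` overrides (YAML-parsed values)."""
        import yaml

        data = self.to_dict()
        for item in overrides:
            if "=" not in item:
                raise ValueError(f"override {item!r} is not of the form section.key=value")
            dotted, raw = item.split("=", 1)
            keys = dotted.split(".")
            node = data
            for k in keys[:-1]:
                if k not in node:
                    raise ValueError(f"unknown configuration section {k!r} in {item!r}")
                node = node[k]
            if keys[-1] not in node:
                raise ValueError(f"unknown configuration key {dotted!r}")
            node[keys[-1]] = yaml.safe_load(raw)
        return RunConfig.from_dict(data)

    # -- serialization --------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        return json.loads(json.dumps(d))  # tuples -> lists, plain types only

    def dump(self, outdir, seed: int | None = None) -> str:
        """Write the resolved configuration (+ seed and code version) into
        ``outdir``; returns the file path."""
        from . import __version__

        os.makedirs(outdir, exist_ok=True)
        payload = {"config": self.to_dict(), "seed": seed, "version": __version__}
        path = os.path.join(outdir, "run_config.json")
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
        return path
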