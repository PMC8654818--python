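"""Declarative run configuration.

A single YAML file drives every pipeline stage; CLI flags only override
individual keys.  Each output artifact gets a provenance sidecar holding
the configuration hash and the seed, so any table can be traced back to
the exact run that produced it.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import yaml

from .models import PriorConfig
from .simulate import STUDY_GROUPS, TruthParams, WorldConfig

__all__ = ["SamplerSettings", "RunConfig", "default_length_weight"]


@dataclass
class SamplerSettings:
    chains: int = 4
    warmup: int = 1000
    iterations: int = 1000


def default_length_weight() -> dict[str, tuple[float, float]]:
    """Synthetic length-weight coefficients (grams at cm), one pair per
    group.  These are test-fixture values with cubic scaling, not
    literature estimates — real analyses must supply their own table.
    """
    return {g: (0.0135, 3.0) for g in STUDY_GROUPS}


@dataclass
class RunConfig:
    """Everything a pipeline run needs, from one file.

    ``inputs`` may point at existing CSVs; when a path is missing the
    pipeline simulates that table from ``world``/``truth`` instead.
    """

    seed: int
    outdir: str = "runs/out"
    overwrite: bool = False
    world: WorldConfig = field(default_factory=WorldConfig)
    truth: TruthParams = field(default_factory=TruthParams)
    sampler: SamplerSettings = field(default_factory=SamplerSettings)
    priors: PriorConfig = field(default_factory=PriorConfig)
    inputs: dict = field(default_factory=dict)  # catch / manta_tows / fish_transects
    length_weight: dict = field(default_factory=default_length_weight)
    lags: tuple[int, ...] = (1, 2, 3, 4, 5, 6)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ValueError("config must set a seed")
        kwargs = dict(raw)
        if "world" in kwargs:
            w = dict(kwargs["world"])
            if "years" in w:
                w["years"] = tuple(w["years"])
            kwargs["world"] = WorldConfig(**w)
        if "truth" in kwargs:
            t = dict(kwargs["truth"])
            if "biomass_slopes" in t:
                t["biomass_slopes"] = {
                    (e["group"], int(e["lag"])): float(e["slope"])
                    for e in t["biomass_slopes"]
                }
            kwargs["truth"] = TruthParams(**t)
        if "sampler" in kwargs:
            kwargs["sampler"] = SamplerSettings(**kwargs["sampler"])
        if "priors" in kwargs:
            kwargs["priors"] = PriorConfig(**kwargs["priors"])
        if "length_weight" in kwargs:
            kwargs["length_weight"] = {
                g: tuple(v) for g, v in kwargs["length_weight"].items()
            }
        if "lags" in kwargs:
            kwargs["lags"] = tuple(int(x) for x in kwargs["lags"])
        cfg = cls(**kwargs)
        # the world seed follows the run seed unless set explicitly
        if "world" not in raw or "seed" not in raw.get("world", {}):
            cfg.world.seed = cfg.seed
        return cfg

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["truth"]["catch_correlation"] = [
            list(map(float, row)) for row in self.truth.catch_correlation
        ]
        d["truth"]["biomass_slopes"] = [
            {"group": g, "lag": x, "slope": v}
            for (g, x), v in sorted(self.truth.biomass_slopes.items())
        ]
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_jsonable(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def write_provenance(self, artifact_path) -> None:
        """Sidecar JSON embedding the config hash and seed."""
        side = str(artifact_path) + ".provenance.json"
        with open(side, "w") as fh:
            json.dump(
                {"config_hash": self.config_hash(), "seed": self.seed}, fh, indent=1
            )

    def check_output(self, path) -> None:
        if os.path.exists(path) and not self.overwrite:
            raise FileExistsError(
                f"refusing to overwrite {path}; set overwrite: true or pass --overwrite"
            )


def write_default_config(path, seed: int = 1) -> None:
    """Emit a commented starter configuration."""
    cfg = {
        "seed": seed,
        "outdir": "runs/demo",
        "overwrite": False,
        "world": {
            "n_grid_sites": 20,
            "reefs_per_site": 2,
            "years": [2000, 2012],
            "frac_unfished": 0.33,
            "tows_per_reef_year": 10,
            "transects_per_reef": 15,
        },
        "sampler": {"chains": 4, "warmup": 1000, "iterations": 1000},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
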