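"""Run configuration, seed management, and model presets.

A single master seed expands deterministically into named per-component
seeds (simulation, training, sampling, ...) through a counter-based
scheme, so every pipeline stage is reproducible from one integer.  Prior
boxes and protocol settings for the bundled models ship as versioned YAML
presets.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from importlib import resources

import numpy as np
import yaml

from .density import FlowConfig, MdnConfig
from .priors import PriorSpec

__all__ = [
    "spawn_seeds",
    "RunConfig",
    "load_preset",
    "preset_prior",
    "grid_cardinality",
]


def spawn_seeds(master_seed: int, names) -> dict:
    """Derive one independent 31-bit seed per name from a master seed.

    Uses a counter-based expansion (SeedSequence with a per-name index),
    so adding names never changes earlier seeds.
    """
    names = list(names)
    out = {}
    for i, name in enumerate(names):
        ss = np.random.SeedSequence(entropy=int(master_seed),
                                    spawn_key=(i,))
        out[name] = int(ss.generate_state(1)[0] % (2 ** 31))
    return out


@dataclass
class RunConfig:
    """Everything needed to reproduce one inference run."""

    model: str
    rounds: int = 1
    n_per_round: int = 1000
    estimator: str = "mdn"  # mdn | maf
    n_components: int = 1
    n_mades: int = 5
    hidden_layer_sizes: list | None = None
    seed: int = 0
    observation_path: str | None = None
    output_path: str | None = None

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def estimator_config(self, n_params: int, n_features: int):
        seeds = spawn_seeds(self.seed, ["estimator_init"])
        if self.estimator == "mdn":
            return MdnConfig(n_params=n_params, n_features=n_features,
                             n_components=self.n_components,
                             hidden_layer_sizes=self.hidden_layer_sizes,
                             seed=seeds["estimator_init"])
        if self.estimator == "maf":
            return FlowConfig(n_params=n_params, n_features=n_features,
                              n_mades=self.n_mades,
                              hidden_layer_sizes=(self.hidden_layer_sizes
                                                  or [50, 50]),
                              seed=seeds["estimator_init"])
        raise ValueError(f"unknown estimator {self.estimator!r}")


def load_preset(name: str) -> dict:
    """Load a bundled model preset (glm_temporal, gabor, omnimodel, hh, stg)."""
    ref = resources.files("mechsbi").joinpath(f"presets/{name}.yaml")
    with ref.open() as fh:
        return yaml.safe_load(fh)


def preset_prior(name: str) -> PriorSpec:
    """Prior distribution from a bundled preset."""
    p = load_preset(name)["prior"]
    if p["kind"] == "glm_smoothness":
        from .encoding import temporal_glm_prior
        return temporal_glm_prior(p["filter_scale"], p["bias_mean"],
                                  p["bias_sd"])
    if p["kind"] == "gabor_transformed":
        from .encoding import gabor_prior
        return gabor_prior()
    if p["kind"] == "uniform":
        return PriorSpec(kind="uniform", lower=np.asarray(p["lower"]),
                         upper=np.asarray(p["upper"]))
    return PriorSpec(kind="gaussian", mean=np.asarray(p["mean"]),
                     cov=np.diag(np.asarray(p["sd"]) ** 2)
                     if "sd" in p else np.asarray(p["cov"]))


def grid_cardinality(points_per_dim: int, n_dims: int) -> int:
    """Number of grid nodes needed to fill a parameter space — the
    combinatorial argument for why grid searches cannot scale."""
    if points_per_dim < 1 or n_dims < 1:
        raise ValueError("points_per_dim and n_dims must be positive")
    return points_per_dim ** n_dims
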