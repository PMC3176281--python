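"""Flat YAML serialization for run configurations.

Kernel/model parameters appear as a flat key block (family, beta, alpha,
theta, power, r_max, background) so config files stay greppable.
"""

from __future__ import annotations

from dataclasses import asdict

import yaml

from .fit import FitConfig
from .forward import RootModelParams
from .kernels import KernelFamily, KernelParams
from .simulate import SyntheticConfig


def model_params_to_dict(params: RootModelParams) -> dict:
    k = params.kernel
    return {"family": params.family.value, "beta": params.beta,
            "alpha": k.alpha, "theta": k.theta, "power": k.power,
            "r_max": k.r_max, "background": params.background}


def model_params_from_dict(d: dict) -> RootModelParams:
    return RootModelParams(
        beta=float(d["beta"]), family=KernelFamily(d["family"]),
        kernel=KernelParams(alpha=d.get("alpha"),
                            theta=float(d.get("theta", 0.0)),
                            power=d.get("power"), r_max=d.get("r_max")),
        background=float(d.get("background", 0.0)))


def synthetic_config_to_dict(config: SyntheticConfig) -> dict:
    d = asdict(config)
    d["true_params"] = model_params_to_dict(config.true_params)
    d["window"] = list(config.window)
    return d


def synthetic_config_from_dict(d: dict) -> SyntheticConfig:
    d = dict(d)
    if "true_params" in d:
        d["true_params"] = model_params_from_dict(d["true_params"])
    if "window" in d:
        d["window"] = tuple(d["window"])
    if isinstance(d.get("fragments_per_core"), list):
        d["fragments_per_core"] = tuple(d["fragments_per_core"])
    if isinstance(d.get("core_offset"), list):
        d["core_offset"] = tuple(d["core_offset"])
    return SyntheticConfig(**d)


def fit_config_to_dict(config: FitConfig) -> dict:
    d = asdict(config)
    d["families"] = [KernelFamily(f).value for f in config.families]
    d["scale_modes"] = list(config.scale_modes)
    d["bounds"] = {k: list(v) for k, v in config.bounds.items()}
    return d


def fit_config_from_dict(d: dict) -> FitConfig:
    d = dict(d)
    if "families" in d:
        d["families"] = tuple(KernelFamily(f) for f in d["families"])
    if "scale_modes" in d:
        d["scale_modes"] = tuple(d["scale_modes"])
    if "bounds" in d:
        d["bounds"] = {k: tuple(v) for k, v in d["bounds"].items()}
    return FitConfig(**d)


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_yaml(obj: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
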