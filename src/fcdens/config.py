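"""YAML pipeline configuration.

A single config fully specifies a study: one data source (``synthetic`` or
``files``), the parameter blocks for preprocessing, degree mapping and
cluster inference, and the analysis seed.  Every constant of the default
analysis (connection threshold sweep, 6 mm neighborhood radius, 6 mm FWHM
smoothing, 0.01/0.05 voxel/cluster correction levels, 0.01–0.1 Hz band,
1.5 mm / 1.5 deg motion screen, 10 discarded volumes) is a default here,
never hard-coded in a stage.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .fcd import FcdParams
from .inference import ClusterInferenceParams
from .preprocess import PreprocParams
from .simulate import ClinicalSpec, EffectSpec, HubSpec, SimulationConfig


class ConfigError(ValueError):
    """Pipeline configuration is invalid."""


def _build(cls, block: dict | None, label: str):
    block = dict(block or {})
    try:
        return cls(**block)
    except TypeError as exc:
        raise ConfigError(f"bad {label} block: {exc}") from exc
    except ValueError as exc:
        raise ConfigError(f"bad {label} block: {exc}") from exc


def simulation_config_from_dict(block: dict) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from plain YAML data."""
    block = dict(block)
    if "grid_dims" in block:
        block["grid_dims"] = tuple(block["grid_dims"])
    block["hubs"] = [
        HubSpec(
            member_voxels=tuple(tuple(v) for v in h["member_voxels"]),
            coupling_rho=h["coupling_rho"],
            range_class=h["range_class"],
        )
        for h in block.get("hubs", [])
    ]
    block["group_effects"] = [
        EffectSpec(**e) for e in block.get("group_effects", [])
    ]
    block["clinical_specs"] = [
        ClinicalSpec(**c) for c in block.get("clinical_specs", [])
    ]
    try:
        return SimulationConfig(**block)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"bad synthetic block: {exc}") from exc


def load_config(config: dict | str | Path):
    """Instantiate an :class:`~fcdens.model.FcdStudy` from a config.

    ``config`` is a YAML path or an equivalent dictionary.
    """
    from .model import FcdStudy

    if not isinstance(config, dict):
        path = Path(config)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        with open(path) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")

    data = config.get("data") or {}
    has_syn = "synthetic" in data
    has_files = "files" in data
    if has_syn == has_files:
        raise ConfigError(
            "config needs exactly one data source: data.synthetic or data.files"
        )

    kwargs = {
        "preproc_params": _build(PreprocParams, config.get("preprocess"), "preprocess"),
        "fcd_params": _build(FcdParams, config.get("fcd"), "fcd"),
        "inference_params": _build(
            ClusterInferenceParams, config.get("inference"), "inference"
        ),
        "adopted_threshold": float(config.get("adopted_threshold", 0.45)),
        "fdr_q": float(config.get("fdr_q", 0.001)),
        "clinical_vars": config.get("clinical_vars"),
        "seed": int(config.get("seed", 0)),
        "config_dict": config,
    }

    if has_syn:
        sim = simulation_config_from_dict(data["synthetic"])
        if "seed" not in config:
            kwargs["seed"] = sim.seed
        return FcdStudy.from_synthetic(sim, **kwargs)

    files = data["files"]
    for key in ("bold", "mask", "table"):
        if key not in files:
            raise ConfigError(f"data.files needs a {key!r} entry")
    return FcdStudy.from_files(
        bold_paths=list(files["bold"]),
        mask_path=files["mask"],
        table_path=files["table"],
        tr_s=files.get("tr_s"),
        **kwargs,
    )
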