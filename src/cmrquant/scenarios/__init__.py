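"""Packaged scenario files describing the default experimental arms."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from ..errors import ConfigurationError
from ..phantom import Cine, Geometry, Noise, PhantomSpec, Tissue

__all__ = ["SCENARIO_FILES", "load_scenario", "spec_from_dict", "spec_to_dict"]

SCENARIO_FILES = {
    "healthy": "healthy.yaml",
    "+HEM": "hem_only.yaml",
    "I-HEM": "i_hem.yaml",
    "I+HEM": "i_plus_hem.yaml",
}

_TUPLE_FIELDS = {
    "center_rc",
    "edema_slices",
    "infarct_slices",
    "hemorrhage_slices",
    "hemorrhage_radial_band",
}


def _build(cls, data: dict):
    allowed = set(cls.__dataclass_fields__)
    unknown = set(data) - allowed
    if unknown:
        raise ConfigurationError(f"unknown {cls.__name__} fields: {sorted(unknown)}")
    coerced = {
        k: (tuple(v) if k in _TUPLE_FIELDS and v is not None else v) for k, v in data.items()
    }
    return cls(**coerced)


def spec_from_dict(data: dict, **overrides) -> PhantomSpec:
    """Build a :class:`PhantomSpec` from a plain (YAML-loaded) mapping.

    ``overrides`` may patch top-level scalars (``seed``), noise (``snr``,
    ``noise_model``) or the arm (``arm``).
    """
    data = dict(data)
    kw: dict = {}
    if "arm" in data:
        kw["arm"] = data.pop("arm")
    if "matrix" in data:
        kw["matrix"] = tuple(data.pop("matrix"))
    if "n_slices" in data:
        kw["n_slices"] = int(data.pop("n_slices"))
    if "voxel_size_mm" in data:
        kw["voxel_size"] = tuple(data.pop("voxel_size_mm"))
    if "voxel_size" in data:
        kw["voxel_size"] = tuple(data.pop("voxel_size"))
    if "seed" in data:
        kw["seed"] = int(data.pop("seed"))
    for name, cls in (("geometry", Geometry), ("tissue", Tissue), ("noise", Noise), ("cine", Cine)):
        if name in data:
            kw[name] = _build(cls, data.pop(name) or {})
    if data:
        raise ConfigurationError(f"unknown scenario keys: {sorted(data)}")

    if "arm" in overrides:
        kw["arm"] = overrides.pop("arm")
    if "seed" in overrides:
        kw["seed"] = int(overrides.pop("seed"))
    snr = overrides.pop("snr", None)
    noise_model = overrides.pop("noise_model", None)
    if snr is not None or noise_model is not None:
        base = kw.get("noise", Noise())
        kw["noise"] = Noise(
            model=noise_model if noise_model is not None else base.model,
            snr=float(snr) if snr is not None else base.snr,
        )
    if overrides:
        raise ConfigurationError(f"unknown scenario overrides: {sorted(overrides)}")
    return PhantomSpec(**kw)


def spec_to_dict(spec: PhantomSpec) -> dict:
    """Plain JSON/YAML-serializable form of a spec (round-trips via spec_from_dict)."""
    from dataclasses import asdict

    d = asdict(spec)
    d["matrix"] = list(spec.matrix)
    d["voxel_size_mm"] = list(d.pop("voxel_size"))
    for name in ("geometry", "tissue", "noise", "cine"):
        d[name] = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d[name].items()}
    return d


def load_scenario(arm_or_path: str, **overrides) -> PhantomSpec:
    """Load a packaged arm scenario (by arm name) or a YAML file path."""
    if arm_or_path in SCENARIO_FILES:
        text = (
            resources.files(__package__).joinpath(SCENARIO_FILES[arm_or_path]).read_text()
        )
    else:
        path = Path(arm_or_path)
        if not path.exists():
            raise ConfigurationError(
                f"{arm_or_path!r} is neither a known arm {sorted(SCENARIO_FILES)} nor a file"
            )
        text = path.read_text()
    return spec_from_dict(yaml.safe_load(text), **overrides)
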