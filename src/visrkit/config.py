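"""YAML (de)serialization of study configurations.

A study is fully described by a nested mapping mirroring the
:class:`~visrkit.pipeline.StudyConfig` dataclass tree; only keys that
deviate from the defaults need to appear in the file.  Round-trips are
lossless, so a written config plus the seed reproduces a study exactly.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .phantom import AcquisitionParams, CohortConfig, Geometry, SequenceTiming
from .pipeline import StudyConfig
from .roi import RoiSpec
from .tracking import TrackingParams
from .visr import FitOptions

__all__ = ["load_config", "save_config", "config_to_dict"]

_NESTED = {
    "cohort": CohortConfig,
    "tracking": TrackingParams,
    "roi": RoiSpec,
    "fit": FitOptions,
    "acquisition": AcquisitionParams,
    "geometry": Geometry,
    "timing": SequenceTiming,
}


def _build(cls, data: dict):
    kwargs = {}
    for key, value in data.items():
        sub = _NESTED.get(key)
        if sub is not None and isinstance(value, dict):
            kwargs[key] = _build(sub, value)
        elif isinstance(value, list):
            kwargs[key] = tuple(tuple(v) if isinstance(v, list) else v for v in value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_listify(v) for v in obj]
    return obj


def config_to_dict(config: StudyConfig) -> dict:
    return _listify(dataclasses.asdict(config))


def load_config(path: str | Path) -> StudyConfig:
    """Read a StudyConfig from YAML; missing keys take their defaults."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    return _build(StudyConfig, data)


def save_config(config: StudyConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False))
    return path
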