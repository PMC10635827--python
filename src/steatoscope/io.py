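"""File I/O: multi-channel TIFF images, tidy CSV tables, scenario YAML."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import synthetic
from .lipidomics import TagProfile, profile_from_frame, profile_to_frame
from .synthetic import AnnotatedImage

__all__ = [
    "write_image",
    "read_image",
    "write_tag_profile",
    "read_tag_profile",
    "write_scenario",
    "read_scenario",
]

_SCENARIO_TYPES = {
    "ImageScenario": synthetic.ImageScenario,
    "LabelingScenario": synthetic.LabelingScenario,
    "TagScenario": synthetic.TagScenario,
    "ScreenScenario": synthetic.ScreenScenario,
}


def write_image(path, image: AnnotatedImage | np.ndarray) -> None:
    """Write a (channel, y, x) TIFF; channel 0 = nuclei, channel 1 = lipid."""
    if isinstance(image, AnnotatedImage):
        stack = np.stack([image.nuclei, image.lipid])
    else:
        stack = np.asarray(image)
    tifffile.imwrite(path, stack)


def read_image(path, nuclei_channel: int = 0, lipid_channel: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Read a multi-channel TIFF and return (nuclei, lipid) planes."""
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        raise ValueError("expected a multi-channel TIFF (channel, y, x)")
    return stack[nuclei_channel], stack[lipid_channel]


def write_tag_profile(path, profile: TagProfile) -> None:
    profile_to_frame(profile).to_csv(path, index=False)


def read_tag_profile(path, condition: str | None = None) -> TagProfile:
    return profile_from_frame(pd.read_csv(path), condition=condition)


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, (tuple, list)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_scenario(path, scenario) -> None:
    kind = type(scenario).__name__
    if kind not in _SCENARIO_TYPES:
        raise TypeError(f"not a scenario type: {kind}")
    payload = {"kind": kind, **_to_plain(scenario)}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def _rebuild(cls, data):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if isinstance(v, list):
            v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        kwargs[f.name] = v
    return cls(**kwargs)


def read_scenario(path):
    data = yaml.safe_load(Path(path).read_text())
    kind = data.pop("kind", None)
    if kind not in _SCENARIO_TYPES:
        raise ValueError(f"unknown scenario kind: {kind!r}")
    cls = _SCENARIO_TYPES[kind]
    if kind == "LabelingScenario":
        data["fatty_acids"] = tuple(
            synthetic.FattyAcid(**fa) if isinstance(fa, dict) else synthetic.FattyAcid(*fa)
            for fa in data["fatty_acids"]
        )
    if kind == "ScreenScenario":
        data["drugs"] = tuple(
            synthetic.DrugSpec(
                name=d["name"], effects=tuple(d["effects"]), toxic=tuple(d["toxic"])
            )
            if isinstance(d, dict)
            else synthetic.DrugSpec(*d)
            for d in data["drugs"]
        )
    return _rebuild(cls, data)
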