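"""Dataclass builders for the YAML/JSON configuration surface."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .losses import LossConfig
from .model import (DiscriminatorSpec, GeneratorSpec, ModelState,
                    PreprocessSpec, TrainConfig)
from .phantom import BeamSpec, PhantomSpec, StructureDef, default_beams


def _tuple3(v):
    return tuple(float(x) for x in v)


def phantom_spec_from_dict(d: dict | None) -> PhantomSpec:
    d = dict(d or {})
    kwargs = {}
    if "structures" in d:
        kwargs["structures"] = tuple(
            StructureDef(s["name"], _tuple3(s["center_mm"]), _tuple3(s["radii_mm"]),
                         float(s["hu_mean"]), float(s["hu_sigma"]),
                         int(s["priority"]))
            for s in d.pop("structures"))
    if "beams" in d:
        kwargs["beams"] = tuple(BeamSpec(**b) for b in d.pop("beams"))
    else:
        kwargs["beams"] = default_beams()
    for key in ("shape", "spacing", "origin"):
        if key in d:
            v = d.pop(key)
            kwargs[key] = tuple(int(x) for x in v) if key == "shape" else _tuple3(v)
    kwargs.update(d)
    return PhantomSpec(**kwargs)


def loss_config_from_dict(d: dict | None) -> LossConfig:
    return LossConfig(**(d or {}))


def train_config_from_dict(d: dict | None) -> TrainConfig:
    return TrainConfig(**(d or {}))


def generator_spec_from_dict(d: dict | None) -> GeneratorSpec:
    return GeneratorSpec(**(d or {}))


def discriminator_spec_from_dict(d: dict | None) -> DiscriminatorSpec:
    return DiscriminatorSpec(**(d or {}))


def preprocess_spec_from_dict(d: dict | None) -> PreprocessSpec:
    return PreprocessSpec(**(d or {}))


def save_model_state(state: ModelState, model_dir) -> None:
    model_dir = Path(model_dir)
    model_dir.mkdir(parents=True, exist_ok=True)
    arrays = {f"g_{i}": a for i, a in enumerate(state.g_cbct2ct)}
    arrays.update({f"f_{i}": a for i, a in enumerate(state.g_ct2cbct)})
    np.savez(model_dir / "model.npz", **arrays)
    meta = {"gen_spec": asdict(state.gen_spec), "pre_spec": asdict(state.pre_spec),
            "n_g": len(state.g_cbct2ct), "n_f": len(state.g_ct2cbct)}
    (model_dir / "meta.json").write_text(json.dumps(meta, indent=2) + "\n")


def load_model_state(model_dir) -> ModelState:
    model_dir = Path(model_dir)
    meta = json.loads((model_dir / "meta.json").read_text())
    data = np.load(model_dir / "model.npz")
    return ModelState(
        gen_spec=GeneratorSpec(**meta["gen_spec"]),
        pre_spec=PreprocessSpec(**meta["pre_spec"]),
        g_cbct2ct=[data[f"g_{i}"] for i in range(meta["n_g"])],
        g_ct2cbct=[data[f"f_{i}"] for i in range(meta["n_f"])],
    )
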