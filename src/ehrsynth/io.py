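"""Persistence: single-file model archive bundling networks and metadata.

The archive is a numpy ``.npz`` holding every network parameter/buffer plus
JSON blobs for the transform metadata, architecture specs and the
categorical sampling frequencies — everything ``sample`` needs to run from
disk without the training data.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .critic import CriticSpec, TabularCritic
from .generator import ConditionSampler, GeneratorSpec, TabularGenerator
from .transform import TableTransformer

__all__ = ["save_model", "load_model"]


def save_model(
    path: str | Path,
    generator: TabularGenerator,
    sampler: ConditionSampler,
    critic: TabularCritic | None = None,
) -> None:
    arrays: dict[str, np.ndarray] = {}
    for k, v in generator.state_arrays().items():
        arrays[f"gen.{k}"] = v
    if critic is not None:
        for k, v in critic.state_arrays().items():
            arrays[f"critic.{k}"] = v
    meta = {
        "transformer": generator.transformer.to_dict(),
        "gen_spec": generator.spec.to_dict(),
        "critic_spec": critic.spec.to_dict() if critic is not None else None,
        "frequencies": {k: v.tolist() for k, v in sampler.frequencies.items()},
    }
    arrays["__meta__"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8
    )
    np.savez_compressed(path, **arrays)


def load_model(
    path: str | Path,
) -> tuple[TabularGenerator, ConditionSampler, TabularCritic | None]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"model archive not found: {path}")
    with np.load(path) as npz:
        arrays = {k: npz[k] for k in npz.files}
    meta = json.loads(bytes(arrays.pop("__meta__")).decode("utf-8"))
    transformer = TableTransformer.from_dict(meta["transformer"])
    generator = TabularGenerator(
        transformer, GeneratorSpec.from_dict(meta["gen_spec"]), rng_seed=0
    )
    generator.load_state_arrays(
        {k[len("gen."):]: v for k, v in arrays.items() if k.startswith("gen.")}
    )
    sampler = ConditionSampler(
        transformer, {k: np.asarray(v) for k, v in meta["frequencies"].items()}
    )
    critic = None
    if meta["critic_spec"] is not None:
        critic = TabularCritic(CriticSpec.from_dict(meta["critic_spec"]), rng_seed=0)
        critic.load_state_arrays(
            {
                k[len("critic."):]: v
                for k, v in arrays.items()
                if k.startswith("critic.")
            }
        )
    return generator, sampler, critic
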