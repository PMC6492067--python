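"""Small shared helpers."""

from __future__ import annotations

import json
import math
from dataclasses import asdict, is_dataclass
from typing import Any

import numpy as np


def round_half_up(x: float) -> int:
    """Round a non-negative real half-up to an integer (0.5 -> 1).

    Population figures are reported this way so that printed tables are
    reproducible regardless of the platform's banker's rounding.
    """
    if math.isinf(x):
        raise ValueError("cannot round an infinite value")
    return int(math.floor(x + 0.5))


def rng_for(seed: int, stream: int = 0) -> np.random.Generator:
    """Derive an independent generator for a named stream of one base seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


def largest_remainder_allocation(weights: np.ndarray, total: int, floor: np.ndarray | None = None) -> np.ndarray:
    """Integer allocation of `total` proportional to `weights`.

    Optionally enforces per-cell minimum counts `floor` (sum(floor) <= total).
    """
    weights = np.asarray(weights, dtype=float)
    if weights.sum() <= 0:
        raise ValueError("weights must have positive sum")
    if floor is None:
        floor = np.zeros_like(weights, dtype=np.int64)
    floor = np.asarray(floor, dtype=np.int64)
    remaining = total - int(floor.sum())
    if remaining < 0:
        raise ValueError("floor exceeds total")
    ideal = weights / weights.sum() * remaining
    base = np.floor(ideal).astype(np.int64)
    short = remaining - int(base.sum())
    frac = ideal - base
    order = np.argsort(-frac, kind="stable")
    base[order[:short]] += 1
    return floor + base


def _jsonable(obj: Any) -> Any:
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return v
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, float) and math.isinf(obj):
        return "inf" if obj > 0 else "-inf"
    return obj


def to_json(obj: Any, **kwargs: Any) -> str:
    """Serialise dataclasses / numpy-bearing structures deterministically."""
    return json.dumps(_jsonable(obj), sort_keys=True, indent=2, **kwargs)
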