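"""Shared helpers: seed derivation, hashing, small validation utilities."""

from __future__ import annotations

import hashlib
import json
from typing import Any, Iterable

import numpy as np

__all__ = ["derive_seed", "spawn_rng", "sha256_of", "require"]


def derive_seed(master_seed: int, *stream: int) -> int:
    """Derive an independent child seed (< 2**31) from a master seed and a stream id.

    Uses :class:`numpy.random.SeedSequence` so children indexed by distinct
    ``stream`` tuples are statistically independent and the mapping is stable
    across runs and execution order.
    """
    ss = np.random.SeedSequence(entropy=[int(master_seed), *map(int, stream)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def spawn_rng(master_seed: int, *stream: int) -> np.random.Generator:
    """A :class:`numpy.random.Generator` seeded from ``derive_seed``."""
    return np.random.default_rng(derive_seed(master_seed, *stream))


def sha256_of(obj: Any) -> str:
    """Stable content hash of arrays / frames / JSON-serializable objects."""
    h = hashlib.sha256()
    if isinstance(obj, np.ndarray):
        h.update(np.ascontiguousarray(obj).tobytes())
        h.update(str(obj.dtype).encode())
        h.update(str(obj.shape).encode())
    elif hasattr(obj, "to_csv"):  # DataFrame / Series
        h.update(obj.to_csv(index=True).encode())
    elif isinstance(obj, (bytes, bytearray)):
        h.update(bytes(obj))
    else:
        h.update(json.dumps(obj, sort_keys=True, default=str).encode())
    return h.hexdigest()


def require(condition: bool, field: str, message: str) -> None:
    """Raise ``ValueError`` naming the offending field unless ``condition``."""
    if not condition:
        raise ValueError(f"invalid {field}: {message}")
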