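"""Seed plumbing and small shared helpers."""

from __future__ import annotations

import hashlib
import json

import numpy as np

__all__ = ["substream_seed", "substream_rng", "config_hash"]


def substream_seed(root_seed: int, name: str) -> int:
    """Deterministic named substream seed derived from one root seed.

    Every source of randomness in a pipeline run draws from a named
    substream so that stages are independently reproducible.  The result is
    kept below 2**31.
    """
    key = int.from_bytes(hashlib.sha256(name.encode()).digest()[:4], "big")
    ss = np.random.SeedSequence([int(root_seed), key])
    return int(ss.generate_state(1)[0] % (2**31))


def substream_rng(root_seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(substream_seed(root_seed, name))


def config_hash(config: dict) -> str:
    """Stable hash of a (JSON-serialisable) configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
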