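"""Shared helpers: quantiles, RNG stream splitting, validation."""

from __future__ import annotations

import numpy as np


def quantile(x, q):
    """Sort-based linear-interpolation quantile (R type 7, numpy default).

    Shared by the schooling-count truncation, pixel classification and
    post-stratified interval code so every quantile in the package follows
    one rule.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("quantile of empty array")
    return np.quantile(x, q)


def spawn_rng(seed: int, stream: str) -> np.random.Generator:
    """Independent generator for a named stream under one master seed.

    Each table (grid, replicates, fish records, ...) draws from its own
    stream so adding one output does not perturb another.
    """
    ss = np.random.SeedSequence(int(seed), spawn_key=(hash_stream(stream),))
    return np.random.default_rng(ss)


def hash_stream(name: str) -> int:
    # stable across processes (builtin hash is salted)
    h = 0
    for ch in name:
        h = (h * 131 + ord(ch)) % (2**31 - 1)
    return h


def check_positive_int(value, name):
    if not (np.isscalar(value) or isinstance(value, (int, np.integer))):
        raise ValueError(f"{name} must be a positive integer, got {value!r}")
    if int(value) != value or value <= 0:
        raise ValueError(f"{name} must be a positive integer, got {value!r}")
    return int(value)
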