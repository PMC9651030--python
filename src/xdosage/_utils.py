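"""Shared helpers: named RNG streams, error types, logging."""

from __future__ import annotations

import logging
import zlib

import numpy as np

logger = logging.getLogger("xdosage")


class ConfigError(ValueError):
    """Invalid configuration value; the message names the offending field."""


class ValidationError(ValueError):
    """Malformed or inconsistent input data."""


def stream_rng(seed: int, name: str) -> np.random.Generator:
    """Return a reproducible RNG stream keyed by (seed, name).

    Each simulator draws from its own named stream so adding a new
    simulator never perturbs the draws of existing ones.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(key,)))
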