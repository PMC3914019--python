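"""Small shared helpers: parameter validation and seed derivation."""

from __future__ import annotations

import zlib

import numpy as np


class ParameterError(ValueError):
    """Invalid parameter value passed to a simulation or calling routine."""


class DimensionError(ValueError):
    """Mismatched shapes or sample sets between inputs."""


class EmptyInputError(ValueError):
    """No usable data (zero overlapping markers, all-missing input, ...)."""


def check(condition: bool, message: str, exc: type[Exception] = ParameterError) -> None:
    if not condition:
        raise exc(message)


def check_probability(value: float, name: str, upper: float = 1.0) -> None:
    check(0.0 <= value <= upper, f"{name} must be in [0, {upper}], got {value!r}")


def derive_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage seed from one master seed.

    Stable across runs and platforms (CRC32 of the stage name mixed with the
    master seed), always in [0, 2**31).
    """
    h = zlib.crc32(stage.encode("utf-8"))
    return int((h ^ (master_seed * 2654435761)) % (2**31))


def rng_for(seed: int, stage: str | None = None) -> np.random.Generator:
    if stage is not None:
        seed = derive_seed(seed, stage)
    return np.random.default_rng(seed)
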