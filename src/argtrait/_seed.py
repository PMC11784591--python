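"""Reproducible random-stream plumbing.

A single master seed is expanded into named substreams in a fixed order
(site selection, allele choice, effect sizes, environmental noise), so
that e.g. adding traits or changing the heritability never perturbs the
earlier draws of a run.
"""

from __future__ import annotations

from typing import Union

import numpy as np

SeedLike = Union[int, np.random.SeedSequence, np.random.Generator, None]


def as_seed_sequence(seed: SeedLike) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    if isinstance(seed, np.random.Generator):
        raise TypeError(
            "a Generator cannot be split into substreams; pass an int or "
            "SeedSequence here")
    if seed is None:
        return np.random.SeedSequence()
    seed = int(seed)
    if seed < 0:
        raise ValueError(f"seed must be non-negative, got {seed}")
    return np.random.SeedSequence(seed)


def as_generator(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(as_seed_sequence(seed))
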