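"""Seed management.

One root seed fans out to named, independent child streams so that every
stage of the pipeline is reproducible in isolation.  The derivation is
``SeedSequence([root_seed, crc32(label)])``, which is stable across runs,
platforms and numpy versions.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_rng", "child_seed"]


def child_seed(root_seed: int, label: str) -> np.random.SeedSequence:
    """Derive the seed sequence for the stage named ``label``."""
    return np.random.SeedSequence([int(root_seed), zlib.crc32(label.encode("utf-8"))])


def child_rng(root_seed: int, label: str) -> np.random.Generator:
    """A PCG64 generator for the stage named ``label`` under ``root_seed``."""
    return np.random.default_rng(child_seed(root_seed, label))
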