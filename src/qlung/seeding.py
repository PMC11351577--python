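"""Stage-namespaced random generators.

Every stochastic stage (phantom generation, backbone init, splitting,
training, ...) draws from its own generator derived from one root seed, so
stages can be re-run independently and reproducibly.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stage_rng"]


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Return a Generator for ``stage`` derived deterministically from ``seed``.

    The stage name is hashed with CRC32 (stable across processes, unlike
    Python's ``hash``) and mixed into a SeedSequence with the root seed.
    """
    tag = zlib.crc32(stage.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))
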