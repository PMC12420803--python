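"""Deterministic named random substreams.

All randomness in the package flows from one root seed; each stage draws
from a substream derived from (root seed, stage name) so that adding or
reordering stages never perturbs the streams of the others.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream", "child_seed"]


def child_seed(seed: int, name: str) -> int:
    """Stable 31-bit child seed for a named stage."""
    digest = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def substream(seed: int, name: str) -> np.random.Generator:
    """Generator for a named stage under a root seed."""
    return np.random.default_rng(child_seed(seed, name))
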