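"""Reproducible random-number streams.

One master seed drives the whole pipeline.  Per-patient (and per-stage)
substreams are derived by stable hashing of string keys, so enlarging a cohort
or reordering stages never reshuffles the draws of existing patients.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["stable_hash", "substream"]


def stable_hash(*keys: object) -> int:
    """Map a tuple of keys to a stable 64-bit integer (SHA-256 based).

    Independent of PYTHONHASHSEED and of the process; identical across runs
    and platforms.
    """
    text = "\x1f".join(str(k) for k in keys)
    digest = hashlib.sha256(text.encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "little")


def substream(master_seed: int, *keys: object) -> np.random.Generator:
    """Return a Generator for the substream identified by ``keys``.

    Uses :class:`numpy.random.SeedSequence` with a spawn key derived from the
    hashed keys, so substreams are statistically independent of each other and
    of the master stream.
    """
    seq = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(stable_hash(*keys),))
    return np.random.default_rng(seq)
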