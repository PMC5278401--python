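"""Named, order-independent random substreams.

Dataset-level operations (forcing a whole pileup, simulating a class
distribution) draw from substreams keyed by a stable string (typically the
locus id or class label), so results are bit-reproducible and do not depend
on iteration order.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, *keys: object) -> np.random.Generator:
    """Return a Generator deterministically derived from ``seed`` and ``keys``.

    The same (seed, keys) always yields the same stream; distinct keys yield
    statistically independent streams (keys are hashed into the SeedSequence
    spawn key).
    """
    label = "\x1f".join(str(k) for k in keys)
    digest = hashlib.blake2b(label.encode(), digest_size=16).digest()
    spawn_key = tuple(int.from_bytes(digest[i : i + 4], "little") for i in range(0, 16, 4))
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=spawn_key)
    return np.random.default_rng(ss)
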