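"""Small shared helpers: seed derivation and exhaustive label arrangements."""

from __future__ import annotations

import hashlib
from collections import Counter
from typing import Iterator, Sequence

import numpy as np

MAX_SEED = 2**31 - 1


def derive_seed(master: int, stage: str) -> int:
    """Stable per-stage seed from a master seed.

    Hash-based so that adding a stage never perturbs the streams of
    earlier stages.
    """
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % MAX_SEED


def rng_for(seed, stage: str | None = None) -> np.random.Generator:
    if stage is not None:
        seed = derive_seed(int(seed), stage)
    return np.random.default_rng(seed)


def multiset_permutations(items: Sequence) -> Iterator[tuple]:
    """Yield every distinct arrangement of ``items`` (a multiset).

    Used by the exhaustive modes of the permutation tests; the number of
    arrangements is n! / (prod of multiplicities!), e.g. 20 for AAABBB.
    """
    counts = Counter(items)
    keys = sorted(counts, key=str)
    n = len(items)

    def rec(prefix):
        if len(prefix) == n:
            yield tuple(prefix)
            return
        for k in keys:
            if counts[k] > 0:
                counts[k] -= 1
                prefix.append(k)
                yield from rec(prefix)
                prefix.pop()
                counts[k] += 1

    yield from rec([])
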