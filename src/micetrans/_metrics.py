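"""Shared low-level similarity metrics.

These primitives are used both for habitat profiles (cover-type vectors)
and for microbiota composition (ASV presence/proportion vectors), so they
live in one place and are re-exported by the consuming modules.
"""

from __future__ import annotations

import numpy as np


def bray_curtis_similarity(x, y) -> float:
    """Bray-Curtis similarity, ``1 - sum|x-y| / sum(x+y)``.

    Defined as 0.0 when both vectors are all-zero. Raises ``ValueError``
    on negative entries or length mismatch.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("Bray-Curtis requires non-negative entries")
    denom = (x + y).sum()
    if denom == 0:
        return 0.0
    return float(1.0 - np.abs(x - y).sum() / denom)


def jaccard(a, b) -> float:
    """Jaccard index |a & b| / |a | b| over two presence sets.

    Defined as 0.0 when both sets are empty.
    """
    a = set(a)
    b = set(b)
    union = len(a | b)
    if union == 0:
        return 0.0
    return len(a & b) / union


def shared_count(a, b) -> int:
    """Number of taxa present in both sets."""
    return len(set(a) & set(b))
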