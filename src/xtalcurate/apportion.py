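"""Largest-remainder apportionment, shared by selection, dedup and generation."""

from __future__ import annotations

from typing import Sequence

import numpy as np


def largest_remainder(weights: Sequence[float], n: int) -> np.ndarray:
    """Apportion ``n`` integer units proportionally to ``weights``.

    Each unit count is ``floor(n * w_i / sum(w))`` plus one extra unit for the
    largest fractional remainders until the counts sum to ``n``.  Remainder
    ties are broken by position (earlier entries win), which keeps the result
    deterministic.  Every count is within 1 of its real-valued quota.
    """
    if n < 0:
        raise ValueError("cannot apportion a negative total")
    w = np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    total = w.sum()
    if total <= 0:
        if n == 0:
            return np.zeros(len(w), dtype=np.int64)
        raise ValueError("cannot apportion a positive total over zero weights")
    quota = n * w / total
    counts = np.floor(quota).astype(np.int64)
    remainder = quota - counts
    short = n - int(counts.sum())
    if short > 0:
        # stable sort => ties broken by position
        order = np.argsort(-remainder, kind="stable")
        counts[order[:short]] += 1
    return counts
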