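"""Sliding-window index arithmetic shared by the windowed statistics.

All windowed estimators in this package (IBS, Fst, Pn/Ps over SNP loci;
percent-identity over ordered RBH matches) use the same scheme: windows of a
fixed number of consecutive items, advanced by a fixed step, restricted to a
single chromosome, with trailing partial windows dropped.
"""

from __future__ import annotations

import numpy as np


def window_starts(n_items: int, window: int, step: int) -> np.ndarray:
    """Start indices of full sliding windows over ``n_items`` ordered items.

    Windows never span chromosomes: call per chromosome. Trailing windows
    with fewer than ``window`` items are dropped, so 250 items with
    window=100, step=25 yield 7 windows and 300 items with window=100,
    step=20 yield 11.
    """
    if window <= 0:
        raise ValueError(f"window must be positive, got {window}")
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    if n_items < window:
        return np.empty(0, dtype=np.int64)
    return np.arange(0, n_items - window + 1, step, dtype=np.int64)
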