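"""Shared brute-force oracles for the test suite."""

import numpy as np


def bruteforce_select(indicator, n_rois, b):
    """Greedy argmax of window means with hard overlap exclusion."""
    work = np.asarray(indicator, dtype=float).copy()
    H, W = work.shape
    chosen = []
    for _ in range(n_rois):
        best, best_pos = -np.inf, None
        for r in range(H - b + 1):
            for c in range(W - b + 1):
                if any(abs(r - rr) < b and abs(c - cc) < b for rr, cc in chosen):
                    continue
                score = work[r : r + b, c : c + b].mean()
                if score > best:
                    best, best_pos = score, (r, c)
        chosen.append(best_pos)
        r, c = best_pos
        work[r : r + b, c : c + b] = 0.0
    return chosen
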