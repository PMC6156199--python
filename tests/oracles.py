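"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's vectorized/DP implementations:
the scan oracle recomputes window statistics position by position with
numpy reductions, the folding oracle enumerates every pseudoknot-free
structure, and the rank-sum oracle enumerates every rank assignment.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

# --- sliding-window scan ---------------------------------------------------

def naive_scan(values, window, sd_threshold, min_segment_len, sd_floor):
    """Position-by-position evaluation of the elevated-run rule.

    A run starts where the value exceeds the trailing window's mean by
    more than sd_threshold * max(sd, sd_floor) and extends while values
    stay above that frozen threshold; runs longer than min_segment_len
    are reported as (start, end) in the scanned orientation.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    runs = []
    i = window
    while i < n:
        win = v[i - window: i]
        m = float(np.mean(win))
        sd = max(float(np.std(win)), sd_floor)
        thr = m + sd_threshold * sd
        if v[i] > thr:
            j = i
            while j < n and v[j] > thr:
                j += 1
            if j - i > min_segment_len:
                runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


# --- RNA folding (simplified pair+stack model) -----------------------------

PAIR_ENERGY = {
    ("G", "C"): -3.0, ("C", "G"): -3.0,
    ("A", "U"): -2.0, ("U", "A"): -2.0,
    ("G", "U"): -1.0, ("U", "G"): -1.0,
}
STACK_BONUS = -1.0
MIN_LOOP = 3


def enumerate_fold_min(seq: str) -> float:
    """Minimum energy over ALL pseudoknot-free structures of a short RNA."""
    s = seq.upper().replace("T", "U")
    n = len(s)

    def structures(i, j):
        if j - i < MIN_LOOP + 1:
            yield frozenset()
            return
        yield from structures(i + 1, j)
        for k in range(i + MIN_LOOP + 1, j + 1):
            if (s[i], s[k]) in PAIR_ENERGY:
                for a in structures(i + 1, k - 1):
                    for b in structures(k + 1, j):
                        yield a | b | {(i, k)}

    best = 0.0
    for st in structures(0, n - 1):
        e = sum(PAIR_ENERGY[(s[i], s[j])] for i, j in st)
        e += sum(STACK_BONUS for (i, j) in st if (i + 1, j - 1) in st)
        best = min(best, e)
    return best


# --- Wilcoxon rank-sum exact p by enumeration ------------------------------

def exact_ranksum_p(x, y) -> float:
    """Two-sided exact p for tie-free samples, by enumerating assignments."""
    x = list(x)
    y = list(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    n1, n = len(x), len(x) + len(y)
    u_obs = sum(1 for a in x for b in y if a > b)
    us = []
    for idx in combinations(range(n), n1):
        sel = set(idx)
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(n) if i not in sel]
        us.append(sum(1 for a in xs for b in ys if a > b))
    us = np.asarray(us)
    p = 2.0 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return float(min(p, 1.0))
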