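"""Independent brute-force oracles used by the test suite.

These deliberately avoid the vectorized algorithms in the package: the
STTC oracle merges tiling intervals with an explicit scan and counts
coincidences with a double loop; the burst oracle enumerates candidate
runs exhaustively.
"""

import numpy as np

from meanet.bursts import Burst


def sttc_oracle(a, b, dt, duration):
    def tiled(train):
        iv = sorted((max(0.0, t - dt), min(duration, t + dt)) for t in train)
        total, (cur_lo, cur_hi) = 0.0, iv[0]
        for lo, hi in iv[1:]:
            if lo > cur_hi:
                total += cur_hi - cur_lo
                cur_lo, cur_hi = lo, hi
            else:
                cur_hi = max(cur_hi, hi)
        total += cur_hi - cur_lo
        return total / duration

    def prop(x, y):
        return sum(1 for t in x if any(abs(t - u) <= dt for u in y)) / len(x)

    ta, tb = tiled(a), tiled(b)
    pa, pb = prop(a, b), prop(b, a)
    terms = []
    if 1 - pa * tb != 0:
        terms.append((pa - tb) / (1 - pa * tb))
    if 1 - pb * ta != 0:
        terms.append((pb - ta) / (1 - pb * ta))
    return float(np.mean(terms)) if terms else None


def brute_force_bursts(train, isith, min_spikes=5):
    """Exhaustive maximal-run scan (fast-threshold branch)."""
    train = np.asarray(train)
    best = []
    n = train.size
    used = np.zeros(n, bool)
    for s in range(n):
        for e in range(n - 1, s, -1):
            seg = train[s : e + 1]
            if np.all(np.diff(seg) <= isith):
                if s > 0 and train[s] - train[s - 1] <= isith:
                    continue
                if e < n - 1 and train[e + 1] - train[e] <= isith:
                    continue
                if e - s + 1 >= min_spikes and not used[s : e + 1].any():
                    best.append(Burst(float(train[s]), float(train[e]), e - s + 1))
                    used[s : e + 1] = True
                break
    return sorted(best)


def greedy_match_count(a, b, tol=1e-3):
    """One-to-one in-order coincidence count between two sorted time lists."""
    i = j = m = 0
    while i < len(a) and j < len(b):
        if abs(a[i] - b[j]) <= tol:
            m += 1
            i += 1
            j += 1
        elif b[j] < a[i] - tol:
            j += 1
        else:
            i += 1
    return m
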