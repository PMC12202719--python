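"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the library's implementation paths: plain
loops, direct definitions.
"""

from __future__ import annotations

import numpy as np


def brute_force_triggers(card_nav: np.ndarray, fs: float, window_s: float = 0.375,
                         prominence_min: float = 0.5, p_lo: float = 10.0,
                         p_hi: float = 98.0) -> np.ndarray:
    """Exhaustive trigger detection on the normalised derivative.

    Candidate maxima are every sample strictly greater than both
    neighbours (plateaus: first sample of a flat top followed by a
    drop); the minimum-separation rule keeps the taller of any pair
    closer than ``window_s`` (processed tallest-first); surviving peaks
    must have topographic prominence >= ``prominence_min`` measured on
    the full signal.  Returns sample indices.
    """
    x = np.asarray(card_nav, dtype=float)
    d = np.gradient(x)
    lo, hi = np.percentile(d, [p_lo, p_hi])
    if hi == lo:
        return np.array([], dtype=int)
    y = (d - lo) / (hi - lo)
    n = y.size

    # local maxima incl. plateau handling (midpoint of flat top)
    candidates = []
    i = 1
    while i < n - 1:
        if y[i - 1] < y[i]:
            j = i
            while j < n - 1 and y[j + 1] == y[i]:
                j += 1
            if j < n - 1 and y[j + 1] < y[i]:
                candidates.append((i + j) // 2)
            i = j + 1
        else:
            i += 1
    candidates = np.array(candidates, dtype=int)
    if candidates.size == 0:
        return candidates

    # minimum separation: keep taller peaks, greedy tallest-first
    order = np.argsort(y[candidates])[::-1]
    keep = np.ones(candidates.size, dtype=bool)
    min_dist = window_s * fs
    for rank, ci in enumerate(order):
        if not keep[ci]:
            continue
        for cj in order[rank + 1:]:
            if keep[cj] and abs(candidates[cj] - candidates[ci]) < min_dist:
                keep[cj] = False
    survivors = np.sort(candidates[keep])

    # topographic prominence on the full signal
    out = []
    for p in survivors:
        left_base = y[:p].min() if p > 0 else y[p]
        for i in range(p - 1, -1, -1):
            if y[i] > y[p]:
                left_base = y[i + 1:p + 1].min()
                break
        else:
            left_base = y[:p + 1].min()
        right_base = y[p]
        for i in range(p + 1, n):
            if y[i] > y[p]:
                right_base = y[p:i].min()
                break
        else:
            right_base = y[p:].min()
        prom = y[p] - max(left_base, right_base)
        if prom >= prominence_min:
            out.append(p)
    return np.array(out, dtype=int)


def enumerate_matches(pt_times, ref_times):
    """Direct interval-walk implementation of the trigger-matching rule."""
    pairs, fps, fns = [], [], []
    for k in range(len(ref_times) - 1):
        inside = [t for t in pt_times
                  if ref_times[k] <= t < ref_times[k + 1]]
        if not inside:
            fns.append(ref_times[k])
        else:
            pairs.append((ref_times[k], inside[0]))
            fps.extend(inside[1:])
    return pairs, fps, fns
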