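"""Independent reference implementations used as oracles in the tests.

These deliberately use naive algorithms (full rescans, explicit loops) so
they share no code path with the package's compiled implementations.
"""

from __future__ import annotations

import numpy as np


def brute_force_euler(track, t0: float) -> int:
    """Count maximal runs >= t0 plus maximal runs <= -t0 by direct scan."""
    n = 0
    for sign in (1.0, -1.0):
        prev = False
        for x in track:
            cur = (sign * x) >= t0
            if cur and not prev:
                n += 1
            prev = cur
    return n


def brute_force_track(values, w_l: int, w_r: int):
    """Score track of one chromosome by direct window means."""
    n = len(values)
    return [
        float(np.mean(values[b : b + w_r]) - np.mean(values[b - w_l : b]))
        for b in range(w_l, n - w_r + 1)
    ]


def reference_segment(values, chrom_starts, significance, E: float):
    """O(P^2) greedy agglomerative clustering, rescanning every boundary.

    ``significance(t, w_l, w_r)`` scores a boundary; at each step the
    boundary with the largest score is merged (ties to the leftmost), until
    all scores are <= E.  Returns [(start, width), ...] in genome order.
    """
    segs = []  # [chrom_index, start, width, sum]
    for c in range(len(chrom_starts) - 1):
        for i in range(chrom_starts[c], chrom_starts[c + 1]):
            segs.append([c, i, 1, float(values[i])])
    while True:
        best = None
        for k in range(len(segs) - 1):
            a, b = segs[k], segs[k + 1]
            if a[0] != b[0]:
                continue
            jump = b[3] / b[2] - a[3] / a[2]
            sig = significance(abs(jump), a[2], b[2])
            pos = b[1]
            if best is None or sig > best[0] or (sig == best[0] and pos < best[2]):
                best = (sig, k, pos)
        if best is None or best[0] <= E:
            break
        k = best[1]
        a, b = segs[k], segs[k + 1]
        segs[k] = [a[0], a[1], a[2] + b[2], a[3] + b[3]]
        del segs[k + 1]
    return [(s[1], s[2]) for s in segs]


def exhaustive_euler_curves(row, probe_map, scale_pairs, thresholds):
    """Mean Euler counts over all cyclic offsets of a single profile."""
    P = len(row)
    out = np.zeros((len(scale_pairs), len(thresholds)))
    for off in range(P):
        shifted = np.roll(row, off)
        for pi, (wl, wr) in enumerate(scale_pairs):
            for ti, t0 in enumerate(thresholds):
                total = 0
                for _, sl in probe_map.chrom_slices():
                    v = shifted[sl]
                    if len(v) < wl + wr:
                        continue
                    total += brute_force_euler(brute_force_track(v, wl, wr), t0)
                out[pi, ti] += total
    return out / P
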