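"""Compiled inner loops: excursion-run counting, significance lookup, segmentation.

Everything here operates on plain numpy arrays so it can be compiled with
numba.  The Python-facing wrappers live in :mod:`rubic.break_stats` and
:mod:`rubic.segmentation`; the significance evaluator is shared between the
two paths so that table lookups and the segmentation heap agree bit-for-bit.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: floor applied to every expected-Euler-characteristic value (log scale)
LOG_SIG_FLOOR = float(np.log(1e-12))


@njit(cache=True, inline="always")
def _bisect_right(a, x):
    lo = 0
    hi = a.shape[0]
    while lo < hi:
        mid = (lo + hi) // 2
        if x < a[mid]:
            hi = mid
        else:
            lo = mid + 1
    return lo


# ---------------------------------------------------------------------------
# Euler-characteristic counting over a threshold grid


@njit(cache=True)
def euler_run_counts(agg, chrom_starts, wls, wrs, thr, out):
    """Accumulate excursion-run start counts for every scale pair and threshold.

    For scale pair ``p`` the break-recurrence track ``t_w(b)`` is evaluated at
    every admissible inter-probe boundary (full ``wl``/``wr`` windows within
    one chromosome) against that pair's own threshold grid ``thr[p]``.
    ``out`` has shape ``(n_pairs, T + 1)`` and is a difference array: after
    ``cumsum`` along axis 1, ``out[p, k]`` is the number of maximal runs of
    ``track >= thr[p, k]`` plus maximal runs of ``track <= -thr[p, k]`` —
    the Euler characteristic at that threshold — accumulated over the calls
    made with this ``out`` buffer.
    """
    P = agg.shape[0]
    cs = np.empty(P + 1)
    cs[0] = 0.0
    for i in range(P):
        cs[i + 1] = cs[i] + agg[i]
    T = thr.shape[1]
    for p in range(wls.shape[0]):
        wl = wls[p]
        wr = wrs[p]
        iwl = 1.0 / wl
        iwr = 1.0 / wr
        row = thr[p]
        t1 = row[1] if T > 1 else np.inf
        z0 = _bisect_right(row, 0.0)  # bins reached by a track value of exactly 0
        for c in range(chrom_starts.shape[0] - 1):
            lo = chrom_starts[c]
            hi = chrom_starts[c + 1]
            if hi - lo < wl + wr:
                continue
            prev_p = 0  # runs extend from "below every threshold" at chrom start
            prev_n = 0
            for b in range(lo + wl, hi - wr + 1):
                t = (cs[b + wr] - cs[b]) * iwr - (cs[b] - cs[b - wl]) * iwl
                if t > 0.0:
                    j = 1 if t < t1 else _bisect_right(row, t)
                    jn = 0
                elif t < 0.0:
                    j = 0
                    u = -t
                    jn = 1 if u < t1 else _bisect_right(row, u)
                else:
                    j = z0
                    jn = z0
                if j > prev_p:
                    out[p, prev_p] += 1.0
                    out[p, j] -= 1.0
                prev_p = j
                if jn > prev_n:
                    out[p, prev_n] += 1.0
                    out[p, jn] -= 1.0
                prev_n = jn


@njit(cache=True)
def euler_run_count_single(track, t0):
    """Euler characteristic of a single-chromosome track at one threshold."""
    n = 0
    in_p = False
    in_n = False
    for i in range(track.shape[0]):
        x = track[i]
        if x >= t0:
            if not in_p:
                n += 1
                in_p = True
        else:
            in_p = False
        if x <= -t0:
            if not in_n:
                n += 1
                in_n = True
        else:
            in_n = False
    return n


# ---------------------------------------------------------------------------
# significance evaluation (shared by table lookup and segmentation)


@njit(cache=True, inline="always")
def _pair_log_sig(row, t, thr, logc, pos_idx, fit_a, fit_b, fit_on):
    """log E[chi] at threshold ``t`` for one tabulated scale pair.

    Piecewise: interpolation of the (isotonic) log curve on the pair's own
    threshold grid up to the last strictly positive tabulated value, then the
    fitted Gaussian-style tail ``a - b t^2`` (clipped to remain below the last
    tabulated value, hence monotone).  Interpolation is linear in t^2, which
    reproduces a Gaussian-style decay exactly between grid nodes; linear-in-t
    chords on the concave log curve would systematically understate E[chi]
    between nodes and make calls anti-conservative.
    """
    pi = pos_idx[row]
    if pi < 0:
        return LOG_SIG_FLOOR
    trow = thr[row]
    tcut = trow[pi]
    if t <= tcut:
        if t <= trow[0]:
            return logc[row, 0]
        j = _bisect_right(trow, t) - 1
        if j >= pi:
            return logc[row, pi]
        t0 = trow[j]
        t1 = trow[j + 1]
        frac = (t * t - t0 * t0) / (t1 * t1 - t0 * t0)
        v = logc[row, j] + frac * (logc[row, j + 1] - logc[row, j])
    else:
        v = logc[row, pi]
        if fit_on:
            w = fit_a[row] - fit_b[row] * t * t
            if w < v:
                v = w
    if v < LOG_SIG_FLOOR:
        v = LOG_SIG_FLOOR
    return v


@njit(cache=True, inline="always")
def _scale_bracket(ls, x):
    """Bracket log-scale ``x`` on grid ``ls``: index i and weight u in [0, 1]."""
    k = ls.shape[0]
    if k == 1:
        return 0, 0.0
    if x <= ls[0]:
        return 0, 0.0
    if x >= ls[k - 1]:
        return k - 2, 1.0
    i = _bisect_right(ls, x) - 1
    if i > k - 2:
        i = k - 2
    u = (x - ls[i]) / (ls[i + 1] - ls[i])
    return i, u


@njit(cache=True, inline="always")
def _pair_row(i, j, k):
    if i > j:
        i, j = j, i
    return i * k - (i * (i - 1)) // 2 + (j - i)


@njit(cache=True)
def sig_eval(t, wl, wr, ls, thr, logc, pos_idx, fit_a, fit_b, fit_on):
    """Expected Euler characteristic at |t| for segment widths (wl, wr).

    Symmetric in (wl, wr); widths are clamped to the tabulated scale range and
    interpolated bilinearly in log-scale space on the log curve values.
    """
    if t < 0.0:
        t = -t
    if wl > wr:
        wl, wr = wr, wl
    k = ls.shape[0]
    x = np.log(float(wl))
    y = np.log(float(wr))
    i, u = _scale_bracket(ls, x)
    j, v = _scale_bracket(ls, y)
    if k == 1:
        return np.exp(_pair_log_sig(0, t, thr, logc, pos_idx, fit_a, fit_b, fit_on))
    val = 0.0
    if (1.0 - u) * (1.0 - v) > 0.0:
        val += (1.0 - u) * (1.0 - v) * _pair_log_sig(
            _pair_row(i, j, k), t, thr, logc, pos_idx, fit_a, fit_b, fit_on
        )
    if u * (1.0 - v) > 0.0:
        val += u * (1.0 - v) * _pair_log_sig(
            _pair_row(i + 1, j, k), t, thr, logc, pos_idx, fit_a, fit_b, fit_on
        )
    if (1.0 - u) * v > 0.0:
        val += (1.0 - u) * v * _pair_log_sig(
            _pair_row(i, j + 1, k), t, thr, logc, pos_idx, fit_a, fit_b, fit_on
        )
    if u * v > 0.0:
        val += u * v * _pair_log_sig(
            _pair_row(i + 1, j + 1, k), t, thr, logc, pos_idx, fit_a, fit_b, fit_on
        )
    return np.exp(val)


# ---------------------------------------------------------------------------
# agglomerative segmentation with a lazy-deletion binary heap


@njit(cache=True, inline="always")
def _heap_above(hkey, hpos, a, b):
    # max-heap on significance; ties broken towards the leftmost boundary
    if hkey[a] > hkey[b]:
        return True
    if hkey[a] == hkey[b] and hpos[a] < hpos[b]:
        return True
    return False


@njit(cache=True, inline="always")
def _heap_swap(hkey, hpos, hseg, hver, a, b):
    hkey[a], hkey[b] = hkey[b], hkey[a]
    hpos[a], hpos[b] = hpos[b], hpos[a]
    hseg[a], hseg[b] = hseg[b], hseg[a]
    hver[a], hver[b] = hver[b], hver[a]


@njit(cache=True, inline="always")
def _heap_push(hkey, hpos, hseg, hver, hn, key, pos, seg, ver):
    i = hn
    hkey[i] = key
    hpos[i] = pos
    hseg[i] = seg
    hver[i] = ver
    while i > 0:
        parent = (i - 1) // 2
        if _heap_above(hkey, hpos, i, parent):
            _heap_swap(hkey, hpos, hseg, hver, i, parent)
            i = parent
        else:
            break
    return hn + 1


@njit(cache=True, inline="always")
def _heap_pop(hkey, hpos, hseg, hver, hn):
    hn -= 1
    _heap_swap(hkey, hpos, hseg, hver, 0, hn)
    i = 0
    while True:
        l = 2 * i + 1
        r = l + 1
        best = i
        if l < hn and _heap_above(hkey, hpos, l, best):
            best = l
        if r < hn and _heap_above(hkey, hpos, r, best):
            best = r
        if best == i:
            break
        _heap_swap(hkey, hpos, hseg, hver, i, best)
        i = best
    return hn


@njit(cache=True)
def segment_kernel(agg, chrom_starts, E, ls, thr, logc, pos_idx, fit_a, fit_b, fit_on):
    """Greedy agglomerative segmentation of the aggregate profile.

    Starts from one segment per probe and repeatedly merges the adjacent pair
    whose boundary has the largest (least significant) expected Euler
    characteristic, rescoring only the two neighbouring boundaries after each
    merge, until every remaining boundary has significance <= ``E``.  Merges
    never cross chromosome boundaries.  Stale heap entries are skipped via
    per-boundary version stamps, keeping the run in P log P time.

    Returns (n_seg, seg_start, seg_width, seg_amp, n_bnd, bnd_pos, bnd_jump,
    bnd_sig); only the first ``n_seg``/``n_bnd`` entries of each buffer are
    valid.  Boundary position is the genome-order index of the first probe of
    the right-hand segment.
    """
    P = agg.shape[0]
    prv = np.empty(P, np.int64)
    nxt = np.empty(P, np.int64)
    width = np.ones(P, np.int64)
    ssum = agg.copy()
    alive = np.ones(P, np.bool_)
    ver = np.zeros(P, np.int64)

    cap = 3 * P + 8
    hkey = np.empty(cap)
    hpos = np.empty(cap, np.int64)
    hseg = np.empty(cap, np.int64)
    hver = np.empty(cap, np.int64)
    hn = 0

    nc = chrom_starts.shape[0] - 1
    for c in range(nc):
        lo = chrom_starts[c]
        hi = chrom_starts[c + 1]
        for i in range(lo, hi):
            prv[i] = i - 1 if i > lo else -1
            nxt[i] = i + 1 if i < hi - 1 else -1
        for s in range(lo, hi - 1):
            jump = agg[s + 1] - agg[s]
            sg = sig_eval(jump, 1, 1, ls, thr, logc, pos_idx, fit_a, fit_b, fit_on)
            hn = _heap_push(hkey, hpos, hseg, hver, hn, sg, s + 1, s, 0)

    while hn > 0:
        key = hkey[0]
        s = hseg[0]
        v = hver[0]
        hn = _heap_pop(hkey, hpos, hseg, hver, hn)
        if not alive[s] or v != ver[s]:
            continue
        b = nxt[s]
        if b == -1:
            continue
        if key <= E:
            break
        # merge right neighbour b into s
        ver[s] += 1
        ver[b] += 1
        ssum[s] += ssum[b]
        width[s] += width[b]
        c = nxt[b]
        nxt[s] = c
        if c != -1:
            prv[c] = s
        alive[b] = False
        p = prv[s]
        if p != -1:
            ver[p] += 1
            jump = ssum[s] / width[s] - ssum[p] / width[p]
            sg = sig_eval(jump, width[p], width[s], ls, thr, logc, pos_idx, fit_a, fit_b, fit_on)
            hn = _heap_push(hkey, hpos, hseg, hver, hn, sg, s, p, ver[p])
        if c != -1:
            jump = ssum[c] / width[c] - ssum[s] / width[s]
            sg = sig_eval(jump, width[s], width[c], ls, thr, logc, pos_idx, fit_a, fit_b, fit_on)
            hn = _heap_push(hkey, hpos, hseg, hver, hn, sg, c, s, ver[s])

    seg_start = np.empty(P, np.int64)
    seg_width = np.empty(P, np.int64)
    seg_amp = np.empty(P)
    bnd_pos = np.empty(P, np.int64)
    bnd_jump = np.empty(P)
    bnd_sig = np.empty(P)
    n_seg = 0
    n_bnd = 0
    for c in range(nc):
        s = chrom_starts[c]
        while s != -1:
            seg_start[n_seg] = s
            seg_width[n_seg] = width[s]
            seg_amp[n_seg] = ssum[s] / width[s]
            n = nxt[s]
            if n != -1:
                jump = ssum[n] / width[n] - ssum[s] / width[s]
                bnd_pos[n_bnd] = n
                bnd_jump[n_bnd] = jump
                bnd_sig[n_bnd] = sig_eval(
                    jump, width[s], width[n], ls, thr, logc, pos_idx, fit_a, fit_b, fit_on
                )
                n_bnd += 1
            n_seg += 1
            s = n
    return n_seg, seg_start, seg_width, seg_amp, n_bnd, bnd_pos, bnd_jump, bnd_sig
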