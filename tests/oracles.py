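"""Independent brute-force oracles used by the test suite.

Everything here is written for clarity, not speed: exhaustive loops, flood
fills and closed forms that are easy to verify by eye.  None of it shares
code with the package implementations it checks.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np

OFFSETS_26 = [d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]
DIRECTIONS_13 = [d for d in itertools.product((-1, 0, 1), repeat=3) if d > (0, 0, 0)]


def entropy_oracle(data, mask, coord, radius, n_bins):
    """Per-voxel neighborhood entropy by direct histogram counting over the
    in-mask voxels of the clipped cubic window."""
    z, y, x = coord
    vals = []
    for dz in range(-radius, radius + 1):
        for dy in range(-radius, radius + 1):
            for dx in range(-radius, radius + 1):
                zz, yy, xx = z + dz, y + dy, x + dx
                if 0 <= zz < data.shape[0] and 0 <= yy < data.shape[1] and 0 <= xx < data.shape[2]:
                    if mask[zz, yy, xx]:
                        vals.append(data[zz, yy, xx])
    counts = np.zeros(n_bins)
    for v in vals:
        b = min(int(v / 256.0 * n_bins), n_bins - 1)
        counts[b] += 1
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def glcm_oracle(levels):
    """Symmetric co-occurrence counts over the 13 directions at distance 1."""
    Ng = int(levels.max())
    C = np.zeros((Ng, Ng))
    shape = levels.shape
    for (z, y, x), v in np.ndenumerate(levels):
        if v == 0:
            continue
        for d in DIRECTIONS_13:
            zz, yy, xx = z + d[0], y + d[1], x + d[2]
            if 0 <= zz < shape[0] and 0 <= yy < shape[1] and 0 <= xx < shape[2]:
                w = levels[zz, yy, xx]
                if w > 0:
                    C[v - 1, w - 1] += 1
                    C[w - 1, v - 1] += 1
    return C


def glrlm_oracle(levels):
    """Run-length counts: walk every maximal run in each of the 13 directions."""
    Ng = int(levels.max())
    shape = levels.shape
    runs = []
    for d in DIRECTIONS_13:
        for (z, y, x), v in np.ndenumerate(levels):
            if v == 0:
                continue
            pz, py, px = z - d[0], y - d[1], x - d[2]
            if (0 <= pz < shape[0] and 0 <= py < shape[1] and 0 <= px < shape[2]
                    and levels[pz, py, px] == v):
                continue  # not a run start
            length = 1
            zz, yy, xx = z + d[0], y + d[1], x + d[2]
            while (0 <= zz < shape[0] and 0 <= yy < shape[1] and 0 <= xx < shape[2]
                   and levels[zz, yy, xx] == v):
                length += 1
                zz, yy, xx = zz + d[0], yy + d[1], xx + d[2]
            runs.append((v, length))
    max_len = max((l for _, l in runs), default=1)
    P = np.zeros((Ng, max_len))
    for v, l in runs:
        P[v - 1, l - 1] += 1
    return P


def glszm_oracle(levels):
    """Size-zone counts by BFS flood fill per gray level (26-connectivity)."""
    Ng = int(levels.max())
    shape = levels.shape
    zones = []
    for g in range(1, Ng + 1):
        todo = {tuple(c) for c in np.argwhere(levels == g)}
        while todo:
            stack = [todo.pop()]
            size = 0
            while stack:
                z, y, x = stack.pop()
                size += 1
                for d in OFFSETS_26:
                    nb = (z + d[0], y + d[1], x + d[2])
                    if nb in todo:
                        todo.remove(nb)
                        stack.append(nb)
            zones.append((g, size))
    max_size = max((s for _, s in zones), default=1)
    P = np.zeros((Ng, max_size))
    for g, s in zones:
        P[g - 1, s - 1] += 1
    return P


def gldm_oracle(levels, alpha=0):
    """Dependence counts: per voxel, 1 + number of 26-neighbours within alpha."""
    Ng = int(levels.max())
    shape = levels.shape
    deps = []
    for (z, y, x), v in np.ndenumerate(levels):
        if v == 0:
            continue
        dep = 0
        for d in OFFSETS_26:
            zz, yy, xx = z + d[0], y + d[1], x + d[2]
            if 0 <= zz < shape[0] and 0 <= yy < shape[1] and 0 <= xx < shape[2]:
                w = levels[zz, yy, xx]
                if w > 0 and abs(int(w) - int(v)) <= alpha:
                    dep += 1
        deps.append((v, dep + 1))
    max_dep = max((j for _, j in deps), default=1)
    D = np.zeros((Ng, max_dep))
    for v, j in deps:
        D[v - 1, j - 1] += 1
    return D


def ngtdm_oracle(levels):
    """(n_i, p_i, s_i) rows by direct neighbour averaging."""
    Ng = int(levels.max())
    shape = levels.shape
    n = np.zeros(Ng)
    s = np.zeros(Ng)
    for (z, y, x), v in np.ndenumerate(levels):
        if v == 0:
            continue
        nbrs = []
        for d in OFFSETS_26:
            zz, yy, xx = z + d[0], y + d[1], x + d[2]
            if 0 <= zz < shape[0] and 0 <= yy < shape[1] and 0 <= xx < shape[2]:
                w = levels[zz, yy, xx]
                if w > 0:
                    nbrs.append(int(w))
        if not nbrs:
            continue
        n[v - 1] += 1
        s[v - 1] += abs(v - np.mean(nbrs))
    p = n / n.sum() if n.sum() else n
    return np.column_stack([n, p, s])


def sahgle_oracle(P):
    """Direct double sum (1/Nz) ΣΣ P(i,j) i² / j²."""
    Nz = P.sum()
    total = 0.0
    for i in range(P.shape[0]):
        for j in range(P.shape[1]):
            total += P[i, j] * (i + 1) ** 2 / (j + 1) ** 2
    return total / Nz


def km_product_limit_oracle(times, events):
    """Kaplan–Meier by the closed-form product over distinct event times.

    Returns ``(event_times, survival)`` where survival[i] applies from
    event_times[i] onwards.
    """
    order = np.argsort(times)
    times = np.asarray(times, float)[order]
    events = np.asarray(events, bool)[order]
    s = 1.0
    out_t, out_s = [], []
    for t in sorted(set(times[events])):
        n_at_risk = int((times >= t).sum())
        d = int(((times == t) & events).sum())
        s *= (n_at_risk - d) / n_at_risk
        out_t.append(t)
        out_s.append(s)
    return np.array(out_t), np.array(out_s)


def youden_oracle(scores, labels):
    """Exhaustive cutoff search for max(sens + spec − 1), lowest on ties."""
    best = (-np.inf, None)
    y = np.asarray(labels).astype(bool)
    for c in sorted(set(scores)):
        pred = np.asarray(scores) >= c
        sens = (pred & y).sum() / y.sum()
        spec = (~pred & ~y).sum() / (~y).sum()
        j = sens + spec - 1
        if j > best[0] + 1e-12:
            best = (j, c)
    return best


def net_benefit_oracle(scores, labels, t):
    pred = np.asarray(scores) >= t
    y = np.asarray(labels).astype(bool)
    n = len(y)
    tp = (pred & y).sum()
    fp = (pred & ~y).sum()
    return tp / n - fp / n * t / (1 - t)
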