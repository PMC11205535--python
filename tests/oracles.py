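"""Independent naive reference implementations used only by the tests.

Everything here is written as explicit double loops straight from the
definitions, deliberately ignoring the vectorized implementations in the
package, so the two can be compared as independent routes to the same
quantity.
"""

import math

import numpy as np


def circ_dist(i, j, n):
    d = abs(i - j)
    return min(d, n - d)


def scn_reference(values, tol=1e-6, max_iter=200):
    """Step-by-step SCN loop on a fully unmasked matrix."""
    W = np.array(values, dtype=float)
    n = W.shape[0]
    for _ in range(max_iter):
        prev = W.copy()
        for i in range(n):
            norm = math.sqrt(sum(W[i, j] ** 2 for j in range(n)))
            if norm > 0:
                W[i, :] = W[i, :] / norm
        for j in range(n):
            norm = math.sqrt(sum(W[i, j] ** 2 for i in range(n)))
            if norm > 0:
                W[:, j] = W[:, j] / norm
        rel = 0.0
        for i in range(n):
            for j in range(n):
                denom = max(abs(prev[i, j]), 1e-300)
                rel = max(rel, abs(W[i, j] - prev[i, j]) / denom)
        if rel < tol:
            break
    return (W + W.T) / 2.0


def decay_reference(values, n):
    out = []
    for s in range(n // 2 + 1):
        vals = [values[i, (i + s) % n] for i in range(n)]
        out.append(sum(vals) / n)
    return np.array(out)


def short_range_frequency_reference(values, n, dmax):
    freq = np.zeros((n, dmax + 1))
    for i in range(n):
        freq[i, 0] = values[i, i]
        for d in range(1, dmax + 1):
            freq[i, d] = (values[i, (i + d) % n] + values[i, (i - d) % n]) / 2.0
    return freq


def short_range_proportion_reference(values, n, w):
    prop = np.full(n, np.nan)
    for i in range(n):
        total = sum(values[i, j] for j in range(n) if j != i)
        near = sum(
            values[i, j]
            for j in range(n)
            if j != i and circ_dist(i, j, n) <= w
        )
        if total > 0:
            prop[i] = near / total
    return prop


def di_reference(values, n, w):
    di = np.zeros(n)
    for i in range(n):
        A = sum(values[i, (i - d) % n] for d in range(1, w + 1))
        B = sum(values[i, (i + d) % n] for d in range(1, w + 1))
        E = (A + B) / 2.0
        if A == B or E == 0:
            di[i] = 0.0
        else:
            di[i] = math.copysign((A - E) ** 2 / E + (B - E) ** 2 / E, B - A)
    return di


def gc_reference(coords):
    """Direct evaluation of the global metric: circle reference with
    length-proportional angular spacing, radius matching the backbone
    contour, chord distances, summed over all ordered pairs."""
    n = len(coords)
    seg = []
    for k in range(n):
        seg.append(float(np.linalg.norm(coords[(k + 1) % n] - coords[k])))
    total = sum(seg)
    theta = [0.0]
    for k in range(n - 1):
        theta.append(theta[-1] + 2 * math.pi * seg[k] / total)
    perimeter_unit = sum(
        2 * math.sin(math.pi * seg[k] / total) for k in range(n)
    )
    radius = total / perimeter_unit
    D_sum = 0.0
    d_sum = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            D_sum += float(np.linalg.norm(coords[i] - coords[j]))
            d_sum += 2 * radius * abs(math.sin((theta[i] - theta[j]) / 2))
    return -math.log2(D_sum / d_sum)


def lc_reference(coords, t, circular=True):
    """Direct evaluation of the local metric with a straight-line
    reference carrying the backbone segment lengths of the window."""
    n = len(coords)
    seg = []
    m = n if circular else n - 1
    for k in range(m):
        seg.append(float(np.linalg.norm(coords[(k + 1) % n] - coords[k])))
    lc = np.zeros(n)
    for i in range(n):
        if circular:
            window = [(i + o) % n for o in range(-t, t + 1)]
        else:
            window = list(range(max(0, i - t), min(n - 1, i + t) + 1))
        pos = [0.0]
        for k in range(1, len(window)):
            pos.append(pos[-1] + seg[window[k - 1] % len(seg)])
        center = window.index(i)
        D_sum = 0.0
        d_sum = 0.0
        for k, j in enumerate(window):
            if j == i:
                continue
            D_sum += float(np.linalg.norm(coords[i] - coords[j]))
            d_sum += abs(pos[k] - pos[center])
        lc[i] = -math.log2(D_sum / d_sum)
    return lc


def macrodomain_means_reference(coords, bins_by_domain):
    means = {}
    names = list(bins_by_domain)
    for ai, a in enumerate(names):
        for b in names[ai:]:
            vals = []
            if a == b:
                bins = list(bins_by_domain[a])
                for x in range(len(bins)):
                    for y in range(x + 1, len(bins)):
                        vals.append(
                            float(np.linalg.norm(coords[bins[x]] - coords[bins[y]]))
                        )
            else:
                for x in bins_by_domain[a]:
                    for y in bins_by_domain[b]:
                        vals.append(float(np.linalg.norm(coords[x] - coords[y])))
            means[(a, b)] = sum(vals) / len(vals) if vals else float("nan")
    return means
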