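"""Independent reference implementations used only as test oracles.

Each function here deliberately takes the slow, obvious route (explicit
loops, full enumeration, textbook formulas) and shares no code with the
package implementations it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def sampen_bruteforce(x: np.ndarray, m: int = 2, r_factor: float = 0.2) -> float:
    """O(N^2) sample entropy by direct template-pair counting.

    B counts length-m template pairs (within Chebyshev distance
    r = r_factor * SD, self-matches excluded) among the N-m templates that
    admit an (m+1)-extension; A does the same at length m+1.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    sd = float(np.sqrt(np.mean((x - x.mean()) ** 2)))
    if sd == 0:
        return float("nan")
    r = r_factor * sd
    n_templates = n - m  # length-m templates with an extension
    b = 0
    a = 0
    for i in range(n_templates - 1):
        for j in range(i + 1, n_templates):
            d_m = max(abs(x[i + k] - x[j + k]) for k in range(m))
            if d_m <= r:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    if a == 0 or b == 0:
        return float("nan")
    return -math.log(a / b)


def sampen_bruteforce_rowwise(x: np.ndarray, m: int = 2, r_factor: float = 0.2) -> float:
    """O(N^2) sample entropy with the pairwise loop vectorised one row at a
    time; same definition as :func:`sampen_bruteforce`, fast enough for
    N ~ 3000."""
    x = np.asarray(x, dtype=float)
    n = x.size
    sd = float(np.sqrt(np.mean((x - x.mean()) ** 2)))
    if sd == 0:
        return float("nan")
    r = r_factor * sd
    n_templates = n - m
    emb_m = np.column_stack([x[k : k + n_templates] for k in range(m)])
    emb_m1 = np.column_stack([x[k : k + n_templates] for k in range(m + 1)])
    b = 0
    a = 0
    for i in range(n_templates - 1):
        d_m = np.max(np.abs(emb_m[i + 1 :] - emb_m[i]), axis=1)
        b += int(np.count_nonzero(d_m <= r))
        d_m1 = np.max(np.abs(emb_m1[i + 1 :] - emb_m1[i]), axis=1)
        a += int(np.count_nonzero(d_m1 <= r))
    if a == 0 or b == 0:
        return float("nan")
    return -math.log(a / b)


def average_ranks(values: np.ndarray) -> np.ndarray:
    """Average ranks computed by explicit sorting and tie-group walking."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values))
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1  # ranks are 1-based
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_rank_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho as Pearson correlation of average ranks, textbook sums."""
    rx = average_ranks(x)
    ry = average_ranks(y)
    n = len(rx)
    mx, my = rx.mean(), ry.mean()
    num = float(np.sum((rx - mx) * (ry - my)))
    den = math.sqrt(float(np.sum((rx - mx) ** 2)) * float(np.sum((ry - my) ** 2)))
    return num / den


def mannwhitney_exact_enumeration(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided rank-sum p-value by enumerating every group assignment.

    Uses the Mann-Whitney U statistic computed by direct pairwise
    comparison (ties count 1/2), a different route from rank sums.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    n_a = len(a)
    n = len(pooled)

    def u_stat(group_a: np.ndarray, group_b: np.ndarray) -> float:
        u = 0.0
        for va in group_a:
            for vb in group_b:
                if va > vb:
                    u += 1.0
                elif va == vb:
                    u += 0.5
        return u

    mu = n_a * (n - n_a) / 2.0
    dev_obs = abs(u_stat(a, b) - mu)
    count = 0
    total = 0
    for idx in itertools.combinations(range(n), n_a):
        mask = np.zeros(n, dtype=bool)
        mask[list(idx)] = True
        u = u_stat(pooled[mask], pooled[~mask])
        total += 1
        if abs(u - mu) >= dev_obs - 1e-9:
            count += 1
    return count / total


def median_frequency_line_spectrum(
    freqs: np.ndarray, powers: np.ndarray, band: tuple[float, float]
) -> float:
    """Median frequency of an analytic line spectrum restricted to a band.

    For discrete lines the cumulative distribution is a step function; the
    median is the frequency where cumulative power first reaches half the
    in-band total, with the midpoint convention when it lands exactly
    between two lines.
    """
    sel = (freqs >= band[0]) & (freqs <= band[1])
    f, p = np.asarray(freqs)[sel], np.asarray(powers)[sel]
    order = np.argsort(f)
    f, p = f[order], p[order]
    cum = np.cumsum(p)
    half = 0.5 * cum[-1]
    for i, c in enumerate(cum):
        if c > half + 1e-12:
            return float(f[i])
        if abs(c - half) <= 1e-12:
            # exactly half: median sits between line i and line i+1
            return float((f[i] + f[i + 1]) / 2) if i + 1 < len(f) else float(f[i])
    return float(f[-1])
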