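"""Independent brute-force oracles used by the tests.

Deliberately written as plain Python loops, independent of the package's
vectorized implementations: these re-evaluate the peak-detection and
stability predicates literally, offset by offset and run by run.
"""

from __future__ import annotations

import numpy as np


def brute_force_peaks(x, fs, s1=100, s2=20, merge_s=0.25):
    """Evaluate the sliding-window peak predicate at every offset, then merge."""
    x = np.asarray(x, dtype=float)
    candidates = []
    for o in range(len(x) - s1 + 1):
        S1 = x[o:o + s1]
        m = S1.mean()
        S2 = S1[s1 - s2:]
        if S2[0] < m and S2[-1] < m and S2.max() > m:
            candidates.append(o + s1 - s2 + int(np.argmax(S2)))
    clusters: list[list[int]] = []
    for a in sorted(set(candidates)):
        if clusters and a - clusters[-1][-1] <= merge_s * fs:
            clusters[-1].append(a)
        else:
            clusters.append([a])
    peaks = []
    for cl in clusters:
        best = cl[0]
        for a in cl[1:]:
            if x[a] > x[best]:
                best = a
        peaks.append(best)
    return np.asarray(peaks, dtype=np.int64)


def brute_force_stable_mask(peak_indices, n, fs, run_peaks=6):
    """Re-check every 6-peak run against the three stability criteria."""
    idx = list(peak_indices)
    mask = np.zeros(n, dtype=bool)
    for i in range(len(idx) - run_peaks + 1):
        run = idx[i:i + run_peaks]
        iv = [(b - a) / fs for a, b in zip(run[:-1], run[1:])]
        iave = sum(iv) / len(iv)
        d = (sum((v - iave) ** 2 for v in iv) / len(iv)) ** 0.5
        ok = (0.6 <= iave <= 1.2) and (d < 0.2) and all(
            0.9 * iave <= v <= 1.1 * iave for v in iv
        )
        if ok:
            mask[run[0]:run[-1]] = True
    return mask


def pearson_by_hand(x, y):
    """Textbook product-moment formula from raw sums."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    num = n * sxy - sx * sy
    den = ((n * sxx - sx * sx) * (n * syy - sy * sy)) ** 0.5
    return num / den


def best_subset(X, y, k):
    """Exhaustive best subset of size k by least-squares residual."""
    import itertools

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    best_cols, best_rss = None, np.inf
    for cols in itertools.combinations(range(X.shape[1]), k):
        A = np.column_stack([np.ones(len(X)), X[:, cols]])
        _, res, rank, _ = np.linalg.lstsq(A, y, rcond=None)
        fitted = A @ np.linalg.lstsq(A, y, rcond=None)[0]
        rss = float(np.sum((y - fitted) ** 2))
        if rss < best_rss - 1e-12:
            best_rss, best_cols = rss, cols
    return best_cols
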