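"""Independent brute-force oracles used to pin expected values.

Deliberately naive re-implementations (pure-Python loops, scalar
arithmetic) kept separate from the library code paths they check.
"""

from __future__ import annotations

import numpy as np


def quartiles_type7(values):
    """Scalar linear-interpolation quartiles (no numpy.quantile)."""
    s = sorted(float(v) for v in values)
    n = len(s)

    def q(p):
        h = (n - 1) * p
        f = int(h)
        c = min(f + 1, n - 1)
        return s[f] + (s[c] - s[f]) * (h - f)

    return q(0.25), q(0.75)


def naive_iterative_cutoff(values, fence_multiplier=1.5, increment_fraction=0.025):
    """One-by-one re-run of the iterative Tukey-fence loop."""
    retained = [float(v) for v in values]
    trace = []
    while True:
        q1, q3 = quartiles_type7(retained)
        iqr = q3 - q1
        lower = q1 - fence_multiplier * iqr
        upper = q3 + fence_multiplier * iqr
        keep = [v for v in retained if lower <= v <= upper]
        trace.append((len(retained), q1, q3, lower, upper, len(retained) - len(keep)))
        if len(keep) == len(retained):
            break
        retained = keep
    return retained, (1.0 + increment_fraction) * max(retained), trace


def youden_scan(cl_values, labels):
    """Exhaustive Youden scan over midpoint candidates (classification cl >= t)."""
    cl = [float(v) for v in cl_values]
    lab = [bool(b) for b in labels]
    uniq = sorted(set(cl))
    cands = [uniq[0] - 1.0] + [(a + b) / 2.0 for a, b in zip(uniq, uniq[1:])]
    best_t, best_j = None, -np.inf
    n_pos = sum(lab)
    n_neg = len(lab) - n_pos
    for t in cands:
        tp = sum(1 for v, b in zip(cl, lab) if b and v >= t)
        tn = sum(1 for v, b in zip(cl, lab) if not b and v < t)
        j = tp / n_pos + tn / n_neg - 1.0
        if j > best_j:
            best_t, best_j = t, j
    return best_t, best_j


def voxelwise_voi_means(intensity, labels):
    """Per-label mean/count via an explicit voxel loop."""
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    flat_i = np.asarray(intensity, dtype=float).ravel()
    flat_l = np.asarray(labels).ravel()
    for v, lab in zip(flat_i, flat_l):
        lab = int(lab)
        sums[lab] = sums.get(lab, 0.0) + float(v)
        counts[lab] = counts.get(lab, 0) + 1
    return {lab: (sums[lab] / counts[lab], counts[lab]) for lab in sums}


def ols_f_test(y, X_full, X_reduced):
    """Group-factor F statistic from explicit normal-equations solves."""
    y = np.asarray(y, dtype=float)

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        return float(resid @ resid)

    rss_full = rss(X_full)
    rss_red = rss(X_reduced)
    df_num = X_full.shape[1] - X_reduced.shape[1]
    df_den = len(y) - X_full.shape[1]
    return ((rss_red - rss_full) / df_num) / (rss_full / df_den)
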