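"""Independent brute-force oracles used by the tests.

These deliberately use plain Python loops and explicit sums of squares so
they share no code path with the implementation they check.
"""

import math

import numpy as np


def loop_extract(suv, labels, voxel_size_mm):
    """Per-voxel loop feature extraction: {label: (max, mean, total, volume_cc)}."""
    voxel_cc = voxel_size_mm[0] * voxel_size_mm[1] * voxel_size_mm[2] / 1000.0
    out = {}
    for lid in sorted(set(int(v) for v in labels.ravel()) - {0}):
        mx = -math.inf
        s = 0.0
        ct = 0
        for idx in np.ndindex(labels.shape):
            if labels[idx] == lid:
                v = float(suv[idx])
                mx = max(mx, v)
                s += v
                ct += 1
        out[lid] = (mx, s / ct, s * voxel_cc, ct * voxel_cc)
    return out


def loop_centroid(labels, voxel_size_mm):
    """Per-voxel loop centroid (voxel-center convention): {label: xyz mm}."""
    out = {}
    for lid in sorted(set(int(v) for v in labels.ravel()) - {0}):
        acc = np.zeros(3)
        ct = 0
        for idx in np.ndindex(labels.shape):
            if labels[idx] == lid:
                acc += (np.array(idx) + 0.5) * np.asarray(voxel_size_mm)
                ct += 1
        out[lid] = acc / ct
    return out


def loop_variance_components(groups, r):
    """Explicit sums-of-squares one-way decomposition; returns
    (d_bar, ms_between, ms_within, m0, var_between, sigma)."""
    r = [float(v) for v in r]
    N = len(r)
    d_bar = sum(r) / N
    by = {}
    for g, v in zip(groups, r):
        by.setdefault(g, []).append(v)
    n = len(by)
    if n == 1:
        mean = d_bar
        var = sum((v - mean) ** 2 for v in r) / (N - 1)
        return d_bar, 0.0, var, 1.0, 0.0, math.sqrt(var)
    ssb = 0.0
    ssw = 0.0
    sum_m2 = 0
    for vals in by.values():
        m = len(vals)
        gm = sum(vals) / m
        ssb += m * (gm - d_bar) ** 2
        ssw += sum((v - gm) ** 2 for v in vals)
        sum_m2 += m * m
    ms_between = ssb / (n - 1)
    ms_within = 0.0 if N == n else ssw / (N - n)
    m0 = (N - sum_m2 / N) / (n - 1)
    var_between = max(0.0, (ms_between - ms_within) / m0)
    return d_bar, ms_between, ms_within, m0, var_between, math.sqrt(var_between + ms_within)


def loop_icc_two_way(a, b):
    """ICC(A,1) from explicit two-way sums of squares (subjects x 2 scans)."""
    n = len(a)
    k = 2
    x = [[float(a[i]), float(b[i])] for i in range(n)]
    grand = sum(sum(row) for row in x) / (n * k)
    row_means = [sum(row) / k for row in x]
    col_means = [sum(x[i][j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((m - grand) ** 2 for m in row_means)
    ss_cols = n * sum((m - grand) ** 2 for m in col_means)
    ss_total = sum((x[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    return (ms_r - ms_e) / (ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e))


def loop_icc_one_way(a, b):
    """ICC(1,1) from explicit one-way sums of squares."""
    n = len(a)
    k = 2
    x = [[float(a[i]), float(b[i])] for i in range(n)]
    grand = sum(sum(row) for row in x) / (n * k)
    row_means = [sum(row) / k for row in x]
    ss_rows = k * sum((m - grand) ** 2 for m in row_means)
    ss_within = sum((x[i][j] - row_means[i]) ** 2 for i in range(n) for j in range(k))
    ms_r = ss_rows / (n - 1)
    ms_w = ss_within / (n * (k - 1))
    return (ms_r - ms_w) / (ms_r + (k - 1) * ms_w)
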