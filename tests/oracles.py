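"""Independent brute-force oracles used by the test suite.

Each function re-derives a quantity by the most literal route available
(explicit loops, design matrices, closed forms) and is kept free of any
code path from the package implementation it checks.
"""

import numpy as np


def naive_region_stats(temps, labels, region_labels, lo, hi, bin_width):
    """Pixel-loop mean and Shannon entropy over a region, fixed histogram."""
    vals = []
    for r in range(temps.shape[0]):
        for c in range(temps.shape[1]):
            if labels[r, c] in region_labels:
                vals.append(temps[r, c])
    if not vals:
        return float("nan"), float("nan"), 0
    n_inner = int(round((hi - lo) / bin_width))
    counts = {}
    for v in vals:
        if v < lo:
            b = -1
        elif v >= hi:
            b = n_inner
        else:
            b = int((v - lo) / bin_width)
            b = min(b, n_inner - 1)
        counts[b] = counts.get(b, 0) + 1
    h = 0.0
    for cnt in counts.values():
        p = cnt / len(vals)
        h -= p * np.log2(p)
    return sum(vals) / len(vals), h, len(vals)


def icc_anova_loops(m, form):
    """Two-way single-measure ICC via explicit sum-of-squares loops."""
    m = np.asarray(m, dtype=float)
    n, k = m.shape
    grand = 0.0
    for i in range(n):
        for j in range(k):
            grand += m[i, j]
    grand /= n * k
    row_means = [sum(m[i, j] for j in range(k)) / k for i in range(n)]
    col_means = [sum(m[i, j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((rm - grand) ** 2 for rm in row_means)
    ss_cols = n * sum((cm - grand) ** 2 for cm in col_means)
    ss_tot = sum((m[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if form == "consistency":
        return (msr - mse) / (msr + (k - 1) * mse)
    return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))


def rmcorr_design_matrix(subjects, x, y):
    """r_rm via explicit dummy-coded ANCOVA least squares."""
    subjects = np.asarray(subjects)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    uniq = np.unique(subjects)
    dummies = np.column_stack([(subjects == s).astype(float) for s in uniq])
    x_full = np.column_stack([dummies, x])
    beta_full, *_ = np.linalg.lstsq(x_full, y, rcond=None)
    ss_full = float(((y - x_full @ beta_full) ** 2).sum())
    beta_red, *_ = np.linalg.lstsq(dummies, y, rcond=None)
    ss_red = float(((y - dummies @ beta_red) ** 2).sum())
    ss_effect = ss_red - ss_full
    slope = beta_full[-1]
    return float(np.sign(slope) * np.sqrt(max(ss_effect, 0.0) / (ss_effect + ss_full)))


def window_argmax_selection(areas, wlen):
    """Per-window argmax frame indices (no occlusion filtering)."""
    out = []
    for w in range(len(areas) // wlen):
        chunk = areas[w * wlen:(w + 1) * wlen]
        best, best_i = -np.inf, 0
        for i, a in enumerate(chunk):
            if a > best:
                best, best_i = a, i
        out.append(w * wlen + best_i)
    return np.array(out)


def naive_rolling_median(series, window):
    """Centred rolling median with truncated edge windows."""
    n = len(series)
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        out[i] = np.median(series[lo:hi])
    return out


def two_point_interp(tq, t, v):
    """Piecewise-linear interpolation, endpoints held."""
    out = np.empty(len(tq))
    for i, q in enumerate(tq):
        if q <= t[0]:
            out[i] = v[0]
        elif q >= t[-1]:
            out[i] = v[-1]
        else:
            j = int(np.searchsorted(t, q, side="right")) - 1
            frac = (q - t[j]) / (t[j + 1] - t[j])
            out[i] = v[j] + frac * (v[j + 1] - v[j])
    return out
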