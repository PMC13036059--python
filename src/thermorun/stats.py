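"""Reliability and correlation statistics, written from first principles.

Pearson/Spearman correlation with Cohen magnitude bands, repeated-measures
correlation (common within-subject slope after removing per-subject
intercepts, ANCOVA parameterisation) with a subject-level percentile
bootstrap CI, and two-way single-measure intraclass correlations:
consistency ICC(3,1) and absolute agreement ICC(2,1), from the two-way
ANOVA mean squares, with F-based confidence intervals and Koo-Li
reliability bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CorrResult",
    "RmcorrResult",
    "ICCResult",
    "correlate",
    "rmcorr",
    "icc",
    "median_split",
    "section_icc_report",
    "holm_bonferroni",
]


def holm_bonferroni(p_values: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values (optional; panels are reported
    uncorrected by default)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def _cohen_label(r: float) -> str:
    a = abs(r)
    if a < 0.1:
        return "trivial"
    if a < 0.3:
        return "small"
    if a < 0.5:
        return "moderate"
    return "large"


def _koo_li_label(value: float) -> str:
    # 0.5 and 0.75 fall in the closed "between" bands; > 0.9 is excellent
    if value < 0.5:
        return "poor"
    if value <= 0.75:
        return "moderate"
    if value <= 0.9:
        return "good"
    return "excellent"


@dataclass(frozen=True)
class CorrResult:
    r: float
    n: int
    p_value: float
    method: str
    magnitude_label: str

    def summary(self) -> str:
        return (f"{self.method} r = {self.r:+.3f} ({self.magnitude_label}), "
                f"n = {self.n}, p = {self.p_value:.3g}")


@dataclass(frozen=True)
class RmcorrResult:
    r_rm: float
    df: int
    p_value: float
    ci_low: float
    ci_high: float
    n_subjects: int
    n_obs: int

    def summary(self) -> str:
        return (f"r_rm = {self.r_rm:+.3f}, df = {self.df}, p = {self.p_value:.3g}, "
                f"95% CI [{self.ci_low:+.3f}, {self.ci_high:+.3f}]")


@dataclass(frozen=True)
class ICCResult:
    icc: float
    form: str           # "ICC(2,1)" (agreement) or "ICC(3,1)" (consistency)
    ci_low: float
    ci_high: float
    n_rows: int
    k_cols: int
    p_value: float
    reliability_label: str

    def summary(self) -> str:
        return (f"{self.form} = {self.icc:.3f} ({self.reliability_label}), "
                f"95% CI [{self.ci_low:.3f}, {self.ci_high:.3f}], "
                f"n = {self.n_rows}, k = {self.k_cols}")


def correlate(x: np.ndarray, y: np.ndarray, method: str = "pearson") -> CorrResult:
    """Product-moment or rank correlation with a two-sided t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 finite paired observations")
    if method == "spearman":
        x = sps.rankdata(x)   # average ranks for ties
        y = sps.rankdata(y)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc ** 2).sum())
    sy = np.sqrt((yc ** 2).sum())
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in x or y")
    r = float((xc * yc).sum() / (sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return CorrResult(r=r, n=n, p_value=p, method=method, magnitude_label=_cohen_label(r))


def _rmcorr_point(subjects: np.ndarray, x: np.ndarray, y: np.ndarray):
    """(r_rm, df, F) for the common-slope ANCOVA; None when degenerate."""
    xt = np.empty_like(x)
    yt = np.empty_like(y)
    n_sub = 0
    n_obs = 0
    for s in np.unique(subjects):
        sel = subjects == s
        if sel.sum() < 2:
            continue
        xt[n_obs:n_obs + sel.sum()] = x[sel] - x[sel].mean()
        yt[n_obs:n_obs + sel.sum()] = y[sel] - y[sel].mean()
        n_obs += int(sel.sum())
        n_sub += 1
    if n_sub < 2:
        return None
    xt, yt = xt[:n_obs], yt[:n_obs]
    ssx = (xt ** 2).sum()
    if ssx <= 0:
        return None
    slope = (xt * yt).sum() / ssx
    ss_effect = slope ** 2 * ssx
    ss_error = ((yt - slope * xt) ** 2).sum()
    df = n_obs - n_sub - 1
    if df <= 0 or ss_effect + ss_error <= 0:
        return None
    r_rm = np.sign(slope) * np.sqrt(ss_effect / (ss_effect + ss_error))
    f = ss_effect / (ss_error / df) if ss_error > 0 else np.inf
    return float(r_rm), int(df), float(f), n_sub, n_obs


def rmcorr(subjects: np.ndarray, x: np.ndarray, y: np.ndarray,
           n_boot: int = 2000, seed: int = 0) -> RmcorrResult:
    """Repeated-measures correlation with subject-cluster bootstrap CI.

    Fits a common slope with per-subject intercepts by least squares;
    r_rm = sign(slope) * sqrt(SS_x / (SS_x + SS_err)) on the within-subject
    centred data, df = N - n_subjects - 1, p from the F statistic.  The 95%
    CI resamples subjects with replacement (percentile interval),
    deterministic given the seed.
    """
    subjects = np.asarray(subjects)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    subjects, x, y = subjects[ok], x[ok], y[ok]
    point = _rmcorr_point(subjects, x, y)
    if point is None:
        raise ValueError("rmcorr degenerate: need >= 2 subjects with >= 2 "
                         "observations and within-subject x variance")
    r_rm, df, f, n_sub, n_obs = point
    p = float(sps.f.sf(f, 1, df))

    rng = np.random.default_rng(seed)
    uniq = np.unique(subjects)
    idx_by_sub = {s: np.flatnonzero(subjects == s) for s in uniq}
    boots = []
    for _ in range(n_boot):
        chosen = rng.choice(uniq, size=uniq.size, replace=True)
        idx = np.concatenate([idx_by_sub[s] for s in chosen])
        # resampled copies of one subject are distinct clusters
        sub_ids = np.concatenate([np.full(idx_by_sub[s].size, i)
                                  for i, s in enumerate(chosen)])
        res = _rmcorr_point(sub_ids, x[idx], y[idx])
        if res is not None:
            boots.append(res[0])
    if boots:
        ci_low, ci_high = np.percentile(boots, [2.5, 97.5])
    else:
        ci_low = ci_high = float("nan")
    return RmcorrResult(r_rm=r_rm, df=df, p_value=p, ci_low=float(ci_low),
                        ci_high=float(ci_high), n_subjects=n_sub, n_obs=n_obs)


def _anova_mean_squares(m: np.ndarray):
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((m - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc(matrix: np.ndarray, form: str = "consistency", alpha: float = 0.05) -> ICCResult:
    """Two-way single-measure intraclass correlation.

    ``matrix`` is rows (targets/timepoints) x columns (raters/sessions);
    rows containing missing cells are dropped listwise.  ``form`` is
    ``consistency`` (ICC(3,1)) or ``agreement`` (ICC(2,1)); confidence
    intervals follow the standard F-based constructions.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("matrix must be 2-D (rows x sessions)")
    m = m[np.isfinite(m).all(axis=1)]
    n, k = m.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 complete rows and 2 columns")
    msr, msc, mse = _anova_mean_squares(m)
    if msr <= 0 and mse <= 0:
        raise ValueError("zero total variance")

    df1, df2 = n - 1, (n - 1) * (k - 1)
    f_rows = msr / mse if mse > 0 else np.inf
    p = float(sps.f.sf(f_rows, df1, df2))

    if form == "consistency":
        value = (msr - mse) / (msr + (k - 1) * mse)
        fl = f_rows / sps.f.ppf(1 - alpha / 2, df1, df2)
        fu = f_rows * sps.f.ppf(1 - alpha / 2, df2, df1)
        lo = (fl - 1) / (fl + k - 1)
        hi = (fu - 1) / (fu + k - 1)
        label_form = "ICC(3,1)"
    elif form == "agreement":
        value = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
        a = (k * value) / (n * (1 - value)) if value < 1 else np.inf
        b = 1 + (k * value * (n - 1)) / (n * (1 - value)) if value < 1 else np.inf
        if np.isfinite(a) and np.isfinite(b) and (a * msc + b * mse) > 0:
            v = (a * msc + b * mse) ** 2 / (
                (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1)))
            f_star = sps.f.ppf(1 - alpha / 2, n - 1, v)
            f_star2 = sps.f.ppf(1 - alpha / 2, v, n - 1)
            lo = n * (msr - f_star * mse) / (
                f_star * (k * msc + (k * n - k - n) * mse) + n * msr)
            hi = n * (f_star2 * msr - mse) / (
                k * msc + (k * n - k - n) * mse + n * f_star2 * msr)
        else:
            lo = hi = 1.0
        label_form = "ICC(2,1)"
    else:
        raise ValueError(f"unknown ICC form {form!r}")
    return ICCResult(icc=float(value), form=label_form, ci_low=float(lo),
                     ci_high=float(hi), n_rows=n, k_cols=k, p_value=p,
                     reliability_label=_koo_li_label(float(value)))


def median_split(values: dict[str, float] | pd.Series) -> tuple[list[str], list[str]]:
    """Split ids at the median of an attribute; with odd n the median id
    joins the lower group; ties broken by id."""
    if isinstance(values, pd.Series):
        items = list(values.items())
    else:
        items = list(values.items())
    items.sort(key=lambda kv: (kv[1], kv[0]))
    n_low = (len(items) + 1) // 2
    low = [k for k, _ in items[:n_low]]
    high = [k for k, _ in items[n_low:]]
    return low, high


def section_icc_report(section_matrices: dict[str, dict[str, np.ndarray]],
                       forms: tuple[str, ...] = ("consistency", "agreement"),
                       ) -> pd.DataFrame:
    """Per-participant, per-section ICC table plus pooled estimates.

    ``section_matrices[participant][section]`` is an aligned (n_time x
    k_sessions) matrix.  Pooled rows (participant = "POOLED") stack the
    per-participant matrices.  Missing sections are flagged, not fatal.
    """
    rows = []
    sections = sorted({s for d in section_matrices.values() for s in d})
    for section in sections:
        stacks = []
        for pid, d in section_matrices.items():
            mat = d.get(section)
            for form in forms:
                if mat is None or np.asarray(mat).size == 0:
                    rows.append({"participant": pid, "section": section, "form": form,
                                 "icc": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                                 "label": "missing", "n_rows": 0, "k_cols": 0,
                                 "valid": False})
                    continue
                try:
                    res = icc(mat, form=form)
                    rows.append({"participant": pid, "section": section, "form": res.form,
                                 "icc": res.icc, "ci_low": res.ci_low,
                                 "ci_high": res.ci_high, "label": res.reliability_label,
                                 "n_rows": res.n_rows, "k_cols": res.k_cols,
                                 "valid": True})
                except ValueError:
                    rows.append({"participant": pid, "section": section, "form": form,
                                 "icc": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                                 "label": "degenerate", "n_rows": 0, "k_cols": 0,
                                 "valid": False})
            if mat is not None and np.asarray(mat).size:
                stacks.append(np.asarray(mat, dtype=float))
        if stacks:
            # pool participants sharing the section's dominant session count
            ks = [s.shape[1] for s in stacks]
            k_mode = max(set(ks), key=ks.count)
            pooled = np.vstack([s for s in stacks if s.shape[1] == k_mode])
            for form in forms:
                res = icc(pooled, form=form)
                rows.append({"participant": "POOLED", "section": section, "form": res.form,
                             "icc": res.icc, "ci_low": res.ci_low, "ci_high": res.ci_high,
                             "label": res.reliability_label, "n_rows": res.n_rows,
                             "k_cols": res.k_cols, "valid": True})
    return pd.DataFrame(rows)
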