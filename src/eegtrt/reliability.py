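"""Test-retest reliability and stability statistics.

Reliability follows a generalizability-theory Persons x Occasion design:
persons are the objects of measurement and test occasion the single facet.
For the balanced complete two-way layout (one observation per cell) the
variance components have the closed form

    sigma2_po_e = MS_res
    sigma2_p    = (MS_P - MS_res) / n_o
    sigma2_o    = (MS_O - MS_res) / n_p

(identical to REML at the optimum for this design; negatives truncated to
zero), and the G-coefficient is

    G = sigma2_p / (sigma2_p + sigma2_po_e / n_o)

which for n_o = 1 equals ICC(3,1) of Shrout & Fleiss. Categories: poor
(G < 0.4), fair (0.4 <= G < 0.6), good (0.6 <= G < 0.75), excellent
(0.75 <= G <= 1.0). Mean stability over occasions is tested with a paired
t-test; changes over task runs with a Session x Run repeated-measures ANOVA,
Greenhouse-Geisser adjusted, with orthonormal polynomial trend contrasts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VarianceComponents",
    "GResult",
    "PairedTestResult",
    "TrendResult",
    "AnovaEffect",
    "AnovaResult",
    "variance_components",
    "g_coefficient",
    "g_category",
    "icc31",
    "paired_t",
    "rm_anova_session_run",
    "polynomial_contrasts",
    "reliability_report",
]


@dataclass(frozen=True)
class VarianceComponents:
    sigma2_p: float  # persons
    sigma2_o: float  # occasion
    sigma2_po_e: float  # persons x occasion + error
    n_persons: int
    n_occasions: int
    raw_sigma2_p: float = None  # untruncated estimates
    raw_sigma2_o: float = None


@dataclass(frozen=True)
class GResult:
    g: float
    n_o: int
    category: str


@dataclass(frozen=True)
class PairedTestResult:
    t: float
    df: int
    p: float
    mean_difference: float
    n: int
    degenerate: bool = False  # zero-variance differences with nonzero mean


@dataclass(frozen=True)
class TrendResult:
    name: str
    F: float
    df: tuple[int, int]
    p: float


@dataclass(frozen=True)
class AnovaEffect:
    name: str
    F: float
    df: tuple[int, int]
    epsilon: float
    p_gg: float
    p_uncorrected: float


@dataclass(frozen=True)
class AnovaResult:
    effects: dict
    trends: dict
    n_persons: int
    n_dropped: int = 0


def _pivot(table) -> np.ndarray:
    """Accept a persons x occasions array or a long measure table; return the
    complete-case persons x occasions matrix."""
    if isinstance(table, pd.DataFrame):
        wide = table.pivot_table(index="subject_id", columns="occasion",
                                 values="value", aggfunc="first")
        wide = wide.dropna(axis=0)
        return wide.to_numpy(float)
    return np.asarray(table, float)


def variance_components(table) -> VarianceComponents:
    """Closed-form two-way random-effects variance components (balanced)."""
    y = _pivot(table)
    n_p, n_o = y.shape
    if n_p < 2 or n_o < 2:
        raise ValueError("need >= 2 persons and >= 2 occasions")
    gm = y.mean()
    pm = y.mean(axis=1)
    om = y.mean(axis=0)
    ss_p = n_o * np.sum((pm - gm) ** 2)
    ss_o = n_p * np.sum((om - gm) ** 2)
    resid = y - pm[:, None] - om[None, :] + gm
    ss_res = np.sum(resid ** 2)
    ms_p = ss_p / (n_p - 1)
    ms_o = ss_o / (n_o - 1)
    ms_res = ss_res / ((n_p - 1) * (n_o - 1))
    raw_p = (ms_p - ms_res) / n_o
    raw_o = (ms_o - ms_res) / n_p
    return VarianceComponents(
        sigma2_p=max(raw_p, 0.0), sigma2_o=max(raw_o, 0.0),
        sigma2_po_e=ms_res, n_persons=n_p, n_occasions=n_o,
        raw_sigma2_p=raw_p, raw_sigma2_o=raw_o)


def g_category(g: float) -> str:
    if g < 0.4:
        return "poor"
    if g < 0.6:
        return "fair"
    if g < 0.75:
        return "good"
    return "excellent"


def g_coefficient(vc: VarianceComponents, n_o: int = 1) -> GResult:
    """G = sigma2_p / (sigma2_p + sigma2_po_e / n_o); 0/0 defined as 0."""
    if n_o < 1:
        raise ValueError("n_o must be >= 1")
    denom = vc.sigma2_p + vc.sigma2_po_e / n_o
    g = 0.0 if denom == 0 else vc.sigma2_p / denom
    return GResult(g=g, n_o=n_o, category=g_category(g))


def icc31(table) -> float:
    """ICC(3,1) from the two-way mixed ANOVA mean squares.

    Serves as an independent check of the G-coefficient at n_o = 1: the two
    are algebraically identical on balanced tables (before truncation).
    """
    y = _pivot(table)
    n_p, n_o = y.shape
    if n_p < 2 or n_o < 2:
        raise ValueError("need >= 2 persons and >= 2 occasions")
    gm = y.mean()
    pm = y.mean(axis=1)
    om = y.mean(axis=0)
    ms_p = n_o * np.sum((pm - gm) ** 2) / (n_p - 1)
    resid = y - pm[:, None] - om[None, :] + gm
    ms_res = np.sum(resid ** 2) / ((n_p - 1) * (n_o - 1))
    denom = ms_p + (n_o - 1) * ms_res
    return 0.0 if denom == 0 else (ms_p - ms_res) / denom


def paired_t(table) -> PairedTestResult:
    """Two-tailed paired t-test of occasion 2 minus occasion 1."""
    y = _pivot(table)
    if y.shape[1] != 2:
        raise ValueError("paired t-test needs exactly 2 occasions")
    d = y[:, 1] - y[:, 0]
    n = len(d)
    if n < 2:
        raise ValueError("need >= 2 complete pairs")
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0:
        if md == 0:
            return PairedTestResult(0.0, n - 1, 1.0, 0.0, n)
        return PairedTestResult(math.inf if md > 0 else -math.inf, n - 1, 0.0,
                                md, n, degenerate=True)
    t = md / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return PairedTestResult(float(t), n - 1, float(p), md, n)


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA with Greenhouse-Geisser correction
# ---------------------------------------------------------------------------

def polynomial_contrasts(k: int, degree: int | None = None) -> np.ndarray:
    """Orthonormal polynomial contrast matrix (k levels x degree columns)."""
    if k < 2:
        raise ValueError("need >= 2 levels")
    degree = k - 1 if degree is None else degree
    x = np.arange(1, k + 1, dtype=float)
    V = np.vander(x - x.mean(), degree + 1, increasing=True)
    Q, _ = np.linalg.qr(V)
    C = Q[:, 1:degree + 1]
    # fix sign: increasing linear trend has positive contrast value
    for j in range(C.shape[1]):
        if C[-1, j] < 0:
            C[:, j] *= -1.0
    return C


def _within_effect(Z: np.ndarray) -> tuple[float, tuple[int, int], float, float]:
    """Univariate repeated-measures F for contrast scores Z (n x q) plus the
    Greenhouse-Geisser epsilon from their sample covariance."""
    n, q = Z.shape
    zbar = Z.mean(axis=0)
    ss_eff = n * np.sum(zbar ** 2)
    ss_err = np.sum((Z - zbar) ** 2)
    df1, df2 = q, q * (n - 1)
    ms_err = ss_err / df2
    F = (ss_eff / df1) / ms_err if ms_err > 0 else math.inf
    if q == 1:
        eps = 1.0
    else:
        S = np.cov(Z, rowvar=False)
        tr = np.trace(S)
        tr2 = np.trace(S @ S)
        eps = (tr ** 2) / (q * tr2) if tr2 > 0 else 1.0
        eps = min(max(eps, 1.0 / q), 1.0)
    return F, (df1, df2), eps, ss_eff


def _contrast_trend(z: np.ndarray, name: str) -> TrendResult:
    """One-df within-subject contrast F test from per-person scores z (n,)."""
    n = len(z)
    var = z.var(ddof=1)
    F = n * z.mean() ** 2 / var if var > 0 else math.inf
    p = float(stats.f.sf(F, 1, n - 1)) if np.isfinite(F) else 0.0
    return TrendResult(name, float(F), (1, n - 1), p)


def rm_anova_session_run(data: np.ndarray) -> AnovaResult:
    """Two-way fully within-subject ANOVA on (persons, sessions=2, runs=k).

    Rows containing NaN (incomplete persons) are dropped and counted. Each
    effect is tested against its own effect-by-subject error term;
    Greenhouse-Geisser epsilon is estimated from the covariance of the
    orthonormal contrast scores. Polynomial trends (linear, quadratic) are
    one-df contrasts over runs, for the Run main effect and the Session x Run
    interaction.
    """
    data = np.asarray(data, float)
    if data.ndim != 3 or data.shape[1] != 2:
        raise ValueError("data must be (persons, 2 sessions, k runs)")
    complete = ~np.isnan(data).any(axis=(1, 2))
    n_dropped = int((~complete).sum())
    y = data[complete]
    n, a, k = y.shape
    if n < 3:
        raise ValueError("need >= 3 complete persons")

    P = polynomial_contrasts(k)  # k x (k-1), orthonormal

    # Session: single contrast (M1 - M2)/sqrt(2) averaged over runs * sqrt(k)
    sess = (y[:, 0, :] - y[:, 1, :]).mean(axis=1) * math.sqrt(k / 2.0)
    F_s, df_s, eps_s, _ = _within_effect(sess[:, None])
    # Run: contrasts of run means averaged over sessions, * sqrt(a)
    run_scores = y.mean(axis=1) @ P * math.sqrt(a)
    F_r, df_r, eps_r, _ = _within_effect(run_scores)
    # Interaction: contrasts of the session difference profile / sqrt(2)
    inter_scores = (y[:, 0, :] - y[:, 1, :]) @ P / math.sqrt(2.0)
    F_i, df_i, eps_i, _ = _within_effect(inter_scores)

    def effect(name, F, df, eps):
        p_unc = float(stats.f.sf(F, *df)) if np.isfinite(F) else 0.0
        p_gg = float(stats.f.sf(F, eps * df[0], eps * df[1])) if np.isfinite(F) else 0.0
        return AnovaEffect(name, float(F), df, float(eps), p_gg, p_unc)

    effects = {
        "session": effect("session", F_s, df_s, eps_s),
        "run": effect("run", F_r, df_r, eps_r),
        "session_x_run": effect("session_x_run", F_i, df_i, eps_i),
    }

    trends = {}
    if k >= 2:
        trends["run_linear"] = _contrast_trend(run_scores[:, 0], "run_linear")
        trends["session_x_run_linear"] = _contrast_trend(
            inter_scores[:, 0], "session_x_run_linear")
    if k >= 3:
        trends["run_quadratic"] = _contrast_trend(run_scores[:, 1], "run_quadratic")
        trends["session_x_run_quadratic"] = _contrast_trend(
            inter_scores[:, 1], "session_x_run_quadratic")
    return AnovaResult(effects=effects, trends=trends, n_persons=n,
                       n_dropped=n_dropped)


# ---------------------------------------------------------------------------
# Study-level report
# ---------------------------------------------------------------------------

def reliability_report(measures: pd.DataFrame, group: str | None = None,
                       n_o: int = 1) -> pd.DataFrame:
    """Per-measure G-coefficients, categories, and paired stability tests.

    Uses session-level rows (run_index == 'all') and complete cases; measures
    with fewer than 2 complete persons are skipped with a warning.
    """
    df = measures.copy()
    df["run_index"] = df["run_index"].astype(str)
    df = df[df["run_index"] == "all"]
    if group is not None:
        df = df[df["group"] == group]
    rows = []
    for name, sub in df.groupby("measure_name", sort=False):
        wide = sub.pivot_table(index="subject_id", columns="occasion",
                               values="value", aggfunc="first").dropna(axis=0)
        if len(wide) < 2 or wide.shape[1] < 2:
            warnings.warn(f"measure {name!r}: fewer than 2 complete persons; skipped")
            continue
        vc = variance_components(wide.to_numpy(float))
        gres = g_coefficient(vc, n_o=n_o)
        tt = paired_t(wide.to_numpy(float))
        rows.append(dict(measure=name, n=len(wide), G=gres.g,
                         category=gres.category, sigma2_p=vc.sigma2_p,
                         sigma2_o=vc.sigma2_o, sigma2_po_e=vc.sigma2_po_e,
                         t=tt.t, df=tt.df, p=tt.p,
                         mean_difference=tt.mean_difference))
    return pd.DataFrame(rows)
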