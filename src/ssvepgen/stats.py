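"""Repeated-measures inference with effect sizes and confidence intervals.

Implements the reporting conventions of the analysis: within-subject ANOVA
from sums of squares with Greenhouse-Geisser (optionally Huynh-Feldt)
sphericity-corrected degrees of freedom, partial eta-squared with a
noncentral-F confidence interval, and paired t-tests with Cohen's d for
difference scores (d = t / sqrt(n)) and a noncentral-t confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import brentq


@dataclass
class AnovaEffect:
    """One within-subject effect with corrected dfs and effect size."""

    name: str
    F: float
    df1_unc: float
    df2_unc: float
    epsilon: float
    p: float
    pes: float
    pes_ci: tuple
    ss_effect: float
    ss_error: float

    @property
    def df1_corr(self) -> float:
        return self.epsilon * self.df1_unc

    @property
    def df2_corr(self) -> float:
        return self.epsilon * self.df2_unc


@dataclass
class AnovaResult:
    effects: dict

    def __getitem__(self, name: str) -> AnovaEffect:
        return self.effects[name]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.effects.values():
            rows.append(
                {
                    "effect": e.name,
                    "F": e.F,
                    "df1": e.df1_unc,
                    "df2": e.df2_unc,
                    "eps": e.epsilon,
                    "df1_corr": round(e.df1_corr, 2),
                    "df2_corr": round(e.df2_corr, 2),
                    "p": e.p,
                    "pes": e.pes,
                    "pes_ci_lo": e.pes_ci[0],
                    "pes_ci_hi": e.pes_ci[1],
                }
            )
        return pd.DataFrame(rows)


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    d: float
    d_ci: tuple


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrast matrix (Helmert, normalized)."""
    c = np.zeros((k - 1, k))
    for i in range(k - 1):
        c[i, : i + 1] = 1.0
        c[i, i + 1] = -(i + 1.0)
        c[i] /= np.linalg.norm(c[i])
    return c


def _gg_epsilon(Y: np.ndarray, C: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the contrast-space covariance.

    ``Y`` is subjects x cells, ``C`` the orthonormal contrasts spanning the
    effect.  epsilon = (tr S)^2 / (d * tr(S^2)) with S = C Sigma C'.
    """
    Z = Y @ C.T
    S = np.cov(Z, rowvar=False)
    S = np.atleast_2d(S)
    d = S.shape[0]
    tr = np.trace(S)
    return float(tr**2 / (d * np.sum(S * S)))


def _hf_epsilon(gg: float, n: int, d: int) -> float:
    hf = (n * d * gg - 2.0) / (d * (n - 1.0 - d * gg))
    return float(min(1.0, hf))


def rm_anova(
    table: pd.DataFrame,
    dv: str,
    within,
    subject: str = "subject",
    sphericity: str = "gg",
    ci: float = 0.95,
) -> AnovaResult:
    """Within-subject ANOVA (one or two factors) from sums of squares.

    Requires a complete, balanced table: every subject contributes exactly
    one value per factor cell (average within cells upstream).  Degrees of
    freedom of multi-level effects are multiplied by the Greenhouse-Geisser
    epsilon (``sphericity="hf"`` selects Huynh-Feldt, ``"none"`` disables
    correction); two-level effects have epsilon 1 by construction.
    """
    within = [within] if isinstance(within, str) else list(within)
    if not 1 <= len(within) <= 2:
        raise ValueError("supports one or two within-subject factors")
    wide = table.pivot_table(
        index=subject, columns=within, values=dv, aggfunc="mean"
    )
    if wide.isna().any().any():
        missing = wide.isna().stack()
        raise ValueError(
            f"missing cells in the design: {missing[missing].index.tolist()}"
        )
    counts = table.groupby([subject] + within).size()
    if (counts != 1).any():
        raise ValueError("table must hold exactly one value per subject cell")
    n = wide.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")

    if len(within) == 1:
        levels_a = list(wide.columns)
        Y = wide.to_numpy().reshape(n, len(levels_a), 1)
        names = {within[0]: (len(levels_a), 1)}
    else:
        levels_a = list(wide.columns.get_level_values(0).unique())
        levels_b = list(wide.columns.get_level_values(1).unique())
        wide = wide.reindex(
            columns=pd.MultiIndex.from_product([levels_a, levels_b])
        )
        Y = wide.to_numpy().reshape(n, len(levels_a), len(levels_b))
        names = {
            within[0]: (len(levels_a), 1),
            within[1]: (1, len(levels_b)),
            f"{within[0]}:{within[1]}": (len(levels_a), len(levels_b)),
        }

    a, b = Y.shape[1], Y.shape[2]
    grand = Y.mean()
    m_s = Y.mean(axis=(1, 2))
    m_a = Y.mean(axis=(0, 2))
    m_b = Y.mean(axis=(0, 1))
    m_ab = Y.mean(axis=0)
    m_sa = Y.mean(axis=2)
    m_sb = Y.mean(axis=1)

    C_a = _orthonormal_contrasts(a) if a > 1 else None
    C_b = _orthonormal_contrasts(b) if b > 1 else None

    effects = {}
    for name, (ka, kb) in names.items():
        if ka > 1 and kb == 1:  # main effect of factor A
            ss_eff = n * b * np.sum((m_a - grand) ** 2)
            ss_err = b * np.sum(
                (m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2
            )
            df1, df2 = a - 1, (a - 1) * (n - 1)
            C = np.kron(C_a, np.ones((1, b)) / b)
        elif kb > 1 and ka == 1:  # main effect of factor B
            ss_eff = n * a * np.sum((m_b - grand) ** 2)
            ss_err = a * np.sum(
                (m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2
            )
            df1, df2 = b - 1, (b - 1) * (n - 1)
            C = np.kron(np.ones((1, a)) / a, C_b)
        else:  # interaction
            resid_ab = (
                m_ab - m_a[:, None] - m_b[None, :] + grand
            )
            ss_eff = n * np.sum(resid_ab**2)
            ss_total_within = np.sum((Y - m_s[:, None, None]) ** 2)
            # error(AB) = within-subject residual after A, B, AB and the
            # subject x A, subject x B strata
            ss_a = n * b * np.sum((m_a - grand) ** 2)
            ss_b = n * a * np.sum((m_b - grand) ** 2)
            ss_as = b * np.sum(
                (m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2
            )
            ss_bs = a * np.sum(
                (m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2
            )
            ss_err = ss_total_within - ss_a - ss_b - ss_eff - ss_as - ss_bs
            df1, df2 = (a - 1) * (b - 1), (a - 1) * (b - 1) * (n - 1)
            C = np.kron(C_a, C_b)
        F = (ss_eff / df1) / (ss_err / df2)
        if df1 == 1 or sphericity == "none":
            eps = 1.0
        else:
            eps = _gg_epsilon(Y.reshape(n, a * b), C)
            if sphericity == "hf":
                eps = _hf_epsilon(eps, n, df1)
        p = float(sps.f.sf(F, eps * df1, eps * df2))
        pes = ss_eff / (ss_eff + ss_err)
        pes_lo, pes_hi = partial_eta_sq_ci(F, df1, df2, ci)
        effects[name] = AnovaEffect(
            name=name, F=float(F), df1_unc=df1, df2_unc=df2,
            epsilon=float(eps), p=p, pes=float(pes), pes_ci=(pes_lo, pes_hi),
            ss_effect=float(ss_eff), ss_error=float(ss_err),
        )
    return AnovaResult(effects)


def partial_eta_sq(F: float, df1: float, df2: float, ci: float = 0.95):
    """Partial eta-squared F*df1/(F*df1+df2) with its noncentral-F CI."""
    if F < 0 or df1 < 1 or df2 < 1:
        raise ValueError("F must be non-negative and dfs at least 1")
    pes = F * df1 / (F * df1 + df2)
    return float(pes), partial_eta_sq_ci(F, df1, df2, ci)


def partial_eta_sq_ci(F: float, df1: float, df2: float, ci: float = 0.95):
    """CI by inverting the noncentral-F distribution for the noncentrality.

    The noncentrality bounds map to partial eta-squared via
    lambda / (lambda + df1 + df2 + 1).  Bounds pinned at 0 (or the upper
    end) when the observed F lies inside the corresponding central tail.
    """
    alpha = 1.0 - ci
    lo_q, hi_q = 1.0 - alpha / 2.0, alpha / 2.0

    def _nc_limit(target):
        # find lambda with P(F' <= F_obs | lambda) = target
        if sps.ncf.cdf(F, df1, df2, 0.0) <= target:
            return 0.0
        hi = 4.0
        while sps.ncf.cdf(F, df1, df2, hi) > target:
            hi *= 2.0
            if hi > 1e7:
                return hi
        return brentq(lambda nc: sps.ncf.cdf(F, df1, df2, nc) - target, 0, hi)

    lam_lo = _nc_limit(lo_q)
    lam_hi = _nc_limit(hi_q)
    denom = df1 + df2 + 1.0
    return (
        float(lam_lo / (lam_lo + denom)),
        float(lam_hi / (lam_hi + denom)),
    )


def cohen_d_ci(t: float, n: int, ci: float = 0.95):
    """CI for d = t/sqrt(n) by inverting the noncentral-t distribution."""
    df = n - 1
    alpha = 1.0 - ci
    span = abs(t) + 20.0

    def _cdf(nc):
        # noncentral-t cdf, with scipy's far-tail NaNs replaced by limits
        v = sps.nct.cdf(t, df, nc)
        if np.isnan(v):
            return 0.0 if nc > t else 1.0
        return v

    nc_lo = brentq(
        lambda nc: (1.0 - _cdf(nc)) - alpha / 2.0, -span, t + span, xtol=1e-10
    )
    nc_hi = brentq(
        lambda nc: _cdf(nc) - alpha / 2.0, t - span, t + span + 30, xtol=1e-10
    )
    rt = np.sqrt(n)
    return float(nc_lo / rt), float(nc_hi / rt)


def paired_t(x, y, ci: float = 0.95) -> TTestResult:
    """Paired t-test with difference-score Cohen's d (= t / sqrt(n))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    diff = x - y
    if np.allclose(diff.std(ddof=1), 0.0):
        raise ValueError("zero variance of the differences")
    res = sps.ttest_rel(x, y)
    t = float(res.statistic)
    d = t / np.sqrt(n)
    return TTestResult(
        t=t, df=n - 1, p=float(res.pvalue), d=float(d),
        d_ci=cohen_d_ci(t, n, ci),
    )
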