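"""Episode-contrast statistics: t-values, Wilcoxon signed-rank Z, Gaussian GLM.

All contrasts are computed on (high-risk − low-risk), so a positive
statistic means a larger value under high risk.  The Wilcoxon Z follows
the SPSS convention: W is the smaller of the positive/negative rank sums,
ties get average ranks with the usual variance correction, and no
continuity correction is applied — hence Z ≤ 0 always.  The Gaussian GLM
uses the maximum-likelihood scale (RSS/n) with Wald chi-square inference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as st

__all__ = [
    "ContrastResult",
    "RiskMeanResult",
    "GlmFit",
    "episode_tvalue",
    "risk_mean_test",
    "wilcoxon_z",
    "glm_gaussian",
    "grouped_summary",
    "adjust_pvalues",
]

Z975 = 1.959964  # standard-normal 97.5% quantile as used for Wald CIs


@dataclass
class ContrastResult:
    """Per-channel contrast statistic with its test metadata."""

    statistic: float
    p_value: float
    n_low: int
    n_high: int
    kind: str  # paired-t | independent-t | welch-t | wilcoxon
    channel: int | None = None
    degenerate: bool = False
    direction: str = "positive = high > low"


@dataclass
class RiskMeanResult:
    """Low/high risk-field means with their difference and t-test."""

    m_low: float
    m_high: float
    d_lh: float
    contrast: ContrastResult


@dataclass
class GlmFit:
    """Gaussian identity-link GLM fit with ML scale and Wald inference."""

    params: np.ndarray
    se: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    wald_chi2: np.ndarray
    df: np.ndarray
    p_values: np.ndarray
    scale: float
    scale_se: float
    n: int
    names: list[str] = field(default_factory=list)
    perfect_fit: bool = False
    model: str = ""

    def summary_frame(self) -> pd.DataFrame:
        """Parameter-estimation table: B, SE, Wald CI, chi-square, df, sig."""
        rows = pd.DataFrame(
            {
                "Parameter": self.names,
                "B": self.params,
                "Std error": self.se,
                "Wald CI lower": self.ci_lower,
                "Wald CI upper": self.ci_upper,
                "Wald chi-square": self.wald_chi2,
                "df": self.df,
                "Sig": self.p_values,
            }
        )
        scale_row = pd.DataFrame(
            {
                "Parameter": ["(Scale)"],
                "B": [self.scale],
                "Std error": [self.scale_se],
                "Wald CI lower": [np.nan],
                "Wald CI upper": [np.nan],
                "Wald chi-square": [np.nan],
                "df": [np.nan],
                "Sig": [np.nan],
            }
        )
        return pd.concat([rows, scale_row], ignore_index=True)


def _zero_spread(x: np.ndarray) -> bool:
    """Sample SD is zero up to float rounding of identical values."""
    sd = x.std(ddof=1)
    return sd == 0 or sd < 1e-12 * np.max(np.abs(x), initial=0.0)


def _t_from_diffs(d: np.ndarray) -> tuple[float, float, bool]:
    n = d.size
    sd = d.std(ddof=1)
    if _zero_spread(d):
        m = d.mean()
        t = 0.0 if m == 0 else np.inf * np.sign(m)
        return t, (1.0 if m == 0 else 0.0), True
    t = d.mean() / (sd / np.sqrt(n))
    p = 2 * st.t.sf(abs(t), n - 1)
    return float(t), float(p), False


def episode_tvalue(
    low_feats,
    high_feats,
    mode: str = "paired",
    channel: int | None = None,
) -> ContrastResult:
    """t statistic of (high − low) episode features.

    ``mode`` is ``paired`` (one-sample t on within-instance differences,
    requires aligned equal-length inputs), ``independent`` (pooled
    variance) or ``welch``.
    """
    low = np.asarray(low_feats, float)
    high = np.asarray(high_feats, float)
    if mode == "paired":
        if low.size != high.size:
            raise ValueError("paired mode requires equal-length aligned samples")
        if low.size < 2:
            raise ValueError("need at least 2 pairs")
        t, p, degen = _t_from_diffs(high - low)
        if degen:
            warnings.warn("zero variance of differences; t degenerate", stacklevel=2)
        kind = "paired-t"
    elif mode in ("independent", "welch"):
        if min(low.size, high.size) < 2:
            raise ValueError("need at least 2 samples per group")
        if _zero_spread(low) and _zero_spread(high):
            m = high.mean() - low.mean()
            t = 0.0 if m == 0 else np.inf * np.sign(m)
            p = 1.0 if m == 0 else 0.0
            degen = True
            warnings.warn("zero variance in both groups; t degenerate", stacklevel=2)
        else:
            res = st.ttest_ind(high, low, equal_var=(mode == "independent"))
            t, p, degen = float(res.statistic), float(res.pvalue), False
        kind = f"{mode}-t" if mode == "welch" else "independent-t"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return ContrastResult(t, p, low.size, high.size, kind, channel, degen)


def risk_mean_test(low_risk_values, high_risk_values, mode: str = "paired") -> RiskMeanResult:
    """Compare risk-field samples between episodes; reports M_L, M_H, D_LH."""
    low = np.asarray(low_risk_values, float)
    high = np.asarray(high_risk_values, float)
    if low.size == 0 or high.size == 0:
        raise ValueError("empty episode sample")
    if mode == "paired" and low.size != high.size:
        mode = "welch"
    contrast = episode_tvalue(low, high, mode=mode)
    m_l, m_h = float(low.mean()), float(high.mean())
    return RiskMeanResult(m_l, m_h, m_h - m_l, contrast)


def wilcoxon_z(low=None, high=None, diffs=None) -> ContrastResult:
    """SPSS-convention Wilcoxon signed-rank Z for paired samples.

    Zero differences are dropped; |differences| are ranked with average
    ranks for ties; ``W = min(W+, W−)`` is standardised by
    ``Z = (W − n(n+1)/4) / sqrt(n(n+1)(2n+1)/24 − Σ(t³−t)/48)``
    with no continuity correction, so Z ≤ 0 by construction.
    """
    if diffs is None:
        d = np.asarray(high, float) - np.asarray(low, float)
    else:
        d = np.asarray(diffs, float)
    n_pairs = d.size
    d = d[d != 0]
    n = d.size
    if n == 0:
        warnings.warn("all differences zero; Wilcoxon degenerate", stacklevel=2)
        return ContrastResult(0.0, 1.0, n_pairs, n_pairs, "wilcoxon", degenerate=True)
    ranks = st.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    w = min(w_pos, w_neg)
    mean_w = n * (n + 1) / 4.0
    # tie correction over groups of tied |differences|
    _, counts = np.unique(np.abs(d), return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / 48.0
    var_w = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var_w <= 0:
        warnings.warn("zero variance in signed ranks; Wilcoxon degenerate", stacklevel=2)
        return ContrastResult(0.0, 1.0, n_pairs, n_pairs, "wilcoxon", degenerate=True)
    z = (w - mean_w) / np.sqrt(var_w)
    p = 2 * st.norm.sf(abs(z))
    return ContrastResult(float(z), float(p), n_pairs, n_pairs, "wilcoxon")


def glm_gaussian(y, X_design, names: list[str] | None = None, model: str = "") -> GlmFit:
    """Gaussian identity-link GLM by maximum likelihood.

    Coefficients are the least-squares solution; ``scale`` is the ML
    variance estimate RSS/n; standard errors come from scale·(XᵀX)⁻¹;
    Wald chi-square is (B/SE)² with 1 df; the 95% Wald CI is B ± 1.959964·SE.
    The scale's standard error is the large-sample value scale·√(2/n).
    """
    y = np.asarray(y, float)
    X = np.asarray(X_design, float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if n <= p:
        raise ValueError("need more observations than parameters")
    if not (np.isfinite(y).all() and np.isfinite(X).all()):
        raise ValueError("non-finite values in model input")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        from scipy.linalg import qr

        _, _, piv = qr(X, pivoting=True)
        bad = sorted(piv[rank:].tolist())
        corr_cols = [names[j] if names else f"x{j}" for j in bad]
        raise ValueError(f"rank-deficient design matrix (collinear columns {corr_cols})")

    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    scale = rss / n
    perfect = scale < 1e-12 * max(1.0, float(y @ y) / n)
    xtx_inv = np.linalg.inv(X.T @ X)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(scale * np.diag(xtx_inv))
        wald = np.where(se > 0, (beta / se) ** 2, np.inf)
    dfs = np.ones(p)
    pvals = st.chi2.sf(wald, dfs)
    if names is None:
        names = ["(Intercept)"] if p == 1 and np.allclose(X, 1) else [f"x{j}" for j in range(p)]
    return GlmFit(
        params=beta,
        se=se,
        ci_lower=beta - Z975 * se,
        ci_upper=beta + Z975 * se,
        wald_chi2=wald,
        df=dfs,
        p_values=pvals,
        scale=scale,
        scale_se=scale * np.sqrt(2.0 / n),
        n=n,
        names=list(names),
        perfect_fit=bool(perfect),
        model=model,
    )


def adjust_pvalues(p, method: str = "bonferroni") -> np.ndarray:
    """Optional multiple-testing adjustment across channels (off by default)."""
    from statsmodels.stats.multitest import multipletests

    method = {"bh": "fdr_bh", "bonferroni": "bonferroni"}.get(method, method)
    return multipletests(np.asarray(p, float), method=method)[1]


def grouped_summary(features: pd.DataFrame, grouping: str) -> pd.DataFrame:
    """Descriptive five-number summaries per group × risk class.

    ``features`` needs columns ``value``, ``risk_class`` and the grouping
    column (``sex`` or ``driving_experience``).  Each row gives min/Q1/
    median/Q3/max and n; groups of one observation are flagged degenerate,
    empty groups are omitted with a warning.  A per-group paired p-value
    (low vs high, Welch t as fallback) is attached where computable.
    """
    if grouping not in features.columns:
        raise KeyError(f"grouping column {grouping!r} missing")
    rows = []
    for gval, gdf in features.groupby(grouping, sort=True):
        for rc, cdf in gdf.groupby("risk_class", sort=True):
            v = cdf["value"].to_numpy(float)
            if v.size == 0:
                warnings.warn(f"empty group {gval}/{rc} omitted", stacklevel=2)
                continue
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            rows.append(
                {
                    grouping: gval,
                    "risk_class": rc,
                    "n": v.size,
                    "min": v.min(),
                    "q1": q1,
                    "median": med,
                    "q3": q3,
                    "max": v.max(),
                    "degenerate": v.size < 2,
                }
            )
        low = gdf.loc[gdf["risk_class"] == "low", "value"].to_numpy(float)
        high = gdf.loc[gdf["risk_class"] == "high", "value"].to_numpy(float)
        if low.size >= 2 and high.size >= 2:
            mode = "paired" if low.size == high.size else "welch"
            p = episode_tvalue(low, high, mode=mode).p_value
            for r in rows:
                if r[grouping] == gval and "p_low_vs_high" not in r:
                    r["p_low_vs_high"] = p
    return pd.DataFrame(rows)
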