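"""Agreement statistics for two-system validation.

Implements the waveform intraclass correlation (two-way single-measure,
absolute-agreement by default, with McGraw & Wong F-based confidence
intervals), the default JZS Bayes-factor t-test (Cauchy prior on the
standardized effect, evaluated by adaptive quadrature), a contrast-based
Bayesian analysis of a within-unit 2x2 design, a sequential Bayes-factor
stopping rule, a tie-corrected Wilcoxon signed-rank test with exact
enumeration at small n, and the Pearson topography correlation.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
from scipy import integrate, stats as st

from .types import BayesFactorResult, ERPWaveform, ICCResult, StoppingTrace

DEFAULT_PRIOR_SCALE = math.sqrt(2.0) / 2.0


# ---------------------------------------------------------------------------
# Intraclass correlation

def _icc_mean_squares(x: np.ndarray) -> tuple[float, float, float]:
    """Row (targets), column (raters), and error mean squares of an n x k
    two-way layout."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_from_table(x: np.ndarray, model: str = "absolute",
                   alpha: float = 0.05) -> ICCResult:
    """Single-measure two-way ICC of an n x k ratings table.

    ``absolute`` is ICC(A,1): systematic offsets between raters count
    against agreement.  ``consistency`` is ICC(C,1).  Confidence intervals
    follow the McGraw & Wong (1996) F-distribution construction.
    """
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    if n < 10:
        raise ValueError("need >= 10 rows for a stable waveform ICC")
    msr, msc, mse = _icc_mean_squares(x)

    if model == "consistency":
        est = (msr - mse) / (msr + (k - 1) * mse)
        f_obs = msr / mse
        df1, df2 = n - 1, (n - 1) * (k - 1)
        fu = st.f.ppf(1 - alpha / 2, df1, df2)
        fl = st.f.ppf(1 - alpha / 2, df2, df1)
        lo = (f_obs / fu - 1) / (f_obs / fu + k - 1)
        hi = (f_obs * fl - 1) / (f_obs * fl + k - 1)
    elif model == "absolute":
        est = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        a = k * est / (n * (1 - est)) if est != 1 else np.inf
        b = 1 + k * est * (n - 1) / (n * (1 - est)) if est != 1 else np.inf
        if np.isfinite(a):
            v = ((a * msc + b * mse) ** 2
                 / ((a * msc) ** 2 / (k - 1)
                    + (b * mse) ** 2 / ((n - 1) * (k - 1))))
            f2u = st.f.ppf(1 - alpha / 2, n - 1, v)
            f2l = st.f.ppf(1 - alpha / 2, v, n - 1)
            lo = (n * (msr - f2u * mse)
                  / (f2u * (k * msc + (k * n - k - n) * mse) + n * msr))
            hi = (n * (f2l * msr - mse)
                  / (k * msc + (k * n - k - n) * mse + n * f2l * msr))
        else:
            lo = hi = 1.0
    else:
        raise ValueError("model must be 'absolute' or 'consistency'")
    est = float(np.clip(est, -1.0, 1.0))
    lo = float(np.clip(lo, -1.0, est))
    hi = float(np.clip(hi, est, 1.0))
    return ICCResult(estimate=est, ci95=(lo, hi), n_points=n, model=model)


def waveform_icc(a: ERPWaveform, b: ERPWaveform, channel: str,
                 model: str = "absolute") -> ICCResult:
    """ICC between two systems' waveforms at one channel.

    Time points are the rated targets and the two systems the raters, so
    the coefficient measures point-by-point agreement of the entire
    waveform shape (and, for the absolute model, its scale).
    """
    if not np.allclose(a.time_ms, b.time_ms):
        raise ValueError("waveforms must share a time axis")
    x = np.column_stack([a.get_channel(channel), b.get_channel(channel)])
    return icc_from_table(x, model=model)


# ---------------------------------------------------------------------------
# JZS Bayes factor

def jzs_bf_from_t(t: float, n: int,
                  prior_scale: float = DEFAULT_PRIOR_SCALE
                  ) -> BayesFactorResult:
    """BF10 of the default Bayesian t-test from a one-sample t statistic.

    Marginal likelihood under H1 integrates the noncentral t density over
    g with g ~ InverseGamma(1/2, r^2/2) (equivalently a Cauchy(0, r) prior
    on the standardized effect).  Evaluated by adaptive quadrature on a
    log-stable integrand.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    nu = n - 1.0

    def log_h1_integrand(g: float) -> float:
        return (-0.5 * math.log1p(n * g)
                - 0.5 * (nu + 1) * math.log1p(t * t / ((1 + n * g) * nu))
                + math.log(prior_scale) - 0.5 * math.log(2 * math.pi)
                - 1.5 * math.log(g) - prior_scale ** 2 / (2 * g))

    # Peel off the H0 likelihood so the ratio is computed in one pass.
    log_h0 = -0.5 * (nu + 1) * math.log1p(t * t / nu)

    def integrand(g: float) -> float:
        if g <= 0:
            return 0.0
        return math.exp(log_h1_integrand(g) - log_h0)

    val, err = integrate.quad(integrand, 0.0, np.inf, limit=200)
    # refine the head of the distribution, where the prior mass sits
    if val <= 0 or err / max(val, 1e-300) > 1e-8:
        val1, err1 = integrate.quad(integrand, 0.0, 1.0, limit=200)
        val2, err2 = integrate.quad(integrand, 1.0, np.inf, limit=200)
        val, err = val1 + val2, err1 + err2
    return BayesFactorResult(bf10=float(val), prior_scale=prior_scale,
                             n=int(n), t_stat=float(t),
                             integration_error=float(err / max(val, 1e-300)))


def jzs_bf_ttest(differences: Sequence[float],
                 prior_scale: float = DEFAULT_PRIOR_SCALE
                 ) -> BayesFactorResult:
    """Paired-sample default Bayes factor from per-unit differences."""
    d = np.asarray(differences, dtype=float)
    if d.size < 2:
        raise ValueError("need at least two paired differences")
    if not np.all(np.isfinite(d)):
        raise ValueError("differences must be finite")
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance in differences; t undefined")
    t = d.mean() / (sd / math.sqrt(d.size))
    return jzs_bf_from_t(float(t), int(d.size), prior_scale)


def bayes_2x2(table: np.ndarray, factors: tuple[str, str] = ("system", "condition"),
              prior_scale: float = DEFAULT_PRIOR_SCALE
              ) -> dict[str, BayesFactorResult]:
    """Bayes factors for a complete within-unit 2x2 design.

    ``table`` has shape (n_units, 2, 2) indexed (unit, factor1, factor2).
    Each main effect is the JZS paired test on the within-unit marginal
    contrast; the interaction uses the difference of differences.  This is
    a transparent contrast-based approximation to a full mixed Bayesian
    ANOVA, exact in spirit for a 2x2 within design.
    """
    x = np.asarray(table, dtype=float)
    if x.ndim != 3 or x.shape[1:] != (2, 2):
        raise ValueError("table must have shape (n, 2, 2)")
    c1 = (x[:, 0, :] - x[:, 1, :]).mean(axis=1)
    c2 = (x[:, :, 0] - x[:, :, 1]).mean(axis=1)
    inter = x[:, 0, 0] - x[:, 0, 1] - x[:, 1, 0] + x[:, 1, 1]
    return {
        factors[0]: jzs_bf_ttest(c1, prior_scale),
        factors[1]: jzs_bf_ttest(c2, prior_scale),
        "interaction": jzs_bf_ttest(inter, prior_scale),
    }


def sequential_stop(data_stream: Iterable[float], min_n: int = 20,
                    low: float = 0.33, high: float = 3.00,
                    prior_scale: float = DEFAULT_PRIOR_SCALE) -> StoppingTrace:
    """Sequential Bayes-factor stopping rule on accumulating paired data.

    The Bayes factor is computed once ``min_n`` units are in hand and after
    each additional unit; sampling stops at the first BF below ``low``
    (systems equivalent) or above ``high`` (systems different).
    """
    values = np.asarray(list(data_stream), dtype=float)
    if values.size < min_n:
        raise ValueError(f"stream shorter than min_n={min_n}")
    per_n: list[tuple[int, float]] = []
    decision, n_final = "undecided", int(values.size)
    for n in range(min_n, values.size + 1):
        bf = jzs_bf_ttest(values[:n], prior_scale).bf10
        per_n.append((n, bf))
        if bf < low:
            decision, n_final = "equivalent", n
            break
        if bf > high:
            decision, n_final = "different", n
            break
    return StoppingTrace(per_n=per_n, decision=decision, n_final=n_final,
                         bounds=(low, high), min_n=min_n)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank

class AllZeroDifferencesError(ValueError):
    """All paired differences are zero: the signed-rank test is undefined."""


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float],
                         method: str = "auto") -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test; returns (Z, p).

    Zero differences are discarded; ties receive average ranks with the
    usual variance correction in the normal approximation.  With ``auto``,
    an exact p-value (enumeration of all sign assignments) replaces the
    approximate one when n <= 12.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    m = d.size
    if m == 0:
        raise AllZeroDifferencesError("all differences zero; no test")
    ranks = st.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    mu = m * (m + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts)) / 48.0
    var = m * (m + 1) * (2 * m + 1) / 24.0 - tie_term
    z = (w_pos - mu) / math.sqrt(var) if var > 0 else 0.0

    if method == "exact" or (method == "auto" and m <= 12):
        p = _exact_signed_rank_p(ranks, w_pos)
    else:
        p = 2.0 * st.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def _exact_signed_rank_p(ranks: np.ndarray, w_obs: float) -> float:
    """Two-sided exact p by enumerating every sign assignment."""
    m = ranks.size
    signs = ((np.arange(2 ** m)[:, None] >> np.arange(m)) & 1).astype(float)
    sums = signs @ ranks
    ge = np.mean(sums >= w_obs - 1e-9)
    le = np.mean(sums <= w_obs + 1e-9)
    return float(min(1.0, 2.0 * min(ge, le)))


def topography_correlation(amps_a: Sequence[float],
                           amps_b: Sequence[float]) -> float:
    """Pearson correlation of per-channel amplitudes between systems."""
    a = np.asarray(amps_a, dtype=float)
    b = np.asarray(amps_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("channel sets must match")
    r, _ = st.pearsonr(a, b)
    return float(r)
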