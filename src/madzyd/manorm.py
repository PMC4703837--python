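"""MA-based two-sample differential enrichment for ChIP-seq peak counts.

The model follows the MA normalization idea: peaks detected in both
samples ("common" peaks) are assumed unchanged on average, a robust linear
fit of M = log2(x/y) on A = 0.5*log2(x*y) over common peaks captures the
global between-sample bias, and every peak's M is rescaled by subtracting
the fitted trend. Significance of each peak's count difference uses the
Audic-Claverie statistic

    P(y | x) = (x + y)! / (x! * y! * 2^(x+y+1)),

the posterior probability of observing y reads in one sample given x in
the other under equal sampling depth; one-sided tails of this distribution
give the p-value. P(. | x) is the NegativeBinomial(x+1, 1/2) pmf, so tails
are evaluated in log space through the regularized incomplete beta
function.

No multiple-testing correction is applied: downstream classification
thresholds the raw -log10(P), and the thresholds are calibrated for that.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import theilslopes
import statsmodels.api as sm


def compute_ma(x, y, pseudocount: float = 0.5):
    """M and A values for count pairs.

    M = log2((x+c)/(y+c)), A = 0.5*log2((x+c)(y+c)). The pseudocount c
    (default 0.5) keeps both defined at zero counts. x is the control
    sample, y the treated one, so peaks depleted by treatment have M > 0.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("counts must be non-negative")
    m = np.log2((x + pseudocount) / (y + pseudocount))
    a = 0.5 * np.log2((x + pseudocount) * (y + pseudocount))
    return m, a


@dataclass
class NormalizationFit:
    """Robust linear trend M = intercept + slope*A fitted on common peaks."""

    intercept: float
    slope: float
    n_common: int
    method: str
    converged: bool = True

    def predict(self, a):
        return self.intercept + self.slope * np.asarray(a, dtype=float)


def fit_normalization(m, a, min_common: int = 10) -> NormalizationFit:
    """Fit the normalization line on common peaks only.

    Iteratively reweighted least squares with the Tukey bisquare loss
    (tuning constant 4.685, max 50 iterations, tol 1e-8); for fewer than 50
    common peaks a Theil-Sen fit is used instead, which is stable at small
    n. Requires at least ``min_common`` peaks — with fewer, the merged peak
    set is probably missing; merge peak sets across samples/stages first.
    """
    m = np.asarray(m, dtype=float)
    a = np.asarray(a, dtype=float)
    if m.size < min_common:
        raise ValueError(
            f"only {m.size} common peaks (< {min_common}); normalization needs "
            "a merged peak set quantified in both samples"
        )
    if np.allclose(a, a[0]):
        # degenerate design: no A spread; slope 0, intercept = median M
        return NormalizationFit(float(np.median(m)), 0.0, m.size, "degenerate")
    if m.size < 50:
        res = theilslopes(m, a)
        return NormalizationFit(float(res.intercept), float(res.slope),
                                m.size, "theil-sen")
    X = sm.add_constant(a)
    rlm = sm.RLM(m, X, M=sm.robust.norms.TukeyBiweight(c=4.685))
    # IRLS with a redescending loss needs a robust start: from the OLS
    # solution a leveraged outlier cloud (e.g. depleted peaks leaking into
    # the common set) can anchor a spurious trend
    start = theilslopes(m, a)
    fit = rlm.fit(maxiter=50, tol=1e-8,
                  start_params=np.array([start.intercept, start.slope]))
    return NormalizationFit(float(fit.params[0]), float(fit.params[1]),
                            m.size, "irls-tukey")


def normalize_m(m_raw, a, fit: NormalizationFit):
    """Rescaled M: the fitted common-peak trend subtracted from every peak."""
    return np.asarray(m_raw, dtype=float) - fit.predict(a)


def rescaled_counts(m_norm, a, pseudocount: float = 0.5):
    """Counts implied by (M_norm, A), rounded to non-negative integers.

    Inverts the MA transform holding A fixed: log2(x') = A + M/2,
    log2(y') = A - M/2. These are the normalized counts on which the count
    statistic is evaluated.
    """
    m_norm = np.asarray(m_norm, dtype=float)
    a = np.asarray(a, dtype=float)
    x = np.rint(np.maximum(2.0 ** (a + m_norm / 2) - pseudocount, 0)).astype(int)
    y = np.rint(np.maximum(2.0 ** (a - m_norm / 2) - pseudocount, 0)).astype(int)
    return x, y


def count_pvalue(x, y, direction: str = "depleted"):
    """One-sided Audic-Claverie tail probability of y given x.

    direction="depleted": p = sum_{k<=y} P(k|x), small when y is low
    relative to x. direction="enriched": p = sum_{k>=y} P(k|x). Evaluated
    in log space via the NegativeBinomial(x+1, 1/2) tail; p in (0, 1].
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("counts must be non-negative integers")
    if not (np.all(np.equal(np.mod(x, 1), 0)) and np.all(np.equal(np.mod(y, 1), 0))):
        raise ValueError("counts must be integers")
    x = x.astype(int)
    y = y.astype(int)
    if direction == "depleted":
        logp = stats.nbinom.logcdf(y, x + 1, 0.5)
    elif direction == "enriched":
        logp = stats.nbinom.logsf(y - 1, x + 1, 0.5)
    else:
        raise ValueError("direction must be 'depleted' or 'enriched'")
    p = np.exp(logp)
    return np.minimum(p, 1.0) if p.ndim else float(min(p, 1.0))


def run_manorm(peaks: pd.DataFrame, x_col: str, y_col: str,
               common_flag=None, pseudocount: float = 0.5) -> tuple[pd.DataFrame, NormalizationFit]:
    """Full MA differential table for one control/treated sample pair.

    ``peaks`` is the merged peak set with raw counts in ``x_col`` (control)
    and ``y_col`` (treated). ``common_flag`` marks peaks detected in both
    samples (used for the normalization fit); when omitted, all peaks are
    treated as common. Returns the table extended with A, M_raw, M_norm,
    p_value, neg_log10_p, common columns, plus the fit.

    p-values are computed on the normalization-rescaled counts, with the
    tail direction taken from the sign of M_norm.
    """
    out = peaks.copy()
    x = out[x_col].to_numpy()
    y = out[y_col].to_numpy()
    m_raw, a = compute_ma(x, y, pseudocount)
    if common_flag is None:
        common = np.ones(len(out), dtype=bool)
    else:
        common = np.asarray(common_flag, dtype=bool)
    fit = fit_normalization(m_raw[common], a[common])
    m_norm = normalize_m(m_raw, a, fit)
    xr, yr = rescaled_counts(m_norm, a, pseudocount)
    p_dep = count_pvalue(xr, yr, "depleted")
    p_enr = count_pvalue(xr, yr, "enriched")
    p = np.where(m_norm >= 0, p_dep, p_enr)
    out["A"] = a
    out["M_raw"] = m_raw
    out["M_norm"] = m_norm
    out["p_value"] = p
    out["neg_log10_p"] = -np.log10(np.maximum(p, np.finfo(float).tiny))
    out["common"] = common
    return out, fit
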