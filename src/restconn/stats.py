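"""Group-level statistics and clinical-covariate interaction analyses.

The statistical plan mirrors a conventional clinical-EEG analysis: pooled
two-sample t-tests on demographics and per-band EEG summaries, chi-square
tests on categorical covariates, a Friedman test across repeated conditions,
Spearman rank correlations between EEG measures and amyloid burden (SUVR) or
ApoE risk, age-partialled variants, percentile-bootstrap confidence intervals
as the multiplicity device for the correlation families, and Bonferroni
correction for the band-by-measure battery.  Normality screening uses the
Lilliefors-corrected Kolmogorov-Smirnov test (parameters are estimated from
the data, so the naive KS reference distribution would be anticonservative).
"""

from __future__ import annotations

import logging
from collections.abc import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

from . import config

log = logging.getLogger("restconn")

EEG_MEASURES = ("power", "coherence", "rpdc")


def two_sample_t(
    xs: Sequence[float] | tuple[float, float, int],
    ys: Sequence[float] | tuple[float, float, int],
) -> tuple[float, float, int]:
    """Pooled-variance unpaired t-test.

    Accepts raw samples or ``(mean, sd, n)`` summary triples (so printed
    summary statistics can be tested directly).  Returns ``(t, p, df)``.
    """

    def as_summary(v):
        if isinstance(v, tuple) and len(v) == 3 and np.isscalar(v[0]):
            return float(v[0]), float(v[1]), int(v[2])
        arr = np.asarray(v, dtype=float)
        if arr.size < 2:
            raise ValueError("need n >= 2 per group")
        return float(arr.mean()), float(arr.std(ddof=1)), int(arr.size)

    m1, s1, n1 = as_summary(xs)
    m2, s2, n2 = as_summary(ys)
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
    if sp2 == 0:
        if m1 == m2:
            return 0.0, 1.0, n1 + n2 - 2
        raise ValueError("zero pooled variance with unequal means")
    t, p = sps.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=True)
    return float(t), float(p), n1 + n2 - 2


def chi_square(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square on a 2 x k contingency table, no continuity
    correction."""
    table = np.asarray(table, dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    chi2, p, _dof, _exp = sps.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def friedman_test(matrix: np.ndarray) -> tuple[float, float]:
    """Friedman rank test across conditions (columns) within subjects (rows)."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need subjects x conditions with at least 2 of each")
    if np.ptp(matrix, axis=1).max() == 0:
        return 0.0, 1.0  # every subject ties across conditions
    stat, p = sps.friedmanchisquare(*matrix.T)
    return float(stat), float(p)


def spearman(x, y) -> tuple[float, float]:
    """Tie-corrected Spearman rank correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need paired samples with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input has no rank correlation")
    r, p = sps.spearmanr(x, y)
    return float(r), float(p)


def partial_corr(x, y, covar, method: str = "spearman") -> tuple[float, float]:
    """Correlation of x and y with a covariate partialled out.

    Residualizes both variables on the covariate and correlates the
    residuals; with ``method='spearman'`` all three variables are
    rank-transformed first, so the unconditional analysis and its partial
    variant stay on the same (rank) scale.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    covar = np.asarray(covar, dtype=float)
    n = x.size
    if not (y.size == n == covar.size) or n < 5:
        raise ValueError("need three aligned samples with n >= 5")
    if method == "spearman":
        x, y, covar = (sps.rankdata(v) for v in (x, y, covar))
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")

    def residuals(v):
        A = np.column_stack([np.ones(n), covar])
        beta, *_ = np.linalg.lstsq(A, v, rcond=None)
        return v - A @ beta

    rx, ry = residuals(x), residuals(y)
    # a variable the covariate explains completely has nil partial association
    if np.linalg.norm(rx) < 1e-10 * np.linalg.norm(x - x.mean()) or np.linalg.norm(
        ry
    ) < 1e-10 * np.linalg.norm(y - y.mean()):
        return 0.0, 1.0
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 3
    r_ = min(max(r, -0.999999), 0.999999)
    t = r_ * np.sqrt(df / (1 - r_**2))
    p = float(2 * sps.t.sf(abs(t), df))
    return r, p


def bootstrap_ci(
    statistic_fn: Callable[..., float],
    data: tuple[np.ndarray, ...] | np.ndarray,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
) -> tuple[float, float, bool]:
    """Percentile bootstrap CI by simple case resampling.

    ``data`` is an array or tuple of aligned arrays; ``statistic_fn`` receives
    the resampled array(s).  Returns ``(lo, hi, significant)`` where
    ``significant`` means the interval excludes zero.  Resamples on which the
    statistic is undefined are redrawn (and logged).
    """
    arrays = data if isinstance(data, tuple) else (np.asarray(data),)
    arrays = tuple(np.asarray(a) for a in arrays)
    n = arrays[0].shape[0]
    if any(a.shape[0] != n for a in arrays):
        raise ValueError("arrays must be aligned on the first axis")
    if n < 8:
        raise ValueError("need n >= 8 for a case-resampling bootstrap")
    rng = np.random.default_rng(seed)
    vals = np.empty(n_boot)
    redraws = 0
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            try:
                vals[b] = statistic_fn(*(a[idx] for a in arrays))
                break
            except (ValueError, FloatingPointError):
                redraws += 1
                if redraws > 10 * n_boot:
                    raise RuntimeError("statistic undefined on almost every resample")
    if redraws:
        log.info("bootstrap_ci: redrew %d degenerate resamples", redraws)
    alpha = 1.0 - level
    lo, hi = np.percentile(vals, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    significant = bool(lo > 0 or hi < 0)
    return float(lo), float(hi), significant


def bonferroni(pvals, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, p * m)."""
    pvals = np.atleast_1d(np.asarray(pvals, dtype=float))
    m = len(pvals) if m is None else int(m)
    if m < len(pvals):
        raise ValueError("family size m smaller than the number of p-values")
    return np.minimum(1.0, pvals * m)


def ks_normality(x) -> tuple[float, float]:
    """Lilliefors-corrected KS test of normality with estimated moments."""
    x = np.asarray(x, dtype=float)
    if x.size < 8:
        raise ValueError("need n >= 8")
    if np.ptp(x) == 0:
        raise ValueError("constant input")
    d, p = lilliefors(x, dist="norm")
    return float(d), float(p)


# ---------------------------------------------------------------------------
# cohort-level batteries


def group_comparison_battery(
    cohort: pd.DataFrame,
    measures: Sequence[str] = EEG_MEASURES,
    bands: Sequence[str] | None = None,
    alpha: float = 0.05,
    m_family: int = config.BONFERRONI_M_BATTERY,
) -> pd.DataFrame:
    """HC-vs-MCI t-tests for every band-by-measure EEG summary.

    Returns a tidy frame (measure, band, t, p, p_adj, significant) with
    Bonferroni adjustment over the whole family.
    """
    from .spectral import BAND_ORDER

    bands = tuple(bands or BAND_ORDER)
    hc = cohort[cohort["group"] == "HC"]
    mci = cohort[cohort["group"] == "MCI"]
    if len(hc) < 2 or len(mci) < 2:
        raise ValueError("both groups must be present with n >= 2")
    rows = []
    for measure in measures:
        for band in bands:
            col = f"{measure}_{band}"
            t, p, df = two_sample_t(hc[col].to_numpy(), mci[col].to_numpy())
            rows.append({"measure": measure, "band": band, "t": t, "p": p, "df": df})
    out = pd.DataFrame(rows)
    out["p_adj"] = bonferroni(out["p"].to_numpy(), m=m_family)
    out["significant"] = out["p_adj"] < alpha
    return out


def clinical_interaction_analysis(
    cohort: pd.DataFrame,
    group: str = "MCI",
    covariates: Sequence[str] = ("suvr", "apoe_ordinal"),
    measures: Sequence[str] = EEG_MEASURES,
    bands: Sequence[str] | None = None,
    n_boot: int = 1000,
    seed: int | None = None,
    age_partial: bool = True,
) -> pd.DataFrame:
    """Spearman correlations of EEG summaries with clinical covariates.

    One row per (covariate, measure, band): rank correlation, its
    age-partialled variant, and the percentile-bootstrap CI of the rank
    correlation with the significance flag the CI implies (the multiplicity
    device used for this family).
    """
    from .spectral import BAND_ORDER

    bands = tuple(bands or BAND_ORDER)
    sub = cohort[cohort["group"] == group]
    rng = np.random.default_rng(seed)
    rows = []
    for covar in covariates:
        c = sub[covar].to_numpy(dtype=float)
        for measure in measures:
            for band in bands:
                y = sub[f"{measure}_{band}"].to_numpy(dtype=float)
                r, p = spearman(c, y)

                def rank_r(a, b):
                    if np.ptp(a) == 0 or np.ptp(b) == 0:
                        raise ValueError("constant resample")  # redrawn by bootstrap_ci
                    return sps.spearmanr(a, b)[0]

                lo, hi, sig = bootstrap_ci(
                    rank_r, (c, y), n_boot=n_boot, seed=int(rng.integers(2**31 - 1))
                )
                row = {
                    "group": group,
                    "covariate": covar,
                    "measure": measure,
                    "band": band,
                    "r": r,
                    "p": p,
                    "ci_lo": lo,
                    "ci_hi": hi,
                    "significant": sig,
                }
                if age_partial:
                    age = sub["age"].to_numpy(dtype=float)
                    rp, pp = partial_corr(c, y, age, method="spearman")
                    row["r_partial_age"] = rp
                    row["p_partial_age"] = pp
                rows.append(row)
    return pd.DataFrame(rows)
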