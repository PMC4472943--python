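"""The central statistic: DE1 vs DE2 and the regression against the null.

For each LPS-induced transcript the effect of *Dusp1* deletion is the mean
expression ratio of *Dusp1*-null to *Dusp1*-wild-type macrophages, taken
over LPS-treated replicates. In a wild-type *Zfp36* background this ratio
is DE1; in the *Zfp36aa* (phospho-dead TTP) background it is DE2. Under
the null hypothesis that the DUSP1 effect is independent of TTP
phosphorylation, DE1 = DE2 for every transcript and the scatter of
(log2 DE1, log2 DE2) lies on the diagonal of slope 1. A through-origin
regression slope below 1 measures the genome-wide fraction of the DUSP1
effect that is mediated by TTP phosphorylation.

"Mean ratio" is implemented as the geometric mean: the difference of log2
group means, identical to the mean of all pairwise replicate log-ratios.

Two per-transcript error models for testing DE1 != DE2 are provided:

* ``pairwise`` forms all replicate-pairwise log2 ratios (n x m per
  background) and Welch-tests the two ratio samples. The ratios are built
  from 3 + 3 values and are therefore statistically dependent, which makes
  this test anticonservative; it is retained because it matches the
  conventional pairwise-comparison recipe.
* ``groupwise`` t-tests the difference of background-wise mean ratios with
  replicate-propagated variance and Satterthwaite degrees of freedom; this
  version is calibrated and is used for null-calibration checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RegressionFit",
    "compute_de",
    "pairwise_ratio_test",
    "groupwise_ratio_test",
    "epistasis_table",
    "fit_epistasis_regression",
    "classify_tiers",
    "de_noise_variance",
]

P_FLOOR = np.finfo(float).tiny

_BACKGROUNDS = {
    "zfp36_wt": ("Dusp1KO", "WT"),
    "zfp36_aa": ("DoubleMut", "Zfp36aa"),
}


def _lps_reps(log2_matrix: pd.DataFrame, design: pd.DataFrame, genotype: str,
              timepoint: str | None) -> np.ndarray:
    sel = (design["genotype"] == genotype) & (design["treatment"] == "LPS")
    if timepoint is not None:
        sel &= design["timepoint"] == timepoint
    cols = design.loc[sel, "sample_id"].tolist()
    if len(cols) < 2:
        raise ValueError(
            f"need >= 2 LPS-treated replicates of genotype {genotype!r}"
            + (f" at {timepoint}" if timepoint else "")
        )
    return log2_matrix[cols].to_numpy(dtype=float)


def compute_de(
    log2_matrix: pd.DataFrame,
    design: pd.DataFrame,
    background: str = "zfp36_wt",
    timepoint: str | None = None,
) -> pd.Series:
    """Per-probe log2 DUSP1 effect in one *Zfp36* background.

    DE = mean(log2, Dusp1-null genotype) - mean(log2, Dusp1-wild-type
    genotype) over LPS-treated samples, i.e. the log2 geometric-mean
    expression ratio.
    """
    if background not in _BACKGROUNDS:
        raise ValueError(f"background must be one of {sorted(_BACKGROUNDS)}")
    null_g, wt_g = _BACKGROUNDS[background]
    ko = _lps_reps(log2_matrix, design, null_g, timepoint)
    wt = _lps_reps(log2_matrix, design, wt_g, timepoint)
    name = "de1_log2" if background == "zfp36_wt" else "de2_log2"
    return pd.Series(ko.mean(axis=1) - wt.mean(axis=1), index=log2_matrix.index, name=name)


def _pairwise_ratios(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """All pairwise log2 ratios; works on 1-D (single probe) or 2-D input."""
    num = np.atleast_2d(num)
    den = np.atleast_2d(den)
    return (num[:, :, None] - den[:, None, :]).reshape(num.shape[0], -1)


def _welch(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized two-sided Welch t-test p-values along axis 1.

    Degenerate rows (zero variance in both samples) get p = 1 when the
    means agree and the machine floor when they separate exactly.
    """
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    se2 = va / na + vb / nb
    degenerate = se2 <= 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(degenerate, np.where(ma == mb, 1.0, P_FLOOR), p)
    return p


def pairwise_ratio_test(wt_reps, ko_reps, zfp_reps, dbl_reps) -> float:
    """p-value for DE1 != DE2 from all pairwise replicate log2 ratios.

    Inputs are log2 replicate vectors of one probe for the four genotypes.
    All n x m ko/wt ratios (the DE1 sample) and dbl/zfp ratios (the DE2
    sample) are formed and compared by a two-sided Welch t-test. See the
    module docstring for the calibration caveat.
    """
    for reps in (wt_reps, ko_reps, zfp_reps, dbl_reps):
        if len(np.atleast_1d(reps)) < 2:
            raise ValueError("need >= 2 replicates per genotype")
    d1 = _pairwise_ratios(np.asarray(ko_reps, float), np.asarray(wt_reps, float))
    d2 = _pairwise_ratios(np.asarray(dbl_reps, float), np.asarray(zfp_reps, float))
    return float(_welch(d1, d2)[0])


def groupwise_ratio_test(wt_reps, ko_reps, zfp_reps, dbl_reps) -> float:
    """Calibrated p-value for DE1 != DE2 via propagated group variances."""
    groups = [np.atleast_2d(np.asarray(g, float)) for g in (ko_reps, wt_reps, dbl_reps, zfp_reps)]
    return float(_groupwise(*groups)[0])


def _groupwise(ko, wt, dbl, zfp) -> np.ndarray:
    diff = (ko.mean(1) - wt.mean(1)) - (dbl.mean(1) - zfp.mean(1))
    parts = [(g.var(1, ddof=1) / g.shape[1], g.shape[1] - 1) for g in (ko, wt, dbl, zfp)]
    se2 = sum(v for v, _ in parts)
    degenerate = se2 <= 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        df = se2**2 / sum(v**2 / d for v, d in parts)
        p = 2.0 * stats.t.sf(np.abs(t), df)
    return np.where(degenerate, np.where(diff == 0.0, 1.0, P_FLOOR), p)


def classify_tiers(p_diff) -> np.ndarray:
    """Significance tiers: ns / significant (p<0.01) / highly_significant (p<0.0001)."""
    p = np.asarray(p_diff, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    tiers = np.where(p < 1e-4, "highly_significant", np.where(p < 0.01, "significant", "ns"))
    return tiers


def epistasis_table(
    log2_matrix: pd.DataFrame,
    design: pd.DataFrame,
    timepoint: str | None = None,
    error_model: str = "pairwise",
) -> pd.DataFrame:
    """Per-probe DE1, DE2, DE1!=DE2 p-value and significance tier."""
    if error_model not in ("pairwise", "groupwise"):
        raise ValueError("error_model must be 'pairwise' or 'groupwise'")
    wt = _lps_reps(log2_matrix, design, "WT", timepoint)
    ko = _lps_reps(log2_matrix, design, "Dusp1KO", timepoint)
    zfp = _lps_reps(log2_matrix, design, "Zfp36aa", timepoint)
    dbl = _lps_reps(log2_matrix, design, "DoubleMut", timepoint)
    de1 = ko.mean(axis=1) - wt.mean(axis=1)
    de2 = dbl.mean(axis=1) - zfp.mean(axis=1)
    if error_model == "pairwise":
        p = _welch(_pairwise_ratios(ko, wt), _pairwise_ratios(dbl, zfp))
    else:
        p = _groupwise(ko, wt, dbl, zfp)
    return pd.DataFrame(
        {
            "de1_log2": de1,
            "de2_log2": de2,
            "p_diff": p,
            "tier": classify_tiers(p),
        },
        index=log2_matrix.index,
    )


def de_noise_variance(log2_matrix: pd.DataFrame, design: pd.DataFrame,
                      timepoint: str | None = None) -> float:
    """Average measurement variance of the DE1 estimate.

    var(DE1-hat) per probe is (s2_ko + s2_wt)/n from the replicate
    variances; the average over probes estimates the x-error variance used
    by the attenuation-corrected regression.
    """
    wt = _lps_reps(log2_matrix, design, "WT", timepoint)
    ko = _lps_reps(log2_matrix, design, "Dusp1KO", timepoint)
    v = ko.var(axis=1, ddof=1) / ko.shape[1] + wt.var(axis=1, ddof=1) / wt.shape[1]
    return float(v.mean())


@dataclass(frozen=True)
class RegressionFit:
    """Best-fit line of log2 DE2 on log2 DE1 with a 95% CI on the slope."""

    slope: float
    intercept: float
    ci_low: float
    ci_high: float
    n: int
    residual_sd: float
    mode: str
    x_error_var: float = 0.0

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n": self.n,
            "residual_sd": self.residual_sd,
            "mode": self.mode,
            "x_error_var": self.x_error_var,
        }


def fit_epistasis_regression(
    de1_log2,
    de2_log2,
    mode: str = "through_origin",
    x_error_var: float | None = None,
) -> RegressionFit:
    """Regress log2 DE2 on log2 DE1 against the slope-1 null diagonal.

    ``through_origin`` (default): slope = sum(xy) / sum(x^2), matching the
    null line through the origin; the 95% CI is the analytic t interval
    from the residual variance on n-1 degrees of freedom. With
    ``free_intercept`` an ordinary least-squares line is fitted (n-2 df).

    Because DE1 is itself a replicate average, its measurement error
    attenuates the raw slope toward zero (classical errors-in-variables
    dilution). Passing ``x_error_var`` — the average measurement variance
    of DE1, e.g. from :func:`de_noise_variance` — applies the
    method-of-moments correction ``slope = sum(xy) / (sum(x^2) - n * V)``,
    which is unbiased under the null and is what calibration checks
    should use.
    """
    x = np.asarray(de1_log2, dtype=float)
    y = np.asarray(de2_log2, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("de1 and de2 must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("DE values must be finite")
    n = x.size
    v = float(x_error_var or 0.0)
    if v < 0:
        raise ValueError("x_error_var must be >= 0")

    if mode == "through_origin":
        sxx = float(x @ x)
        if sxx == 0.0:
            raise ZeroDivisionError("slope undefined: all DE1 values are zero")
        denom = sxx - n * v
        if denom <= 0.0:
            raise ValueError("x_error_var too large: corrected sum of squares <= 0")
        slope = float(x @ y) / denom
        resid = y - slope * x
        df = n - 1
        s2 = float(resid @ resid) / df
        se = np.sqrt(s2 / denom)
        intercept = 0.0
    elif mode == "free_intercept":
        xc = x - x.mean()
        sxx = float(xc @ xc)
        if sxx == 0.0:
            raise ZeroDivisionError("slope undefined: DE1 values are constant")
        denom = sxx - n * v
        if denom <= 0.0:
            raise ValueError("x_error_var too large: corrected sum of squares <= 0")
        slope = float(xc @ (y - y.mean())) / denom
        intercept = float(y.mean() - slope * x.mean())
        resid = y - intercept - slope * x
        df = n - 2
        s2 = float(resid @ resid) / df
        se = np.sqrt(s2 / denom)
    else:
        raise ValueError("mode must be 'through_origin' or 'free_intercept'")

    tcrit = stats.t.ppf(0.975, df)
    return RegressionFit(
        slope=slope,
        intercept=intercept,
        ci_low=slope - tcrit * se,
        ci_high=slope + tcrit * se,
        n=n,
        residual_sd=float(np.sqrt(s2)),
        mode=mode,
        x_error_var=v,
    )


def bootstrap_slope_ci(
    de1_log2, de2_log2, mode: str = "through_origin", n_boot: int = 2000,
    seed: int = 0, x_error_var: float | None = None,
) -> tuple[float, float]:
    """Seeded percentile bootstrap (resampling transcripts) of the slope."""
    x = np.asarray(de1_log2, dtype=float)
    y = np.asarray(de2_log2, dtype=float)
    rng = np.random.default_rng(seed)
    slopes = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, x.size, x.size)
        slopes[i] = fit_epistasis_regression(
            x[idx], y[idx], mode=mode, x_error_var=x_error_var
        ).slope
    lo, hi = np.percentile(slopes, [2.5, 97.5])
    return float(lo), float(hi)
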