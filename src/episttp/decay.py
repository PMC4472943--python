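"""Relative qPCR quantification and mRNA half-life estimation.

Transcription-shutoff (actinomycin D/DRB) chases yield abundance time
courses normalized to a reference gene and to the zero timepoint. Under
first-order decay, abundance follows 100 * exp(-k t); the default fit is
ordinary least squares of ln(abundance) on time (equal relative error,
matching the normalization convention), giving the rate constant k, its
standard error, and the half-life t1/2 = ln 2 / k. A plateau model
y = p + (100 - p) * exp(-k t) is available for transcripts with a stable
fraction. Genotype comparisons are z-tests on the fitted rate constants,
which are the directly estimated, approximately Gaussian parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .simulate import DecaySeries

__all__ = ["DecayFit", "ddct", "fit_decay", "compare_half_lives"]

LN2 = float(np.log(2.0))


def ddct(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
) -> float:
    """Relative expression by the delta-delta-Ct method.

    2^-((Ct_target,sample - Ct_ref,sample) - (Ct_target,cal - Ct_ref,cal)),
    e.g. with Gapdh as the reference gene and an untreated or t=0 sample as
    the calibrator.
    """
    for name, ct in (
        ("ct_target_sample", ct_target_sample),
        ("ct_ref_sample", ct_ref_sample),
        ("ct_target_calibrator", ct_target_calibrator),
        ("ct_ref_calibrator", ct_ref_calibrator),
    ):
        if not np.isfinite(ct) or ct <= 0:
            raise ValueError(f"{name} must be a positive finite Ct value")
    ddct_val = (ct_target_sample - ct_ref_sample) - (
        ct_target_calibrator - ct_ref_calibrator
    )
    return float(2.0 ** (-ddct_val))


@dataclass(frozen=True)
class DecayFit:
    """First-order decay fit of one chase series."""

    gene: str
    genotype: str
    k_per_h: float  # decay rate constant; 0 when no measurable decay
    half_life_h: float  # ln2 / k; inf when no measurable decay
    se_k: float
    r_squared: float
    model: str
    no_decay: bool = False
    plateau: float | None = None


def fit_decay(series: DecaySeries, model: str = "log_linear") -> DecayFit:
    """Estimate the decay rate of one chase series.

    ``log_linear``: OLS of ln(value) on time; k = -slope; R^2 of the log
    fit. ``plateau``: nonlinear least squares of
    y = p + (100 - p) exp(-k t) with p in [0, 100).

    A non-positive fitted rate is reported as "no measurable decay" with an
    infinite half-life rather than an error.
    """
    t = np.asarray(series.timepoints_h, dtype=float)
    y = np.asarray(series.values, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 timepoints")
    if np.any(y <= 0):
        raise ValueError("abundances must be strictly positive")

    if model == "log_linear":
        res = stats.linregress(t, np.log(y))
        k = -float(res.slope)
        se = float(res.stderr)
        r2 = float(res.rvalue**2)
        plateau = None
    elif model == "plateau":
        def f(tt, p, kk):
            return p + (100.0 - p) * np.exp(-kk * tt)

        k0 = max(LN2 / max(t[-1], 1e-6), 1e-3)
        (p_hat, k), cov = optimize.curve_fit(
            f, t, y, p0=[0.0, k0], bounds=([0.0, 0.0], [100.0 - 1e-9, np.inf]),
            maxfev=10000,
        )
        se = float(np.sqrt(cov[1, 1]))
        ss_res = float(((y - f(t, p_hat, k)) ** 2).sum())
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        plateau = float(p_hat)
        k = float(k)
    else:
        raise ValueError("model must be 'log_linear' or 'plateau'")

    if k <= 0.0:
        return DecayFit(
            series.gene, series.genotype, 0.0, np.inf, se, r2, model,
            no_decay=True, plateau=plateau,
        )
    return DecayFit(
        series.gene, series.genotype, k, LN2 / k, se, r2, model, plateau=plateau
    )


def compare_half_lives(fit_a: DecayFit, fit_b: DecayFit) -> tuple[float, float]:
    """Half-life ratio a/b and a two-sided z-test on the rate constants.

    The z statistic is (k_a - k_b) / sqrt(se_a^2 + se_b^2). An infinite
    half-life on one side yields a ratio of inf (or 0); two infinite
    half-lives have no defined ratio.
    """
    if fit_a.no_decay and fit_b.no_decay:
        raise ValueError("both series show no measurable decay; ratio undefined")
    if fit_b.no_decay:
        ratio = 0.0
    elif fit_a.no_decay:
        ratio = np.inf
    else:
        ratio = fit_a.half_life_h / fit_b.half_life_h
    se2 = fit_a.se_k**2 + fit_b.se_k**2
    dk = fit_a.k_per_h - fit_b.k_per_h
    if se2 == 0.0:
        p = 1.0 if dk == 0.0 else float(np.finfo(float).tiny)
    else:
        z = dk / np.sqrt(se2)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return float(ratio), p
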