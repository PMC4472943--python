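"""Per-probe two-way ANOVA, BH step-up FDR and LPS-induction summaries.

The differential analysis treats genotype and treatment as crossed fixed
factors. For each probe of a balanced design, main-effect and interaction
F statistics come from the classical sums-of-squares decomposition, and
pairwise contrasts between cell means (LPS vs untreated within wild type;
knockout vs wild type under LPS) are t-tested against the pooled residual
variance. Multiplicity is handled by Benjamini-Hochberg step-up q-values.

Fold changes are ratios of group geometric means, i.e. differences of
log2 group means back-transformed to the linear scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "anova_two_way",
    "bh_fdr",
    "induction_analysis",
    "summarize_induction",
]

DEFAULT_FOLD_THRESHOLDS = (1.0, 3.0, 5.0, 10.0)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved.

    q_(i) = min over j >= i of m * p_(j) / j, clipped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must be finite and in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _cell_arrays(log2_matrix: pd.DataFrame, design: pd.DataFrame,
                 factors: tuple[str, str]):
    fa, fb = factors
    a_levels = list(dict.fromkeys(design[fa]))
    b_levels = list(dict.fromkeys(design[fb]))
    cells = {}
    n_per_cell = None
    for ai in a_levels:
        for bi in b_levels:
            cols = design.loc[
                (design[fa] == ai) & (design[fb] == bi), "sample_id"
            ].tolist()
            if not cols:
                raise ValueError(f"empty design cell ({ai}, {bi})")
            if n_per_cell is None:
                n_per_cell = len(cols)
            elif len(cols) != n_per_cell:
                raise ValueError("unbalanced design: unequal replicate counts per cell")
            cells[(ai, bi)] = log2_matrix[cols].to_numpy(dtype=float)
    if n_per_cell < 2:
        raise ValueError("at least 2 replicates per cell are required")
    return a_levels, b_levels, cells, n_per_cell


def anova_two_way(
    log2_matrix: pd.DataFrame,
    design: pd.DataFrame,
    factors: tuple[str, str] = ("genotype", "treatment"),
    contrasts: list[tuple[str, tuple[str, str], tuple[str, str]]] | None = None,
) -> pd.DataFrame:
    """Vectorized balanced two-way fixed-effects ANOVA per probe.

    Parameters
    ----------
    log2_matrix : DataFrame, probes x samples (log2 scale)
    design : DataFrame with ``sample_id`` and the factor columns.
    contrasts : list of (name, cell_1, cell_2)
        Each cell is an (a_level, b_level) pair; the contrast is the
        difference of cell means, t-tested with the pooled residual
        variance on the error degrees of freedom.

    Returns
    -------
    DataFrame per probe with F/p for both main effects and the
    interaction, the pooled residual variance, an ``untestable`` flag
    (zero residual variance), and per contrast ``diff_log2_*`` / ``p_*``
    columns.
    """
    fa, fb = factors
    a_levels, b_levels, cells, n = _cell_arrays(log2_matrix, design, factors)
    a, b = len(a_levels), len(b_levels)
    n_probes = len(log2_matrix)

    M = np.empty((n_probes, a, b))
    sse = np.zeros(n_probes)
    for i, ai in enumerate(a_levels):
        for j, bj in enumerate(b_levels):
            x = cells[(ai, bj)]
            M[:, i, j] = x.mean(axis=1)
            sse += ((x - M[:, i, j][:, None]) ** 2).sum(axis=1)

    grand = M.mean(axis=(1, 2))
    a_means = M.mean(axis=2)
    b_means = M.mean(axis=1)
    ssa = n * b * ((a_means - grand[:, None]) ** 2).sum(axis=1)
    ssb = n * a * ((b_means - grand[:, None]) ** 2).sum(axis=1)
    interaction = M - a_means[:, :, None] - b_means[:, None, :] + grand[:, None, None]
    ssab = n * (interaction**2).sum(axis=(1, 2))

    df_a, df_b, df_ab = a - 1, b - 1, (a - 1) * (b - 1)
    df_e = a * b * (n - 1)
    mse = sse / df_e
    untestable = mse <= 0.0

    def f_and_p(ss, df):
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (ss / df) / mse
        f = np.where(untestable, np.nan, f)
        p = np.where(np.isnan(f), np.nan, stats.f.sf(f, df, df_e))
        return f, p

    out = pd.DataFrame(index=log2_matrix.index)
    for name, ss, df in ((fa, ssa, df_a), (fb, ssb, df_b), ("interaction", ssab, df_ab)):
        f, p = f_and_p(ss, df)
        out[f"F_{name}"] = f
        out[f"p_{name}"] = p
    out["mse"] = mse
    out["df_error"] = df_e
    out["untestable"] = untestable

    for name, c1, c2 in contrasts or []:
        i1, j1 = a_levels.index(c1[0]), b_levels.index(c1[1])
        i2, j2 = a_levels.index(c2[0]), b_levels.index(c2[1])
        diff = M[:, i1, j1] - M[:, i2, j2]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = diff / np.sqrt(mse * 2.0 / n)
        p = np.where(untestable, np.nan, 2.0 * stats.t.sf(np.abs(t), df_e))
        out[f"diff_log2_{name}"] = diff
        out[f"p_{name}"] = p
    return out


def induction_analysis(
    log2_matrix: pd.DataFrame,
    design: pd.DataFrame,
    alpha: float = 0.05,
    fold_thresholds: tuple[float, ...] = DEFAULT_FOLD_THRESHOLDS,
) -> pd.DataFrame:
    """LPS-induction and knockout-dysregulation calls per probe.

    Restricted to wild-type and *Dusp1* knockout samples (the two-genotype
    comparison behind the induced/up/down bookkeeping). Computes the WT
    LPS/untreated fold change and the Dusp1KO/WT fold change under LPS
    (both geometric-mean ratios), BH q-values for the matching contrasts,
    and per-threshold induced / up_in_ko / down_in_ko flags at the given
    significance gate.
    """
    sub = design[design["genotype"].isin(["WT", "Dusp1KO"])].reset_index(drop=True)
    stats_df = anova_two_way(
        log2_matrix[sub["sample_id"].tolist()],
        sub,
        contrasts=[
            ("induction_wt", ("WT", "LPS"), ("WT", "untreated")),
            ("ko_vs_wt_lps", ("Dusp1KO", "LPS"), ("WT", "LPS")),
        ],
    )
    res = pd.DataFrame(index=stats_df.index)
    res["fold_wt_lps"] = np.exp2(stats_df["diff_log2_induction_wt"])
    res["fold_ko_vs_wt"] = np.exp2(stats_df["diff_log2_ko_vs_wt_lps"])
    res["p_induction"] = stats_df["p_induction_wt"]
    res["p_ko_vs_wt"] = stats_df["p_ko_vs_wt_lps"]
    testable = ~stats_df["untestable"]
    for col in ("p_induction", "p_ko_vs_wt"):
        q = np.full(len(res), np.nan)
        q[testable] = bh_fdr(res.loc[testable, col])
        res[col.replace("p_", "q_")] = q
    sig_ind = testable & (res["q_induction"] < alpha)
    for thr in fold_thresholds:
        res[f"induced_at_{_fmt_thr(thr)}"] = sig_ind & (res["fold_wt_lps"] > thr)
    sig_ko = testable & (res["q_ko_vs_wt"] < alpha)
    res["up_in_ko"] = sig_ko & (res["fold_ko_vs_wt"] > 1)
    res["down_in_ko"] = sig_ko & (res["fold_ko_vs_wt"] < 1)
    return res


def _fmt_thr(thr: float) -> str:
    return f"{thr:g}".replace(".", "p")


def summarize_induction(
    results: pd.DataFrame, fold_thresholds: tuple[float, ...] = DEFAULT_FOLD_THRESHOLDS
) -> pd.DataFrame:
    """Count induced transcripts and their dysregulation per fold threshold.

    One row per threshold: number of LPS-induced transcripts (fold above
    the threshold at the significance gate), and among them how many are
    significantly over-/under-expressed in the knockout, with integer
    percentages.
    """
    rows = []
    for thr in fold_thresholds:
        col = f"induced_at_{_fmt_thr(thr)}"
        if col not in results.columns:
            raise KeyError(f"missing induction flag column {col!r}")
        induced = results[col]
        n_ind = int(induced.sum())
        n_up = int((induced & results["up_in_ko"]).sum())
        n_down = int((induced & results["down_in_ko"]).sum())
        rows.append(
            {
                "fold_threshold": thr,
                "n_induced": n_ind,
                "n_up_in_ko": n_up,
                "pct_up_in_ko": round(100.0 * n_up / n_ind) if n_ind else 0,
                "n_down_in_ko": n_down,
                "pct_down_in_ko": round(100.0 * n_down / n_ind) if n_ind else 0,
            }
        )
    return pd.DataFrame(rows)
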