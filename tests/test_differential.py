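"""ANOVA against a hand sums-of-squares oracle; BH FDR against the step-up
definition; induction bookkeeping against manual enumeration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from episttp import anova_two_way, bh_fdr, induction_analysis, summarize_induction
from conftest import make_design, make_matrix


def brute_force_bh(p):
    """Literal step-up definition: q_i = min over p_(j) >= p_i of m p_(j)/rank_j."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    running = np.inf
    for idx in range(m - 1, -1, -1):
        running = min(running, m * p[order[idx]] / (idx + 1))
        q_sorted[idx] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def anova_oracle(groups):
    """Loop-based two-way SS decomposition for one probe.

    ``groups`` maps (a_level, b_level) -> replicate values.
    """
    a_levels = sorted({k[0] for k in groups})
    b_levels = sorted({k[1] for k in groups})
    n = len(next(iter(groups.values())))
    cell = {k: np.mean(v) for k, v in groups.items()}
    grand = np.mean([v for vals in groups.values() for v in vals])
    amean = {a: np.mean([cell[(a, b)] for b in b_levels]) for a in a_levels}
    bmean = {b: np.mean([cell[(a, b)] for a in a_levels]) for b in b_levels}
    ssa = n * len(b_levels) * sum((amean[a] - grand) ** 2 for a in a_levels)
    ssb = n * len(a_levels) * sum((bmean[b] - grand) ** 2 for b in b_levels)
    ssab = n * sum(
        (cell[(a, b)] - amean[a] - bmean[b] + grand) ** 2
        for a in a_levels
        for b in b_levels
    )
    sse = sum(
        (v - cell[k]) ** 2 for k, vals in groups.items() for v in vals
    )
    dfa, dfb = len(a_levels) - 1, len(b_levels) - 1
    dfab = dfa * dfb
    dfe = len(a_levels) * len(b_levels) * (n - 1)
    mse = sse / dfe
    return {
        "F_a": (ssa / dfa) / mse,
        "F_b": (ssb / dfb) / mse,
        "F_ab": (ssab / dfab) / mse,
        "mse": mse,
        "dfe": dfe,
    }


class TestBhFdr:
    def test_hand_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_and_degenerate(self):
        np.testing.assert_allclose(bh_fdr([0.04]), [0.04])
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(50):
            p = rng.random(rng.integers(1, 200))
            np.testing.assert_allclose(bh_fdr(p), brute_force_bh(p), atol=1e-12)

    def test_q_at_least_p_and_order_preserved(self, rng):
        p = rng.random(500)
        q = bh_fdr(p)
        assert (q >= p - 1e-15).all()
        assert (q <= 1.0).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestAnovaTwoWay:
    def setup_method(self):
        self.design = make_design(genotypes=("WT", "Dusp1KO"))

    def test_matches_hand_sums_of_squares(self, rng):
        groups = {
            ("WT", "untreated"): [10.0, 10.05, 9.95],
            ("WT", "LPS"): [10.02, 9.98, 10.01],
            ("Dusp1KO", "untreated"): [10.01, 10.03, 9.99],
            ("Dusp1KO", "LPS"): [13.0, 13.05, 12.95],
        }
        m = np.exp2(make_matrix(self.design, {k: [v] for k, v in groups.items()}))
        res = anova_two_way(np.log2(m), self.design)
        oracle = anova_oracle(groups)
        assert res["F_genotype"].iloc[0] == pytest.approx(oracle["F_a"], abs=1e-6)
        assert res["F_treatment"].iloc[0] == pytest.approx(oracle["F_b"], abs=1e-6)
        assert res["F_interaction"].iloc[0] == pytest.approx(oracle["F_ab"], abs=1e-6)
        assert res["mse"].iloc[0] == pytest.approx(oracle["mse"], abs=1e-9)

    def test_contrast_t_matches_pooled_formula(self):
        groups = {
            ("WT", "untreated"): [8.0, 8.1, 7.9],
            ("WT", "LPS"): [9.0, 9.1, 8.9],
            ("Dusp1KO", "untreated"): [8.0, 8.2, 7.8],
            ("Dusp1KO", "LPS"): [9.3, 9.2, 9.4],
        }
        m = np.exp2(make_matrix(self.design, {k: [v] for k, v in groups.items()}))
        res = anova_two_way(
            np.log2(m),
            self.design,
            contrasts=[("ind", ("WT", "LPS"), ("WT", "untreated"))],
        )
        mse = anova_oracle(groups)["mse"]
        diff = np.mean(groups[("WT", "LPS")]) - np.mean(groups[("WT", "untreated")])
        t = diff / np.sqrt(mse * 2 / 3)
        p = 2 * stats.t.sf(abs(t), 8)
        assert res["diff_log2_ind"].iloc[0] == pytest.approx(diff, abs=1e-9)
        assert res["p_ind"].iloc[0] == pytest.approx(p, abs=1e-9)

    def test_null_f_distribution(self, rng):
        """Equal cell means: contrast p roughly uniform, mean F near 1."""
        n_probes = 1000
        cols = {
            row["sample_id"]: np.exp2(10 + 0.3 * rng.standard_normal(n_probes))
            for _, row in self.design.iterrows()
        }
        m = pd.DataFrame(cols, index=[f"p{i}" for i in range(n_probes)])
        res = anova_two_way(
            np.log2(m),
            self.design,
            contrasts=[("c", ("Dusp1KO", "LPS"), ("WT", "LPS"))],
        )
        # E[F(d1, d2)] = d2 / (d2 - 2); here d2 = 8
        assert res["F_interaction"].mean() == pytest.approx(8 / 6, abs=0.2)
        assert res["p_c"].mean() == pytest.approx(0.5, abs=0.05)
        assert (res["p_c"] < 0.05).mean() == pytest.approx(0.05, abs=0.03)

    def test_replicate_relabeling_invariance(self, rng):
        n_probes = 20
        cols = {
            row["sample_id"]: np.exp2(8 + rng.standard_normal(n_probes))
            for _, row in self.design.iterrows()
        }
        m = pd.DataFrame(cols, index=[f"p{i}" for i in range(n_probes)])
        res1 = anova_two_way(np.log2(m), self.design)
        shuffled = self.design.copy()
        shuffled["replicate"] = shuffled.groupby(["genotype", "treatment"])["replicate"].transform(
            lambda r: r.sample(frac=1, random_state=1).to_numpy()
        )
        res2 = anova_two_way(np.log2(m), shuffled)
        pd.testing.assert_frame_equal(res1, res2)

    def test_zero_residual_variance_flagged_untestable(self):
        m = make_matrix(self.design, {}, default=100.0)
        res = anova_two_way(np.log2(m), self.design)
        assert bool(res["untestable"].iloc[0])
        assert np.isnan(res["p_genotype"].iloc[0])


class TestInductionSummary:
    def make_results(self):
        """Ten probes with hand-assigned folds and flags."""
        folds = [0.5, 2, 4, 4, 6, 6, 12, 12, 20, 1.5]
        sig = [False, True, True, False, True, True, True, True, True, True]
        up = [False, True, False, False, True, False, True, False, True, False]
        down = [False, False, True, False, False, False, False, False, False, False]
        df = pd.DataFrame({"fold_wt_lps": folds})
        for thr, name in [(1, "1"), (3, "3"), (5, "5"), (10, "10")]:
            df[f"induced_at_{name}"] = [f > thr and s for f, s in zip(folds, sig)]
        df["up_in_ko"] = up
        df["down_in_ko"] = down
        return df

    def test_counts_match_manual_enumeration(self):
        out = summarize_induction(self.make_results())
        # manual: induced@1 = probes 1,2,4,5,6,7,8,9 -> 8; up among them 5? count by hand
        assert out.loc[out.fold_threshold == 1, "n_induced"].item() == 8
        assert out.loc[out.fold_threshold == 1, "n_up_in_ko"].item() == 4
        assert out.loc[out.fold_threshold == 1, "n_down_in_ko"].item() == 1
        assert out.loc[out.fold_threshold == 3, "n_induced"].item() == 6
        assert out.loc[out.fold_threshold == 5, "n_induced"].item() == 5
        assert out.loc[out.fold_threshold == 10, "n_induced"].item() == 3
        assert out.loc[out.fold_threshold == 10, "pct_up_in_ko"].item() == 67

    def test_counts_monotone_in_threshold(self, small_experiment):
        m, d, _ = small_experiment
        res = induction_analysis(np.log2(m + 1), d)
        out = summarize_induction(res)
        counts = out["n_induced"].to_numpy()
        assert (np.diff(counts) <= 0).all()

    def test_no_induced_probes_gives_zeros(self):
        df = self.make_results().iloc[:1]  # only the non-induced probe
        out = summarize_induction(df)
        assert (out["n_induced"] == 0).all()
        assert (out["pct_up_in_ko"] == 0).all()

    def test_single_threshold_single_row(self):
        out = summarize_induction(self.make_results(), fold_thresholds=(1,))
        assert len(out) == 1


def test_induction_analysis_recovers_planted_effects(responsive_params):
    """Simulated induced genes are called induced; KO overexpression detected."""
    from episttp import simulate_experiment

    m, d, truth = simulate_experiment(responsive_params)
    res = induction_analysis(np.log2(m + 1), d)
    # every gene induced (mean log2 FC 2.5): the vast majority should be called
    assert res["induced_at_1"].mean() > 0.9
    strong = truth["dusp1_effect_log2"] > 1.0
    assert res.loc[strong.to_numpy(), "up_in_ko"].mean() > 0.8
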