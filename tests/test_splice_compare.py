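"""Group summaries, dPSI, pooled SD, Holm correction and two-way ANOVA."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from titinpsi import (
    BinCounts,
    anova_two_way,
    build_psi_table,
    delta_psi,
    pooled_sd,
    sequential_bonferroni,
    summarize_groups,
)

from conftest import metadata_frame


def table_from_psi(values: dict[str, dict[str, float]], toy_model):
    """Build a PsiTable directly from {sample: {bin: psi}} (support 1000)."""
    counts = []
    for s, bins in values.items():
        for b, psi in bins.items():
            if psi is None:
                counts.append(BinCounts(s, b, 0, 0))
            else:
                counts.append(BinCounts(s, b, round(1000 * psi),
                                        1000 - round(1000 * psi)))
    return build_psi_table(counts, toy_model, metadata_frame(list(values)))


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

class TestSummarizeGroups:
    def test_hand_computed_mean_and_sd(self, toy_model):
        vals = {f"WT_EDL_{k}": {"1": v, "2": 1.0, "3": 1.0}
                for k, v in zip((1, 2, 3), (0.2, 0.4, 0.6))}
        out = summarize_groups(table_from_psi(vals, toy_model))
        row = out[out.bin_id == "1"].iloc[0]
        assert row["mean_psi"] == pytest.approx(0.4)
        assert row["sd_psi"] == pytest.approx(0.2)
        const = out[out.bin_id == "2"].iloc[0]
        assert (const["mean_psi"], const["sd_psi"]) == (1.0, 0.0)

    def test_single_sample_group_flagged_sd_zero(self, toy_model):
        vals = {"WT_EDL_1": {"1": 0.5, "2": 0.5, "3": 0.5}}
        out = summarize_groups(table_from_psi(vals, toy_model))
        assert (out["sd_psi"] == 0).all()
        assert out["single_sample"].all()

    def test_missing_cells_excluded_from_n(self, toy_model):
        vals = {"WT_EDL_1": {"1": 0.5, "2": 0.5, "3": 0.5},
                "WT_EDL_2": {"1": None, "2": 0.7, "3": 0.7}}
        out = summarize_groups(table_from_psi(vals, toy_model))
        assert int(out[out.bin_id == "1"]["n"].iloc[0]) == 1
        assert int(out[out.bin_id == "2"]["n"].iloc[0]) == 2


# ---------------------------------------------------------------------------
# pooled SD
# ---------------------------------------------------------------------------

class TestPooledSd:
    @pytest.mark.parametrize("n1,s1,n2,s2,expected", [
        (3, 0.1, 3, 0.1, 0.1),                       # equal-variance fixed point
        (3, 0.0, 3, 0.0, 0.0),
        (4, 0.2, 3, 0.1, math.sqrt(0.028)),          # hand arithmetic
        (21, 2.14, 20, 0.97, math.sqrt((20 * 2.14**2 + 19 * 0.97**2) / 39)),
    ])
    def test_printed_formula(self, n1, s1, n2, s2, expected):
        assert pooled_sd(n1, s1, n2, s2) == pytest.approx(expected, abs=1e-12)

    def test_too_few_samples_raises(self):
        with pytest.raises(ValueError):
            pooled_sd(1, 0.1, 1, 0.1)

    @given(n1=st.integers(2, 30), n2=st.integers(2, 30),
           s1=st.floats(0, 5, allow_nan=False), s2=st.floats(0, 5, allow_nan=False),
           c=st.floats(0.01, 10, allow_nan=False))
    @settings(max_examples=200, deadline=None)
    def test_symmetry_and_homogeneity(self, n1, n2, s1, s2, c):
        """Symmetric in the two groups; degree-1 homogeneous in (s1, s2)."""
        assert pooled_sd(n1, s1, n2, s2) == pytest.approx(
            pooled_sd(n2, s2, n1, s1), rel=1e-12)
        assert pooled_sd(n1, c * s1, n2, c * s2) == pytest.approx(
            c * pooled_sd(n1, s1, n2, s2), rel=1e-9)


# ---------------------------------------------------------------------------
# dPSI
# ---------------------------------------------------------------------------

class TestDeltaPsi:
    def _summaries(self, mean_wt, mean_mdm, n=3, sd=0.05):
        return pd.DataFrame([
            {"bin_id": "1", "genotype": "WT", "muscle": "EDL", "n": n,
             "mean_psi": mean_wt, "sd_psi": sd, "single_sample": False},
            {"bin_id": "1", "genotype": "mdm", "muscle": "EDL", "n": n,
             "mean_psi": mean_mdm, "sd_psi": sd, "single_sample": False},
        ])

    def test_equal_means_zero(self):
        out = delta_psi(self._summaries(0.7, 0.7))
        assert out["dpsi"].iloc[0] == 0.0

    def test_wt_higher_inclusion_is_negative(self):
        """dPSI = mean(mdm) - mean(WT): WT-dominant inclusion prints negative."""
        out = delta_psi(self._summaries(0.9, 0.6))
        assert out["dpsi"].iloc[0] == pytest.approx(-0.3)
        assert out["sd_pooled"].iloc[0] == pytest.approx(0.05)

    def test_antisymmetric_under_label_swap(self):
        s = self._summaries(0.9, 0.6)
        fwd = delta_psi(s, case_label="mdm", control_label="WT")
        rev = delta_psi(s, case_label="WT", control_label="mdm")
        assert fwd["dpsi"].iloc[0] == pytest.approx(-rev["dpsi"].iloc[0])
        assert fwd["p_value"].iloc[0] == pytest.approx(rev["p_value"].iloc[0])

    def test_unmatched_bin_skipped_with_warning(self, caplog):
        import logging

        s = self._summaries(0.9, 0.6)
        s = s[s.genotype == "WT"]
        with caplog.at_level(logging.WARNING, logger="titinpsi"):
            out = delta_psi(s)
        assert out.empty
        assert "skipped" in caplog.text


# ---------------------------------------------------------------------------
# Holm step-down
# ---------------------------------------------------------------------------

class TestSequentialBonferroni:
    def test_single_p_unchanged(self):
        adj, sig = sequential_bonferroni([0.03], alpha=0.05)
        assert adj[0] == pytest.approx(0.03)
        assert sig[0]

    def test_hand_computed_three_values(self):
        adj, sig = sequential_bonferroni([0.01, 0.04, 0.03], alpha=0.05)
        assert adj == pytest.approx([0.03, 0.06, 0.06])
        assert list(sig) == [True, False, False]

    def test_all_ones_no_rejections(self):
        _, sig = sequential_bonferroni([1.0] * 5, alpha=0.05)
        assert not sig.any()

    def test_missing_p_propagates(self):
        adj, sig = sequential_bonferroni([0.01, np.nan, 0.04], alpha=0.05)
        assert np.isnan(adj[1]) and not sig[1]
        # m = 2 non-missing tests
        assert adj[0] == pytest.approx(0.02)

    def test_matches_statsmodels_holm(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(20):
            p = rng.uniform(0, 1, rng.integers(1, 40))
            adj, sig = sequential_bonferroni(p, alpha=0.05)
            ref_sig, ref_adj, *_ = multipletests(p, alpha=0.05, method="holm")
            assert adj == pytest.approx(ref_adj)
            assert (sig == ref_sig).all()

    def test_rejection_nesting(self, rng):
        """Bonferroni rejections ⊆ Holm rejections ⊆ unadjusted rejections."""
        alpha = 0.05
        for _ in range(200):
            p = rng.uniform(0, 1, rng.integers(1, 50)) ** 3
            m = len(p)
            _, holm = sequential_bonferroni(p, alpha)
            bonf = p <= alpha / m
            raw = p <= alpha
            assert (~bonf | holm).all()
            assert (~holm | raw).all()


# ---------------------------------------------------------------------------
# two-way ANOVA
# ---------------------------------------------------------------------------

def sum_coded_design(df):
    """Full-rank sum-to-zero coded design matrix blocks for genotype x muscle."""
    def code(levels, series):
        levels = sorted(levels)
        cols = []
        for lv in levels[:-1]:
            c = (series == lv).astype(float) - (series == levels[-1]).astype(float)
            cols.append(c.to_numpy())
        return np.column_stack(cols)

    g = code(df["genotype"].unique(), df["genotype"])
    m = code(df["muscle"].unique(), df["muscle"])
    inter = np.column_stack([g[:, i] * m[:, j]
                             for i in range(g.shape[1])
                             for j in range(m.shape[1])])
    return g, m, inter


def oracle_anova(df):
    """Type III F-tests via explicit least squares on sum-coded blocks."""
    y = df["psi"].to_numpy()
    g, m, inter = sum_coded_design(df)
    one = np.ones((len(y), 1))

    def rss(*blocks):
        X = np.column_stack([one, *blocks]) if blocks else one
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r), X.shape[1]

    rss_full, p_full = rss(g, m, inter)
    df_res = len(y) - p_full
    out = {}
    for name, reduced, q in (
        ("genotype", (m, inter), g.shape[1]),
        ("muscle", (g, inter), m.shape[1]),
        ("interaction", (g, m), inter.shape[1]),
    ):
        rss_red, _ = rss(*reduced)
        f = ((rss_red - rss_full) / q) / (rss_full / df_res)
        from scipy import stats
        out[name] = (f, float(stats.f.sf(f, q, df_res)))
    return out, df_res


def random_unbalanced_df(rng, effect_genotype=0.0, sigma=0.05):
    rows = []
    for g in ("WT", "mdm"):
        for m in ("EDL", "psoas", "soleus"):
            n = int(rng.integers(3, 7))
            mu = 0.5 + (effect_genotype if g == "mdm" else 0.0)
            for _ in range(n):
                rows.append({"psi": float(rng.normal(mu, sigma)),
                             "genotype": g, "muscle": m})
    return pd.DataFrame(rows)


class TestAnovaTwoWay:
    def test_matches_design_matrix_oracle(self, rng):
        """Type III with sum contrasts equals the explicit partial-F fit."""
        for _ in range(10):
            df = random_unbalanced_df(rng, effect_genotype=0.1)
            res = anova_two_way(df)
            exp, df_res = oracle_anova(df)
            assert res.df_residual == df_res
            assert res.f_genotype == pytest.approx(exp["genotype"][0], abs=1e-8)
            assert res.p_genotype == pytest.approx(exp["genotype"][1], abs=1e-8)
            assert res.f_muscle == pytest.approx(exp["muscle"][0], abs=1e-8)
            assert res.f_interaction == pytest.approx(exp["interaction"][0],
                                                      abs=1e-8)

    def test_balanced_design_type_i_equals_type_iii(self, rng):
        """On a balanced 2x3 design Type I and Type III sums coincide."""
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        rows = [{"psi": float(rng.normal(0.5, 0.1)), "genotype": g, "muscle": m}
                for g in ("WT", "mdm") for m in ("EDL", "psoas", "soleus")
                for _ in range(4)]
        df = pd.DataFrame(rows)
        res = anova_two_way(df)
        fit = ols("psi ~ C(genotype, Sum) * C(muscle, Sum)", data=df).fit()
        t1 = sm.stats.anova_lm(fit, typ=1)
        assert res.f_genotype == pytest.approx(
            float(t1.loc["C(genotype, Sum)", "F"]), abs=1e-8)
        assert res.f_muscle == pytest.approx(
            float(t1.loc["C(muscle, Sum)", "F"]), abs=1e-8)

    def test_injected_genotype_effect_detected(self, rng):
        """A 0.3 PSI genotype shift at sigma=0.05 is essentially always seen."""
        hits = 0
        for _ in range(20):
            df = random_unbalanced_df(rng, effect_genotype=0.3)
            if anova_two_way(df).p_genotype < 0.001:
                hits += 1
        assert hits >= 19

    def test_single_level_factor_raises(self):
        df = pd.DataFrame({"psi": [0.1, 0.2, 0.3],
                           "genotype": ["WT"] * 3,
                           "muscle": ["EDL", "psoas", "soleus"]})
        with pytest.raises(ValueError, match="two observed levels"):
            anova_two_way(df)

    def test_all_missing_bin_returns_none(self):
        df = pd.DataFrame({"psi": [np.nan, np.nan],
                           "genotype": ["WT", "mdm"],
                           "muscle": ["EDL", "EDL"]})
        assert anova_two_way(df) is None
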