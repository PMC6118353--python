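import numpy as np
import pandas as pd
import pytest

from foodwebs.core import FoodWebError
from foodwebs.stats import (
    _letters,
    fit_metric_lme,
    lme_summary_table,
    pc1_contrast,
    pca_metrics,
    simulate_metric_table,
)


@pytest.fixture(scope="module")
def fixture_table():
    """Deterministic unbalanced-effect table; reference values below were
    computed with R lmerTest/emmeans on the identical CSV."""
    return simulate_metric_table(
        n_ecosystems=7, reps=4,
        type_effects={"FS": 2.0, "BA": 0.0, "RR": 0.3},
        ecosystem_sd=1.5, residual_sd=1.0, seed=42,
    )


class TestMixedModel:
    def test_matches_reference_mixed_model(self, fixture_table):
        res = fit_metric_lme(fixture_table, "value", log_transform="off")
        # R: anova() F = 62.836, ddf = 75; VarCorr: eco 1.62584, resid 0.54946
        assert res.fstat == pytest.approx(62.836, rel=1e-3)
        assert res.df_num == 2
        assert res.df_den == pytest.approx(75.0, abs=0.1)
        assert res.var_ecosystem == pytest.approx(1.62584, rel=1e-3)
        assert res.var_residual == pytest.approx(0.54946, rel=1e-3)

    def test_tukey_matches_reference(self, fixture_table):
        res = fit_metric_lme(fixture_table, "value", log_transform="off")
        pw = res.pairwise.set_index(["a", "b"])
        # R emmeans tukey: FS-BA t=10.979 p<1e-4; BA-RR t=-3.529 p=0.0020
        assert pw.loc[("FS", "BA"), "t"] == pytest.approx(10.979, rel=1e-3)
        assert pw.loc[("BA", "RR"), "t"] == pytest.approx(-3.529, rel=1e-3)
        assert pw.loc[("BA", "RR"), "p_tukey"] == pytest.approx(0.00205, rel=0.02)
        assert res.letters == {"BA": "a", "RR": "b", "FS": "c"}

    def test_strong_effect_letter_pattern(self):
        t = simulate_metric_table(
            type_effects={"FS": 5.0, "BA": 0.0, "RR": 0.0},
            ecosystem_sd=1.0, residual_sd=1.0, seed=3,
        )
        res = fit_metric_lme(t, "value", log_transform="off")
        assert res.pvalue < 0.001
        assert res.letters["FS"] == "b"
        assert res.letters["BA"] == res.letters["RR"] == "a"

    def test_single_ecosystem_falls_back_to_anova(self):
        t = simulate_metric_table(n_ecosystems=1, reps=6, seed=1)
        res = fit_metric_lme(t, "value", log_transform="off")
        assert res.fallback_ols

    def test_letters_consistent_with_pairwise(self, fixture_table):
        res = fit_metric_lme(fixture_table, "value", log_transform="off")
        for _, row in res.pairwise.iterrows():
            shared = set(res.letters[row["a"]]) & set(res.letters[row["b"]])
            if row["p_tukey"] < 0.05:
                assert not shared
            else:
                assert shared

    def test_log_transform_auto_on_skewed_response(self):
        t = simulate_metric_table(seed=2, residual_sd=0.3, baseline=1.0)
        t["value"] = np.exp(3 * t["value"])
        res = fit_metric_lme(t, "value", log_transform="auto")
        assert res.log_transformed

    def test_letters_helper_all_nonsig(self):
        means = {"FS": 1.0, "BA": 1.1, "RR": 0.9}
        pairs = {frozenset(p) for p in [("FS", "BA"), ("FS", "RR"), ("BA", "RR")]}
        assert set(_letters(means, pairs).values()) == {"a"}


class TestPca:
    def test_rank_one_table(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=12)
        t = pd.DataFrame({
            "ecosystem": ["e"] * 12, "web_type": ["FS"] * 12,
            "m1": base, "m2": 2 * base, "m3": np.ones(12),
        })
        res = pca_metrics(t, metrics=["m1", "m2", "m3"])
        assert res.variance_pct[0] == pytest.approx(100.0)

    def test_total_variation_is_trace(self):
        rng = np.random.default_rng(1)
        t = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("abcd"))
        t["ecosystem"] = "e"
        t["web_type"] = "FS"
        res = pca_metrics(t, metrics=list("abcd"))
        assert res.total_variation == pytest.approx(
            sum(t[c].var(ddof=1) for c in "abcd")
        )
        assert res.variance_pct.sum() == pytest.approx(100.0)

    def test_scores_preserve_distances_full_rank(self):
        rng = np.random.default_rng(2)
        t = pd.DataFrame(rng.normal(size=(15, 3)), columns=list("abc"))
        t["ecosystem"] = "e"
        t["web_type"] = "FS"
        res = pca_metrics(t, metrics=list("abc"))
        Z = t[list("abc")].to_numpy() - t[list("abc")].to_numpy().mean(axis=0)
        S = res.scores.to_numpy()
        d0 = np.linalg.norm(Z[:, None] - Z[None], axis=2)
        d1 = np.linalg.norm(S[:, None] - S[None], axis=2)
        assert np.allclose(d0, d1)

    def test_constant_column_with_standardize_errors(self):
        t = pd.DataFrame({"ecosystem": ["e"] * 5, "web_type": ["FS"] * 5,
                          "m1": np.arange(5.0), "m2": np.ones(5)})
        with pytest.raises(FoodWebError, match="m2"):
            pca_metrics(t, metrics=["m1", "m2"], standardize=True)


class TestPc1Contrast:
    def test_equals_lme_on_score_column(self, fixture_table):
        t = fixture_table.rename(columns={"value": "m1"}).copy()
        rng = np.random.default_rng(5)
        t["m2"] = rng.normal(size=len(t))
        pca = pca_metrics(t, metrics=["m1", "m2"])
        res = pc1_contrast(pca, t)
        direct_tab = t[["ecosystem", "web_type"]].copy()
        direct_tab["score"] = pca.scores["PC1"].to_numpy()
        direct = fit_metric_lme(direct_tab, "score", log_transform="off")
        assert res.fstat == pytest.approx(direct.fstat)
        assert res.pvalue == pytest.approx(direct.pvalue)

    def test_permuting_labels_destroys_signal(self, fixture_table):
        t = fixture_table.copy()
        rng = np.random.default_rng(0)
        hits = 0
        n = 40
        for k in range(n):
            t2 = t.copy()
            t2["web_type"] = rng.permutation(t2["web_type"].to_numpy())
            res = fit_metric_lme(t2, "value", log_transform="off")
            hits += res.pvalue < 0.05
        assert hits / n < 0.2  # near-nominal once type labels are shuffled


def test_summary_table_shape(fixture_table):
    t = fixture_table.rename(columns={"value": "species_number"})
    out = lme_summary_table(t, metrics=["species_number"])
    assert {"FS_mean", "BA_se", "F", "p", "letters", "signif"} <= set(out.columns)
    assert len(out) == 1
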