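"""Factorial linear model, Type II F tests, BH-FDR and the LRT."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from diffmet import diffabund, synth
from diffmet.diffabund import (
    ConfigurationError,
    DesignError,
    fdr_adjust,
    fit_model,
    lrt_interaction,
    subset_warm_cool,
)
from conftest import make_table, two_condition_design


def _single_factor_table(y, levels):
    ann = pd.DataFrame({"sex": ["male"] * len(y), "group": levels})
    return make_table(np.asarray(y, dtype=float)[None, :], sample_ann=ann)


def _factorial_table(n_features=3, seed=0, sex="male"):
    """Full 4x2x4 design, one sex, iid normal responses."""
    design = synth.generate_design(synth.DesignSpec(technical_duplicates=1))
    design = design[design["sex"] == sex]
    rng = np.random.default_rng(seed)
    vals = rng.normal(size=(n_features, len(design)))
    feats = pd.DataFrame(
        {"mz": 100.0, "rt": 60.0, "column": "C18", "snr": 20.0},
        index=pd.Index([f"F{i + 1:04d}" for i in range(n_features)], name="feature_id"),
    )
    intens = pd.DataFrame(vals, index=feats.index, columns=design.index)
    from diffmet.datatypes import FeatureTable

    return FeatureTable(intens, feats, design)


class TestFitModel:
    def test_closed_form_single_factor(self):
        # y=(1,2,3,4), groups (a,a,b,b): effect 2, F = (SSR/1)/(SSE/2) = 8
        t = _single_factor_table([1, 2, 3, 4], ["a", "a", "b", "b"])
        res = fit_model(t, factors=("group",))
        row = res.stats.iloc[0]
        assert row["F"] == pytest.approx(8.0)
        assert res.coefficients.loc["F0001", "group[b]"] == pytest.approx(2.0)

    def test_constant_response_gives_f_zero_p_one(self):
        t = _single_factor_table([5, 5, 5, 5], ["a", "a", "b", "b"])
        res = fit_model(t, factors=("group",))
        assert (res.stats["F"] == 0).all()
        assert (res.stats["p"] == 1).all()

    def test_matches_statsmodels_type2_anova(self):
        t = _factorial_table(n_features=4, seed=5)
        res = fit_model(t)
        formula = (
            "y ~ C(dev_temp)*C(adult_temp) + C(dev_temp)*C(genotype) "
            "+ C(adult_temp)*C(genotype)"
        )
        name_map = {
            "C(dev_temp)": "dev_temp",
            "C(adult_temp)": "adult_temp",
            "C(genotype)": "genotype",
            "C(dev_temp):C(adult_temp)": "dev_temp:adult_temp",
            "C(dev_temp):C(genotype)": "dev_temp:genotype",
            "C(adult_temp):C(genotype)": "adult_temp:genotype",
        }
        for fid in t.feature_ids:
            df = t.samples.assign(y=t.intensities.loc[fid].to_numpy())
            ref = anova_lm(smf.ols(formula, df).fit(), typ=2)
            mine = res.stats[res.stats["feature"] == fid].set_index("term")
            for sm_name, term in name_map.items():
                assert mine.loc[term, "F"] == pytest.approx(ref.loc[sm_name, "F"], rel=1e-8)
                assert mine.loc[term, "p"] == pytest.approx(ref.loc[sm_name, "PR(>F)"], rel=1e-8)

    def test_null_pvalues_uniform(self):
        t = _factorial_table(n_features=400, seed=11)
        res = fit_model(t)
        from scipy import stats as sps

        for term in ("dev_temp", "adult_temp", "genotype"):
            p = res.stats.loc[res.stats["term"] == term, "p"].to_numpy()
            assert sps.kstest(p, "uniform").pvalue > 0.01

    def test_rank_deficient_design_reports_aliased_terms(self):
        # dev_temp confounded with adult_temp (only 18->18 and 27->27 cells)
        design = two_condition_design(6)
        rng = np.random.default_rng(0)
        from diffmet.datatypes import FeatureTable

        feats = pd.DataFrame(
            {"mz": [100.0], "rt": [60.0], "column": ["C18"], "snr": [20.0]},
            index=pd.Index(["F0001"], name="feature_id"),
        )
        intens = pd.DataFrame(
            rng.normal(size=(1, len(design))), index=feats.index, columns=design.index
        )
        t = FeatureTable(intens, feats, design)
        with pytest.raises((DesignError, ConfigurationError)):
            fit_model(t, factors=("dev_temp", "adult_temp"))

    def test_missing_sex_rejected(self):
        t = _factorial_table()
        with pytest.raises(ConfigurationError):
            fit_model(t, sex="other")


class TestFdrAdjust:
    def test_bh_by_hand(self):
        flags, adj = fdr_adjust([0.001, 0.02, 0.03, 0.04], q=0.05)
        assert adj == pytest.approx([0.004, 0.04, 0.04, 0.04])
        assert flags.all()

    def test_all_ones_nothing_significant(self):
        flags, adj = fdr_adjust([1.0, 1.0, 1.0], q=0.05)
        assert not flags.any() and (adj == 1).all()

    def test_single_pvalue_unchanged(self):
        _, adj = fdr_adjust([0.03], q=0.05)
        assert adj == pytest.approx([0.03])

    def test_matches_bruteforce_oracle(self):
        def bh_oracle(p):
            p = np.asarray(p, float)
            m = len(p)
            order = np.argsort(p)
            adj = p[order] * m / (np.arange(m) + 1)
            adj = np.minimum.accumulate(adj[::-1])[::-1]  # cummin from largest rank
            out = np.empty(m)
            out[order] = np.minimum(adj, 1.0)
            return out

        rng = np.random.default_rng(2)
        for _ in range(100):
            p = rng.random(rng.integers(1, 40))
            _, adj = fdr_adjust(p, q=0.05)
            assert np.allclose(adj, bh_oracle(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.5])

    def test_flags_monotone_in_q(self):
        rng = np.random.default_rng(3)
        p = rng.random(50) ** 2
        f1, _ = fdr_adjust(p, q=0.01)
        f2, _ = fdr_adjust(p, q=0.10)
        assert (f2 | ~f1).all()  # every q=0.01 discovery survives at q=0.10


class TestLrtInteraction:
    def test_unknown_term_rejected(self):
        t = _factorial_table()
        with pytest.raises(ConfigurationError):
            lrt_interaction(t, "dev_temp:batch")

    def test_planted_interaction_detected(self):
        # 2-SD dev_temp x genotype interaction: LRT p < 0.01 nearly always
        design = synth.generate_design(
            synth.DesignSpec(genotypes=("g1", "g2"), sexes=("f",),
                             biological_replicates=24, technical_duplicates=1)
        )
        rng = np.random.default_rng(8)
        hits = 0
        n_sim = 20
        from diffmet.datatypes import FeatureTable

        feats = pd.DataFrame(
            {"mz": [100.0], "rt": [60.0], "column": ["C18"], "snr": [20.0]},
            index=pd.Index(["F0001"], name="feature_id"),
        )
        inter = (
            ((design["dev_temp"] == 27) & (design["genotype"] == "g2")).to_numpy() * 2.0
        )
        for _ in range(n_sim):
            y = rng.normal(size=len(design)) + inter
            t = FeatureTable(
                pd.DataFrame(y[None, :], index=feats.index, columns=design.index),
                feats, design,
            )
            p = lrt_interaction(t, "dev_temp:genotype")["p"].iloc[0]
            hits += p < 0.01
        assert hits >= 0.9 * n_sim

    def test_null_statistic_matches_exact_finite_sample_law(self):
        # Under the null, n*log(RSS_r/RSS_f) = n*log(1 + df1/df2 * F) with
        # F ~ F(df1, df2): invert and check uniformity of the exact p-values.
        t = _factorial_table(n_features=300, seed=21)
        out = lrt_interaction(t, "dev_temp:adult_temp")
        from scipy import stats as sps

        from diffmet.diffabund import build_design_matrix

        X, _, _ = build_design_matrix(t.samples)
        n, rank = X.shape[0], np.linalg.matrix_rank(X)
        df1, df2 = out["df"].iloc[0], n - rank
        f_equiv = (np.exp(out["statistic"] / n) - 1) * df2 / df1
        p_exact = sps.f.sf(f_equiv, df1, df2)
        assert sps.kstest(p_exact, "uniform").pvalue > 0.01


class TestSubsetWarmCool:
    def test_keeps_half_of_default_design(self):
        t = _factorial_table(sex="male")
        out = subset_warm_cool(t)
        assert out.n_samples == t.n_samples / 2
        assert sorted(out.samples["temperature"].unique()) == [18, 27]

    def test_combined_factor_has_two_levels(self):
        t = _factorial_table()
        out = subset_warm_cool(t)
        assert out.samples["temperature"].nunique() == 2
        assert (out.samples["dev_temp"] == out.samples["adult_temp"]).all()

    def test_empty_subset_is_error(self):
        design = synth.generate_design(
            synth.DesignSpec(temperature_groups=((18, 27),), biological_replicates=2)
        )
        rng = np.random.default_rng(0)
        from diffmet.datatypes import FeatureTable

        feats = pd.DataFrame(
            {"mz": [100.0], "rt": [60.0], "column": ["C18"], "snr": [20.0]},
            index=pd.Index(["F0001"], name="feature_id"),
        )
        t = FeatureTable(
            pd.DataFrame(rng.normal(size=(1, len(design))), index=feats.index,
                         columns=design.index),
            feats, design,
        )
        with pytest.raises(ConfigurationError):
            subset_warm_cool(t)
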