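"""Weighted trait meta-models, Type III tests, nesting and variance components."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from statsmodels.stats.anova import anova_lm

from flightline.traits_meta import (
    TRAIT_MODEL_FORMULAS,
    compare_models,
    fit_trait_models,
    make_weights,
    meta_table,
    type3_anova,
    variance_components,
    weighted_lm,
)


def random_meta(rng, n=38, interaction=-0.08, sd_resid=2.0):
    volt = rng.choice([1.0, 2.0, 3.0, 3.5, 4.0], n)
    onset = rng.uniform(70, 200, n)
    stage = rng.choice(["larva", "pupa", "adult"], n)
    sens = -4.7 + interaction * volt * (onset - 120) / 10 + rng.normal(0, sd_resid, n)
    return pd.DataFrame(
        {
            "species": [f"sp{i}" for i in range(n)],
            "sensitivity": sens,
            "voltinism": volt,
            "mean_onset": onset,
            "overwinter_stage": stage,
            "sd_onset": rng.uniform(4, 35, n),
        }
    )


def test_equal_weights_reduce_to_ols(rng):
    df = random_meta(rng)
    w = np.full(len(df), 2.7)
    res_w = weighted_lm("sensitivity ~ voltinism * mean_onset", df, w)
    res_o = sm.OLS(
        df["sensitivity"],
        sm.add_constant(
            np.column_stack(
                [df.voltinism, df.mean_onset, df.voltinism * df.mean_onset]
            )
        ),
    ).fit()
    np.testing.assert_allclose(np.sort(res_w.params), np.sort(res_o.params), rtol=1e-9)


def test_wls_matches_weighted_normal_equations(rng):
    for _ in range(25):
        df = random_meta(rng, n=int(rng.integers(15, 50)))
        w = 1.0 / df["sd_onset"].to_numpy()
        res = weighted_lm("sensitivity ~ voltinism * mean_onset", df, w)
        X = np.column_stack(
            [
                np.ones(len(df)),
                df.voltinism,
                df.mean_onset,
                df.voltinism * df.mean_onset,
            ]
        )
        W = np.diag(w)
        beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ df["sensitivity"].to_numpy())
        np.testing.assert_allclose(res.params.to_numpy(), beta, rtol=1e-10)


def test_weights_rules_and_guards(rng):
    sd = pd.Series([2.0, 4.0])
    assert make_weights(sd, "inv_sd").tolist() == [0.5, 0.25]
    assert make_weights(sd, "inv_var").tolist() == [0.25, 0.0625]
    with pytest.raises(ValueError):
        make_weights(pd.Series([2.0, 0.0]))
    df = random_meta(rng, n=10)
    with pytest.raises(ValueError, match="sp3"):
        weighted_lm(
            "sensitivity ~ voltinism", df, np.where(np.arange(10) == 3, -1.0, 1.0)
        )


def test_estimates_invariant_to_weight_rescaling(rng):
    df = random_meta(rng)
    w = 1.0 / df["sd_onset"].to_numpy()
    a = weighted_lm("sensitivity ~ voltinism * mean_onset", df, w)
    b = weighted_lm("sensitivity ~ voltinism * mean_onset", df, 17.3 * w)
    np.testing.assert_allclose(a.params, b.params, rtol=1e-10)
    np.testing.assert_allclose(a.bse, b.bse, rtol=1e-10)


def test_rank_deficient_design_raises(rng):
    df = random_meta(rng, n=12)
    df["volt_copy"] = df["voltinism"]
    with pytest.raises(ValueError, match="rank"):
        weighted_lm("sensitivity ~ voltinism + volt_copy", df, np.ones(12))


def test_type3_f_equals_t_squared_for_continuous_terms(rng):
    df = random_meta(rng)
    res = weighted_lm(
        "sensitivity ~ voltinism * mean_onset", df, 1.0 / df["sd_onset"]
    )
    tab = type3_anova(res).set_index("term")
    t = res.tvalues["voltinism:mean_onset"]
    assert tab.loc["voltinism:mean_onset", "F"] == pytest.approx(t**2, rel=1e-8)
    for term in ("voltinism", "mean_onset"):
        assert tab.loc[term, "F"] == pytest.approx(res.tvalues[term] ** 2, rel=1e-8)


def test_type3_matches_statsmodels_anova_lm(rng):
    df = random_meta(rng)
    res = weighted_lm(
        "sensitivity ~ voltinism * C(overwinter_stage, Sum)",
        df,
        1.0 / df["sd_onset"],
    )
    mine = type3_anova(res).set_index("term")
    ref = anova_lm(res, typ=3)
    for term in mine.index:
        assert mine.loc[term, "F"] == pytest.approx(ref.loc[term, "F"], rel=1e-8)
        assert mine.loc[term, "p_value"] == pytest.approx(
            ref.loc[term, "PR(>F)"], rel=1e-8
        )


def test_type3_equals_type1_on_balanced_and_orthogonal_designs(rng):
    # balanced two-level factor crossed with a centered covariate whose
    # values repeat identically in each cell -> orthogonal design
    stage = np.repeat(["larva", "adult"], 12)
    z = np.tile(np.arange(-5.5, 6.5), 2)
    y = 1.0 + 0.5 * z + (stage == "larva") * 2.0 + rng.normal(0, 1, 24)
    df = pd.DataFrame({"y": y, "z": z, "stage": stage, "species": range(24)})
    res = weighted_lm("y ~ z + C(stage, Sum)", df, np.ones(24))
    t3 = type3_anova(res).set_index("term")
    t1 = anova_lm(res, typ=1)
    for term in t3.index:
        assert t3.loc[term, "F"] == pytest.approx(t1.loc[term, "F"], rel=1e-8)


def test_interaction_f_invariant_to_centering_mean_onset(rng):
    df = random_meta(rng)
    w = 1.0 / df["sd_onset"]
    f1 = type3_anova(
        weighted_lm("sensitivity ~ voltinism * mean_onset", df, w)
    ).set_index("term")
    df2 = df.assign(mean_onset=df["mean_onset"] - df["mean_onset"].mean())
    f2 = type3_anova(
        weighted_lm("sensitivity ~ voltinism * mean_onset", df2, w)
    ).set_index("term")
    assert f1.loc["voltinism:mean_onset", "F"] == pytest.approx(
        f2.loc["voltinism:mean_onset", "F"], rel=1e-8
    )


def test_compare_models_guards_and_hand_computed_toy():
    # 6-point toy with hand-computed residual sums of squares
    df = pd.DataFrame(
        {
            "species": list("abcdef"),
            "y": [1.0, 2.0, 2.0, 3.0, 5.0, 4.0],
            "x": [0.0, 1.0, 2.0, 3.0, 4.0, 5.0],
            "z": [0.0, 1.0, 0.0, 1.0, 0.0, 1.0],
        }
    )
    w = np.ones(6)
    small = weighted_lm("y ~ x", df, w)
    large = weighted_lm("y ~ x + z", df, w)
    f, df1, df2, p = compare_models(small, large)
    # oracle: explicit normal-equation fits and RSS differences
    X1 = np.column_stack([np.ones(6), df.x])
    X2 = np.column_stack([np.ones(6), df.x, df.z])
    y = df["y"].to_numpy()
    rss = []
    for X in (X1, X2):
        b = np.linalg.lstsq(X, y, rcond=None)[0]
        rss.append(float(np.sum((y - X @ b) ** 2)))
    f_oracle = (rss[0] - rss[1]) / 1 / (rss[1] / 3)
    assert f == pytest.approx(f_oracle, rel=1e-10)
    assert (df1, df2) == (1, 3.0)
    with pytest.raises(ValueError, match="identical"):
        compare_models(small, small)
    other = weighted_lm("y ~ z", df, w)
    with pytest.raises(ValueError, match="nested"):
        compare_models(other, weighted_lm("y ~ x", df, w))


def test_adding_pure_noise_column_gives_uniform_comparison_p(rng):
    n, reps, hits = 30, 400, 0
    for _ in range(reps):
        df = pd.DataFrame(
            {
                "species": range(n),
                "y": rng.normal(size=n),
                "x": rng.normal(size=n),
                "noise": rng.normal(size=n),
            }
        )
        small = weighted_lm("y ~ x", df, np.ones(n))
        large = weighted_lm("y ~ x + noise", df, np.ones(n))
        hits += compare_models(small, large)[3] < 0.05
    se = np.sqrt(0.05 * 0.95 / reps)
    assert abs(hits / reps - 0.05) < 3 * se


def test_meta_table_drops_flagged_fits_and_missing_traits():
    fits = pd.DataFrame(
        {
            "species": ["a", "b", "c"],
            "slope": [-3.0, np.nan, -5.0],
            "mean_onset": [100.0, np.nan, 150.0],
            "sd_onset": [8.0, np.nan, 12.0],
            "ok": [True, False, True],
        }
    )
    traits = pd.DataFrame(
        {
            "species": ["a", "b", "c"],
            "voltinism": [2.0, 1.0, np.nan],
            "overwinter_stage": ["larva", "pupa", "adult"],
            "family": ["F", "F", "F"],
            "subfamily": ["S", "S", "S"],
            "genus": ["G1", "G2", "G3"],
        }
    )
    meta = meta_table(fits, traits)
    assert list(meta["species"]) == ["a"]
    assert dict(meta.attrs["dropped"]) == {
        "b": "no valid sensitivity fit",
        "c": "incomplete traits",
    }


def balanced_taxon_frame(rng, s2=(4.0, 2.0, 1.0, 1.0), a=6, b=2, c=3, n=3):
    rows = []
    for f in range(a):
        ef = rng.normal(0, np.sqrt(s2[0]))
        for s in range(b):
            es = rng.normal(0, np.sqrt(s2[1]))
            for g in range(c):
                eg = rng.normal(0, np.sqrt(s2[2]))
                for i in range(n):
                    rows.append(
                        {
                            "family": f"F{f}",
                            "subfamily": f"S{f}_{s}",
                            "genus": f"G{f}_{s}_{g}",
                            "sensitivity": ef + es + eg + rng.normal(0, np.sqrt(s2[3])),
                        }
                    )
    return pd.DataFrame(rows)


def ems_oracle(df, a, b, c, n):
    """Balanced nested ANOVA expected-mean-squares estimators."""
    gm = df["sensitivity"].mean()
    fam = df.groupby("family")["sensitivity"].mean()
    sub = df.groupby(["family", "subfamily"])["sensitivity"].mean()
    gen = df.groupby(["family", "subfamily", "genus"])["sensitivity"].mean()
    ms_fam = b * c * n * ((fam - gm) ** 2).sum() / (a - 1)
    dev_sub = sub - fam.reindex(sub.index.get_level_values(0)).to_numpy()
    ms_sub = c * n * (dev_sub**2).sum() / (a * (b - 1))
    dev_gen = gen - sub.reindex(gen.index.droplevel("genus")).to_numpy()
    ms_gen = n * (dev_gen**2).sum() / (a * b * (c - 1))
    cell_mean = df.groupby(["family", "subfamily", "genus"])["sensitivity"].transform(
        "mean"
    )
    ms_res = ((df["sensitivity"] - cell_mean) ** 2).sum() / (a * b * c * (n - 1))
    s_res = ms_res
    s_gen = (ms_gen - ms_res) / n
    s_sub = (ms_sub - ms_gen) / (c * n)
    s_fam = (ms_fam - ms_sub) / (b * c * n)
    return s_fam, s_sub, s_gen, s_res


def test_variance_components_match_balanced_anova_oracle(rng):
    # REML on a balanced nested design with interior estimates equals the
    # classical ANOVA estimators
    df = balanced_taxon_frame(rng, a=8, b=2, c=3, n=3)
    s_fam, s_sub, s_gen, s_res = ems_oracle(df, 8, 2, 3, 3)
    assert min(s_fam, s_sub, s_gen, s_res) > 0, "need an interior case"
    vc = variance_components(df)
    assert vc.family == pytest.approx(s_fam, rel=2e-3, abs=1e-3)
    assert vc.subfamily == pytest.approx(s_sub, rel=2e-3, abs=1e-3)
    assert vc.genus == pytest.approx(s_gen, rel=2e-3, abs=1e-3)
    assert vc.residual == pytest.approx(s_res, rel=2e-3, abs=1e-3)
    assert sum(vc.percentages().values()) == pytest.approx(100.0, abs=1e-6)


def test_variance_components_degenerate_constant_within_genus():
    # genus means balanced so family/subfamily contribute exactly nothing
    rows = []
    for f in range(2):
        for s in range(2):
            for g, mean in enumerate((-3.0, 0.0, 3.0)):
                for i in range(3):
                    rows.append(
                        {
                            "family": f"F{f}",
                            "subfamily": f"S{f}_{s}",
                            "genus": f"G{f}_{s}_{g}",
                            "sensitivity": mean,
                        }
                    )
    vc = variance_components(pd.DataFrame(rows))
    pct = vc.percentages()
    assert vc.pct_genus_or_below > 99.0
    assert pct["residual"] < 1.0
    assert pct["family"] + pct["subfamily"] < 1.0


def test_inconsistent_nesting_is_rejected():
    df = pd.DataFrame(
        {
            "family": ["F1", "F2"],
            "subfamily": ["S1", "S1"],
            "genus": ["G1", "G2"],
            "sensitivity": [1.0, 2.0],
        }
    )
    with pytest.raises(ValueError, match="inconsistent taxonomy"):
        variance_components(df)


def test_standard_model_set_fits_and_reports(rng):
    df = random_meta(rng)
    models = fit_trait_models(df)
    assert set(models) == set(TRAIT_MODEL_FORMULAS)
    tab = type3_anova(models["interaction"])
    assert {"voltinism", "mean_onset", "voltinism:mean_onset"} == set(tab["term"])
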