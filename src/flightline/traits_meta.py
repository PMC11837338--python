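"""Trait meta-models of phenological sensitivity across species.

Species-level sensitivity slopes are modelled as a function of traits —
voltinism (continuous generations/year, range midpoints when variable),
overwintering stage (larva/pupa/adult) and mean onset date — by weighted
least squares.  Species whose onset dates are highly variable yield less
precise slopes, so observations are weighted inversely by the standard
deviation of onset date (1/SD; the conventional 1/SD^2 is available via
``weight_rule``).

Inference uses marginal (Type III) per-term F tests, valid in the
presence of interactions provided factors carry sum-to-zero contrasts,
nested-model comparison by extra-sum-of-squares F tests, and a
taxonomic variance-components decomposition (nested random intercepts
for family / subfamily / genus, REML) to gauge phylogenetic signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
import statsmodels.formula.api as smf

#: The standard model set, in increasing complexity.  Factors use
#: sum-to-zero contrasts so Type III tests are meaningful.
TRAIT_MODEL_FORMULAS: dict[str, str] = {
    "voltinism_only": "sensitivity ~ voltinism",
    "additive": "sensitivity ~ voltinism + mean_onset",
    "interaction": "sensitivity ~ voltinism * mean_onset",
    "voltinism_x_stage": "sensitivity ~ voltinism * C(overwinter_stage, Sum)",
    "interaction_plus_stage": "sensitivity ~ voltinism * mean_onset"
    " + C(overwinter_stage, Sum)",
}


@dataclass(frozen=True)
class VarianceComponents:
    """Variance of sensitivity attributed to nested taxonomic levels.

    With (near-)one species per genus the genus component is confounded
    with the residual; ``pct_genus_or_below`` reports their sum, the
    quantity that remains identifiable.
    """

    family: float
    subfamily: float
    genus: float
    residual: float
    converged: bool = True

    @property
    def total(self) -> float:
        return self.family + self.subfamily + self.genus + self.residual

    def percentages(self) -> dict[str, float]:
        t = self.total
        return {
            "family": 100.0 * self.family / t,
            "subfamily": 100.0 * self.subfamily / t,
            "genus": 100.0 * self.genus / t,
            "residual": 100.0 * self.residual / t,
        }

    @property
    def pct_genus_or_below(self) -> float:
        p = self.percentages()
        return p["genus"] + p["residual"]


def meta_table(
    fits: pd.DataFrame,
    traits: pd.DataFrame,
    sd_floor: float = 0.0,
) -> pd.DataFrame:
    """Join per-species sensitivity fits with traits into one meta row per species.

    Species with a flagged (null) fit, missing traits, or sd_onset at or
    below ``sd_floor`` are dropped with a note column in the returned
    frame's ``.attrs["dropped"]``.
    """
    df = fits.merge(traits, on="species", how="left", validate="1:1")
    dropped = []
    ok = df["ok"].astype(bool) if "ok" in df else pd.Series(True, index=df.index)
    for _, row in df[~ok].iterrows():
        dropped.append((row["species"], "no valid sensitivity fit"))
    df = df[ok]
    incomplete = df[["voltinism", "overwinter_stage", "family"]].isna().any(axis=1)
    for _, row in df[incomplete].iterrows():
        dropped.append((row["species"], "incomplete traits"))
    df = df[~incomplete]
    bad_sd = df["sd_onset"] <= sd_floor
    for _, row in df[bad_sd].iterrows():
        dropped.append((row["species"], "non-positive onset SD"))
    df = df[~bad_sd]
    out = df.rename(columns={"slope": "sensitivity"}).reset_index(drop=True)
    out.attrs["dropped"] = dropped
    return out


def make_weights(sd_onset: pd.Series, rule: str = "inv_sd") -> pd.Series:
    """Observation weights from onset-date variability.

    ``inv_sd`` (default) weights by 1/SD; ``inv_var`` by 1/SD^2.
    """
    sd = pd.Series(sd_onset, dtype=float)
    bad = ~(sd > 0)
    if bad.any():
        raise ValueError(
            f"non-positive onset SD at rows {list(sd.index[bad])}; "
            "weights must be strictly positive"
        )
    if rule == "inv_sd":
        return 1.0 / sd
    if rule == "inv_var":
        return 1.0 / sd**2
    raise ValueError(f"unknown weight rule: {rule!r}")


def weighted_lm(formula: str, data: pd.DataFrame, weights) -> sm.regression.linear_model.RegressionResultsWrapper:
    """Weighted least squares via a model formula.

    Weights multiply squared residuals (the R ``lm(weights=)``
    convention), so estimates are invariant to rescaling all weights by
    a positive constant.
    """
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0) or np.any(~np.isfinite(w)):
        i = int(np.flatnonzero((w <= 0) | ~np.isfinite(w))[0])
        name = data.iloc[i].get("species", i)
        raise ValueError(f"non-positive weight for {name}")
    model = smf.wls(formula, data=data, weights=w)
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        raise ValueError(f"rank-deficient design for formula {formula!r}")
    return model.fit()


def fit_trait_models(
    meta: pd.DataFrame,
    weight_rule: str = "inv_sd",
    formulas: dict[str, str] | None = None,
) -> dict[str, sm.regression.linear_model.RegressionResultsWrapper]:
    """Fit the standard trait model set on one meta table."""
    w = make_weights(meta["sd_onset"], rule=weight_rule)
    return {
        name: weighted_lm(f, meta, w)
        for name, f in (formulas or TRAIT_MODEL_FORMULAS).items()
    }


def type3_anova(result) -> pd.DataFrame:
    """Marginal (Type III) F test for each term of a fitted (W)LS model.

    Each term's F compares the full model against the full model with
    that term's columns removed, on the same weights.  For a single-df
    continuous term this equals the square of the coefficient's t.
    Factors must be coded with sum-to-zero contrasts for the tests to be
    interpretable; the model-set formulas here use ``C(..., Sum)``.
    """
    model = result.model
    design_info = model.data.design_info
    exog = np.asarray(model.exog, dtype=float)
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        raise ValueError("aliased terms in design; Type III tests undefined")
    y = np.asarray(model.endog, dtype=float)
    w = getattr(model, "weights", np.ones(len(y)))

    rss_full = float(result.ssr)
    df_resid = float(result.df_resid)
    rows = []
    for term in design_info.terms:
        name = term.name()
        if name == "Intercept":
            continue
        sl = design_info.term_name_slices[name]
        q = sl.stop - sl.start
        keep = np.ones(exog.shape[1], dtype=bool)
        keep[sl] = False
        reduced = sm.WLS(y, exog[:, keep], weights=w).fit()
        f = ((float(reduced.ssr) - rss_full) / q) / (rss_full / df_resid)
        from scipy import stats as _st

        p = float(_st.f.sf(f, q, df_resid))
        rows.append(
            {"term": name, "F": f, "df_num": q, "df_den": df_resid, "p_value": p}
        )
    return pd.DataFrame(rows, columns=["term", "F", "df_num", "df_den", "p_value"])


def compare_models(small, large) -> tuple[float, int, float, float]:
    """Extra-sum-of-squares F test between nested (W)LS fits.

    Returns ``(F, df1, df2, p)``.  The smaller model's terms must be a
    strict subset of the larger's, fitted on identical rows and weights.
    """
    small_terms = set(small.model.data.design_info.term_names)
    large_terms = set(large.model.data.design_info.term_names)
    if small_terms == large_terms:
        raise ValueError("models are identical; comparison F is undefined")
    if not small_terms < large_terms:
        raise ValueError("models are not nested")
    if small.nobs != large.nobs:
        raise ValueError("models were fitted on different rows")
    w_small = getattr(small.model, "weights", None)
    w_large = getattr(large.model, "weights", None)
    if w_small is not None and w_large is not None and not np.allclose(
        w_small, w_large
    ):
        raise ValueError("models carry different weights")

    df1 = int(small.df_resid - large.df_resid)
    df2 = float(large.df_resid)
    f = ((float(small.ssr) - float(large.ssr)) / df1) / (float(large.ssr) / df2)
    from scipy import stats as _st

    p = float(_st.f.sf(f, df1, df2))
    return f, df1, df2, p


def _check_nesting(taxonomy: pd.DataFrame) -> None:
    for child, parent in (("genus", "subfamily"), ("subfamily", "family")):
        counts = taxonomy.groupby(child)[parent].nunique()
        bad = counts[counts > 1]
        if len(bad):
            raise ValueError(
                f"inconsistent taxonomy: {child} {bad.index[0]!r} maps to "
                f"multiple {parent} values"
            )


def variance_components(
    data: pd.DataFrame,
    response: str = "sensitivity",
) -> VarianceComponents:
    """Nested taxonomic variance-components decomposition by REML.

    Fits random intercepts for family, subfamily-in-family and
    genus-in-subfamily (labels must be globally unique across branches,
    which :func:`_check_nesting` enforces indirectly), with species as
    the residual level.  Components are non-negative by construction;
    singular fits come back with zero components and ``converged=False``.
    """
    df = data.dropna(subset=[response, "family", "subfamily", "genus"]).copy()
    _check_nesting(df[["family", "subfamily", "genus"]])
    df["_one"] = 1

    vc = {
        "family": "0 + C(family)",
        "subfamily": "0 + C(subfamily)",
        "genus": "0 + C(genus)",
    }
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(
                f"{response} ~ 1",
                data=df,
                groups="_one",
                vc_formula=vc,
                re_formula="0",
            )
            fit = model.fit(reml=True)
    except np.linalg.LinAlgError:
        # singular profile (e.g. one species per genus everywhere): report
        # all variance in the residual, flagged as non-converged
        return VarianceComponents(
            family=0.0,
            subfamily=0.0,
            genus=0.0,
            residual=float(np.var(df[response], ddof=1)),
            converged=False,
        )
    comp = {
        name: max(float(v), 0.0)
        for name, v in zip(model.exog_vc.names, fit.vcomp)
    }
    return VarianceComponents(
        family=comp.get("family", 0.0),
        subfamily=comp.get("subfamily", 0.0),
        genus=comp.get("genus", 0.0),
        residual=max(float(fit.scale), 0.0),
        converged=bool(getattr(fit, "converged", True)),
    )
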