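"""Descriptive statistics: phenotypic correlations, nodule-number ANOVA,
population least-squares means."""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .mixedmodel import DEFAULT_TRAITS, MixedModelResults

__all__ = ["pearson_by_env", "nodule_anova", "population_means"]


def pearson_by_env(
    table: pd.DataFrame, trait_names: list[str] | None = None
) -> dict[str, dict[str, pd.DataFrame]]:
    """Pairwise Pearson correlations among traits, per environment.

    Returns, for each environment, matrices of r, sample size and two-sided
    p.  A pair involving a constant trait is reported as NaN (undefined).
    """
    trait_names = trait_names or DEFAULT_TRAITS
    out: dict[str, dict[str, pd.DataFrame]] = {}
    for e in sorted(table["env"].unique()):
        sub = table.loc[table["env"] == e, trait_names].dropna()
        if len(sub) < 3:
            raise ValueError(f"need >= 3 complete records in {e!r}, found {len(sub)}")
        k = len(trait_names)
        r = np.eye(k)
        p = np.zeros((k, k))
        n = np.full((k, k), len(sub))
        for i in range(k):
            for j in range(i + 1, k):
                x, y = sub.iloc[:, i], sub.iloc[:, j]
                if x.std() == 0 or y.std() == 0:
                    r[i, j] = r[j, i] = np.nan
                    p[i, j] = p[j, i] = np.nan
                    continue
                res = stats.pearsonr(x, y)
                r[i, j] = r[j, i] = res.statistic
                p[i, j] = p[j, i] = res.pvalue
        out[e] = {
            "r": pd.DataFrame(r, index=trait_names, columns=trait_names),
            "n": pd.DataFrame(n, index=trait_names, columns=trait_names),
            "p": pd.DataFrame(p, index=trait_names, columns=trait_names),
        }
    return out


def nodule_anova(table: pd.DataFrame, unit: str = "individuals") -> pd.DataFrame:
    """Sequential ANOVA of nodule number on treatment, herbivory and biomass.

    Fits nodules ~ light treatment + herbivory + root + shoot + the
    treatment-by-covariate interactions, with sequential (fit-order,
    type I) sums of squares in the printed term order.  With
    ``unit="population_means"`` the regression runs on population-by-
    environment mean trait values (for a balanced two-environment design
    with 8 populations this leaves 8 denominator df).
    """
    if unit not in ("individuals", "population_means"):
        raise ValueError("unit must be 'individuals' or 'population_means'")
    df = table.copy()
    if unit == "population_means":
        df = (
            df.groupby(["population", "env"], as_index=False)[DEFAULT_TRAITS].mean()
        )
    # sequential (type I) sums of squares in the printed term order, via
    # nested OLS fits so formula machinery cannot reorder terms
    terms = [
        ("light_treatment", "C(env)"),
        ("herbivory", "herbivory"),
        ("root", "root"),
        ("shoot", "shoot"),
        ("light_treatment:herbivory", "C(env):herbivory"),
        ("light_treatment:root", "C(env):root"),
        ("light_treatment:shoot", "C(env):shoot"),
    ]
    rhs = "1"
    prev = smf.ols(f"nodules ~ {rhs}", data=df).fit()
    rows = []
    ranks = []
    for label, piece in terms:
        rhs = f"{rhs} + {piece}"
        cur = smf.ols(f"nodules ~ {rhs}", data=df).fit()
        ss = prev.ssr - cur.ssr
        dfi = int(round(prev.df_resid - cur.df_resid))
        rows.append((label, dfi, ss))
        ranks.append((label, dfi))
        prev = cur
    full = prev
    aliased = [label for label, dfi in ranks if dfi == 0]
    mse = full.ssr / full.df_resid

    def _f(ss, dfi):
        if dfi <= 0:
            return np.nan
        ms = ss / dfi
        if mse == 0.0:
            return 0.0 if abs(ms) < 1e-12 else np.inf
        return ms / mse

    out = pd.DataFrame(
        [
            {
                "df": dfi,
                "mean_square": ss / dfi if dfi > 0 else np.nan,
                "F": _f(ss, dfi),
                "p": stats.f.sf(_f(ss, dfi), dfi, full.df_resid) if dfi > 0 else np.nan,
            }
            for _, dfi, ss in rows
        ],
        index=[label for label, _, _ in rows],
    )
    out.attrs["df_resid"] = int(full.df_resid)
    out.attrs["mse_resid"] = float(mse)
    out.attrs["aliased_terms"] = aliased
    if aliased:
        out.attrs["note"] = f"aliased terms (zero added rank): {aliased}"
    return out


def population_means(
    table: pd.DataFrame, fitted: MixedModelResults
) -> pd.DataFrame:
    """Least-squares population means per environment from the fitted model.

    Model-adjusted cell means from the multivariate mixed model's
    fixed-effect solution, averaging over block effects with equal weight
    per block within each environment.
    """
    if not fitted.converged:
        raise ValueError("mixed model did not converge; lsmeans are not trustworthy")
    pops = set(table["population"].unique())
    model_pops = set(fitted.model._table["population"].unique())
    if pops != model_pops:
        raise ValueError("table populations do not match the fitted model's")
    for e in fitted.model.envs:
        present = set(table.loc[table["env"] == e, "population"].unique())
        missing = pops - present
        if missing:
            raise ValueError(f"population(s) {sorted(missing)} absent from {e!r}")
    return fitted.population_lsmeans()
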