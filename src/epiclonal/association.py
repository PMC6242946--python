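"""Per-epilocus association testing with Benjamini-Hochberg FDR control.

Simple (one covariate at a time) binomial-logit regressions of methylation
state on site climate, and Welch's unequal-variance t-tests of per-donor
D50% bud-set timing between methylation states.  Both analyses use the
fragment-absence-as-unmethylated scoring so no state is missing.  P-values
are pooled per analysis and corrected by the Benjamini-Hochberg step-up
procedure at q = 0.05 by default.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["epilocus_glm", "welch_test", "bh_fdr", "apply_fdr",
           "CLIMATE_COVARIATES"]

log = logging.getLogger(__name__)

CLIMATE_COVARIATES = ("t_jan", "t_jul", "t_mar", "precip", "frost_days",
                      "pet", "cn_topsoil")

#: |slope| on a standardized covariate beyond which the fit is treated as
#: separated / non-estimable.
SEPARATION_SLOPE = 15.0


def epilocus_glm(states: pd.DataFrame, climate: pd.DataFrame,
                 covariates: tuple[str, ...] = CLIMATE_COVARIATES,
                 ) -> pd.DataFrame:
    """Binomial-logit regression of each polymorphic epilocus on each
    covariate, one covariate per model.

    ``states`` is a samples x loci 0/1 matrix (absence scored as
    unmethylated, so no missing values); ``climate`` holds one row per
    sample (same index) with the covariate columns.  Returns one row per
    (locus, covariate) with the slope, Wald z, two-sided p and an
    ``estimable`` flag; complete separation or non-convergence flags the
    result non-estimable and excludes it from FDR.
    """
    import statsmodels.api as sm

    climate = climate.reindex(states.index)
    if climate.isna().any().any():
        raise ValueError("climate covariates missing for some samples")
    rows = []
    for cov in covariates:
        x = climate[cov].to_numpy(float)
        sd = x.std()
        if sd == 0:
            raise ValueError(f"constant covariate {cov!r}")
        X = np.column_stack([np.ones_like(x), x])
        for locus in states.columns:
            y = states[locus].to_numpy(float)
            if np.isnan(y).any():
                raise ValueError("states must be fully scored (zero-absence "
                                 "mode)")
            if y.min() == y.max():
                continue  # monomorphic under this coding
            estimable = True
            slope = z = p = np.nan
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(
                        maxiter=100)
                slope = float(fit.params[1])
                se = float(fit.bse[1])
                if (not fit.converged or not np.isfinite(se)
                        or abs(slope * sd) > SEPARATION_SLOPE):
                    estimable = False
                else:
                    z = slope / se
                    p = 2.0 * stats.norm.sf(abs(z))
            except Exception as exc:  # perfect separation raises in some paths
                log.warning("GLM failed for %s ~ %s: %s", locus, cov, exc)
                estimable = False
            rows.append({"locus_id": locus, "covariate": cov,
                         "estimate": slope, "statistic": z, "df": np.nan,
                         "p_value": p, "estimable": estimable})
    return pd.DataFrame(rows)


def welch_test(d50_table: pd.DataFrame, states: pd.DataFrame) -> pd.DataFrame:
    """Welch's t-test of D50% between methylation states per epilocus.

    ``states`` is indexed by donor (zero-absence scoring).  Loci methylated
    in only one donor, or in all but one, are discarded before testing.
    A locus with both groups constant at different means gets p reported at
    the smallest positive float and is flagged.
    """
    d50 = d50_table.set_index("donor_id")["d50"]
    common = states.index.intersection(d50.index)
    states = states.loc[common]
    d50 = d50.loc[common]
    rows = []
    for locus in states.columns:
        y = states[locus]
        g1 = d50[y == 1.0].to_numpy(float)
        g0 = d50[y == 0.0].to_numpy(float)
        if min(len(g0), len(g1)) <= 1:
            continue  # discard rule
        flagged = False
        if np.ptp(g0) == 0 and np.ptp(g1) == 0:
            if g0[0] == g1[0]:
                t, p, df = 0.0, 1.0, np.nan
            else:
                t = np.inf if g1[0] > g0[0] else -np.inf
                p = np.finfo(float).tiny
                df = np.nan
                flagged = True
        else:
            t, p = stats.ttest_ind(g1, g0, equal_var=False)
            v1, v0 = g1.var(ddof=1) / len(g1), g0.var(ddof=1) / len(g0)
            df = (v1 + v0) ** 2 / (v1**2 / (len(g1) - 1)
                                   + v0**2 / (len(g0) - 1))
        rows.append({"locus_id": locus, "covariate": "d50",
                     "estimate": float(np.mean(g1) - np.mean(g0)),
                     "statistic": float(t), "df": float(df),
                     "p_value": float(p), "estimable": not flagged})
    return pd.DataFrame(rows)


def bh_fdr(p_values, q: float = 0.05) -> pd.DataFrame:
    """Benjamini-Hochberg step-up adjustment.

    Returns a DataFrame aligned with the input order: raw p, adjusted p
    (min over j >= rank of p_(j) * m / j, capped at 1) and significance at
    the given q.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return pd.DataFrame(columns=["p_value", "p_adjusted",
                                     "significant_at_q05"])
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    from statsmodels.stats.multitest import multipletests

    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return pd.DataFrame({"p_value": p, "p_adjusted": p_adj,
                         "significant_at_q05": reject})


def apply_fdr(results: pd.DataFrame, q: float = 0.05,
              family: str = "pooled") -> pd.DataFrame:
    """Attach BH-adjusted p-values to an association table.

    ``family='pooled'`` corrects all estimable tests together;
    ``'per_covariate'`` corrects within each covariate separately.
    Non-estimable rows keep NaN adjusted p and are never significant.
    """
    if family not in ("pooled", "per_covariate"):
        raise ValueError(f"unknown FDR family {family!r}")
    out = results.copy()
    out["p_adjusted"] = np.nan
    out["significant_at_q05"] = False
    ok = out["estimable"] & out["p_value"].notna()
    if family == "pooled":
        blocks = [out.index[ok]]
    else:
        blocks = [out.index[ok & (out["covariate"] == c)]
                  for c in out.loc[ok, "covariate"].unique()]
    for idx in blocks:
        if len(idx) == 0:
            continue
        adj = bh_fdr(out.loc[idx, "p_value"].to_numpy(), q=q)
        out.loc[idx, "p_adjusted"] = adj["p_adjusted"].to_numpy()
        out.loc[idx, "significant_at_q05"] = adj["significant_at_q05"].to_numpy()
    return out
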