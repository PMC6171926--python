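"""Lesion outcome modelling: partial mixed model, stepwise selection, full model.

The analysis links pen-level aggression structure to pen-mean skin
lesion counts in three stages:

1. *Partial model* — a linear mixed model of the pen-mean lesion count
   on breed, sex, mean pen weight and the number of aggressive
   interactions (fixed effects) with experimental batch as a random
   intercept, fitted by REML.  Its residuals carry the variation the
   husbandry covariates cannot explain.
2. *Stepwise selection* — classic entry/stay stepwise regression of
   those residuals on the candidate network and dyadic traits.
3. *Full model* — the partial model refitted with the selected traits
   added as fixed covariates, reporting RMSE, AIC, marginal and
   conditional R^2 and variance inflation factors.

Acute (24 h) outcomes are baseline-subtracted pen means (and may be
negative); chronic (3 wk) outcomes are raw pen means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf
from statsmodels.stats.outliers_influence import variance_inflation_factor
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "ModelFit",
    "StepwiseResult",
    "SpearmanMatrix",
    "pen_lesion_outcomes",
    "pen_covariate_table",
    "fit_partial_model",
    "fit_full_model",
    "stepwise_select",
    "spearman_matrix",
]

REGIONS = ("anterior", "central", "posterior")
DEFAULT_SLENTRY = 0.15
DEFAULT_SLSTAY = 0.15
VIF_THRESHOLD = 10.0


class AliasedTermWarning(UserWarning):
    pass


class CollinearityWarning(UserWarning):
    pass


def pen_lesion_outcomes(lesions: pd.DataFrame, roster: pd.DataFrame) -> pd.DataFrame:
    """Pen-mean lesion outcomes per timepoint and body region.

    24 h values are pen means of the per-pig difference (24 h count minus
    pre-mixing count) and may be negative; 3 wk values are pen means of
    the raw counts.  ``total`` is the sum over the three regions, and the
    divisor is always the pen's actual roster size.
    """
    merged = lesions.merge(roster[["pig_id", "pen_id"]], on="pig_id", how="left")
    if merged["pen_id"].isna().any():
        orphans = merged.loc[merged["pen_id"].isna(), "pig_id"].unique()
        raise ValueError(f"lesion records for pigs not in roster: {list(orphans)[:5]}")
    sizes = roster.groupby("pen_id")["pig_id"].nunique()
    regions = list(REGIONS)

    def by_tp(tp: str) -> pd.DataFrame:
        sub = merged[merged["timepoint"] == tp]
        if sub["pig_id"].duplicated().any():
            raise ValueError(f"duplicate {tp} lesion record(s)")
        return sub.set_index("pig_id")

    frames = []
    h24 = by_tp("24h")
    if len(h24):
        pre = by_tp("pre")
        missing = h24.index.difference(pre.index)
        if len(missing):
            raise ValueError(
                f"24h lesion records without a pre-mix baseline: {list(missing)[:5]}"
            )
        delta = h24[regions] - pre.loc[h24.index, regions]
        delta["pen_id"] = h24["pen_id"]
        pen_mean = delta.groupby("pen_id")[regions].sum().div(sizes, axis=0).dropna()
        pen_mean["timepoint"] = "24h"
        frames.append(pen_mean)
    wk3 = by_tp("3wk")
    if len(wk3):
        pen_mean = wk3.groupby("pen_id")[regions].sum().div(sizes, axis=0).dropna()
        pen_mean["timepoint"] = "3wk"
        frames.append(pen_mean)
    if not frames:
        return pd.DataFrame(columns=["pen_id", "timepoint", "region", "value"])
    wide = pd.concat(frames).reset_index()
    wide["total"] = wide[regions].sum(axis=1)
    tidy = wide.melt(
        id_vars=["pen_id", "timepoint"],
        value_vars=[*regions, "total"],
        var_name="region",
        value_name="value",
    )
    return tidy.sort_values(["pen_id", "timepoint", "region"], ignore_index=True)


def pen_covariate_table(roster: pd.DataFrame, events: pd.DataFrame) -> pd.DataFrame:
    """Pen-level fixed-effect covariates for the partial model."""
    cov = (
        roster.groupby("pen_id")
        .agg(
            breed=("breed", "first"),
            sex=("sex", "first"),
            batch_id=("batch_id", "first"),
            mean_weight=("weight", "mean"),
            n_pigs=("pig_id", "nunique"),
        )
        .reset_index()
    )
    counts = events.groupby("pen_id").size().rename("n_interactions")
    cov = cov.merge(counts, on="pen_id", how="left")
    cov["n_interactions"] = cov["n_interactions"].fillna(0).astype(int)
    return cov


@dataclass
class ModelFit:
    """A fitted partial or full model with the quantities the pipeline reuses."""

    response: str
    formula: str
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    resid_marginal: pd.Series  # y - X beta, indexed by pen
    resid_conditional: pd.Series  # y - X beta - batch BLUP
    fitted_fixed: pd.Series
    scale: float  # residual variance
    batch_var: float
    rmse: float
    aic: float
    r2_marginal: float
    r2_conditional: float
    vif: pd.Series
    n: int
    mixed: bool
    # frozen design, for refits with permuted trait columns
    endog: np.ndarray = field(repr=False, default=None)
    exog: np.ndarray = field(repr=False, default=None)
    exog_names: list[str] = field(repr=False, default_factory=list)
    groups: np.ndarray = field(repr=False, default=None)
    pen_ids: list[str] = field(repr=False, default_factory=list)

    @property
    def r2(self) -> float:
        """Headline variance explained (marginal: fixed effects only)."""
        return self.r2_marginal

    def residuals(self, kind: str = "conditional") -> pd.Series:
        return self.resid_conditional if kind == "conditional" else self.resid_marginal

    def summary_dict(self) -> dict:
        return {
            "response": self.response,
            "formula": self.formula,
            "n_pens": self.n,
            "coefficients": {
                name: {
                    "estimate": float(self.params[name]),
                    "se": float(self.bse[name]),
                    "p": float(self.pvalues[name]),
                }
                for name in self.params.index
            },
            "batch_variance": self.batch_var,
            "residual_variance": self.scale,
            "rmse": self.rmse,
            "aic": self.aic,
            "r2_marginal": self.r2_marginal,
            "r2_conditional": self.r2_conditional,
            "vif": {k: float(v) for k, v in self.vif.items()},
        }


def _fixed_effect_terms(data: pd.DataFrame, extra: list[str]) -> list[str]:
    terms = []
    for factor in ("breed", "sex"):
        if data[factor].nunique() > 1:
            terms.append(f"C({factor})")
        else:
            warnings.warn(
                f"{factor} has a single level and was dropped from the model",
                AliasedTermWarning,
                stacklevel=3,
            )
    terms += ["mean_weight", "n_interactions"]
    terms += extra
    return terms


def _fit_linear(
    outcomes: pd.DataFrame,
    pen_covariates: pd.DataFrame,
    timepoint: str,
    region: str,
    trait_values: pd.DataFrame | None,
    trait_names: list[str],
) -> ModelFit:
    sel = outcomes[(outcomes["timepoint"] == timepoint) & (outcomes["region"] == region)]
    if sel.empty:
        raise ValueError(f"no outcomes for timepoint={timepoint!r} region={region!r}")
    data = pen_covariates.merge(sel[["pen_id", "value"]], on="pen_id", how="inner")
    if trait_values is not None:
        data = data.merge(trait_values, on="pen_id", how="inner")
    data = data.sort_values("pen_id").reset_index(drop=True)

    terms = _fixed_effect_terms(data, trait_names)
    formula = "value ~ " + " + ".join(terms)
    n = len(data)
    response = f"{timepoint}/{region}"

    multi_batch = data["batch_id"].nunique() > 1
    if multi_batch:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            model = smf.mixedlm(formula, data, groups=data["batch_id"])
            try:
                result = model.fit(reml=True)
            except np.linalg.LinAlgError:
                # near-singular REML information matrix (tiny herds); a
                # derivative-free optimiser usually still converges
                try:
                    result = model.fit(reml=True, method="powell")
                except np.linalg.LinAlgError:
                    warnings.warn(
                        "mixed model is singular; dropping the batch random effect",
                        AliasedTermWarning,
                        stacklevel=3,
                    )
                    multi_batch = False
    if multi_batch:
        batch_var = float(np.asarray(result.cov_re)[0, 0])
        scale = float(result.scale)
        fitted = np.asarray(result.model.exog) @ np.asarray(result.fe_params)
        resid_m = data["value"].to_numpy() - fitted
        blup = np.array(
            [float(result.random_effects[g].iloc[0]) for g in data["batch_id"]]
        )
        resid_c = resid_m - blup
        params = result.fe_params
        bse = result.bse_fe
        pvalues = result.pvalues[params.index]
        llf = float(result.llf)
        k = len(params) + 2  # fixed effects + batch variance + residual variance
        aic = -2.0 * llf + 2.0 * k
        exog = np.asarray(result.model.exog)
        exog_names = list(result.model.exog_names)
    else:
        result = smf.ols(formula, data).fit()
        batch_var = 0.0
        scale = float(result.mse_resid)
        fitted = np.asarray(result.fittedvalues)
        resid_m = np.asarray(result.resid)
        resid_c = resid_m
        params, bse, pvalues = result.params, result.bse, result.pvalues
        aic = float(result.aic)
        exog = np.asarray(result.model.exog)
        exog_names = list(result.model.exog_names)

    var_fixed = float(np.var(fitted))
    denom = var_fixed + batch_var + scale
    r2_m = var_fixed / denom if denom > 0 else 0.0
    r2_c = (var_fixed + batch_var) / denom if denom > 0 else 0.0

    vif = pd.Series(dtype=float)
    if exog.shape[1] > 2:
        with np.errstate(divide="ignore"):
            vif = pd.Series(
                {
                    name: float(variance_inflation_factor(exog, j))
                    for j, name in enumerate(exog_names)
                    if name != "Intercept"
                }
            )
        high = vif[vif > VIF_THRESHOLD]
        if len(high):
            warnings.warn(
                f"VIF above {VIF_THRESHOLD:g} for: {', '.join(high.index)}",
                CollinearityWarning,
                stacklevel=3,
            )

    pen_index = pd.Index(data["pen_id"], name="pen_id")
    return ModelFit(
        response=response,
        formula=formula,
        params=pd.Series(params, index=params.index),
        bse=pd.Series(bse, index=params.index),
        pvalues=pd.Series(pvalues, index=params.index),
        resid_marginal=pd.Series(resid_m, index=pen_index),
        resid_conditional=pd.Series(resid_c, index=pen_index),
        fitted_fixed=pd.Series(fitted, index=pen_index),
        scale=scale,
        batch_var=batch_var,
        rmse=float(np.sqrt(scale)),
        aic=float(aic),
        r2_marginal=r2_m,
        r2_conditional=r2_c,
        vif=vif,
        n=n,
        mixed=multi_batch,
        endog=data["value"].to_numpy(),
        exog=exog,
        exog_names=exog_names,
        groups=data["batch_id"].to_numpy(),
        pen_ids=list(data["pen_id"]),
    )


def fit_partial_model(
    outcomes: pd.DataFrame,
    pen_covariates: pd.DataFrame,
    timepoint: str = "24h",
    region: str = "total",
) -> ModelFit:
    """REML mixed model of pen-mean lesions on husbandry fixed effects.

    Fixed effects: breed, sex, mean pen weight, number of aggressive
    interactions; random intercept: experimental batch.  With a single
    batch the random effect is dropped and the fit reduces to OLS.
    Residuals are conditional (batch BLUP subtracted) by default, so the
    stepwise stage sees only variation unexplained by fixed effects and
    batch.
    """
    return _fit_linear(outcomes, pen_covariates, timepoint, region, None, [])


def fit_full_model(
    outcomes: pd.DataFrame,
    pen_covariates: pd.DataFrame,
    traits: pd.DataFrame,
    selected: list[str],
    timepoint: str = "24h",
    region: str = "total",
) -> ModelFit:
    """Partial model plus the selected network/dyadic traits as fixed effects."""
    if not selected:
        raise ValueError("selected_traits must be non-empty; use fit_partial_model otherwise")
    deduped = list(dict.fromkeys(selected))
    if len(deduped) != len(selected):
        warnings.warn("duplicate traits in selection were removed", CollinearityWarning)
    missing = [t for t in deduped if t not in traits.columns]
    if missing:
        raise KeyError(f"traits not present in trait table: {missing}")
    trait_values = traits[["pen_id", *deduped]]
    safe = {t: f"Q('{t}')" for t in deduped}
    fit = _fit_linear(
        outcomes, pen_covariates, timepoint, region, trait_values, [safe[t] for t in deduped]
    )
    return fit


@dataclass
class StepwiseResult:
    """Outcome of entry/stay stepwise selection on partial-model residuals."""

    selected: list[str]
    slentry: float
    slstay: float
    steps: list[dict] = field(default_factory=list)
    skipped_collinear: list[str] = field(default_factory=list)


def _ols_stats(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Coefficients and two-sided p-values of an OLS fit (fast path)."""
    n, p = X.shape
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - rank
    if dof <= 0:
        return beta, np.ones(p)
    sigma2 = resid @ resid / dof
    xtx_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.maximum(np.diag(xtx_inv) * sigma2, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    pvals = 2.0 * scipy.stats.t.sf(np.abs(t), dof)
    return beta, pvals


def stepwise_select(
    residuals: pd.Series,
    candidates: pd.DataFrame,
    slentry: float = DEFAULT_SLENTRY,
    slstay: float = DEFAULT_SLSTAY,
    vif_threshold: float = VIF_THRESHOLD,
) -> StepwiseResult:
    """Classic stepwise regression of residuals on candidate traits.

    At each step the candidate with the smallest coefficient p-value
    enters if p < ``slentry``; any included trait whose p-value rises
    above ``slstay`` is then removed.  Iteration stops at a fixed point,
    or immediately if a step would revisit a previous model state (no
    re-entry cycling).  A candidate whose variance inflation factor
    against the included traits exceeds ``vif_threshold`` is skipped with
    a collinearity warning.
    """
    if not 0 < slentry < 1 or not 0 < slstay < 1:
        raise ValueError("slentry and slstay must lie in (0, 1)")
    cand_df = candidates.set_index("pen_id") if "pen_id" in candidates.columns else candidates
    common = residuals.index.intersection(cand_df.index)
    if len(common) < len(residuals):
        raise ValueError("candidate traits and residuals are not aligned by pen")
    y = residuals.loc[common].to_numpy(dtype=float)
    cols = list(cand_df.columns)
    Xall = cand_df.loc[common, cols].to_numpy(dtype=float)
    n = len(y)
    intercept = np.ones((n, 1))

    included: list[str] = []
    steps: list[dict] = []
    skipped: list[str] = []
    seen_states = {frozenset()}

    tss = float(np.sum((y - y.mean()) ** 2))
    while True:
        changed = False
        # forward step (unless the current model already fits perfectly)
        best_name, best_p = None, np.inf
        Xin = Xall[:, [cols.index(c) for c in included]]
        cur_resid = y - np.hstack([intercept, Xin]) @ np.linalg.lstsq(
            np.hstack([intercept, Xin]), y, rcond=None
        )[0]
        if float(cur_resid @ cur_resid) <= 1e-10 * max(tss, 1.0):
            break
        for name in cols:
            if name in included:
                continue
            xj = Xall[:, cols.index(name)]
            if np.std(xj) == 0:
                continue
            if included:
                # VIF of the candidate against what is already in the model
                b, _, _, _ = np.linalg.lstsq(
                    np.hstack([intercept, Xin]), xj, rcond=None
                )
                e = xj - np.hstack([intercept, Xin]) @ b
                tss = np.sum((xj - xj.mean()) ** 2)
                r2 = 1.0 - (e @ e) / tss if tss > 0 else 1.0
                vif = np.inf if r2 >= 1 else 1.0 / (1.0 - r2)
                if vif > vif_threshold:
                    if name not in skipped:
                        skipped.append(name)
                        warnings.warn(
                            f"candidate {name!r} skipped: VIF {vif:.1f} against included traits",
                            CollinearityWarning,
                            stacklevel=2,
                        )
                    continue
            X = np.hstack([intercept, Xin, xj[:, None]])
            _, pvals = _ols_stats(X, y)
            if pvals[-1] < best_p:
                best_name, best_p = name, pvals[-1]
        if best_name is not None and best_p < slentry:
            state = frozenset(included) | {best_name}
            if state in seen_states:
                break  # would revisit a previous model: stop
            included.append(best_name)
            seen_states.add(state)
            steps.append({"action": "enter", "trait": best_name, "p": float(best_p)})
            changed = True

        # backward step
        while included:
            Xin = Xall[:, [cols.index(c) for c in included]]
            X = np.hstack([intercept, Xin])
            _, pvals = _ols_stats(X, y)
            trait_p = pvals[1:]
            worst = int(np.argmax(trait_p))
            if trait_p[worst] > slstay:
                name = included[worst]
                state = frozenset(included) - {name}
                included.remove(name)
                steps.append({"action": "remove", "trait": name, "p": float(trait_p[worst])})
                changed = True
                if state in seen_states:
                    return StepwiseResult(included, slentry, slstay, steps, skipped)
                seen_states.add(state)
            else:
                break

        if not changed:
            break

    return StepwiseResult(included, slentry, slstay, steps, skipped)


@dataclass
class SpearmanMatrix:
    rho: pd.DataFrame
    p: pd.DataFrame


def spearman_matrix(trait_table: pd.DataFrame) -> SpearmanMatrix:
    """Pairwise Spearman rank correlations between trait columns.

    Uses average ranks for ties and two-sided p-values.  A constant
    column has no defined rank correlation and is reported as missing.
    """
    numeric = trait_table.select_dtypes(include=[np.number])
    numeric = numeric.drop(columns=[c for c in ("n_nodes", "n_edges") if c in numeric])
    if len(numeric) < 3:
        raise ValueError("Spearman correlation requires at least 3 pens")
    cols = list(numeric.columns)
    k = len(cols)
    rho = np.eye(k)
    pval = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            xi, xj = numeric.iloc[:, i], numeric.iloc[:, j]
            if xi.nunique() <= 1 or xj.nunique() <= 1:
                r, p = np.nan, np.nan
            else:
                r, p = scipy.stats.spearmanr(xi, xj)
            rho[i, j] = rho[j, i] = r
            pval[i, j] = pval[j, i] = p
    return SpearmanMatrix(
        rho=pd.DataFrame(rho, index=cols, columns=cols),
        p=pd.DataFrame(pval, index=cols, columns=cols),
    )
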