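"""Hierarchical models separating factor identity from number and dissimilarity.

Joint responses in a randomized factor-pool design vary for three confounded
reasons: which factors are present (identity), how many act at once, and how
dissimilar they are. The identity contribution is captured by using the three
null-model predictions as the baseline predictors (Model 1); the remaining
models add number of factors and dissimilarity on top of that baseline, so
their R-squared increments measure contributions beyond identity:

=====  =============================================================
Model  Predictors
=====  =============================================================
1      additive, multiplicative and dominative null predictions
2      number of factors only
3      normalized dissimilarity only
4      Model 1 + number of factors
5      Model 1 + dissimilarity
6      Model 1 + number of factors + dissimilarity
7      Model 6 + binary factor composition
=====  =============================================================

Two backends: a Gaussian-identity GLM (ordinary least squares; AIC and nested
F-tests) and a random-forest ensemble (out-of-bag R-squared; Altmann-style
permutation importance, where the null distribution of each predictor's
importance comes from refitting on response-permuted data).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance as sk_permutation_importance

from ._seeds import stage_rng, stage_seed
from .design import split_factors
from .effects import adjust_pvalues_bh

__all__ = [
    "NULL_PREDICTORS",
    "MODEL_SPECS",
    "DELTA_BASE",
    "build_feature_table",
    "fit_hierarchy",
    "permutation_importance",
    "HierarchyReport",
]

NULL_PREDICTORS = ["null_additive", "null_multiplicative", "null_dominative"]

#: Predictor sets of the seven models ("composition" expands to the binary
#: factor-presence columns).
MODEL_SPECS: dict[int, list[str]] = {
    1: list(NULL_PREDICTORS),
    2: ["n_factors"],
    3: ["di_norm"],
    4: NULL_PREDICTORS + ["n_factors"],
    5: NULL_PREDICTORS + ["di_norm"],
    6: NULL_PREDICTORS + ["n_factors", "di_norm"],
    7: NULL_PREDICTORS + ["n_factors", "di_norm", "composition"],
}

#: R-squared increments are reported against these base models.
DELTA_BASE: dict[int, int] = {4: 1, 5: 1, 6: 1, 7: 6}


def build_feature_table(
    design: pd.DataFrame,
    responses: pd.DataFrame,
    effects: pd.DataFrame,
    nullpred: pd.DataFrame,
    di: pd.DataFrame,
    factors: Sequence[str],
) -> pd.DataFrame:
    """One row per non-control unit x response with all model predictors.

    Null-prediction columns are on the response scale: for multi-factor
    treatments they are the bootstrap prediction means; for single-factor
    treatments all three models coincide with control mean + effect size.
    Singles get level 1 and, by convention, di_norm 0 (they have no factor
    pairs). Composition columns follow pool order.
    """
    control_mean = (
        responses[responses["treatment_id"] == "control"]
        .groupby("response")["value"]
        .mean()
    )
    if control_mean.empty:
        raise ValueError("control group missing from the response table")

    preds = nullpred.pivot_table(
        index=["treatment_id", "response"], columns="model", values="pred_mean"
    )
    eff = effects.set_index(["treatment_id", "response"])["effect"]

    keep = design[design["kind"].isin(["single", "multi"])]
    design_idx = keep.set_index("treatment_id")
    units = responses[responses["treatment_id"].isin(design_idx.index)]

    orphans = set(preds.index.get_level_values(0)) - set(design_idx.index)
    if orphans:
        raise ValueError(f"null predictions for treatments not in the design: {sorted(orphans)}")

    di_norm = di.set_index("treatment_id")["di_norm"] if len(di) else pd.Series(dtype=float)

    rows = []
    for (tid, response), grp in units.groupby(["treatment_id", "response"]):
        drow = design_idx.loc[tid]
        members = split_factors(drow["factors"])
        if drow["kind"] == "single":
            base = float(control_mean.loc[response])
            es = float(eff.loc[(tid, response)])
            p_add = p_mult = p_dom = base + es
            dnorm = 0.0
        else:
            try:
                prow = preds.loc[(tid, response)]
            except KeyError:
                raise ValueError(f"missing null predictions for {(tid, response)}") from None
            p_add, p_mult, p_dom = (
                float(prow["additive"]),
                float(prow["multiplicative"]),
                float(prow["dominative"]),
            )
            dnorm = float(di_norm.loc[tid])
        comp = {f"comp_{f}": int(f in members) for f in factors}
        for _, urow in grp.iterrows():
            rows.append(
                dict(
                    unit_id=urow["unit_id"],
                    treatment_id=tid,
                    response=response,
                    y=float(urow["value"]),
                    null_additive=p_add,
                    null_multiplicative=p_mult,
                    null_dominative=p_dom,
                    n_factors=int(drow["level"]),
                    di_norm=dnorm,
                    **comp,
                )
            )
    cols = (
        ["unit_id", "treatment_id", "response", "y"]
        + NULL_PREDICTORS
        + ["n_factors", "di_norm"]
        + [f"comp_{f}" for f in factors]
    )
    return pd.DataFrame(rows, columns=cols)


def _expand(predictors: Sequence[str], features: pd.DataFrame) -> list[str]:
    cols: list[str] = []
    for p in predictors:
        if p == "composition":
            cols.extend(c for c in features.columns if c.startswith("comp_"))
        else:
            cols.append(p)
    return cols


def _drop_aliased(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    """Greedily keep columns that increase matrix rank; warn when dropping."""
    kept: list[int] = []
    rank = 0
    for j in range(X.shape[1]):
        candidate = X[:, kept + [j]]
        new_rank = np.linalg.matrix_rank(candidate)
        if new_rank > rank:
            kept.append(j)
            rank = new_rank
    dropped = [names[j] for j in range(X.shape[1]) if j not in kept]
    if dropped:
        warnings.warn(f"dropping aliased predictor columns: {dropped}", RuntimeWarning, stacklevel=2)
    return X[:, kept], [names[j] for j in kept]


@dataclass
class HierarchyReport:
    """Per-response metrics of the seven-model hierarchy."""

    response: str
    backend: str
    models: dict[int, dict] = field(default_factory=dict)
    importance: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        out = {
            "response": self.response,
            "backend": self.backend,
            "models": {str(k): v for k, v in self.models.items()},
        }
        if self.importance is not None:
            out["importance"] = self.importance.to_dict(orient="records")
        return out


def _fit_glm_models(features: pd.DataFrame, y: np.ndarray) -> dict[int, dict]:
    results = {}
    fitted = {}
    for mid, predictors_spec in MODEL_SPECS.items():
        cols = _expand(predictors_spec, features)
        X = features[cols].to_numpy(dtype=float)
        X, kept = _drop_aliased(X, cols)
        exog = sm.add_constant(X, has_constant="add")
        res = sm.OLS(y, exog).fit()
        fitted[mid] = res
        results[mid] = {
            "r2": float(res.rsquared),
            "aic": float(res.aic),
            "predictors": kept,
        }
    for mid, base in DELTA_BASE.items():
        results[mid]["delta_r2"] = results[mid]["r2"] - results[base]["r2"]
        results[mid]["delta_aic"] = results[mid]["aic"] - results[base]["aic"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                f, p, _ = fitted[mid].compare_f_test(fitted[base])
                results[mid]["anova_p"] = float(p)
            except Exception:  # degenerate nesting after alias dropping
                results[mid]["anova_p"] = float("nan")
    return results


def _forest(seed: int, n_estimators: int) -> RandomForestRegressor:
    return RandomForestRegressor(
        n_estimators=n_estimators,
        oob_score=True,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )


def _fit_forest_models(
    features: pd.DataFrame, y: np.ndarray, seed: int, n_estimators: int, oob: bool
) -> dict[int, dict]:
    results = {}
    for mid, predictors_spec in MODEL_SPECS.items():
        cols = _expand(predictors_spec, features)
        X = features[cols].to_numpy(dtype=float)
        rf = _forest(stage_seed(seed, f"rf:{mid}"), n_estimators)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # OOB warning on tiny samples
            rf.fit(X, y)
        r2 = float(rf.oob_score_) if oob else float(rf.score(X, y))
        results[mid] = {"r2": r2, "predictors": cols}
    for mid, base in DELTA_BASE.items():
        results[mid]["delta_r2"] = results[mid]["r2"] - results[base]["r2"]
    return results


def permutation_importance(
    features: pd.DataFrame,
    y: np.ndarray,
    predictors: Sequence[str],
    n_perm: int = 1000,
    seed: int = 0,
    n_estimators: int = 200,
    n_repeats: int = 5,
) -> pd.DataFrame:
    """Permutation importance with Altmann-style p-values, BH-adjusted.

    Importance of a predictor is the mean increase in forest MSE over
    ``n_repeats`` independent shuffles of its column. The null distribution of
    each importance is built by refitting on ``n_perm`` response permutations
    and recomputing the statistic; p = (1 + #{null >= observed}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    cols = _expand(predictors, features)
    X = features[cols].to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)

    def statistic(y_fit: np.ndarray, tag: str) -> np.ndarray:
        rf = _forest(stage_seed(seed, f"permimp-fit:{tag}"), n_estimators)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rf.fit(X, y_fit)
        imp = sk_permutation_importance(
            rf,
            X,
            y_fit,
            scoring="neg_mean_squared_error",
            n_repeats=n_repeats,
            random_state=stage_seed(seed, f"permimp-shuffle:{tag}"),
            n_jobs=1,
        )
        return imp.importances_mean

    observed = statistic(y, "observed")
    rng = stage_rng(seed, "permimp-null")
    null = np.empty((n_perm, len(cols)))
    for b in range(n_perm):
        null[b] = statistic(rng.permutation(y), f"null:{b}")
    p_raw = (1.0 + (null >= observed[None, :]).sum(axis=0)) / (1.0 + n_perm)
    return pd.DataFrame(
        {
            "predictor": cols,
            "importance": observed,
            "p_raw": p_raw,
            "p_adj": adjust_pvalues_bh(p_raw),
        }
    )


def fit_hierarchy(
    features: pd.DataFrame,
    backend: str = "glm",
    seed: int = 0,
    n_estimators: int = 200,
    n_perm: int = 0,
    oob: bool = True,
    min_rows: int = 30,
    importance_predictors: Sequence[str] | None = None,
) -> dict[str, HierarchyReport]:
    """Fit Models 1-7 per response; return a report per response.

    ``backend`` is ``"glm"`` (OLS: R-squared, AIC, nested F-tests) or
    ``"forest"`` (random forest: out-of-bag R-squared by default). With the
    forest backend and ``n_perm > 0``, Altmann permutation importance is
    computed for the Model 6 predictors (override via
    ``importance_predictors``).
    """
    if backend not in ("glm", "forest"):
        raise ValueError(f"unknown backend {backend!r}; choose 'glm' or 'forest'")
    reports: dict[str, HierarchyReport] = {}
    for response, grp in features.groupby("response"):
        if len(grp) < min_rows:
            raise ValueError(
                f"response {response!r} has {len(grp)} rows, fewer than min_rows={min_rows}"
            )
        y = grp["y"].to_numpy(dtype=float)
        if backend == "glm":
            models = _fit_glm_models(grp, y)
            importance = None
        else:
            models = _fit_forest_models(
                grp, y, seed=stage_seed(seed, f"hier:{response}"), n_estimators=n_estimators, oob=oob
            )
            importance = None
            if n_perm > 0:
                importance = permutation_importance(
                    grp,
                    y,
                    importance_predictors or MODEL_SPECS[6],
                    n_perm=n_perm,
                    seed=stage_seed(seed, f"hier-imp:{response}"),
                    n_estimators=n_estimators,
                )
        reports[response] = HierarchyReport(
            response=response, backend=backend, models=models, importance=importance
        )
    return reports
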