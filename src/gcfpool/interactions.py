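"""Net-interaction classification from deviations off null predictions.

For each multi-factor treatment x response, the observed group mean is
compared with the bootstrap distribution of the null-model prediction:

* inside the 95% CI — no net interaction;
* outside — the rescaled deviation DN = (observed - mean) / sd of the
  prediction draws determines the type. For responses that increase under
  stress, DN > 0 is synergistic and DN < 0 antagonistic; for responses that
  decrease under stress (decomposition rate, water-stable aggregates) the rule
  flips: DN < 0 is synergistic.

Per response, the best-fitting null model is the one with the smallest sum of
squared deviations (SSD) of observed group means from prediction means, with
ties broken additive > multiplicative > dominative. Per-level one-sample
t-tests on DN and Spearman correlations of DN against the normalized
dissimilarity index quantify whether deviations grow with the number of
factors or with factor dissimilarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .effects import adjust_pvalues_bh
from .nullmodels import MODELS, NullPrediction

__all__ = [
    "InteractionCall",
    "rescaled_deviation",
    "classify_interaction",
    "interaction_calls",
    "select_best_null",
    "deviation_group_tests",
    "dn_vs_di_correlation",
]

LABELS = ("synergistic", "antagonistic", "none")


@dataclass
class InteractionCall:
    treatment_id: str | None
    response: str | None
    model: str
    observed: float
    dn: float
    label: str
    direction: int


def rescaled_deviation(observed: float, prediction: NullPrediction) -> float:
    """DN: observed minus prediction mean, in units of the prediction sd."""
    if prediction.draws.size < 2 or prediction.sd == 0.0:
        if observed == prediction.mean:
            return 0.0
        raise ValueError(
            "null-prediction distribution has zero spread but the observation "
            "differs from its mean; DN undefined"
        )
    return float((observed - prediction.mean) / prediction.sd)


def classify_interaction(
    observed: float, prediction: NullPrediction, direction: int
) -> InteractionCall:
    """Label one treatment x response given one null-prediction distribution.

    ``direction`` is +1 for responses expected to increase under stress and
    -1 for those expected to decrease.
    """
    if direction not in (-1, +1):
        raise ValueError(f"direction must be +1 or -1, got {direction!r}")
    if prediction.ci_low <= observed <= prediction.ci_high:
        dn = rescaled_deviation(observed, prediction) if prediction.sd > 0 else 0.0
        label = "none"
    else:
        dn = rescaled_deviation(observed, prediction)
        if direction > 0:
            label = "synergistic" if dn > 0 else "antagonistic"
        else:
            label = "synergistic" if dn < 0 else "antagonistic"
    return InteractionCall(
        treatment_id=prediction.treatment_id,
        response=prediction.response,
        model=prediction.model,
        observed=float(observed),
        dn=dn,
        label=label,
        direction=direction,
    )


def interaction_calls(
    predictions: Sequence[NullPrediction],
    responses: pd.DataFrame,
    directions: Mapping[str, int],
) -> pd.DataFrame:
    """Classify every prediction against the observed treatment group mean."""
    observed = responses.groupby(["treatment_id", "response"])["value"].mean()
    rows = []
    for pred in predictions:
        if pred.response not in directions:
            raise ValueError(f"no declared direction for response {pred.response!r}")
        key = (pred.treatment_id, pred.response)
        if key not in observed.index:
            raise ValueError(f"no observed data for treatment {key}")
        call = classify_interaction(float(observed.loc[key]), pred, directions[pred.response])
        rows.append(
            dict(
                treatment_id=call.treatment_id,
                response=call.response,
                model=call.model,
                observed=call.observed,
                dn=call.dn,
                label=call.label,
            )
        )
    return pd.DataFrame(
        rows, columns=["treatment_id", "response", "model", "observed", "dn", "label"]
    )


def select_best_null(calls: pd.DataFrame) -> pd.DataFrame:
    """SSD per (response, model); flag the best model per response.

    SSD sums squared (observed - prediction mean) over treatments; ties break
    in the order additive, multiplicative, dominative. Raises if any model is
    missing for a response. Expects the prediction mean to be recoverable as
    observed - dn * sd — so it works directly on frames that carry
    ``observed`` and ``pred_mean``; otherwise pass a merged frame.
    """
    if "pred_mean" not in calls.columns:
        raise ValueError("select_best_null needs a 'pred_mean' column (merge predictions first)")
    rows = []
    for response, grp in calls.groupby("response"):
        present = set(grp["model"])
        missing = set(MODELS) - present
        if missing:
            raise ValueError(f"response {response!r} missing models: {sorted(missing)}")
        ssd = {
            m: float(((g["observed"] - g["pred_mean"]) ** 2).sum())
            for m, g in grp.groupby("model")
        }
        best = min(MODELS, key=lambda m: (ssd[m], MODELS.index(m)))
        for m in MODELS:
            rows.append(dict(response=response, model=m, ssd=ssd[m], is_best=m == best))
    return pd.DataFrame(rows, columns=["response", "model", "ssd", "is_best"])


def deviation_group_tests(calls: pd.DataFrame) -> pd.DataFrame:
    """Per (response, level): two-sided one-sample t-test of H0: mean DN = 0.

    ``calls`` must carry a ``level`` column. p-values are BH-adjusted across
    all (response, level) cells; degenerate (zero-variance or n < 2) cells get
    NaN statistics and are excluded from the adjustment.
    """
    if "level" not in calls.columns:
        raise ValueError("deviation_group_tests needs a 'level' column")
    rows = []
    for (response, level), grp in calls.groupby(["response", "level"]):
        dn = grp["dn"].to_numpy(dtype=float)
        if dn.size < 2 or np.allclose(dn.std(ddof=1), 0.0):
            if dn.size >= 2 and np.allclose(dn, 0.0):
                t, p = 0.0, 1.0
            else:
                t, p = np.nan, np.nan
        else:
            t, p = stats.ttest_1samp(dn, 0.0)
        rows.append(
            dict(response=response, level=int(level), n=int(dn.size), t=float(t), p=float(p))
        )
    out = pd.DataFrame(rows, columns=["response", "level", "n", "t", "p"])
    out["p_adj"] = np.nan
    ok = out["p"].notna()
    if ok.any():
        out.loc[ok, "p_adj"] = adjust_pvalues_bh(out.loc[ok, "p"].to_numpy())
    return out


def dn_vs_di_correlation(
    calls: pd.DataFrame, indices: pd.DataFrame, per_level: bool = False
) -> pd.DataFrame:
    """Spearman correlation of DN against normalized DI, per response
    (optionally also per level). Requires >= 3 matched treatments."""
    merged = calls.merge(
        indices[["treatment_id", "level", "di_norm"]], on="treatment_id", how="inner"
    )
    if merged.empty:
        raise ValueError("no matched treatment ids between calls and dissimilarity indices")
    keys = ["response", "level"] if per_level else ["response"]
    rows = []
    for key, grp in merged.groupby(keys):
        if len(grp) < 3:
            raise ValueError(f"fewer than 3 matched pairs for group {key}")
        rho, p = stats.spearmanr(grp["dn"], grp["di_norm"])
        rec = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        rec.update(rho=float(rho), p=float(p), n=int(len(grp)))
        rows.append(rec)
    return pd.DataFrame(rows)
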