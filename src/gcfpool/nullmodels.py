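"""Null models for joint effects of co-acting factors.

A null model predicts the joint effect of N co-acting factors from their
single-factor effect sizes, assuming no interaction:

* additive       — ``P = sum_i ES_i`` (sensitivities negatively correlated);
* multiplicative — ``P = CT * prod_i(1 + ES_i/CT) - CT`` with CT the control
  response (effects combine as proportional changes);
* dominative     — ``P = ES_j`` where ``|ES_j|`` is maximal (the strongest
  factor overrides the rest; ties go to the first occurrence).

All three coincide on a single factor. The bootstrap prediction distribution
resamples the control and each member's single-factor group with replacement,
forms the per-iteration effect sizes ``Z = t_i - c_i``, combines them under the
chosen rule, and adds back the resampled control mean; K iterations give the
distribution of the predicted joint response with its mean and percentile CI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._seeds import stage_rng
from .design import split_factors

__all__ = [
    "MODELS",
    "predict_additive",
    "predict_multiplicative",
    "predict_dominative",
    "point_prediction",
    "NullPrediction",
    "bootstrap_null_distribution",
    "null_predictions",
    "predictions_frame",
]

MODELS = ("additive", "multiplicative", "dominative")


def predict_additive(es_list: Sequence[float]) -> float:
    """Sum of single-factor effect sizes."""
    es = np.asarray(es_list, dtype=float)
    if es.size < 1:
        raise ValueError("need at least one effect size")
    return float(es.sum())


def predict_multiplicative(es_list: Sequence[float], ct: float) -> float:
    """Proportional-change combination relative to the control level CT."""
    es = np.asarray(es_list, dtype=float)
    if es.size < 1:
        raise ValueError("need at least one effect size")
    if ct == 0:
        raise ValueError("multiplicative null model undefined for control level CT = 0")
    brackets = 1.0 + es / ct
    if np.any(brackets <= -1.0):
        warnings.warn(
            "multiplicative bracket (1 + ES/CT) <= -1: proportional-change "
            "combination flips sign; prediction kept as computed",
            RuntimeWarning,
            stacklevel=2,
        )
    return float(ct * np.prod(brackets) - ct)


def predict_dominative(es_list: Sequence[float]) -> float:
    """The signed effect with the largest absolute value (first wins ties)."""
    es = np.asarray(es_list, dtype=float)
    if es.size < 1:
        raise ValueError("need at least one effect size")
    return float(es[np.argmax(np.abs(es))])


def point_prediction(model: str, es_list: Sequence[float], ct: float | None = None) -> float:
    if model == "additive":
        return predict_additive(es_list)
    if model == "multiplicative":
        if ct is None:
            raise ValueError("multiplicative prediction needs the control level ct")
        return predict_multiplicative(es_list, ct)
    if model == "dominative":
        return predict_dominative(es_list)
    raise ValueError(f"unknown null model {model!r}; choose from {MODELS}")


def _combine(Z: np.ndarray, model: str, c: np.ndarray) -> np.ndarray:
    """Vectorized combination of a K x N matrix of effect sizes per the model."""
    if model == "additive":
        return Z.sum(axis=1)
    if model == "multiplicative":
        return c * (np.prod(1.0 + Z / c[:, None], axis=1) - 1.0)
    if model == "dominative":
        idx = np.argmax(np.abs(Z), axis=1)
        return Z[np.arange(Z.shape[0]), idx]
    raise ValueError(f"unknown null model {model!r}; choose from {MODELS}")


@dataclass
class NullPrediction:
    """Bootstrap distribution of the predicted joint response of one treatment
    under one null model."""

    model: str
    draws: np.ndarray
    mean: float
    ci_low: float
    ci_high: float
    n_flagged: int = 0
    treatment_id: str | None = None
    response: str | None = None
    sd: float = field(init=False)

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)
        self.sd = float(self.draws.std(ddof=1)) if self.draws.size > 1 else 0.0


def bootstrap_null_distribution(
    control_values: np.ndarray,
    single_treatment_values: Sequence[np.ndarray],
    model: str,
    K: int = 1000,
    ci_level: float = 0.95,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> NullPrediction:
    """K-draw bootstrap distribution of the predicted joint response.

    Per iteration the control and every member group are independently
    resampled with replacement (one shared control resample per iteration);
    the control mean ``c_i`` and member means ``t_i`` give effect sizes
    ``Z_i = t_i - c_i``; the null rule combines them into ``Z`` (the
    multiplicative rule uses ``CT := c_i``); the predicted joint response is
    ``T_i = c_i + Z``.

    Multiplicative iterations with ``c_i == 0`` are flagged and redrawn
    (``n_flagged`` reports how many).
    """
    if model not in MODELS:
        raise ValueError(f"unknown null model {model!r}; choose from {MODELS}")
    if K < 1:
        raise ValueError("K must be >= 1")
    control = np.asarray(control_values, dtype=float)
    groups = [np.asarray(g, dtype=float) for g in single_treatment_values]
    if control.size == 0 or any(g.size == 0 for g in groups) or not groups:
        raise ValueError("control and every single-factor group must be non-empty")
    if rng is None:
        rng = np.random.default_rng(seed)

    def draw(n_iter: int) -> tuple[np.ndarray, np.ndarray]:
        c = control[rng.integers(0, control.size, size=(n_iter, control.size))].mean(axis=1)
        t = np.stack(
            [g[rng.integers(0, g.size, size=(n_iter, g.size))].mean(axis=1) for g in groups],
            axis=1,
        )
        return c, t

    c, t = draw(K)
    n_flagged = 0
    if model == "multiplicative":
        for _ in range(100):
            bad = c == 0.0
            if not bad.any():
                break
            n_flagged += int(bad.sum())
            c_new, t_new = draw(int(bad.sum()))
            c[bad] = c_new
            t[bad] = t_new
        else:
            raise ValueError("control resamples keep averaging to zero; multiplicative model undefined")
    Z = t - c[:, None]
    T = c + _combine(Z, model, c)
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(T, [alpha, 1.0 - alpha])
    return NullPrediction(
        model=model,
        draws=T,
        mean=float(T.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        n_flagged=n_flagged,
    )


def _group_values(responses: pd.DataFrame, treatment_id: str, response: str) -> np.ndarray:
    mask = (responses["treatment_id"] == treatment_id) & (responses["response"] == response)
    return responses.loc[mask, "value"].to_numpy(dtype=float)


def null_predictions(
    design: pd.DataFrame,
    responses: pd.DataFrame,
    models: Sequence[str] = MODELS,
    K: int = 1000,
    ci_level: float = 0.95,
    seed: int = 0,
) -> list[NullPrediction]:
    """Bootstrap prediction distributions for every multi-factor treatment x
    response x null model.

    Group lookups are keyed on the single-factor treatments ``single_<factor>``
    and the ``control`` treatment. Reproducible: each (treatment, response,
    model) gets its own seed stream derived from ``seed``.
    """
    for m in models:
        if m not in MODELS:
            raise ValueError(f"unknown null model {m!r}; choose from {MODELS}")
    response_names = sorted(responses["response"].unique())
    control_cache = {r: _group_values(responses, "control", r) for r in response_names}
    if any(v.size == 0 for v in control_cache.values()):
        raise ValueError("control group missing from the response table")
    single_cache: dict[tuple[str, str], np.ndarray] = {}
    out: list[NullPrediction] = []
    multi = design[design["kind"] == "multi"]
    for _, row in multi.iterrows():
        members = split_factors(row["factors"])
        for response in response_names:
            singles = []
            for f in members:
                key = (f, response)
                if key not in single_cache:
                    single_cache[key] = _group_values(responses, f"single_{f}", response)
                    if single_cache[key].size == 0:
                        raise ValueError(f"no single-factor data for {f!r} / {response!r}")
                singles.append(single_cache[key])
            for model in models:
                rng = stage_rng(seed, f"nullpred:{row['treatment_id']}:{response}:{model}")
                pred = bootstrap_null_distribution(
                    control_cache[response], singles, model, K=K, ci_level=ci_level, rng=rng
                )
                pred.treatment_id = row["treatment_id"]
                pred.response = response
                out.append(pred)
    return out


def predictions_frame(predictions: Sequence[NullPrediction]) -> pd.DataFrame:
    """Summarize prediction objects as a tidy frame (draws are dropped)."""
    return pd.DataFrame(
        {
            "treatment_id": [p.treatment_id for p in predictions],
            "response": [p.response for p in predictions],
            "model": [p.model for p in predictions],
            "pred_mean": [p.mean for p in predictions],
            "pred_sd": [p.sd for p in predictions],
            "ci_low": [p.ci_low for p in predictions],
            "ci_high": [p.ci_high for p in predictions],
            "n_draws": [p.draws.size for p in predictions],
            "n_flagged": [p.n_flagged for p in predictions],
        }
    )
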