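"""Bootstrap effect sizes of treatment groups versus control.

The effect size of a treatment group is the mean difference from the control
group, estimated by a nonparametric bootstrap: both groups are resampled with
replacement B times, the statistic is mean(treatment resample) minus
mean(control resample), the reported effect is the mean of the bootstrap
distribution, and the CI is its percentile interval. Two-sided p-values come
from the bootstrap sign frequency, and significance across treatments within
one response family is controlled with the Benjamini-Hochberg step-up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._seeds import stage_rng

__all__ = [
    "EffectEstimate",
    "bootstrap_effect_size",
    "adjust_pvalues_bh",
    "effects_table",
]


@dataclass
class EffectEstimate:
    treatment_id: str | None
    response: str | None
    effect: float
    ci_low: float
    ci_high: float
    p_raw: float
    p_adj: float | None = None


def bootstrap_effect_size(
    treatment_values: np.ndarray,
    control_values: np.ndarray,
    B: int = 10_000,
    ci_level: float = 0.95,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> EffectEstimate:
    """Bootstrap mean-difference effect size with percentile CI and p-value.

    p_raw = 2 * min(Pr(stat <= 0), Pr(stat >= 0)), clipped to [2/B, 1].
    """
    t = np.asarray(treatment_values, dtype=float)
    c = np.asarray(control_values, dtype=float)
    if t.size == 0 or c.size == 0:
        raise ValueError("treatment and control groups must be non-empty")
    if B < 1:
        raise ValueError("B must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    t_means = t[rng.integers(0, t.size, size=(B, t.size))].mean(axis=1)
    c_means = c[rng.integers(0, c.size, size=(B, c.size))].mean(axis=1)
    stat = t_means - c_means
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(stat, [alpha, 1.0 - alpha])
    p = 2.0 * min((stat <= 0).mean(), (stat >= 0).mean())
    p = float(np.clip(p, 2.0 / B, 1.0))
    return EffectEstimate(
        treatment_id=None,
        response=None,
        effect=float(stat.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        p_raw=p,
    )


def adjust_pvalues_bh(p_raw) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving, clipped at 1."""
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def effects_table(
    design: pd.DataFrame,
    responses: pd.DataFrame,
    B: int = 10_000,
    ci_level: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """One bootstrap effect estimate per (non-control treatment x response).

    Water-control units are excluded. BH adjustment is applied within each
    response family across treatments. Each (treatment, response) cell draws
    from its own seed stream, so results do not depend on iteration order.
    """
    control_ids = set(design.loc[design["kind"] == "control", "treatment_id"])
    if not control_ids:
        raise ValueError("design contains no control treatment")
    test_ids = design.loc[design["kind"].isin(["single", "multi"]), "treatment_id"].tolist()
    response_names = sorted(responses["response"].unique())

    by_group = {
        (tid, resp): grp["value"].to_numpy(dtype=float)
        for (tid, resp), grp in responses.groupby(["treatment_id", "response"])
    }
    rows = []
    for response in response_names:
        control = np.concatenate(
            [by_group.get((cid, response), np.empty(0)) for cid in sorted(control_ids)]
        )
        if control.size == 0:
            raise ValueError(f"no control observations for response {response!r}")
        for tid in test_ids:
            values = by_group.get((tid, response))
            if values is None or values.size == 0:
                raise ValueError(f"no observations for treatment {tid!r} / {response!r}")
            est = bootstrap_effect_size(
                values,
                control,
                B=B,
                ci_level=ci_level,
                rng=stage_rng(seed, f"effects:{tid}:{response}"),
            )
            rows.append(
                dict(
                    treatment_id=tid,
                    response=response,
                    effect=est.effect,
                    ci_low=est.ci_low,
                    ci_high=est.ci_high,
                    p_raw=est.p_raw,
                )
            )
    table = pd.DataFrame(rows)
    table["p_adj"] = np.nan
    for response in response_names:
        mask = table["response"] == response
        table.loc[mask, "p_adj"] = adjust_pvalues_bh(table.loc[mask, "p_raw"].to_numpy())
    return table
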