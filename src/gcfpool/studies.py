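"""Seeded simulation studies validating the pipeline against known truth.

Each study generates synthetic experiments with the generator's reference
conditions (20 controls, 8 replicates per single factor, unit noise sigma = 1
unless stated), runs the relevant pipeline stage, and reports recovery or
calibration rates. They double as the package's operating characteristics:

* :func:`calibration_study` — type-I error of the interaction classifier
  under a correctly specified null world with no interactions;
* :func:`synergy_recovery_study` — power to recover injected
  distance-proportional synergy and the induced DN-DI correlation;
* :func:`best_null_recovery_study` — how often SSD selection identifies the
  generating null world at low noise;
* :func:`hierarchy_recovery_study` — whether Models 4/5 detect injected
  number-of-factors / dissimilarity terms (and stay quiet without them).

Classifier calibration is an asymptotic property (derivation in
docs/methods.md): the "no interaction" rate approaches the nominal 95% only
when (a) the observed treatment mean's own noise is small against the
bootstrap prediction spread — with the reference single replicate per
multi-factor treatment the extra sigma^2 term pushes coverage to ~65%
regardless of the classifier — and (b) the single-factor and control groups
are large enough that the percentile bootstrap's (n-1)/n variance shrinkage
and the sampling variability of the group variances stop eroding coverage
(the percentile interval behaves like a z-interval where a t-interval is
needed: with the dominative prediction resting on a single group of n the
two-sided coverage is ~P(|t_{n-1}| < 1.96 * sqrt((n-1)/n)), ~92.3% at
n = 24). The calibration study therefore uses 48 single-factor replicates,
120 controls and 700 replicates per multi-factor treatment — sized so the
t-correction erosion is under ~1.5 points and the observed-mean variance
stays below ~5% of the *smallest* prediction variance across the three
worlds, the dominative one (1/48 + 1/120). The power study, which measures
detection rather than coverage, keeps the reference 8/20 groups with 40
replicates per multi-factor treatment.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._seeds import stage_rng, stage_seed
from .design import DEFAULT_FACTORS, FactorPool, sample_design, split_factors
from .dissimilarity import dissimilarity_table, distance_matrix_from_effects
from .effects import effects_table
from .hierarchy import build_feature_table, fit_hierarchy, permutation_importance
from .interactions import dn_vs_di_correlation, interaction_calls, select_best_null
from .nullmodels import MODELS, null_predictions, predictions_frame
from .synthetic import GroundTruth, InteractionRule, gamma_for_mean_shift, make_ground_truth, simulate_experiment

__all__ = [
    "calibration_study",
    "synergy_recovery_study",
    "best_null_recovery_study",
    "hierarchy_recovery_study",
    "importance_calibration_study",
]

#: Two-response truth used by the studies: one response expected to rise under
#: stress, one to fall, so both classification branches are exercised.
_STUDY_RESPONSES = ("up_response", "down_response")
_STUDY_DIRECTIONS = {"up_response": +1, "down_response": -1}

#: Replication of the calibration study (see module docstring).
CALIBRATION_PLAN = {"control": 120, "water_control": 0, "single": 48, "multi": 700}

#: Replicates per multi-factor treatment in the power study.
N_MULTI_REPLICATES = 40


def _study_truth(
    world: str,
    seed: int,
    sigma: float = 1.0,
    responses: Sequence[str] = _STUDY_RESPONSES,
    interaction: InteractionRule | None = None,
) -> GroundTruth:
    directions = {r: _STUDY_DIRECTIONS.get(r, +1) for r in responses}
    truth = make_ground_truth(
        {
            "responses": tuple(responses),
            "directions": directions,
            "control_mean": 10.0,
            "control_sd": sigma,
            "effect_mean": 0.5,
            "effect_sd": 1.0,
            "world": world,
        },
        seed=seed,
    )
    if interaction is not None:
        truth = dataclasses.replace(truth, interaction=interaction)
    return truth


def calibration_study(
    world: str,
    n_replicates: int = 300,
    levels: Sequence[int] = (2, 5),
    n_per_level: int = 2,
    K: int = 1000,
    sigma: float = 1.0,
    seed: int = 0,
) -> dict:
    """Type-I error of the classifier under a pure null world.

    Per replicate a fresh truth (no interactions) and design are drawn, data
    are simulated, and every multi-factor treatment x response is classified
    against the *matching* null model's bootstrap prediction distribution.
    Returns pooled label rates over all treatment x replicate cases.

    Flags are strongly correlated within a replicate (all treatments share
    the same realized single-factor samples), so the default uses many
    replicates with few treatments each rather than the reverse.
    """
    if world not in MODELS:
        raise ValueError(f"unknown world {world!r}")
    pool = FactorPool(DEFAULT_FACTORS)
    counts = {"synergistic": 0, "antagonistic": 0, "none": 0}
    for rep in range(n_replicates):
        truth = _study_truth(world, seed=stage_seed(seed, f"cal-truth:{world}:{rep}"), sigma=sigma)
        design = sample_design(
            pool,
            levels=levels,
            n_per_level=n_per_level,
            replicate_plan=CALIBRATION_PLAN,
            seed=stage_seed(seed, f"cal-design:{world}:{rep}"),
        )
        responses = simulate_experiment(
            truth, design, seed=stage_seed(seed, f"cal-sim:{world}:{rep}")
        )
        preds = null_predictions(
            design, responses, models=(world,), K=K,
            seed=stage_seed(seed, f"cal-pred:{world}:{rep}"),
        )
        calls = interaction_calls(preds, responses, truth.directions)
        for label, n in calls["label"].value_counts().items():
            counts[label] += int(n)
    total = sum(counts.values())
    return {
        "world": world,
        "n_cases": total,
        "none_rate": counts["none"] / total,
        "synergistic_rate": counts["synergistic"] / total,
        "antagonistic_rate": counts["antagonistic"] / total,
    }


def synergy_recovery_study(
    n_replicates: int = 100,
    n_treatments: int = 50,
    K: int = 1000,
    B: int = 1000,
    sigma: float = 1.0,
    seed: int = 0,
) -> dict:
    """Power to recover injected distance-proportional synergy (2-factor level).

    The truth uses the reference seven-response structure so the true factor
    distances are 7-dimensional (concentrated, as in the real design), and the
    interaction sign equals each response's direction, making every injected
    term synergistic. gamma is calibrated per replicate so the mean injected
    interaction equals three standard errors of the detection statistic
    (observed treatment mean minus prediction mean), i.e.
    3 * sigma * sqrt(2/n_single + 1/n_control + 1/n_multi) — the textbook
    ~85%-power shift for a two-sided test at the 95% level, eroded a few
    points by the spread of pair distances across treatments.
    Reports the pooled fraction of treatment x response cases labeled
    synergistic under the generating (additive) null and how often
    Spearman(DN, DI_norm) pooled over responses is significantly positive.
    """
    pool = FactorPool(DEFAULT_FACTORS)
    n_single, n_control = 8, 20
    target_shift = 3.0 * sigma * np.sqrt(
        2.0 / n_single + 1.0 / n_control + 1.0 / N_MULTI_REPLICATES
    )
    n_syn = n_total = 0
    n_sig_pos = 0
    rhos = []
    for rep in range(n_replicates):
        design = sample_design(
            pool,
            levels=(2,),
            n_per_level=n_treatments,
            replicate_plan={"water_control": 0, "multi": N_MULTI_REPLICATES},
            seed=stage_seed(seed, f"syn-design:{rep}"),
        )
        base = make_ground_truth(
            {"control_mean": 10.0, "control_sd": sigma, "world": "additive"},
            seed=stage_seed(seed, f"syn-truth:{rep}"),
        )
        gamma = gamma_for_mean_shift(base, design, target_shift)
        truth = dataclasses.replace(
            base,
            interaction=InteractionRule(
                "distance_proportional", gamma=gamma, sign=dict(base.directions)
            ),
        )
        responses = simulate_experiment(truth, design, seed=stage_seed(seed, f"syn-sim:{rep}"))
        preds = null_predictions(
            design, responses, models=("additive",), K=K,
            seed=stage_seed(seed, f"syn-pred:{rep}"),
        )
        calls = interaction_calls(preds, responses, truth.directions)
        n_syn += int((calls["label"] == "synergistic").sum())
        n_total += len(calls)

        effects = effects_table(
            design, responses, B=B, seed=stage_seed(seed, f"syn-eff:{rep}")
        )
        single = effects[effects["treatment_id"].str.startswith("single_")].copy()
        single["factor"] = single["treatment_id"].str.removeprefix("single_")
        matrix = single.pivot(index="factor", columns="response", values="effect")
        dm = distance_matrix_from_effects(matrix)
        di = dissimilarity_table(design, dm)
        # DN is signed toward synergy per each response's direction before pooling
        signed = calls.copy()
        signed["dn"] = signed["dn"] * signed["response"].map(truth.directions)
        signed["response"] = "all"
        corr = dn_vs_di_correlation(signed, di)
        rho, p = float(corr["rho"].iloc[0]), float(corr["p"].iloc[0])
        rhos.append(rho)
        if rho > 0 and p < 0.05:
            n_sig_pos += 1
    return {
        "n_replicates": n_replicates,
        "synergistic_fraction": n_syn / n_total,
        "spearman_significant_fraction": n_sig_pos / n_replicates,
        "mean_rho": float(np.mean(rhos)),
    }


def best_null_recovery_study(
    n_replicates: int = 100,
    sigma: float = 0.05,
    K: int = 300,
    seed: int = 0,
) -> dict:
    """How often SSD selection recovers the generating null world.

    Low-noise setting: unit sigma = 0.05 against single-factor effects of
    order 1 and a control level of 10, so the three worlds' predictions are
    well separated relative to all estimation noise.
    """
    pool = FactorPool(DEFAULT_FACTORS)
    hits = {m: 0 for m in MODELS}
    for rep in range(n_replicates):
        design = sample_design(
            pool,
            levels=(2, 5),
            n_per_level=12,
            replicate_plan={"water_control": 0, "multi": 4},
            seed=stage_seed(seed, f"bn-design:{rep}"),
        )
        for world in MODELS:
            truth = _study_truth(
                world, seed=stage_seed(seed, f"bn-truth:{world}:{rep}"), sigma=sigma,
                responses=("up_response",),
            )
            responses = simulate_experiment(
                truth, design, seed=stage_seed(seed, f"bn-sim:{world}:{rep}")
            )
            preds = null_predictions(
                design, responses, K=K, seed=stage_seed(seed, f"bn-pred:{world}:{rep}")
            )
            calls = interaction_calls(preds, responses, truth.directions)
            merged = calls.merge(
                predictions_frame(preds)[["treatment_id", "response", "model", "pred_mean"]],
                on=["treatment_id", "response", "model"],
            )
            best = select_best_null(merged)
            chosen = best.loc[best["is_best"], "model"].iloc[0]
            hits[world] += int(chosen == world)
    return {
        "n_replicates": n_replicates,
        "recovery_rate": {m: hits[m] / n_replicates for m in MODELS},
        "overall_recovery_rate": sum(hits.values()) / (3 * n_replicates),
    }


def _true_di_norm(truth: GroundTruth, design: pd.DataFrame) -> pd.Series:
    """Within-level range-normalized DI computed from the *true* distances."""
    dm = truth.factor_distances()
    di = dissimilarity_table(design, dm)
    return di.set_index("treatment_id")["di_norm"]


def _simulate_with_extra_term(
    truth: GroundTruth,
    design: pd.DataFrame,
    kind: str,
    beta: float,
    seed: int,
) -> pd.DataFrame:
    """Additive-world responses plus an injected beta * n_factors or
    beta * true-DI term on multi-factor units ("none" injects nothing)."""
    responses = simulate_experiment(truth, design, seed=seed)
    if kind == "none" or beta == 0.0:
        return responses
    if kind == "n_factors":
        extra = design.set_index("treatment_id")["level"].astype(float) * beta
    elif kind == "di_norm":
        extra = _true_di_norm(truth, design) * beta
        extra = extra.reindex(design["treatment_id"].unique(), fill_value=0.0)
    else:
        raise ValueError(f"unknown injected-term kind {kind!r}")
    multi_ids = set(design.loc[design["kind"] == "multi", "treatment_id"])
    add = responses["treatment_id"].map(lambda t: extra.get(t, 0.0) if t in multi_ids else 0.0)
    out = responses.copy()
    out["value"] = out["value"] + add
    return out


def hierarchy_recovery_study(
    kind: str,
    n_replicates: int = 40,
    beta: float = 1.0,
    sigma: float = 1.0,
    B: int = 1000,
    K: int = 300,
    seed: int = 0,
) -> dict:
    """Does the hierarchy detect an injected term beyond the identity baseline?

    ``kind`` is "n_factors" (Model 4 should win over Model 1), "di_norm"
    (Model 5 should win), or "none" (both increments should be ~0). beta = 1
    with sigma = 1 puts the injected term well above the noise (the
    number-of-factors term spans 2..8, the DI term 0..1 within a level... the
    DI study scales beta by 5 to reach a comparable signal).
    """
    if kind not in ("n_factors", "di_norm", "none"):
        raise ValueError(f"unknown kind {kind!r}")
    pool = FactorPool(DEFAULT_FACTORS)
    model_id = {"n_factors": 4, "di_norm": 5}.get(kind)
    eff_beta = beta * (5.0 if kind == "di_norm" else 1.0)
    wins = 0
    deltas = {4: [], 5: []}
    for rep in range(n_replicates):
        design = sample_design(
            pool,
            levels=(2, 5, 8),
            n_per_level=15,
            replicate_plan={"water_control": 0, "multi": 1},
            seed=stage_seed(seed, f"hr-design:{kind}:{rep}"),
        )
        truth = _study_truth(
            "additive", seed=stage_seed(seed, f"hr-truth:{kind}:{rep}"), sigma=sigma,
            responses=("up_response",),
        )
        responses = _simulate_with_extra_term(
            truth, design, kind, eff_beta, seed=stage_seed(seed, f"hr-sim:{kind}:{rep}")
        )
        effects = effects_table(design, responses, B=B, seed=stage_seed(seed, f"hr-eff:{kind}:{rep}"))
        preds = null_predictions(
            design, responses, K=K, seed=stage_seed(seed, f"hr-pred:{kind}:{rep}")
        )
        pred_frame = predictions_frame(preds)
        single = effects[effects["treatment_id"].str.startswith("single_")].copy()
        single["factor"] = single["treatment_id"].str.removeprefix("single_")
        matrix = single.pivot(index="factor", columns="response", values="effect")
        di = dissimilarity_table(design, distance_matrix_from_effects(matrix))
        features = build_feature_table(design, responses, effects, pred_frame, di, pool.factors)
        reports = fit_hierarchy(features, backend="glm", seed=stage_seed(seed, f"hr-fit:{kind}:{rep}"))
        models = reports["up_response"].models
        for mid in (4, 5):
            deltas[mid].append(models[mid]["delta_r2"])
        if model_id is not None:
            if models[model_id]["delta_r2"] > 0 and models[model_id]["aic"] < models[1]["aic"]:
                wins += 1
    out = {
        "kind": kind,
        "n_replicates": n_replicates,
        "mean_delta_r2_model4": float(np.mean(deltas[4])),
        "mean_delta_r2_model5": float(np.mean(deltas[5])),
    }
    if model_id is not None:
        out["win_rate"] = wins / n_replicates
    return out


def importance_calibration_study(
    n_replicates: int = 12,
    n_perm: int = 60,
    n_estimators: int = 60,
    sigma: float = 1.0,
    seed: int = 0,
) -> dict:
    """Altmann permutation p-values for n_factors / di_norm when neither
    truly matters: they should be roughly uniform (mean ~0.5, few < 0.05)."""
    pool = FactorPool(DEFAULT_FACTORS)
    pvalues = []
    for rep in range(n_replicates):
        design = sample_design(
            pool,
            levels=(2, 5, 8),
            n_per_level=10,
            replicate_plan={"water_control": 0, "multi": 1},
            seed=stage_seed(seed, f"imp-design:{rep}"),
        )
        truth = _study_truth(
            "additive", seed=stage_seed(seed, f"imp-truth:{rep}"), sigma=sigma,
            responses=("up_response",),
        )
        responses = simulate_experiment(truth, design, seed=stage_seed(seed, f"imp-sim:{rep}"))
        effects = effects_table(design, responses, B=1000, seed=stage_seed(seed, f"imp-eff:{rep}"))
        preds = null_predictions(design, responses, K=300, seed=stage_seed(seed, f"imp-pred:{rep}"))
        single = effects[effects["treatment_id"].str.startswith("single_")].copy()
        single["factor"] = single["treatment_id"].str.removeprefix("single_")
        matrix = single.pivot(index="factor", columns="response", values="effect")
        di = dissimilarity_table(design, distance_matrix_from_effects(matrix))
        features = build_feature_table(
            design, responses, effects, predictions_frame(preds), di, pool.factors
        )
        imp = permutation_importance(
            features,
            features["y"].to_numpy(),
            ["null_additive", "null_multiplicative", "null_dominative", "n_factors", "di_norm"],
            n_perm=n_perm,
            seed=stage_seed(seed, f"imp-perm:{rep}"),
            n_estimators=n_estimators,
        )
        for pred in ("n_factors", "di_norm"):
            pvalues.append(float(imp.loc[imp["predictor"] == pred, "p_raw"].iloc[0]))
    pvalues = np.asarray(pvalues)
    return {
        "n_pvalues": int(pvalues.size),
        "mean_p": float(pvalues.mean()),
        "fraction_below_0.05": float((pvalues < 0.05).mean()),
    }
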