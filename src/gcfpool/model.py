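"""Model/Results front-end over the full analysis.

:class:`MultiFactorExperiment` bundles a design table and a response table
(measured or simulated) and ``fit()`` runs the whole chain — bootstrap effect
sizes, factor distances and dissimilarity indices, null-model prediction
distributions, net-interaction classification, best-null selection, deviation
statistics, within-level trends, and the seven-model hierarchy — returning a
:class:`MultiFactorResults` that carries every stage output and renders a
text ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._seeds import stage_seed
from .correlations import spearman_trend
from .design import DEFAULT_FACTORS, FactorPool, default_design, design_summary, validate_design
from .dissimilarity import (
    dissimilarity_table,
    distance_matrix_from_effects,
    hierarchical_cluster,
    pcoa,
)
from .effects import effects_table
from .hierarchy import build_feature_table, fit_hierarchy
from .interactions import (
    deviation_group_tests,
    dn_vs_di_correlation,
    interaction_calls,
    select_best_null,
)
from .nullmodels import null_predictions, predictions_frame
from .synthetic import DEFAULT_DIRECTIONS, make_ground_truth, simulate_experiment

__all__ = ["MultiFactorExperiment", "MultiFactorResults", "normalize_directions"]


def normalize_directions(directions: Mapping[str, object]) -> dict[str, int]:
    """Accept +1/-1 or 'positive'/'negative' and return the integer form."""
    out: dict[str, int] = {}
    for resp, d in directions.items():
        if d in (+1, -1):
            out[resp] = int(d)
        elif isinstance(d, str) and d.lower() in ("positive", "negative"):
            out[resp] = +1 if d.lower() == "positive" else -1
        else:
            raise ValueError(f"direction for {resp!r} must be +1/-1 or 'positive'/'negative'")
    return out


@dataclass
class MultiFactorResults:
    """All fitted quantities of one experiment; produced by ``fit()``."""

    design: pd.DataFrame
    effects: pd.DataFrame
    single_effect_matrix: pd.DataFrame
    distance_matrix: pd.DataFrame
    dissimilarity: pd.DataFrame
    pcoa_coordinates: pd.DataFrame
    pcoa_variance_fractions: np.ndarray
    newick: str
    null_predictions: pd.DataFrame
    interaction_calls: pd.DataFrame
    best_null: pd.DataFrame
    level_tests: pd.DataFrame
    dn_di_correlations: pd.DataFrame
    trends: pd.DataFrame
    hierarchy: dict | None = None
    seed: int = 0

    @property
    def best_calls(self) -> pd.DataFrame:
        """Interaction calls restricted to each response's best-fitting null."""
        best = self.best_null[self.best_null["is_best"]][["response", "model"]]
        return self.interaction_calls.merge(best, on=["response", "model"])

    def label_counts(self) -> pd.DataFrame:
        """Per response: counts of synergistic / antagonistic / none under the
        best-fitting null model."""
        return (
            self.best_calls.groupby(["response", "label"])
            .size()
            .unstack(fill_value=0)
            .reindex(columns=["synergistic", "antagonistic", "none"], fill_value=0)
        )

    def summary(self) -> str:
        lines = ["Multi-factor experiment — fit summary", "=" * 46]
        s = design_summary(self.design)
        lines.append(
            f"design: {s['total_treatments']} treatments, {s['total_units']} units "
            f"({s['units_per_kind']})"
        )
        n_resp = self.effects["response"].nunique()
        lines.append(
            f"effect sizes: {len(self.effects)} estimates over {n_resp} responses "
            f"({int((self.effects['p_adj'] < 0.05).sum())} with BH-adjusted p < 0.05)"
        )
        fr = ", ".join(f"{100 * f:.1f}%" for f in self.pcoa_variance_fractions[:2])
        lines.append(f"factor ordination: PCoA axes explain {fr}")
        lines.append("")
        lines.append("best-fitting null model and net-interaction calls per response:")
        counts = self.label_counts()
        best = self.best_null[self.best_null["is_best"]].set_index("response")["model"]
        for resp in counts.index:
            c = counts.loc[resp]
            lines.append(
                f"  {resp:<22s} {best.loc[resp]:<14s} "
                f"syn={int(c['synergistic']):3d}  ant={int(c['antagonistic']):3d}  "
                f"none={int(c['none']):3d}"
            )
        lines.append("")
        lines.append("Spearman DN vs normalized DI (best null model):")
        for _, row in self.dn_di_correlations.iterrows():
            lines.append(
                f"  {row['response']:<22s} rho={row['rho']:+.3f}  p={row['p']:.3g}  n={int(row['n'])}"
            )
        if self.hierarchy:
            lines.append("")
            lines.append("hierarchy (R² by model, delta vs baseline):")
            for resp, rep in self.hierarchy.items():
                m = rep.models
                lines.append(
                    f"  {resp:<22s} M1={m[1]['r2']:.3f}  "
                    f"dR²(+n)={m[4].get('delta_r2', float('nan')):+.3f}  "
                    f"dR²(+DI)={m[5].get('delta_r2', float('nan')):+.3f}  "
                    f"M7={m[7]['r2']:.3f}"
                )
        return "\n".join(lines)

    def plot_dn_vs_di(self, response: str, ax=None):
        """Scatter of rescaled deviation against normalized DI, colored by
        interaction label, for one response (best-fitting null model)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        data = self.best_calls.merge(
            self.dissimilarity[["treatment_id", "di_norm"]], on="treatment_id"
        )
        data = data[data["response"] == response]
        colors = {"synergistic": "tab:red", "antagonistic": "tab:blue", "none": "0.6"}
        for label, grp in data.groupby("label"):
            ax.scatter(grp["di_norm"], grp["dn"], s=18, c=colors[label], label=label)
        ax.axhline(0.0, color="k", lw=0.8)
        ax.set_xlabel("normalized dissimilarity index")
        ax.set_ylabel("rescaled deviation from null (DN)")
        ax.set_title(response)
        ax.legend(frameon=False, fontsize=8)
        return ax

    def plot_effects(self, response: str, ax=None):
        """Forest-style plot of effect sizes with bootstrap CIs."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 6))
        data = self.effects[self.effects["response"] == response]
        y = np.arange(len(data))
        ax.errorbar(
            data["effect"],
            y,
            xerr=[data["effect"] - data["ci_low"], data["ci_high"] - data["effect"]],
            fmt="o",
            ms=3,
            lw=0.8,
        )
        ax.axvline(0.0, color="k", lw=0.8)
        ax.set_yticks(y)
        ax.set_yticklabels(data["treatment_id"], fontsize=6)
        ax.set_xlabel(f"effect size on {response}")
        return ax


class MultiFactorExperiment:
    """A randomized factor-pool experiment ready to fit.

    Parameters
    ----------
    design, responses:
        Tidy tables following the design/responses CSV schemas.
    directions:
        Response name -> +1 (expected increase under stress) or -1.
    pool:
        Factor pool; defaults to the 12 reference factors present in the
        design's single-factor treatments.
    B, K, ci_level:
        Effect-size bootstrap depth, null-model bootstrap depth, and CI level.
    """

    def __init__(
        self,
        design: pd.DataFrame,
        responses: pd.DataFrame,
        directions: Mapping[str, object] | None = None,
        pool: FactorPool | None = None,
        B: int = 10_000,
        K: int = 1000,
        ci_level: float = 0.95,
    ) -> None:
        validate_design(design, pool=pool)
        if B < 1 or K < 1:
            raise ValueError("bootstrap depths B and K must be >= 1")
        if not 0.0 < ci_level < 1.0:
            raise ValueError("ci_level must be in (0, 1)")
        self.design = design.reset_index(drop=True)
        self.responses = responses.reset_index(drop=True)
        if pool is None:
            singles = design.loc[design["kind"] == "single", "factors"].tolist()
            pool = FactorPool(tuple(singles) if singles else DEFAULT_FACTORS)
        self.pool = pool
        response_names = sorted(self.responses["response"].unique())
        if directions is None:
            directions = {r: DEFAULT_DIRECTIONS.get(r, +1) for r in response_names}
        self.directions = normalize_directions(directions)
        missing = set(response_names) - set(self.directions)
        if missing:
            raise ValueError(f"no declared direction for responses: {sorted(missing)}")
        self.B, self.K, self.ci_level = B, K, ci_level
        self.ground_truth = None  # set by from_config

    @classmethod
    def from_config(cls, config: Mapping | None = None, seed: int = 0) -> "MultiFactorExperiment":
        """Simulate a synthetic experiment from a ground-truth config.

        The design defaults to the reference layout (levels 2/5/8, 50 draws per
        level, 276 units); design parameters may be overridden via the
        ``design`` sub-mapping (levels, n_per_level, replicate_plan).
        """
        cfg = dict(config or {})
        truth = make_ground_truth(cfg.get("truth", cfg.get("ground_truth", {})),
                                  seed=stage_seed(seed, "truth"))
        pool = FactorPool(truth.factors)
        dcfg = dict(cfg.get("design", {}))
        from .design import sample_design

        design = sample_design(
            pool,
            levels=tuple(dcfg.get("levels", (2, 5, 8))),
            n_per_level=int(dcfg.get("n_per_level", 50)),
            replicate_plan=dcfg.get("replicate_plan"),
            seed=stage_seed(seed, "design"),
        )
        responses = simulate_experiment(truth, design, seed=stage_seed(seed, "simulate"))
        exp = cls(
            design,
            responses,
            directions=truth.directions,
            pool=pool,
            B=int(cfg.get("B", 10_000)),
            K=int(cfg.get("K", 1000)),
            ci_level=float(cfg.get("ci_level", 0.95)),
        )
        exp.ground_truth = truth
        return exp

    def fit(
        self,
        seed: int = 0,
        hierarchy_backend: str | None = "glm",
        n_perm: int = 0,
        n_estimators: int = 200,
    ) -> MultiFactorResults:
        """Run the full analysis chain; deterministic under ``seed``."""
        effects = effects_table(
            self.design, self.responses, B=self.B, ci_level=self.ci_level,
            seed=stage_seed(seed, "effects"),
        )
        single = effects[effects["treatment_id"].str.startswith("single_")].copy()
        single["factor"] = single["treatment_id"].str.removeprefix("single_")
        effect_matrix = (
            single.pivot(index="factor", columns="response", values="effect")
            .reindex(index=list(self.pool.factors))
        )
        dm = distance_matrix_from_effects(effect_matrix)
        di = dissimilarity_table(self.design, dm)
        coords, fractions = pcoa(dm, n_axes=2)
        _, newick = hierarchical_cluster(dm)

        preds = null_predictions(
            self.design, self.responses, K=self.K, ci_level=self.ci_level,
            seed=stage_seed(seed, "nullpred"),
        )
        pred_frame = predictions_frame(preds)
        calls = interaction_calls(preds, self.responses, self.directions)
        merged = calls.merge(
            pred_frame[["treatment_id", "response", "model", "pred_mean"]],
            on=["treatment_id", "response", "model"],
        )
        best = select_best_null(merged)
        level_map = self.design.set_index("treatment_id")["level"]
        best_models = best[best["is_best"]][["response", "model"]]
        best_calls = calls.merge(best_models, on=["response", "model"]).copy()
        best_calls["level"] = best_calls["treatment_id"].map(level_map).astype(int)
        level_tests = deviation_group_tests(best_calls)
        dn_di = dn_vs_di_correlation(best_calls, di)
        trends = spearman_trend(self.responses, di, self.design)

        hierarchy = None
        if hierarchy_backend is not None:
            features = build_feature_table(
                self.design, self.responses, effects, pred_frame, di, self.pool.factors
            )
            hierarchy = fit_hierarchy(
                features,
                backend=hierarchy_backend,
                seed=stage_seed(seed, "hierarchy"),
                n_estimators=n_estimators,
                n_perm=n_perm,
            )

        return MultiFactorResults(
            design=self.design,
            effects=effects,
            single_effect_matrix=effect_matrix,
            distance_matrix=dm,
            dissimilarity=di,
            pcoa_coordinates=coords,
            pcoa_variance_fractions=fractions,
            newick=newick,
            null_predictions=pred_frame,
            interaction_calls=calls,
            best_null=best,
            level_tests=level_tests,
            dn_di_correlations=dn_di,
            trends=trends,
            hierarchy=hierarchy,
            seed=seed,
        )
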