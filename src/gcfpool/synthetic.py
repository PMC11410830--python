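"""Synthetic microcosm data with known ground truth.

The generator emulates the structure of a randomized factor-pool soil
experiment: a control level per response, a matrix of true single-factor
effects, a combination rule per response (one of the three null-model worlds),
optional pairwise interaction terms, and homoscedastic Gaussian unit noise.
Every downstream stage of the pipeline can therefore be tested against known
truth without any external data.

Default dimensions mirror the reference experiment: 12 factors x 7 soil
responses (decomposition rate, pH, water-stable aggregates, and four
extracellular enzyme activities). Responses with an expected negative
direction under stress (decomposition rate, WSA) get negative mean effects so
the direction-dependent classification branch is exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .design import DEFAULT_FACTORS, split_factors
from .nullmodels import MODELS, point_prediction

__all__ = [
    "DEFAULT_RESPONSES",
    "DEFAULT_DIRECTIONS",
    "InteractionRule",
    "GroundTruth",
    "make_ground_truth",
    "simulate_experiment",
    "gamma_for_mean_shift",
]

DEFAULT_RESPONSES: tuple[str, ...] = (
    "decomposition_rate",
    "ph",
    "wsa",
    "nag",
    "cellulase",
    "beta_glucosidase",
    "phosphatase",
)

#: +1 = response expected to increase under stress, -1 = decrease.
DEFAULT_DIRECTIONS: dict[str, int] = {
    "decomposition_rate": -1,
    "ph": +1,
    "wsa": -1,
    "nag": +1,
    "cellulase": +1,
    "beta_glucosidase": +1,
    "phosphatase": +1,
}


@dataclass(frozen=True)
class InteractionRule:
    """How pairwise interaction terms are injected into multi-factor units.

    kind = "none"                  — pure null world;
    kind = "fixed"                 — each unordered member pair adds ``gamma``;
    kind = "distance_proportional" — each pair (i, j) adds
    ``sign * gamma * d_ij`` where ``d_ij`` is the Euclidean distance between
    the true effect profiles of i and j (synergy growing with dissimilarity
    when ``sign`` matches the response direction).

    ``sign`` is +1/-1, applied to every response, or a mapping
    response -> +1/-1 (set it equal to each response's direction to make the
    injected interaction synergistic everywhere).
    """

    kind: str = "none"
    gamma: float = 0.0
    sign: int | Mapping[str, int] = +1

    def __post_init__(self) -> None:
        if self.kind not in ("none", "fixed", "distance_proportional"):
            raise ValueError(f"unknown interaction rule {self.kind!r}")
        signs = self.sign.values() if isinstance(self.sign, Mapping) else (self.sign,)
        if any(s not in (-1, +1) for s in signs):
            raise ValueError("interaction sign must be +1 or -1")

    def sign_for(self, response: str) -> int:
        if isinstance(self.sign, Mapping):
            try:
                return self.sign[response]
            except KeyError:
                raise ValueError(f"no interaction sign declared for response {response!r}") from None
        return self.sign


@dataclass
class GroundTruth:
    """Generative truth of a synthetic experiment."""

    factors: tuple[str, ...]
    responses: tuple[str, ...]
    control_mean: np.ndarray
    control_sd: np.ndarray
    effect_matrix: np.ndarray  # factors x responses
    world: dict[str, str]  # response -> null-model world
    interaction: InteractionRule = field(default_factory=InteractionRule)
    directions: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.factors = tuple(self.factors)
        self.responses = tuple(self.responses)
        self.control_mean = np.asarray(self.control_mean, dtype=float)
        self.control_sd = np.asarray(self.control_sd, dtype=float)
        self.effect_matrix = np.asarray(self.effect_matrix, dtype=float)
        F, R = len(self.factors), len(self.responses)
        if self.control_mean.shape != (R,) or self.control_sd.shape != (R,):
            raise ValueError("control_mean/control_sd must have one entry per response")
        if self.effect_matrix.shape != (F, R):
            raise ValueError(
                f"effect_matrix must be factors x responses = {(F, R)}, got {self.effect_matrix.shape}"
            )
        if np.any(self.control_sd < 0):
            raise ValueError("control_sd must be >= 0")
        missing = set(self.responses) - set(self.world)
        if missing:
            raise ValueError(f"world not declared for responses: {sorted(missing)}")
        for r, w in self.world.items():
            if w not in MODELS:
                raise ValueError(f"unknown world {w!r} for response {r!r}")
        if not self.directions:
            self.directions = {
                r: DEFAULT_DIRECTIONS.get(r, +1) for r in self.responses
            }

    def factor_index(self, name: str) -> int:
        try:
            return self.factors.index(name)
        except ValueError:
            raise KeyError(f"unknown factor {name!r} in ground truth") from None

    def factor_distances(self) -> pd.DataFrame:
        """True pairwise Euclidean distances between factor effect profiles."""
        d = squareform(pdist(self.effect_matrix, metric="euclidean"))
        return pd.DataFrame(d, index=list(self.factors), columns=list(self.factors))


def make_ground_truth(config: Mapping | None = None, seed: int = 0) -> GroundTruth:
    """Build a :class:`GroundTruth` from a plain-dict config.

    Recognized keys (all optional): ``factors``, ``responses``,
    ``control_mean`` (scalar or per-response list), ``control_sd`` (idem),
    ``effect_matrix`` (explicit factors x responses list-of-lists),
    ``effect_mean`` / ``effect_sd`` (generative normal per cell; the mean is
    multiplied by each response's direction so negative-direction responses
    get negative expected effects), ``world`` (one name or per-response map),
    ``interaction`` (mapping with kind/gamma/sign), ``directions``.

    Deterministic under ``seed`` when the effect matrix is drawn.
    """
    cfg = dict(config or {})
    factors = tuple(cfg.get("factors", DEFAULT_FACTORS))
    responses = tuple(cfg.get("responses", DEFAULT_RESPONSES))
    F, R = len(factors), len(responses)
    directions = dict(cfg.get("directions", {}))
    if not directions:
        directions = {r: DEFAULT_DIRECTIONS.get(r, +1) for r in responses}
    missing_dir = set(responses) - set(directions)
    if missing_dir:
        raise ValueError(f"directions missing for responses: {sorted(missing_dir)}")

    def per_response(key: str, default: float) -> np.ndarray:
        v = cfg.get(key, default)
        arr = np.full(R, float(v)) if np.isscalar(v) else np.asarray(v, dtype=float)
        if arr.shape != (R,):
            raise ValueError(f"{key} must be scalar or length {R}, got shape {arr.shape}")
        return arr

    control_mean = per_response("control_mean", 10.0)
    control_sd = per_response("control_sd", 1.0)

    if "effect_matrix" in cfg:
        effect_matrix = np.asarray(cfg["effect_matrix"], dtype=float)
        if effect_matrix.shape != (F, R):
            raise ValueError(
                f"effect_matrix must be {F} x {R}, got {effect_matrix.shape}"
            )
    else:
        rng = np.random.default_rng(seed)
        mean = per_response("effect_mean", 0.5) * np.array(
            [directions[r] for r in responses], dtype=float
        )
        sd = per_response("effect_sd", 1.0)
        effect_matrix = rng.normal(loc=mean, scale=sd, size=(F, R))

    world_cfg = cfg.get("world", "additive")
    if isinstance(world_cfg, str):
        world = {r: world_cfg for r in responses}
    else:
        world = {r: world_cfg[r] for r in responses}

    inter_cfg = cfg.get("interaction", {})
    if isinstance(inter_cfg, InteractionRule):
        interaction = inter_cfg
    else:
        interaction = InteractionRule(
            kind=inter_cfg.get("kind", "none"),
            gamma=float(inter_cfg.get("gamma", 0.0)),
            sign=int(inter_cfg.get("sign", +1)),
        )

    return GroundTruth(
        factors=factors,
        responses=responses,
        control_mean=control_mean,
        control_sd=control_sd,
        effect_matrix=effect_matrix,
        world=world,
        interaction=interaction,
        directions=directions,
    )


def _interaction_term(truth: GroundTruth, members: Sequence[str], dmat: np.ndarray) -> float:
    """Unsigned total pairwise interaction for one treatment (the per-response
    sign is applied by the caller)."""
    rule = truth.interaction
    if rule.kind == "none" or len(members) < 2:
        return 0.0
    idx = [truth.factor_index(m) for m in members]
    if rule.kind == "fixed":
        n_pairs = len(idx) * (len(idx) - 1) // 2
        return rule.gamma * n_pairs
    total = 0.0
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            total += dmat[idx[a], idx[b]]
    return rule.gamma * total


def noiseless_value(truth: GroundTruth, members: Sequence[str], response: str) -> float:
    """Expected unit value for one treatment x response (no noise)."""
    r = truth.responses.index(response)
    base = truth.control_mean[r]
    if not members:
        return float(base)
    es = [truth.effect_matrix[truth.factor_index(m), r] for m in members]
    combined = point_prediction(truth.world[response], es, ct=truth.control_mean[r])
    inter = _interaction_term(truth, members, truth.factor_distances().to_numpy())
    return float(base + combined + truth.interaction.sign_for(response) * inter)


def simulate_experiment(truth: GroundTruth, design: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Simulate a long-format response table for ``design``.

    Unit value = control mean + world-rule combination of the members' true
    effects + pairwise interaction term + N(0, sigma^2) noise. Controls and
    water controls carry no effect term.
    """
    rng = np.random.default_rng(seed)
    dmat = truth.factor_distances().to_numpy()
    unit_ids: list[np.ndarray] = []
    treatment_ids: list[np.ndarray] = []
    response_names: list[np.ndarray] = []
    values: list[np.ndarray] = []
    for _, row in design.iterrows():
        members = split_factors(row["factors"])
        idx = [truth.factor_index(m) for m in members]  # raises on unknown factors
        n = int(row["n_replicates"])
        inter = _interaction_term(truth, members, dmat)
        units = np.array([f"{row['treatment_id']}_u{j + 1:03d}" for j in range(n)])
        for r, response in enumerate(truth.responses):
            base = truth.control_mean[r]
            if members:
                es = truth.effect_matrix[idx, r]
                delta = point_prediction(truth.world[response], es, ct=base)
                delta += truth.interaction.sign_for(response) * inter
            else:
                delta = 0.0
            noise = rng.normal(0.0, truth.control_sd[r], size=n)
            unit_ids.append(units)
            treatment_ids.append(np.repeat(row["treatment_id"], n))
            response_names.append(np.repeat(response, n))
            values.append(base + delta + noise)
    return pd.DataFrame(
        {
            "unit_id": np.concatenate(unit_ids),
            "treatment_id": np.concatenate(treatment_ids),
            "response": np.concatenate(response_names),
            "value": np.concatenate(values),
        }
    )


def gamma_for_mean_shift(
    truth: GroundTruth, design: pd.DataFrame, target_shift: float
) -> float:
    """Distance-proportional gamma so that the mean total injected term over
    the design's multi-factor treatments equals ``target_shift``."""
    dmat = truth.factor_distances().to_numpy()
    sums = []
    for _, row in design[design["kind"] == "multi"].iterrows():
        idx = [truth.factor_index(m) for m in split_factors(row["factors"])]
        s = sum(
            dmat[idx[a], idx[b]] for a in range(len(idx)) for b in range(a + 1, len(idx))
        )
        sums.append(s)
    if not sums:
        raise ValueError("design has no multi-factor treatments")
    mean_sum = float(np.mean(sums))
    if mean_sum == 0:
        raise ValueError("all pairwise true distances are zero; cannot calibrate gamma")
    return float(target_shift) / mean_sum
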