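"""Randomized factor-pool experimental designs.

A multi-factor experiment draws combinations of global-change factors (GCFs)
from a fixed pool instead of crossing them factorially: at each
number-of-factors level k, a fixed number of distinct k-subsets is sampled
without replacement from the complete enumeration of C(|pool|, k) subsets.
Controls, solvent (water) controls and single-factor treatments complete the
design.

The design is represented as a tidy :class:`pandas.DataFrame` with columns
``treatment_id, kind, level, factors, n_replicates`` where ``factors`` is a
semicolon-joined member list in pool order.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FactorPool",
    "Combination",
    "DEFAULT_FACTORS",
    "DEFAULT_REPLICATE_PLAN",
    "DESIGN_COLUMNS",
    "enumerate_combinations",
    "sample_design",
    "design_summary",
    "validate_design",
    "default_design",
]

#: The 12-factor pool used throughout: common anthropogenic stressors of soil.
DEFAULT_FACTORS: tuple[str, ...] = (
    "salinity",
    "drought",
    "microplastic",
    "fungicide",
    "herbicide",
    "antibiotic",
    "insecticide",
    "surfactant",
    "nitrogen_deposition",
    "heavy_metal",
    "pfas",
    "lithium",
)

#: Replicate structure of the reference design: 20 controls, 10 solvent
#: controls, 8 replicates per single factor, 1 unit per multi-factor treatment.
DEFAULT_REPLICATE_PLAN: dict[str, int] = {
    "control": 20,
    "water_control": 10,
    "single": 8,
    "multi": 1,
}

DESIGN_COLUMNS = ["treatment_id", "kind", "level", "factors", "n_replicates"]

KINDS = ("control", "water_control", "single", "multi")


@dataclass(frozen=True)
class FactorPool:
    """An ordered pool of unique factor names.

    The declaration order is fixed and defines lexicographic tie-breaking and
    the column order of binary composition matrices.
    """

    factors: tuple[str, ...]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        factors = tuple(str(f) for f in self.factors)
        if len(factors) == 0:
            raise ValueError("factor pool must not be empty")
        if len(set(factors)) != len(factors):
            raise ValueError("factor names must be unique")
        object.__setattr__(self, "factors", factors)
        object.__setattr__(self, "_index", {f: i for i, f in enumerate(factors)})

    def __len__(self) -> int:
        return len(self.factors)

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"unknown factor {name!r}; pool = {self.factors}") from None

    def sort_members(self, members: Iterable[str]) -> tuple[str, ...]:
        """Return ``members`` sorted by pool order (validates membership)."""
        return tuple(sorted(members, key=self.index))


@dataclass(frozen=True)
class Combination:
    """An unordered subset of the pool, stored in pool order."""

    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"duplicate members in combination: {self.members}")
        if len(self.members) < 1:
            raise ValueError("a combination needs at least one member")

    @property
    def level(self) -> int:
        return len(self.members)

    @property
    def id(self) -> str:
        """Stable key, invariant under member order at construction."""
        return "+".join(self.members)


def enumerate_combinations(pool: FactorPool, k: int) -> list[Combination]:
    """All C(|pool|, k) unordered k-subsets, in lexicographic pool order.

    Raises ``ValueError`` when k is outside ``1..|pool|``.
    """
    if not 1 <= k <= len(pool):
        raise ValueError(
            f"k={k} out of range for a pool of {len(pool)} factors (need 1 <= k <= {len(pool)})"
        )
    return [Combination(members) for members in itertools.combinations(pool.factors, k)]


def _join(members: Sequence[str]) -> str:
    return ";".join(members)


def split_factors(cell: str | float) -> tuple[str, ...]:
    """Inverse of the semicolon join used in the ``factors`` column."""
    if cell is None or (isinstance(cell, float) and math.isnan(cell)) or cell == "":
        return ()
    return tuple(str(cell).split(";"))


def sample_design(
    pool: FactorPool,
    levels: Sequence[int],
    n_per_level: int,
    replicate_plan: Mapping[str, int] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample a randomized factor-pool design.

    Per level k, the complete set of k-subsets is enumerated, shuffled with a
    seeded generator, and the first ``n_per_level`` are taken — sampling
    without replacement that is exact and reproducible.

    Raises ``ValueError`` if ``n_per_level`` exceeds C(|pool|, k) at any level.
    """
    plan = dict(DEFAULT_REPLICATE_PLAN)
    if replicate_plan is not None:
        plan.update(replicate_plan)
    for kind, count in plan.items():
        if kind not in KINDS:
            raise ValueError(f"unknown kind {kind!r} in replicate plan")
        if count < 0:
            raise ValueError(f"replicate count for {kind!r} must be >= 0")

    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    if plan.get("control", 0) > 0:
        rows.append(
            dict(treatment_id="control", kind="control", level=0, factors="", n_replicates=plan["control"])
        )
    if plan.get("water_control", 0) > 0:
        rows.append(
            dict(
                treatment_id="water_control",
                kind="water_control",
                level=0,
                factors="",
                n_replicates=plan["water_control"],
            )
        )
    if plan.get("single", 0) > 0:
        for f in pool.factors:
            rows.append(
                dict(
                    treatment_id=f"single_{f}",
                    kind="single",
                    level=1,
                    factors=f,
                    n_replicates=plan["single"],
                )
            )
    for k in levels:
        full = enumerate_combinations(pool, k)
        if n_per_level > len(full):
            raise ValueError(
                f"cannot sample {n_per_level} distinct combinations at level {k}: "
                f"only C({len(pool)},{k}) = {len(full)} exist"
            )
        order = rng.permutation(len(full))[:n_per_level]
        for j, idx in enumerate(order, start=1):
            comb = full[idx]
            rows.append(
                dict(
                    treatment_id=f"L{k}_{j:03d}",
                    kind="multi",
                    level=k,
                    factors=_join(comb.members),
                    n_replicates=plan.get("multi", 1),
                )
            )
    design = pd.DataFrame(rows, columns=DESIGN_COLUMNS)
    validate_design(design, pool=pool)
    return design


def validate_design(design: pd.DataFrame, pool: FactorPool | None = None) -> None:
    """Check design-table invariants; raise ``ValueError`` on violation."""
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise ValueError(f"design table missing columns: {missing}")
    if design["treatment_id"].duplicated().any():
        dups = design.loc[design["treatment_id"].duplicated(), "treatment_id"].tolist()
        raise ValueError(f"duplicated treatment ids: {dups}")
    if (design["n_replicates"] <= 0).any():
        raise ValueError("replicate counts must be positive")
    bad_kind = set(design["kind"]) - set(KINDS)
    if bad_kind:
        raise ValueError(f"unknown treatment kinds: {sorted(bad_kind)}")
    for level, grp in design[design["kind"] == "multi"].groupby("level"):
        combos = grp["factors"].tolist()
        if len(set(combos)) != len(combos):
            raise ValueError(f"duplicated combinations within level {level}")
    if pool is not None:
        for cell in design["factors"]:
            for member in split_factors(cell):
                if member not in pool:
                    raise ValueError(f"factor {member!r} not in pool {pool.factors}")


def design_summary(design: pd.DataFrame) -> dict:
    """Unit counts per kind plus totals; idempotent on the same table."""
    validate_design(design)
    per_kind = design.groupby("kind")["n_replicates"].sum().to_dict()
    return {
        "units_per_kind": {k: int(per_kind.get(k, 0)) for k in KINDS},
        "treatments_per_kind": design["kind"].value_counts().to_dict(),
        "total_units": int(design["n_replicates"].sum()),
        "total_treatments": int(len(design)),
    }


def default_design(seed: int = 0, pool: FactorPool | None = None) -> pd.DataFrame:
    """The reference design: levels (2, 5, 8), 50 combinations per level,
    20 controls, 10 water controls, 12 single factors with 8 replicates
    (276 units in total)."""
    pool = pool or FactorPool(DEFAULT_FACTORS)
    return sample_design(pool, levels=(2, 5, 8), n_per_level=50, seed=seed)
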