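"""Factor dissimilarity from single-factor effect profiles.

Each factor's profile is its vector of effect sizes across the measured
responses. Profiles are standardized (each response column z-scored across
factors), pairwise Euclidean distances between standardized profiles give the
factor distance matrix, and the dissimilarity index (DI) of a combination is
the sum of pairwise distances over all member pairs. Because the number of
pairs grows with the level (C(2,2)=1 vs C(8,2)=28), raw DIs are range-
normalized within each number-of-factors level to [0, 1] before levels are
compared. PCoA and hierarchical clustering provide ordination/cluster views
of the factor distances.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix as SkbioDistanceMatrix
from skbio import TreeNode
from skbio.stats.ordination import pcoa as skbio_pcoa

from .design import split_factors

__all__ = [
    "standardize_effects",
    "distance_matrix",
    "distance_matrix_from_effects",
    "dissimilarity_index",
    "dissimilarity_table",
    "normalize_within_level",
    "pcoa",
    "hierarchical_cluster",
]


def standardize_effects(effect_matrix: pd.DataFrame) -> pd.DataFrame:
    """z-score each response column across factors (mean 0, sample sd 1).

    Zero-variance columns are mapped to all zeros with a warning. Requires at
    least two factors (the sd across factors is undefined otherwise).
    """
    if effect_matrix.shape[0] < 2:
        raise ValueError("standardization needs at least two factors")
    if effect_matrix.isna().any().any():
        raise ValueError("effect matrix contains missing cells")
    centered = effect_matrix - effect_matrix.mean(axis=0)
    sd = effect_matrix.std(axis=0, ddof=1)
    zero = sd == 0
    if zero.any():
        warnings.warn(
            f"zero-variance response columns set to zero: {list(sd.index[zero])}",
            RuntimeWarning,
            stacklevel=2,
        )
        sd = sd.mask(zero, 1.0)
    out = centered / sd
    out.loc[:, zero] = 0.0
    return out


def distance_matrix(standardized: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Euclidean distances between factor rows (square, labeled)."""
    d = squareform(pdist(standardized.to_numpy(dtype=float), metric="euclidean"))
    labels = list(standardized.index)
    return pd.DataFrame(d, index=labels, columns=labels)


def distance_matrix_from_effects(
    effects: pd.DataFrame, standardize: bool = True
) -> pd.DataFrame:
    """Distance matrix straight from a factors x responses effect table."""
    return distance_matrix(standardize_effects(effects) if standardize else effects)


def dissimilarity_index(members: Sequence[str], dm: pd.DataFrame) -> float:
    """Raw DI: sum of pairwise distances over all C(N, 2) member pairs.

    A single-member combination has no pairs and DI 0; a 2-factor combination's
    DI is a single matrix entry.
    """
    unknown = [m for m in members if m not in dm.index]
    if unknown:
        raise KeyError(f"combination members not in distance matrix: {unknown}")
    total = 0.0
    for a in range(len(members)):
        for b in range(a + 1, len(members)):
            total += float(dm.loc[members[a], members[b]])
    return total


def dissimilarity_table(design: pd.DataFrame, dm: pd.DataFrame) -> pd.DataFrame:
    """Raw and within-level-normalized DI for every multi-factor treatment."""
    multi = design[design["kind"] == "multi"]
    rows = [
        dict(
            treatment_id=row["treatment_id"],
            level=int(row["level"]),
            di_raw=dissimilarity_index(split_factors(row["factors"]), dm),
        )
        for _, row in multi.iterrows()
    ]
    return normalize_within_level(pd.DataFrame(rows, columns=["treatment_id", "level", "di_raw"]))


def normalize_within_level(indices: pd.DataFrame) -> pd.DataFrame:
    """Range-normalize di_raw to [0, 1] within each level (min->0, max->1).

    A level with zero range gets di_norm 0 everywhere, with a warning.
    """
    out = indices.copy()
    out["di_norm"] = np.nan
    for level, grp in out.groupby("level"):
        lo, hi = grp["di_raw"].min(), grp["di_raw"].max()
        if hi == lo:
            warnings.warn(
                f"level {level}: dissimilarity indices have zero range; di_norm set to 0",
                RuntimeWarning,
                stacklevel=2,
            )
            out.loc[grp.index, "di_norm"] = 0.0
        else:
            out.loc[grp.index, "di_norm"] = (grp["di_raw"] - lo) / (hi - lo)
    return out


def pcoa(dm: pd.DataFrame, n_axes: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical (Torgerson) scaling of a distance matrix.

    Returns the first ``n_axes`` coordinate columns and the fraction of
    variance per returned axis, where fractions are eigenvalue / sum of
    positive eigenvalues (negative eigenvalues are excluded from the
    denominator).
    """
    skdm = SkbioDistanceMatrix(dm.to_numpy(dtype=float), ids=[str(i) for i in dm.index])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # skbio warns on tiny negative eigenvalues
        res = skbio_pcoa(skdm, method="eigh")
    eig = res.eigvals.to_numpy()
    positive = eig[eig > 0].sum()
    fractions = np.where(eig > 0, eig, 0.0) / positive if positive > 0 else np.zeros_like(eig)
    n_axes = min(n_axes, res.samples.shape[1])
    coords = res.samples.iloc[:, :n_axes].copy()
    coords.index = list(dm.index)
    coords.columns = [f"pcoa{i + 1}" for i in range(n_axes)]
    return coords, fractions[:n_axes]


def hierarchical_cluster(
    dm: pd.DataFrame, linkage: str = "average"
) -> tuple[np.ndarray, str]:
    """Agglomerative clustering of factors on the distance matrix.

    Returns the scipy linkage matrix and its Newick serialization. Input rows
    follow pool order, so distance ties resolve deterministically by pool
    order. Default linkage is UPGMA (average).
    """
    if dm.shape[0] < 2:
        raise ValueError("clustering needs at least two factors")
    Z = scipy_linkage(squareform(dm.to_numpy(dtype=float), checks=False), method=linkage)
    tree = TreeNode.from_linkage_matrix(Z, [str(i) for i in dm.index])
    return Z, str(tree).strip()
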