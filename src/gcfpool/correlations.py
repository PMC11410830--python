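"""Within-level Spearman trends of responses against dissimilarity.

These correlations describe how a response changes across the normalized
dissimilarity range within each number-of-factors level. On their own they
cannot establish a dissimilarity effect: combinations with high dissimilarity
are also more likely to contain a factor with an extreme single effect, so
the trend confounds dissimilarity with factor identity. The hierarchical
models (:mod:`gcfpool.hierarchy`) are the inferential surface; this module is
descriptive.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["spearman_trend"]


def spearman_trend(
    responses: pd.DataFrame,
    indices: pd.DataFrame,
    design: pd.DataFrame,
    level: int | None = None,
) -> pd.DataFrame:
    """Spearman rho (two-sided p, t approximation; tied values get average
    ranks) of treatment-mean response against normalized DI, per response and
    level.

    Requires >= 3 matched treatments per cell; a constant response or index
    vector yields NaN rho/p for that cell.
    """
    means = (
        responses.groupby(["treatment_id", "response"])["value"].mean().reset_index()
    )
    merged = means.merge(
        indices[["treatment_id", "level", "di_norm"]], on="treatment_id", how="inner"
    )
    if level is not None:
        merged = merged[merged["level"] == level]
    if merged.empty:
        raise ValueError("no matched treatments between responses and dissimilarity indices")
    rows = []
    for (response, lvl), grp in merged.groupby(["response", "level"]):
        if len(grp) < 3:
            raise ValueError(
                f"fewer than 3 matched treatments for response {response!r} at level {lvl}"
            )
        x = grp["di_norm"].to_numpy(dtype=float)
        y = grp["value"].to_numpy(dtype=float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            rho, p = np.nan, np.nan
        else:
            rho, p = stats.spearmanr(x, y)
        rows.append(
            dict(response=response, level=int(lvl), rho=float(rho), p=float(p), n=int(len(grp)))
        )
    return pd.DataFrame(rows, columns=["response", "level", "rho", "p", "n"])
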