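"""End-to-end pipeline runner with an artifact manifest.

``run_pipeline`` executes design -> (simulate) -> effects -> dissimilarity ->
null predictions -> classification -> hierarchy -> trends and, when an output
directory is given, writes every stage table plus a manifest recording the
master seed, bootstrap depths, row counts and SHA-256 checksums. Identical
config + seed gives identical manifests.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .io import write_distance_matrix, write_json, write_newick, write_table
from .model import MultiFactorExperiment, MultiFactorResults

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    ``truth`` holds the synthetic ground-truth config (see
    :func:`gcfpool.synthetic.make_ground_truth`); it is ignored when a
    measured response table is supplied. ``directions`` may be omitted when
    the responses use the default names.
    """

    design: dict = field(default_factory=dict)
    truth: dict = field(default_factory=dict)
    directions: dict = field(default_factory=dict)
    B: int = 10_000
    K: int = 1000
    n_perm: int = 0
    ci_level: float = 0.95
    hierarchy_backend: str | None = "glm"
    n_estimators: int = 200

    def __post_init__(self) -> None:
        if self.B < 1 or self.K < 1:
            raise ValueError("bootstrap depths B and K must be >= 1")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must be in (0, 1)")

    @classmethod
    def from_mapping(cls, cfg: Mapping | None) -> "PipelineConfig":
        cfg = dict(cfg or {})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(cfg) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**cfg)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: PipelineConfig | Mapping | None = None,
    seed: int = 0,
    responses: pd.DataFrame | None = None,
    design: pd.DataFrame | None = None,
    outdir: str | Path | None = None,
) -> tuple[MultiFactorResults, dict]:
    """Run all stages; return (results, manifest).

    With ``responses`` (and optionally ``design``) given, measured data are
    analyzed; otherwise a synthetic experiment is generated from the config's
    ground truth. With ``outdir`` set, all artifacts and the manifest are
    written there.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_mapping(config)

    if responses is None:
        exp = MultiFactorExperiment.from_config(
            {
                "truth": config.truth,
                "design": config.design,
                "B": config.B,
                "K": config.K,
                "ci_level": config.ci_level,
            },
            seed=seed,
        )
    else:
        if design is None:
            raise ValueError("a design table is required when responses are supplied")
        exp = MultiFactorExperiment(
            design,
            responses,
            directions=config.directions or None,
            B=config.B,
            K=config.K,
            ci_level=config.ci_level,
        )
    results = exp.fit(
        seed=seed,
        hierarchy_backend=config.hierarchy_backend,
        n_perm=config.n_perm,
        n_estimators=config.n_estimators,
    )

    manifest: dict = {
        "gcfpool_version": __version__,
        "seed": seed,
        "depths": {"B": config.B, "K": config.K, "n_perm": config.n_perm},
        "ci_level": config.ci_level,
        "design_units": int(exp.design["n_replicates"].sum()),
        "rows": {
            "design": len(exp.design),
            "responses": len(exp.responses),
            "effects": len(results.effects),
            "nullpred": len(results.null_predictions),
            "calls": len(results.interaction_calls),
            "di": len(results.dissimilarity),
        },
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_table(exp.design, outdir / "design.csv", schema="design")
        write_table(exp.responses, outdir / "responses.csv", schema="responses")
        write_table(results.effects, outdir / "effects.csv", schema="effects")
        write_table(results.null_predictions, outdir / "nullpred.csv", schema="nullpred")
        write_table(results.interaction_calls, outdir / "calls.csv", schema="calls")
        write_table(results.dissimilarity, outdir / "di.csv", schema="di")
        write_table(results.best_null, outdir / "best_null.csv")
        write_table(results.level_tests, outdir / "level_tests.csv")
        write_table(results.dn_di_correlations, outdir / "dn_di_correlations.csv")
        write_table(results.trends, outdir / "trends.csv")
        write_distance_matrix(results.distance_matrix, outdir / "distance_matrix.csv")
        write_table(results.pcoa_coordinates.reset_index(names="factor"), outdir / "pcoa.csv")
        write_newick(results.newick, outdir / "dendrogram.nwk")
        if results.hierarchy is not None:
            write_json(
                {r: rep.to_dict() for r, rep in results.hierarchy.items()},
                outdir / "hierarchy.json",
            )
        manifest["checksums"] = {
            p.name: _sha256(p)
            for p in sorted(outdir.iterdir())
            if p.suffix in (".csv", ".nwk", ".json") and p.name != "manifest.json"
        }
        write_json(manifest, outdir / "manifest.json")
    return results, manifest
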