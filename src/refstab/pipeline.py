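"""End-to-end reference-gene evaluation pipeline.

Ties the stages together in the order a validation study runs them:
(optional) efficiency estimation from raw curves -> five stability methods
on every scope -> cross-entropy consensus ranking per scope -> (optional)
efficiency-corrected quantification of a target gene against the top
consensus references.  Output is a machine-readable bundle plus per-scope
CSV tables; two runs with the same config and seed produce byte-identical
JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import aggregate as agg
from . import quantify, stability
from .core import CqMatrix, EfficiencyTable

log = logging.getLogger("refstab")


@dataclass
class RunConfig:
    seed: int | None = None
    scopes: list[str] | None = None  # default: each panel + "all"
    methods: list[str] = field(default_factory=lambda: list(stability.METHODS))
    groups_column: str | None = None
    cutoff: float = 0.15
    n_consensus_refs: int = 2
    target: str | None = None
    worst_ref_contrast: bool = True
    ce_sample_size: int = 500
    ce_rarity: float = 0.1
    ce_smoothing: float = 0.7
    ce_max_iter: int = 200
    output_dir: Path | None = None


def _rankings_for_scope(results: dict[str, stability.StabilityResult]) -> list[agg.RankedList]:
    return [agg.RankedList(method, res.ranking) for method, res in results.items()]


def run_full_pipeline(
    cq: CqMatrix,
    config: RunConfig,
    eff: EfficiencyTable | None = None,
    candidate_genes: list[str] | None = None,
) -> dict:
    """Run stability -> consensus -> (optional) quantification.

    ``candidate_genes`` restricts the stability/consensus stages (e.g. to
    exclude the quantification target from the reference-candidate panel).
    Returns the report bundle as a plain dict; writes CSV/JSON artifacts to
    ``config.output_dir`` when set.
    """
    if config.seed is None:
        raise ValueError("a seed is required: the consensus stage is stochastic")
    panel = cq.select_genes(candidate_genes) if candidate_genes else cq
    if eff is None:
        eff = EfficiencyTable.default(cq.genes)
    log.info("stage=stability scopes=%s", config.scopes or "auto")
    all_results = stability.run_all_methods(
        panel, eff, config.scopes, config.groups_column, config.cutoff
    )
    bundle: dict = {"seed": config.seed, "scopes": {}}
    for i, (scope, results) in enumerate(all_results.items()):
        selected = {m: r for m, r in results.items() if m in config.methods}
        lists = _rankings_for_scope(selected)
        log.info("stage=aggregate scope=%s", scope)
        consensus = agg.aggregate_ce(
            lists,
            sample_size=config.ce_sample_size,
            rarity=config.ce_rarity,
            smoothing=config.ce_smoothing,
            max_iter=config.ce_max_iter,
            seed=config.seed + i,
        )
        pv = results["geNorm"].extra.get("pairwise_variation")
        bundle["scopes"][scope] = {
            "method_rankings": {m: r.ranking for m, r in selected.items()},
            "method_scores": {
                m: {g: {k: _jsonify(v) for k, v in row.items()} for g, row in r.scores.iterrows()}
                for m, r in selected.items()
            },
            "consensus": {
                "genes": consensus.genes,
                "objective": consensus.objective,
                "iterations": consensus.iterations,
                "converged": consensus.converged,
                "top": consensus.genes[: config.n_consensus_refs],
            },
            "pairwise_variation": {
                "v": {str(n): float(val) for n, val in pv.v.items()},
                "minimal_n": pv.minimal_n,
                "optimal_n": pv.optimal_n,
                "cutoff": pv.cutoff,
            }
            if pv is not None
            else None,
        }
    if config.target:
        log.info("stage=quantify target=%s", config.target)
        all_scope = bundle["scopes"].get("all") or next(iter(bundle["scopes"].values()))
        best = all_scope["consensus"]["top"]
        worst = all_scope["consensus"]["genes"][-1]
        best_prof, worst_prof, bias = quantify.bias_contrast(
            cq, config.target, best, worst, eff
        )
        bundle["quantification"] = {
            "target": config.target,
            "best_refs": best,
            "worst_ref": worst,
            "fold_changes_best": _profile_dict(best_prof),
            "fold_changes_worst": _profile_dict(worst_prof),
            "log2_bias": {f"{p}:{c}": float(v) for (p, c), v in bias.items()},
        }
    if config.output_dir is not None:
        _write_bundle(bundle, all_results, Path(config.output_dir))
    return bundle


def _jsonify(v):
    if isinstance(v, (bool,)):
        return v
    if pd.isna(v):
        return None
    return float(v)


def _profile_dict(prof: quantify.ExpressionProfile) -> dict:
    return {
        f"{p}:{c}": {"fold_change": float(r.fold_change), "sd": float(r.sd)}
        for (p, c), r in prof.profile.iterrows()
    }


def _write_bundle(bundle: dict, all_results, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "report.json", "w") as fh:
        json.dump(bundle, fh, indent=2, sort_keys=True)
    for scope, results in all_results.items():
        safe = scope.replace("/", "_")
        for method, res in results.items():
            res.scores.rename_axis("gene").to_csv(
                outdir / f"stability_{safe}_{method}.csv", float_format="%.6g"
            )
    rows = [
        {"scope": scope, "rank": i + 1, "gene": g}
        for scope, entry in bundle["scopes"].items()
        for i, g in enumerate(entry["consensus"]["genes"])
    ]
    pd.DataFrame(rows).to_csv(outdir / "consensus.csv", index=False)
    log.info("stage=report dir=%s", outdir)
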