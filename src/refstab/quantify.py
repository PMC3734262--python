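"""Efficiency-corrected relative quantification of a target gene.

Implements the validation stage of a reference-gene study: the target's
relative quantity is divided by a normalization factor (geometric mean of
the chosen reference genes' relative quantities) and calibrated to the mock
condition of each experiment panel, giving per-condition fold changes with
an SD over biological replicates.  ``bias_contrast`` quantifies, per
condition, the log2 distortion introduced by normalizing to an unstable
reference instead of the recommended set.

Technical replicates are averaged on the Cq scale before conversion —
standard practice for quantification, and deliberately different from the
stability statistics, which treat every reaction as an observation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CqMatrix, EfficiencyTable, RQMatrix, cq_to_rq, geometric_mean


@dataclass
class NormalizationFactor:
    scope: str
    reference_genes: list[str]
    nf: pd.Series  # per-reaction positive factor


@dataclass
class ExpressionProfile:
    target: str
    reference_genes: list[str]
    profile: pd.DataFrame  # index (panel, condition); fold_change, sd, n_bio
    calibrator: str


def normalization_factor(rq: RQMatrix, reference_genes: list[str], scope: str = "all") -> NormalizationFactor:
    """Per-reaction geometric mean of the reference genes' relative quantities."""
    if not reference_genes:
        raise ValueError("reference gene list must be non-empty")
    missing = [g for g in reference_genes if g not in rq.rq.index]
    if missing:
        raise KeyError(f"reference genes absent from panel: {missing}")
    sub = rq.rq.loc[reference_genes]
    nf = np.exp(np.log(sub).mean(axis=0))
    return NormalizationFactor(scope, list(reference_genes), nf)


def normalized_expression(
    cq: CqMatrix,
    target: str,
    reference_genes: list[str],
    eff: EfficiencyTable | None = None,
    calibrator: str = "is_mock",
) -> ExpressionProfile:
    """Fold change of ``target`` per condition, calibrated per panel.

    Pipeline: average technical replicates on the Cq scale -> convert to
    relative quantities with each gene's efficiency -> divide the target's
    RQ by the normalization factor -> per condition, fold change is the mean
    normalized quantity over biological replicates divided by the panel
    calibrator's mean; the SD comes from the spread over biological
    replicates.  ``calibrator`` is either ``"is_mock"`` (pool the panel's
    mock-flagged reactions) or a condition label present in every panel.
    """
    if target not in cq.genes:
        raise KeyError(f"target gene {target!r} not in panel")
    collapsed = cq.average_technical_replicates()
    if eff is None:
        eff = EfficiencyTable.default(collapsed.genes)
    rq = cq_to_rq(collapsed, eff)
    nf = normalization_factor(rq, reference_genes)
    q = rq.rq.loc[target] / nf.nf
    ann = collapsed.annotations
    rows = []
    for panel in collapsed.panels:
        in_panel = ann["panel"] == panel
        if calibrator == "is_mock":
            cal_mask = in_panel & ann["is_mock"]
        else:
            cal_mask = in_panel & (ann["condition"] == calibrator)
        if not cal_mask.any():
            raise ValueError(f"no calibrator reactions in panel {panel!r}")
        cal_mean = float(q[ann.index[cal_mask]].mean())
        for cond in ann.loc[in_panel, "condition"].unique():
            cols = ann.index[in_panel & (ann["condition"] == cond)]
            vals = q[cols]
            fold = float(vals.mean() / cal_mean)
            sd = float(vals.std(ddof=1) / cal_mean) if len(vals) > 1 else 0.0
            rows.append(
                {
                    "panel": panel,
                    "condition": cond,
                    "fold_change": fold,
                    "sd": sd,
                    "n_bio": int(len(vals)),
                }
            )
    profile = pd.DataFrame(rows).set_index(["panel", "condition"])
    if (profile["fold_change"] <= 0).any():
        raise ValueError("fold changes must be positive")
    return ExpressionProfile(target, list(reference_genes), profile, calibrator)


def bias_contrast(
    cq: CqMatrix,
    target: str,
    best_refs: list[str],
    worst_ref: str,
    eff: EfficiencyTable | None = None,
    calibrator: str = "is_mock",
) -> tuple[ExpressionProfile, ExpressionProfile, pd.Series]:
    """Fold-change profiles under best vs worst references, plus log2 bias.

    bias_c = log2(fold_worst_c / fold_best_c): positive when the unstable
    reference inflates the apparent induction of the target.
    """
    best = normalized_expression(cq, target, best_refs, eff, calibrator)
    worst = normalized_expression(cq, target, [worst_ref], eff, calibrator)
    bias = np.log2(
        worst.profile["fold_change"] / best.profile["fold_change"]
    ).rename("log2_bias")
    return best, worst, bias
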