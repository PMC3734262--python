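"""Five expression-stability algorithms for candidate reference genes.

Each algorithm consumes a Cq panel restricted to one analysis scope (a
single experiment panel, or all panels pooled) and emits per-gene scores
plus a ranking from most to least stable:

* ``stability_index`` — per-gene coefficient of variation of Cq times the
  slope of the gene's Cq regressed on the per-reaction overall mean Cq
  (sensitivity to general expression-promoting conditions).
* ``genorm_*`` — pairwise log2-ratio variation (M values) on relative
  quantities, iterative-exclusion ranking, normalized CV, and the
  V(n/n+1) pairwise-variation series that chooses how many reference
  genes a normalization factor needs (0.15 cutoff).
* ``normfinder_stability`` — variance-decomposition stability value on
  log2 relative quantities, with optional treatment groups.
* ``bestkeeper`` — Cq dispersion about the per-gene geometric mean plus
  correlation with the per-reaction geometric-mean index.
* ``delta_ct_stability`` — mean SD of pairwise Cq differences.

Scores are comparable only within a method; rankings are the common
currency (see :mod:`refstab.aggregate` for the consensus step).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import CqMatrix, EfficiencyTable, RQMatrix, cq_to_rq

METHODS = ("SI", "geNorm", "NormFinder", "BestKeeper", "dCt")


@dataclass
class StabilityResult:
    scope: str
    method: str
    scores: pd.DataFrame  # per-gene score fields; index = gene
    ranking: list[str]  # most stable first
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if sorted(self.ranking) != sorted(self.scores.index):
            raise ValueError("ranking must be a permutation of the scored genes")


@dataclass
class PairwiseVariationSeries:
    scope: str
    v: pd.Series  # index n = 2..K-1, value V_{n/n+1}
    cutoff: float
    minimal_n: int  # smallest n with V < cutoff
    optimal_n: int  # argmin V


def _rank_by(scores: pd.Series) -> list[str]:
    """Ascending-score ranking with gene-label tie-break (stable)."""
    return scores.sort_values(kind="stable").index.tolist()


def _require(cq: CqMatrix, min_genes: int, min_reactions: int, what: str) -> None:
    if len(cq.genes) < min_genes:
        raise ValueError(f"{what} needs >= {min_genes} genes")
    if len(cq.reactions) < min_reactions:
        raise ValueError(f"{what} needs >= {min_reactions} reactions")


# ---------------------------------------------------------------------------
# Stability index (CV x slope)

def stability_index(cq: CqMatrix, scope: str = "all") -> StabilityResult:
    """Brunner-style stability index: SI = CV(%) x |slope|.

    CV is 100 * SD / mean of the gene's Cq over reactions; the slope comes
    from regressing the gene's per-reaction Cq on the per-reaction mean Cq
    across all genes.  A gene insensitive to conditions that raise or lower
    overall expression has slope near zero.  The absolute slope is used:
    negative sensitivity is no more desirable than positive.
    """
    _require(cq, 1, 3, "stability index")
    overall = cq.cq.mean(axis=0, skipna=True)
    if np.isclose(overall.var(ddof=1), 0.0):
        warnings.warn("no variance in per-reaction overall means; slopes set to 0", stacklevel=2)
        degenerate = True
    else:
        degenerate = False
    rows = {}
    for gene in cq.genes:
        y = cq.cq.loc[gene]
        ok = y.notna() & overall.notna()
        mean, sd = float(y[ok].mean()), float(y[ok].std(ddof=1))
        cv = 100.0 * sd / mean
        if degenerate or ok.sum() < 3:
            slope, intercept = 0.0, mean
        else:
            fit = stats.linregress(overall[ok].to_numpy(), y[ok].to_numpy())
            slope, intercept = float(fit.slope), float(fit.intercept)
        rows[gene] = {
            "mean_cq": mean,
            "sd": sd,
            "cv": cv,
            "slope": slope,
            "intercept": intercept,
            "si": cv * abs(slope),
        }
    scores = pd.DataFrame(rows).T
    return StabilityResult(scope, "SI", scores, _rank_by(scores["si"]))


# ---------------------------------------------------------------------------
# geNorm family (operates on relative quantities)

def _log2_rq(rq: RQMatrix) -> pd.DataFrame:
    vals = rq.rq
    if (vals.to_numpy() <= 0).any():
        raise ValueError("geNorm requires strictly positive relative quantities")
    return np.log2(vals)


def genorm_m_values(rq: RQMatrix) -> pd.Series:
    """Per-gene M: mean over partner genes of SD(log2 pairwise ratio).

    A low M means the gene's expression ratio with every other candidate is
    nearly constant across samples, i.e. the gene tracks the common profile.
    """
    y = _log2_rq(rq)
    genes = list(y.index)
    if len(genes) < 2 or y.shape[1] < 2:
        raise ValueError("geNorm M needs >= 2 genes and >= 2 reactions")
    m = {}
    for j in genes:
        sds = [
            float((y.loc[j] - y.loc[k]).std(ddof=1)) for k in genes if k != j
        ]
        m[j] = float(np.mean(sds))
    return pd.Series(m, name="M")


def genorm_ranking(rq: RQMatrix, scope: str = "all") -> StabilityResult:
    """Classic iterative-exclusion geNorm ranking.

    At each step the gene with the highest M is removed and its M at that
    step recorded as its average stability M_A; the final two genes share
    the last value (with two genes left the pairwise M is common).  Ranking
    is the reverse exclusion order.  Genes with M_A > 1 are flagged as
    unacceptable for heterogeneous sample sets.
    """
    genes = list(rq.rq.index)
    if len(genes) < 3:
        raise ValueError("geNorm ranking needs >= 3 genes")
    remaining = list(genes)
    m_a: dict[str, float] = {}
    exclusion_order: list[str] = []
    while len(remaining) > 2:
        sub = RQMatrix(rq.rq.loc[remaining], rq.annotations)
        m = genorm_m_values(sub)
        worst_val = m.max()
        ties = sorted(m.index[np.isclose(m, worst_val)])
        if len(ties) > 1:
            warnings.warn(
                f"tied M values at exclusion step ({ties}); breaking by label order",
                stacklevel=2,
            )
        worst = ties[-1]  # later labels excluded first, so ties rank in label order
        m_a[worst] = float(m[worst])
        exclusion_order.append(worst)
        remaining.remove(worst)
    final_pair = RQMatrix(rq.rq.loc[remaining], rq.annotations)
    final_m = genorm_m_values(final_pair)
    for g in sorted(remaining, reverse=True):
        m_a[g] = float(final_m[g])
        exclusion_order.append(g)
    ranking = exclusion_order[::-1]
    scores = pd.DataFrame({"m_a": pd.Series(m_a)}).loc[genes]
    scores["acceptable"] = scores["m_a"] <= 1.0
    return StabilityResult(
        scope,
        "geNorm",
        scores,
        ranking,
        extra={"all_acceptable": bool(scores["acceptable"].all())},
    )


def genorm_cv(rq: RQMatrix, reference_set: list[str]) -> pd.Series:
    """CV of each gene's RQ after normalization to a reference set.

    NF_i is the geometric mean of the reference genes' RQ at reaction i;
    cv_norm is SD/mean of the normalized values z = rq / NF.
    """
    if not reference_set:
        raise ValueError("reference set must be non-empty")
    y = _log2_rq(rq)
    log_nf = y.loc[reference_set].mean(axis=0)
    out = {}
    for gene in rq.rq.index:
        z = np.power(2.0, y.loc[gene] - log_nf)
        out[gene] = float(z.std(ddof=1) / z.mean())
    return pd.Series(out, name="cv_norm")


def pairwise_variation(
    rq: RQMatrix, ranking: list[str], cutoff: float = 0.15, scope: str = "all"
) -> PairwiseVariationSeries:
    """V(n/n+1) series deciding how many reference genes the NF needs.

    V is the SD across reactions of log2(NF_n / NF_{n+1}) where NF_n is the
    geometric mean of the n top-ranked genes' RQ.  The first n with
    V < cutoff (conventionally 0.15) is the minimal number of reference
    genes; adding more no longer changes the normalization factor
    appreciably.
    """
    k = len(ranking)
    if k < 3:
        raise ValueError("pairwise variation needs >= 3 ranked genes")
    y = _log2_rq(rq).loc[ranking]
    v = {}
    for n in range(2, k):
        log_nf_n = y.iloc[:n].mean(axis=0)
        log_nf_n1 = y.iloc[: n + 1].mean(axis=0)
        v[n] = float((log_nf_n - log_nf_n1).std(ddof=1))
    series = pd.Series(v, name="V")
    below = [n for n, val in series.items() if val < cutoff]
    if below:
        minimal_n = below[0]
    else:
        warnings.warn(
            f"no V below cutoff {cutoff}; reporting all {k} genes as needed",
            stacklevel=2,
        )
        minimal_n = k
    optimal_n = int(series.idxmin())
    return PairwiseVariationSeries(scope, series, cutoff, minimal_n, optimal_n)


# ---------------------------------------------------------------------------
# NormFinder

def normfinder_stability(
    rq: RQMatrix, groups: pd.Series | None = None, scope: str = "all"
) -> StabilityResult:
    """Variance-decomposition stability value rho on log2 relative quantities.

    Without groups: log2 RQ is centered by the per-reaction mean across
    genes (removing sample-to-sample loading) and rho is the bias-corrected
    SD of the centered values — the centering over K genes contracts each
    gene's variance by (K-1)/K, so the variance is rescaled by K/(K-1).

    With groups: per group the intragroup variance s2 of centered residuals
    and the intergroup deviation d (group mean minus the gene's overall
    centered mean) are combined as rho = mean over groups of
    |d_shrunk| + sqrt(s2/n), where d is shrunk toward zero by
    gamma2 / (gamma2 + s2/n) with gamma2 the across-genes mean of d^2
    (a simple moment estimator of the true intergroup variance).
    """
    y = _log2_rq(rq)
    genes = list(y.index)
    k = len(genes)
    if k < 3:
        raise ValueError("NormFinder needs >= 3 genes")
    centered = y - y.mean(axis=0)
    if groups is None:
        var = centered.var(axis=1, ddof=1) * k / (k - 1)
        scores = pd.DataFrame({"rho": np.sqrt(var)})
        return StabilityResult(scope, "NormFinder", scores, _rank_by(scores["rho"]))

    groups = groups.loc[centered.columns]
    labels = [g for g in pd.unique(groups)]
    if len(labels) < 2:
        raise ValueError("grouped NormFinder needs >= 2 groups")
    overall_mean = centered.mean(axis=1)
    d = pd.DataFrame(index=genes, columns=labels, dtype=float)
    s2 = pd.DataFrame(index=genes, columns=labels, dtype=float)
    n_g = {}
    for lab in labels:
        cols = groups.index[groups == lab]
        if len(cols) < 2:
            raise ValueError(f"group {lab!r} has < 2 reactions")
        n_g[lab] = len(cols)
        block = centered[cols]
        d[lab] = block.mean(axis=1) - overall_mean
        s2[lab] = block.var(axis=1, ddof=1)
    gamma2 = float((d.to_numpy() ** 2).mean())
    rho = {}
    for gene in genes:
        terms = []
        for lab in labels:
            sampling = s2.loc[gene, lab] / n_g[lab]
            shrink = gamma2 / (gamma2 + sampling) if gamma2 + sampling > 0 else 0.0
            d_tilde = d.loc[gene, lab] * shrink
            terms.append(abs(d_tilde) + np.sqrt(sampling))
        rho[gene] = float(np.mean(terms))
    scores = pd.DataFrame({"rho": pd.Series(rho)})
    return StabilityResult(scope, "NormFinder", scores, _rank_by(scores["rho"]))


# ---------------------------------------------------------------------------
# BestKeeper

def bestkeeper(cq: CqMatrix, scope: str = "all") -> StabilityResult:
    """Descriptive BestKeeper statistics on raw Cq.

    Per gene: SD_Cp is the mean absolute deviation of Cq about the gene's
    geometric mean Cq (the convention of the original spreadsheet, despite
    its "SD" label), CV_BK = 100 * SD_Cp / geomean, and r_index is the
    Pearson correlation of the gene's Cq with the BestKeeper index (the
    per-reaction geometric mean over all genes).  Ranking is by SD_Cp
    ascending; r_index is reported but not used for ordering.
    """
    _require(cq, 2, 2, "BestKeeper")
    vals = cq.cq
    if (vals.to_numpy() <= 0).any():
        raise ValueError("BestKeeper requires positive Cq values")
    log_vals = np.log(vals)
    index = np.exp(log_vals.mean(axis=0))  # per-reaction geometric mean
    rows = {}
    for gene in cq.genes:
        y = vals.loc[gene].dropna()
        geo = float(np.exp(np.log(y).mean()))
        sd_cp = float((y - geo).abs().mean())
        if np.isclose(y.std(ddof=1), 0.0):
            r = np.nan  # undefined for a constant gene; not an error
        else:
            r = float(stats.pearsonr(y.to_numpy(), index[y.index].to_numpy())[0])
        rows[gene] = {"geo_mean_cq": geo, "sd_cp": sd_cp, "cv_bk": 100.0 * sd_cp / geo, "r_index": r}
    scores = pd.DataFrame(rows).T
    return StabilityResult(scope, "BestKeeper", scores, _rank_by(scores["sd_cp"]))


# ---------------------------------------------------------------------------
# Comparative delta-Ct

def delta_ct_stability(cq: CqMatrix, scope: str = "all") -> StabilityResult:
    """Comparative dCt: mean SD of a gene's pairwise Cq differences.

    For each gene pair the per-reaction difference dCt = Cq_g - Cq_h is
    formed; a stable pair has constant dCt.  A gene's score is the mean of
    SD(dCt) over all partners.  With perfect doubling efficiency this is
    identical, gene by gene, to the geNorm M value computed on relative
    quantities (log2 ratios equal Cq differences up to sign and constant).
    """
    _require(cq, 2, 2, "comparative dCt")
    genes = cq.genes
    sds = pd.DataFrame(np.nan, index=genes, columns=genes, dtype=float)
    for g, h in itertools.combinations(genes, 2):
        s = float((cq.cq.loc[g] - cq.cq.loc[h]).std(ddof=1))
        sds.loc[g, h] = sds.loc[h, g] = s
    mean_sd = sds.mean(axis=1)  # skips the NaN diagonal
    scores = pd.DataFrame({"mean_sd": mean_sd})
    return StabilityResult(scope, "dCt", scores, _rank_by(scores["mean_sd"]))


# ---------------------------------------------------------------------------
# Scope-sweep driver

def run_all_methods(
    cq: CqMatrix,
    eff: EfficiencyTable | None = None,
    scopes: list[str] | None = None,
    groups_column: str | None = None,
    cutoff: float = 0.15,
) -> dict[str, dict[str, StabilityResult]]:
    """All five methods on each requested scope (default: each panel + pooled).

    Returns ``{scope: {method: StabilityResult}}``; the geNorm entry's
    ``extra`` carries the pairwise-variation series and normalized-CV table
    for the scope.
    """
    if scopes is None:
        scopes = cq.panels + ["all"]
    if eff is None:
        eff = EfficiencyTable.default(cq.genes)
    out: dict[str, dict[str, StabilityResult]] = {}
    for scope in scopes:
        sub = cq.subset(scope).drop_sparse_genes()
        rq = cq_to_rq(sub, eff)
        groups = sub.annotations[groups_column] if groups_column else None
        results = {
            "SI": stability_index(sub, scope),
            "geNorm": genorm_ranking(rq, scope),
            "NormFinder": normfinder_stability(rq, groups, scope),
            "BestKeeper": bestkeeper(sub, scope),
            "dCt": delta_ct_stability(sub, scope),
        }
        gn = results["geNorm"]
        pv = pairwise_variation(rq, gn.ranking, cutoff, scope)
        gn.extra["pairwise_variation"] = pv
        gn.extra["cv_norm"] = genorm_cv(rq, gn.ranking[: max(2, pv.minimal_n)])
        out[scope] = results
    return out
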