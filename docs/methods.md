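# Methods

## The problem and the data model

A Cq value is the PCR cycle at which a reaction's fluorescence crosses
threshold; it is logarithmic in starting template amount, with one cycle
corresponding to a factor *E* (the per-cycle amplification efficiency,
2 at perfect doubling).  The universal input is a Cq matrix (genes x
reactions) with per-reaction annotations: experiment panel, condition,
treatment group, biological replicate, technical replicate, and a mock
flag.  Every reaction is one observation — technical replicates are *not*
pre-averaged for the stability statistics, matching the reaction counts
such studies report; quantification is the deliberate exception (below).

Relative quantities are q = E^(Cq_min − Cq) per gene, so q ∈ (0, 1] with
the gene's most-expressed sample as calibrator.  No published convention
fixes this calibrator; any per-gene constant cancels in every downstream
ratio statistic (pairwise log ratios, normalization factors, fold
changes), so the choice is consequence-free and made for numerical
hygiene.  Missing Cq cells are carried as missing, never zero; pairwise
statistics use pairwise-complete observations, and genes with fewer than
3 present values in a scope are excluded from that scope with a warning.

## The five stability statistics

All ratio logarithms are base 2 (the geNorm convention); NormFinder's ρ is
therefore reported in log2 units.

**Stability index.**  Per gene: CV = 100·SD/mean of Cq, and the OLS slope
of the gene's per-reaction Cq on the per-reaction mean Cq across genes
(sensitivity to conditions that shift overall expression).  SI =
CV · |slope|.  The absolute slope is deliberate: a gene moving *against*
the panel is no better a reference than one moving with it, and fitted
slopes can be negative even though published tables print only positive
ones.  SI is the one method not invariant to an additive Cq offset (the
mean sits in CV's denominator) — a documented asymmetry.

**geNorm.**  M_j = mean over partners k of SD_i(log2 q_ji − log2 q_ki).
Ranking by iterative exclusion: the highest-M gene is removed and its M at
that step recorded as its M_A; the final two genes share the last
(common) value.  Ties are broken toward label order (later labels excluded
first, so fully tied panels rank alphabetically, with a warning).  Genes
with M_A > 1 are flagged as unacceptable for heterogeneous sample sets.
The normalized CV is SD/mean of q/NF with NF the geometric mean of a
reference set.  Pairwise variation V(n/n+1) = SD_i(log2 NF_n,i/NF_{n+1,i})
over the ranking's top-n genes; the minimal number of references is the
first n with V below the 0.15 cutoff (reported as the panel size, with a
warning, if none passes).  Geometric means are computed in log space, so a
gene exactly proportional to NF_n contributes V = 0.

**NormFinder.**  On y = log2 q, columns are centered by the per-reaction
mean across the K genes, removing sample loading.  Without groups, ρ_g is
the SD of the centered values with the variance rescaled by K/(K−1):
centering over K genes contracts each gene's own variance by (K−1)/K, and
the rescaling undoes the bulk of that contraction.  With groups, per group
the intragroup variance s² of centered values and the intergroup deviation
d (group mean minus the gene's overall centered mean) combine as
ρ_g = mean over groups of |d̃| + sqrt(s²/n), where d̃ shrinks d by
γ²/(γ² + s²/n) and γ² is the across-genes, across-groups mean of d² — a
simple moment estimator of the true intergroup variance.  Groups need at
least 2 reactions each.

**BestKeeper.**  Per gene, the dispersion statistic is the mean absolute
deviation of Cq about the gene's *geometric* mean Cq (the convention of
the original spreadsheet, although it is conventionally labelled "SD"),
plus CV_BK = 100·MAD/geomean and the Pearson correlation of the gene's Cq
with the BestKeeper index (per-reaction geometric mean over all genes,
the gene itself included).  Ranking is by the dispersion; the correlation
is reported but never used for ordering, and is missing (not an error) for
a constant gene.

**Comparative ΔCt.**  For every gene pair, SD_i(Cq_g − Cq_h); a gene's
score is the mean over partners.  With all E = 2 this equals the geNorm M
gene for gene (log2 ratios of E=2 quantities are Cq differences up to sign
and a per-gene constant); the identity is verified numerically to ~1e−15
relative and serves as a cross-implementation check.

## Consensus ranking

The objective is the mean Spearman footrule distance (sum of absolute
1-based rank displacements) to the five method rankings; the unweighted
form is the default, with a min-max score-weighted variant available.  The
cross-entropy optimizer keeps an n x n (gene, position) probability matrix
starting uniform; each iteration samples 500 orderings (positions filled
left to right, drawing an unused gene from the renormalized column),
retains the best 10% (rarity 0.1) as the elite, and updates the matrix as
0.7·(elite frequencies) + 0.3·(previous), flooring entries at 1e−12 and
renormalizing columns.  It stops when the elite objective has not improved
for 5 iterations (tolerance 1e−8) or at 200 iterations, and returns the
best ordering ever seen, so the incumbent objective is monotone.  The
hyperparameters follow common cross-entropy practice; all are exposed, and
a seed is mandatory.  Exhaustive enumeration (≤ 8 genes, ties to the
lexicographically smallest ordering) provides the oracle: on random
6-gene, 5-list instances the CE result attains the enumerated optimum
essentially always and can never undercut it.

## Efficiency estimation

Within the exponential phase, log10 fluorescence is linear in cycle with
slope log10 E.  The noise floor is the median of cycles 1–8 plus 10x their
SD (early cycles carry only background); the plateau threshold is 90% of
the curve maximum.  Among all contiguous windows of 4–6 cycles lying
strictly between the two, the OLS fit of log10 F on cycle with the highest
r² wins (ties: steeper slope, then earlier window); E = 10^slope.
Estimates with r² < 0.99 or E outside (1, 2.2] are dropped before the
per-amplicon mean ± SD (n−1 denominator, as everywhere in the package).
Scaling a curve by any positive constant shifts only the intercept, and on
noiseless exponentials any eligible window recovers E to machine
precision.  On saturating curves the estimator is slightly conservative:
the logistic bend begins below the plateau threshold, so fitted slopes sit
a few hundredths low (≈ 1.77 for a true 1.8 at the generator's default
noise) — the same behavior window-of-linearity tools show on real data.

## Synthetic study generator

Cq[g, c, b, t] = b_g + s_g·L_c + δ_{g,group(c)} + u_{g,c,b} + e_{g,c,b,t},
with condition loads L_c ~ N(0,1) shared across genes (the
expression-promoting component the SI slope detects), biological noise
u ~ N(0, σ_bio²) shared by a sample's technical replicates, and technical
noise e ~ N(0, σ_tech²) per reaction.  Noise is Gaussian on the Cq scale
because Cq is already logarithmic in quantity.  The default design is 13
candidates over seven panels — a 5-stage ripening series, fungal-infection
series on fruit (5), crown (8) and petiole (8) of one cultivar, petiole of
a second cultivar (7), and two hormone-elicitation series (9, 6) — 48
conditions, 2 biological x 2 technical replicates: 192 reactions per gene,
with baselines spanning 8–30 cycles and per-gene SDs up to ~1.4 cycles,
the ranges real panels report.  An optional 14th gene is an induced target
(−3 cycles in treated groups = 8-fold at E = 2).

The true stability order ranks genes by
τ_g = sqrt(σ_bio² + σ_tech²) + |s_g|·SD(L) + SD(δ_g,·).  The default
parameter ladder (σ_bio = σ_tech from 0.05 to 1.0 cycles; slopes 0 to
0.37; G01 the designed true reference with zero slope and minimal noise)
keeps the noise component dominant.  This is a deliberate identifiability
choice, not a convenience: the pairwise methods (geNorm, ΔCt) score
deviation from the panel consensus rather than absolute load response, so
if load sensitivities spread widely the methods would legitimately
disagree about the "true" order and no single ground truth would exist.
The generator therefore emulates panels whose candidates differ mainly in
noise — which is also what passing the recovery tests does and does not
show: recovery of a noise-dominated ladder, not of panels where
co-regulation or strong shared trends dominate (geNorm's known blind
spot applies there on real data exactly as the generator cannot represent
it).  Amplification curves use a logistic plateau
F_c = P·F0·E^c/(P + F0(E^c − 1)) plus additive read noise (defaults:
F0 = 1e−6, P = 1.0, SD 2e−4, 40 cycles — a baseline-subtracted SYBR
trace); baseline drift is not modelled.

## Quantification

For quantification (and only there) technical replicates are averaged on
the Cq scale first — standard qPCR practice, and a documented asymmetry
with the stability stages.  The normalization factor is the per-reaction
geometric mean of the reference genes' relative quantities; the target's
normalized quantity q is calibrated per panel to the mean over the panel's
mock-flagged reactions (or a named condition).  Published designs calibrate
"each sample to its corresponding mock" without defining the pairing;
pooling the panel's mocks is used here because the generator's induction is
uniform within treated groups — time-matched pairing would matter for
time-varying inductions and is the natural extension.  Fold change per
condition is mean(q over its biological replicates)/mean(q over the
calibrator's); the SD is the biological-replicate spread divided by the
calibrator mean.  Fold-change aggregation is arithmetic on the linear
scale (a geometric option exists).  The bias contrast reruns the
quantification with a single unstable reference and reports
log2(fold_worst/fold_best) per condition; a reference with a +1-cycle
treatment effect produces exactly +1 log2 unit of bias at E = 2.

## Numerical choices and edge cases

Sample statistics use the n−1 denominator throughout.  Rankings sort
ascending with stable label-order tie-breaks.  A zero-variance predictor
in the SI regression yields slope 0 with a warning; a constant gene is
legal everywhere (SI = 0, M = 0, ρ at the panel minimum, BestKeeper
correlation missing).  Cq values must lie in (0, 45); efficiencies in
(1, 2.2].  The exact-zero pairwise-variation fixtures use power-of-two
quantities with evenly dividing log2 sums so geometric means are exact in
floating point; generic scalar-multiple profiles give V below 1e−12
rather than bitwise zero.  Problem sizes in the test suite and acceptance
script (100 recovery seeds, 50 consensus seeds, 100 optimizer instances,
100 curves) were chosen as the smallest that make the pass criteria
statistically comfortable.

## Known limitations

The generator omits missing-data patterns, plate/run batch effects,
co-regulated gene clusters and inhibition kinetics; the efficiency module
does not call Cq from curves or reproduce any specific tool's windowing
heuristics version by version; the consensus stage implements the footrule
objective only (no Kendall tau, no genetic-algorithm search); confidence
intervals on M or ρ are out of scope.  The bundled published table allows
arithmetic-consistency checks only — the underlying per-reaction Cq data
were never deposited, so the published per-panel M_A, V, NormFinder and
BestKeeper values cannot be recomputed, and the package's correctness on
those statistics rests on the hand-computed oracles, cross-method
identities and parameter-recovery results instead.
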