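"""Synthetic RT-qPCR study generator with known ground truth.

Generates Cq panels with the statistical structure the five stability
methods assume, so every downstream stage is testable without real data.
The default configuration emulates a strawberry defense-response study
design: 13 candidate reference genes plus one induced target gene, seven
experiment panels totalling 48 conditions, and 2 biological x 2 technical
replicates, i.e. 192 reactions per gene.

Model (all on the Cq scale, which is logarithmic in template amount):

    Cq[g, c, b, t] = b_g + s_g * L_c + delta_{g, group(c)} + u_{g,c,b} + e_{g,c,b,t}

with per-condition load L_c ~ N(0, 1) shared across genes (general
expression-promoting conditions that the stability-index slope detects),
biological noise u ~ N(0, sigma_bio_g^2) per biological replicate, and
technical noise e ~ N(0, sigma_tech_g^2) per reaction.

The implied true stability order ranks genes by the total perturbation

    tau_g = sqrt(sigma_bio_g^2 + sigma_tech_g^2) + |s_g| * SD(L) + SD(delta_g, .)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CqMatrix
from .efficiency import AmplificationCurve


@dataclass(frozen=True)
class GeneParams:
    """Generative parameters for one gene."""

    name: str
    baseline: float  # cycles
    slope: float = 0.0  # dimensionless load sensitivity, >= 0
    sigma_bio: float = 0.0  # cycles
    sigma_tech: float = 0.0  # cycles
    group_effects: tuple[tuple[str, float], ...] = ()  # (group, cycles)

    def __post_init__(self) -> None:
        if self.sigma_bio < 0 or self.sigma_tech < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.slope < 0:
            raise ValueError("load sensitivity must be non-negative")

    def delta(self, group: str) -> float:
        return dict(self.group_effects).get(group, 0.0)


@dataclass(frozen=True)
class Condition:
    label: str
    group: str
    is_mock: bool = False


@dataclass(frozen=True)
class PanelSpec:
    label: str
    conditions: tuple[Condition, ...]


@dataclass
class SimulationConfig:
    genes: list[GeneParams]
    panels: list[PanelSpec]
    bio_reps: int = 2
    tech_reps: int = 2
    seed: int = 0
    target: GeneParams | None = None

    def __post_init__(self) -> None:
        if self.bio_reps < 1 or self.tech_reps < 1:
            raise ValueError("replicate counts must be positive")
        if not self.genes:
            raise ValueError("at least one gene required")

    @property
    def n_conditions(self) -> int:
        return sum(len(p.conditions) for p in self.panels)


@dataclass
class SyntheticTruth:
    """Realized generator parameters and the implied true stability order."""

    genes: list[GeneParams]
    load: pd.Series  # per-condition L_c, index "panel:condition"
    tau: pd.Series  # per-gene total perturbation score
    true_stability_order: list[str]  # most stable first

    def to_dict(self) -> dict:
        return {
            "tau": {g: float(t) for g, t in self.tau.items()},
            "true_stability_order": list(self.true_stability_order),
            "load": {k: float(v) for k, v in self.load.items()},
        }


# Default study design: seven panels, 48 conditions.  Panel codes follow the
# field's shorthand for a ripening series, fungal-infection time courses on
# fruit/crown/petiole in two cultivars, and two hormone-elicitation series.
def _tc(group: str, times, mock: bool = False) -> list[Condition]:
    return [Condition(f"{group}_{t}", group, mock) for t in times]


DEFAULT_PANELS: tuple[PanelSpec, ...] = (
    PanelSpec(
        "RCF",
        tuple(
            Condition(stage, "ripening", stage == "G")
            for stage in ("G", "W", "R", "OR", "SE")
        ),
    ),
    PanelSpec(
        "FCF",
        (
            Condition("mock", "mock", True),
            *[Condition(f"grade{i}", "infected") for i in (1, 2, 3, 4)],
        ),
    ),
    PanelSpec(
        "FCC",
        tuple(_tc("mock", (1, 3, 5, 7), True) + _tc("infected", (1, 3, 5, 7))),
    ),
    PanelSpec(
        "FCP",
        tuple(_tc("mock", (1, 3, 5, 7), True) + _tc("infected", (1, 3, 5, 7))),
    ),
    PanelSpec(
        "FAP",
        tuple(_tc("mock", (3, 5, 7), True) + _tc("infected", (1, 3, 5, 7))),
    ),
    PanelSpec(
        "HCY",
        tuple(
            _tc("mock", (12, 24, 48), True)
            + _tc("SA", (12, 24, 48))
            + _tc("MeJA", (12, 24, 48))
        ),
    ),
    PanelSpec(
        "HCC",
        tuple(_tc("mock", (4, 6), True) + _tc("SA", (4, 6)) + _tc("MeJA", (4, 6))),
    ),
)

# Default candidate-gene parameters.  Noise SDs are well separated (0.05 to
# 1.0 cycles, matching the 0.2-1.9 SD range seen in real panels) and load
# slopes are kept modest relative to the noise spread: pairwise methods
# (geNorm, comparative dCt) score deviation from the panel consensus rather
# than absolute load response, so a single well-defined true order across all
# five methods requires the noise component to dominate.  G01 is the designed
# "true reference" (zero slope, minimal noise).  Baselines span the 8-30
# cycle range of real panels.
_BASELINES = (22.6, 8.5, 23.1, 23.9, 22.3, 25.6, 17.4, 23.3, 22.9, 30.0, 26.7, 17.1, 24.1)
_SIGMAS = (0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35, 0.40, 0.50, 0.60, 0.70, 0.85, 1.00)
_SLOPES = (0.00, 0.01, 0.02, 0.03, 0.05, 0.07, 0.09, 0.12, 0.15, 0.19, 0.24, 0.30, 0.37)


def default_gene_params() -> list[GeneParams]:
    return [
        GeneParams(f"G{k + 1:02d}", _BASELINES[k], _SLOPES[k], _SIGMAS[k], _SIGMAS[k])
        for k in range(13)
    ]


def default_target_params(induction_cycles: float = -3.0) -> GeneParams:
    """An induced target gene: induction_cycles = -3 is an 8-fold rise at E=2."""
    return GeneParams(
        "TARGET",
        26.0,
        0.0,
        0.15,
        0.15,
        tuple((g, induction_cycles) for g in ("infected", "SA", "MeJA")),
    )


def default_config(seed: int = 0, include_target: bool = True) -> SimulationConfig:
    return SimulationConfig(
        genes=default_gene_params(),
        panels=list(DEFAULT_PANELS),
        bio_reps=2,
        tech_reps=2,
        seed=seed,
        target=default_target_params() if include_target else None,
    )


def _true_order(genes: list[GeneParams], load_sd: float, groups: list[str]) -> tuple[pd.Series, list[str]]:
    tau = {}
    for gp in genes:
        deltas = np.array([gp.delta(g) for g in groups], dtype=float)
        tau[gp.name] = (
            float(np.hypot(gp.sigma_bio, gp.sigma_tech))
            + gp.slope * load_sd
            + float(np.std(deltas))
        )
    ser = pd.Series(tau)
    order = ser.sort_values(kind="stable").index.tolist()
    return ser, order


def simulate_study(config: SimulationConfig) -> tuple[CqMatrix, SyntheticTruth]:
    """Simulate a full Cq panel; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    genes = list(config.genes) + ([config.target] if config.target else [])
    conditions = [
        (panel.label, cond) for panel in config.panels for cond in panel.conditions
    ]
    load = pd.Series(
        rng.normal(0.0, 1.0, size=len(conditions)),
        index=[f"{p}:{c.label}" for p, c in conditions],
    )
    groups_in_design = sorted({c.group for _, c in conditions})

    cols, rows = [], []
    cq = {g.name: [] for g in genes}
    for (panel, cond), L in zip(conditions, load):
        # biological noise is shared by the technical replicates of a sample
        u = {
            (g.name, b): rng.normal(0.0, g.sigma_bio)
            for b in range(1, config.bio_reps + 1)
            for g in genes
        }
        for b in range(1, config.bio_reps + 1):
            for t in range(1, config.tech_reps + 1):
                rid = f"{panel}:{cond.label}:b{b}t{t}"
                cols.append(rid)
                rows.append(
                    {
                        "panel": panel,
                        "condition": cond.label,
                        "group": cond.group,
                        "bio_rep": b,
                        "tech_rep": t,
                        "is_mock": cond.is_mock,
                    }
                )
                for g in genes:
                    e = rng.normal(0.0, g.sigma_tech)
                    cq[g.name].append(
                        g.baseline + g.slope * L + g.delta(cond.group) + u[(g.name, b)] + e
                    )
    ann = pd.DataFrame(rows, index=pd.Index(cols, name="reaction_id"))
    mat = CqMatrix(
        pd.DataFrame(cq, index=cols).T.set_axis([g.name for g in genes]), ann
    )
    load_sd = float(np.std(load.to_numpy()))
    tau, order = _true_order(list(config.genes), load_sd, groups_in_design)
    truth = SyntheticTruth(list(config.genes), load, tau, order)
    return mat, truth


def simulate_amplification_curves(
    n_curves: int,
    e_true: float = 1.8,
    f0: float = 1e-6,
    plateau: float = 1.0,
    noise_sd: float = 2e-4,
    n_cycles: int = 40,
    seed: int = 0,
    amplicon: str = "amp",
) -> list[AmplificationCurve]:
    """Logistic (saturating) amplification curves with additive read noise.

    F_c = plateau * F0 * E^c / (plateau + F0 * (E^c - 1)) + N(0, noise_sd^2),
    clipped at 0.  ``plateau = inf`` gives a pure exponential.
    """
    if not 1.0 < e_true <= 2.0:
        raise ValueError("amplification factor must lie in (1, 2]")
    if f0 <= 0 or plateau <= f0:
        raise ValueError("need F0 > 0 and plateau > F0")
    rng = np.random.default_rng(seed)
    cycles = np.arange(1, n_cycles + 1, dtype=float)
    growth = f0 * np.power(e_true, cycles)
    if np.isinf(plateau):
        clean = growth
    else:
        clean = plateau * growth / (plateau + growth - f0)
    curves = []
    for i in range(n_curves):
        noisy = clean + rng.normal(0.0, noise_sd, size=n_cycles) if noise_sd > 0 else clean.copy()
        curves.append(
            AmplificationCurve(
                reaction_id=f"{amplicon}_r{i + 1}",
                amplicon=amplicon,
                fluorescence=np.clip(noisy, 0.0, None),
            )
        )
    return curves
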