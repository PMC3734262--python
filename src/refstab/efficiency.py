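"""PCR efficiency estimation from raw fluorescence curves.

Window-of-linearity approach: within the exponential phase of an
amplification curve, log-fluorescence is linear in cycle number with slope
log10(E).  The estimator scans all contiguous cycle windows of length 4-6
whose readings sit above the baseline noise floor and below the plateau,
fits log10(F) on cycle by ordinary least squares, and keeps the window with
the best coefficient of determination.  Per-amplicon efficiencies are then
aggregated to mean +/- SD, the form used for efficiency-corrected
quantification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import EfficiencyTable


@dataclass
class AmplificationCurve:
    """Per-cycle fluorescence readings for one reaction."""

    reaction_id: str
    amplicon: str
    fluorescence: np.ndarray  # arbitrary fluorescence units, cycle 1..n

    def __post_init__(self) -> None:
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.fluorescence.ndim != 1 or self.fluorescence.size < 15:
            raise ValueError("curve needs >= 15 per-cycle readings")
        if not np.isfinite(self.fluorescence).all():
            raise ValueError("non-finite fluorescence reading")


@dataclass
class EfficiencyEstimate:
    reaction_id: str
    amplicon: str
    e_hat: float  # amplification factor per cycle, 10**slope
    window: tuple[int, int]  # first and last cycle, inclusive, 1-based
    r_squared: float
    log_f0: float  # fitted intercept, log10-fluorescence at cycle 0


class NoExponentialPhaseError(ValueError):
    pass


def _noise_floor(f: np.ndarray) -> float:
    """Baseline threshold: median of the first 8 cycles + 10 x their SD.

    Early cycles carry only background signal, so readings must clear this
    floor to count as exponential-phase data.
    """
    base = f[:8]
    return float(np.median(base) + 10.0 * np.std(base, ddof=1))


def estimate_efficiency(
    curve: AmplificationCurve,
    window_min: int = 4,
    window_max: int = 6,
    plateau_fraction: float = 0.9,
) -> EfficiencyEstimate:
    """Best log-linear window fit; E_hat = 10**slope.

    Candidate windows must lie strictly between the noise floor and
    ``plateau_fraction`` of the maximum reading, and contain only positive
    readings.  Ties on r^2 go to the steeper slope, then the earlier window.
    """
    if not 2 <= window_min <= window_max:
        raise ValueError("window bounds must satisfy 2 <= min <= max")
    f = curve.fluorescence
    n = f.size
    floor = _noise_floor(f)
    ceiling = plateau_fraction * float(f.max())
    best = None
    for length in range(window_min, window_max + 1):
        for start in range(0, n - length + 1):
            seg = f[start : start + length]
            if (seg <= floor).any() or (seg >= ceiling).any() or (seg <= 0).any():
                continue
            cycles = np.arange(start + 1, start + length + 1, dtype=float)
            fit = stats.linregress(cycles, np.log10(seg))
            key = (fit.rvalue**2, fit.slope, -start)
            if best is None or key > best[0]:
                best = (key, fit, (start + 1, start + length))
    if best is None:
        raise NoExponentialPhaseError(
            f"no exponential phase detected in {curve.reaction_id!r}"
        )
    _, fit, window = best
    return EfficiencyEstimate(
        reaction_id=curve.reaction_id,
        amplicon=curve.amplicon,
        e_hat=float(10.0**fit.slope),
        window=window,
        r_squared=float(fit.rvalue**2),
        log_f0=float(fit.intercept),
    )


def aggregate_efficiency(
    estimates: list[EfficiencyEstimate],
    r2_min: float = 0.99,
    e_max: float = 2.2,
) -> EfficiencyTable:
    """Per-amplicon mean and SD (n-1) of accepted window estimates.

    Estimates with r^2 below ``r2_min`` or an amplification factor outside
    (1, e_max] are excluded (quality control on the window fit); a mean
    outside the plausible band triggers the EfficiencyTable warning.
    """
    if not estimates:
        raise ValueError("no efficiency estimates to aggregate")
    rows = [
        {"amplicon": est.amplicon, "e_hat": est.e_hat}
        for est in estimates
        if est.r_squared >= r2_min and 1.0 < est.e_hat <= e_max
    ]
    if not rows:
        raise ValueError("no estimate passed quality control")
    df = pd.DataFrame(rows)
    agg = df.groupby("amplicon")["e_hat"].agg(
        mean_E="mean", sd_E=lambda x: x.std(ddof=1) if len(x) > 1 else 0.0, n_reactions="size"
    )
    agg["sd_E"] = agg["sd_E"].fillna(0.0)
    return EfficiencyTable(agg)


def read_curves(path) -> list[AmplificationCurve]:
    """Long-format CSV: reaction_id, amplicon, cycle, fluorescence."""
    df = pd.read_csv(path)
    required = {"reaction_id", "amplicon", "cycle", "fluorescence"}
    if not required.issubset(df.columns):
        raise ValueError(f"curve file needs columns {sorted(required)}")
    curves = []
    for (rid, amp), sub in df.groupby(["reaction_id", "amplicon"], sort=False):
        sub = sub.sort_values("cycle")
        curves.append(AmplificationCurve(str(rid), str(amp), sub["fluorescence"].to_numpy()))
    return curves


def write_curves(curves: list[AmplificationCurve], path) -> None:
    frames = []
    for c in curves:
        frames.append(
            pd.DataFrame(
                {
                    "reaction_id": c.reaction_id,
                    "amplicon": c.amplicon,
                    "cycle": np.arange(1, c.fluorescence.size + 1),
                    "fluorescence": c.fluorescence,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.10g")
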