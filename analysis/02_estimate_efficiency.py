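#!/usr/bin/env python
"""Estimate PCR efficiency from synthetic amplification curves.

Simulates logistic amplification curves (true per-cycle factor 1.8, the
middle of the plausible SYBR range) for each amplicon, runs the
window-of-linearity estimator on every curve, and aggregates to the
per-amplicon mean +/- SD table used for efficiency-corrected analyses.
Writes results/efficiency/efficiency_table.csv.
"""

from pathlib import Path

from refstab.core import write_efficiency_table
from refstab.efficiency import aggregate_efficiency, estimate_efficiency
from refstab.simulate import simulate_amplification_curves

SEED = 1
E_TRUE = 1.8
OUT = Path(__file__).resolve().parents[1] / "results" / "efficiency"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    estimates = []
    for i, amplicon in enumerate(f"G{k + 1:02d}" for k in range(13)):
        curves = simulate_amplification_curves(
            16, e_true=E_TRUE, seed=SEED * 1000 + i, amplicon=amplicon
        )
        estimates += [estimate_efficiency(c) for c in curves]
    table = aggregate_efficiency(estimates)
    write_efficiency_table(table, OUT / "efficiency_table.csv")
    mean_of_means = table.table["mean_E"].mean()
    print(table.table.round(4).to_string())
    print(f"\ngrand mean E_hat = {mean_of_means:.4f} (truth {E_TRUE}); "
          f"estimates sit slightly low because the logistic bend begins "
          f"before the plateau threshold")
    print(f"wrote {OUT / 'efficiency_table.csv'}")


if __name__ == "__main__":
    main()
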