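#!/usr/bin/env python
"""Merge the five method rankings into a consensus per scope.

Reads rankings.json from 03_stability_methods.py (regenerating inputs if
absent) and minimizes the mean Spearman footrule distance with the
cross-entropy Monte-Carlo optimizer.  The recommended reference pair for
each scope is the consensus top-2.  Writes results/consensus/consensus.json
and a per-scope ordered CSV.
"""

import json
from pathlib import Path

import pandas as pd

from refstab.aggregate import RankedList, aggregate_ce

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "consensus"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rankings_path = ROOT / "stability" / "rankings.json"
    if not rankings_path.exists():
        raise SystemExit("run analysis/03_stability_methods.py first")
    with open(rankings_path) as fh:
        rankings = json.load(fh)
    bundle, rows = {}, []
    for i, (scope, by_method) in enumerate(sorted(rankings.items())):
        lists = [RankedList(m, genes) for m, genes in by_method.items()]
        cons = aggregate_ce(lists, seed=SEED + i)
        bundle[scope] = {
            "genes": cons.genes,
            "objective": cons.objective,
            "iterations": cons.iterations,
            "converged": cons.converged,
        }
        rows += [{"scope": scope, "rank": r + 1, "gene": g} for r, g in enumerate(cons.genes)]
        print(f"{scope:>4}: recommended pair {cons.genes[:2]}, least stable "
              f"{cons.genes[-1]}, footrule objective {cons.objective:.2f}")
    with open(OUT / "consensus.json", "w") as fh:
        json.dump(bundle, fh, indent=2, sort_keys=True)
    pd.DataFrame(rows).to_csv(OUT / "consensus.csv", index=False)
    print(f"wrote consensus tables to {OUT}")


if __name__ == "__main__":
    main()
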