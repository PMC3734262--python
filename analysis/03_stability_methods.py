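#!/usr/bin/env python
"""Run the five stability methods on the synthetic study, per scope.

Consumes the Cq table from 01_simulate_study.py (regenerating it if absent),
restricts to the 13 candidate genes, and scores every panel plus the pooled
"all" scope with the stability index, geNorm (M_A, V series, normalized CV),
NormFinder, BestKeeper, and the comparative dCt method.  Writes one score
CSV per scope x method and a rankings.json bundle under results/stability/.
"""

import json
from pathlib import Path

from refstab.core import read_cq_table
from refstab.simulate import default_config, simulate_study
from refstab.stability import run_all_methods

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "stability"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cq_path = ROOT / "synthetic" / "cq.csv"
    if cq_path.exists():
        cq = read_cq_table(cq_path, ROOT / "synthetic" / "annotations.csv")
    else:
        cq, _ = simulate_study(default_config(seed=SEED))
    candidates = [g for g in cq.genes if g != "TARGET"]
    results = run_all_methods(cq.select_genes(candidates))
    rankings = {}
    for scope, by_method in results.items():
        rankings[scope] = {m: r.ranking for m, r in by_method.items()}
        for method, res in by_method.items():
            res.scores.rename_axis("gene").to_csv(
                OUT / f"stability_{scope}_{method}.csv", float_format="%.6g"
            )
        pv = by_method["geNorm"].extra["pairwise_variation"]
        print(f"{scope:>4}: top by method "
              + ", ".join(f"{m}={r.ranking[0]}" for m, r in by_method.items())
              + f"; minimal reference genes n={pv.minimal_n} (cutoff {pv.cutoff})")
    with open(OUT / "rankings.json", "w") as fh:
        json.dump(rankings, fh, indent=2, sort_keys=True)
    print(f"wrote per-method score tables and rankings.json to {OUT}")


if __name__ == "__main__":
    main()
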