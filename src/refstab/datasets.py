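"""Bundled reference datasets.

``strawberry_stability_index.csv`` is the printed per-panel summary table of
a published strawberry defense-response reference-gene survey: for 13
candidate genes in each of seven experiment panels plus the pooled set (104
rows), it lists mean Cq, SD, CV (%), the slope and intercept of the gene's
Cq regressed on per-sample overall mean Cq, and the resulting stability
index (CV x slope).  Panel codes: RCF fruit ripening, FCF/FCC/FCP fungal
infection of Camarosa fruit/crown/petiole, FAP fungal infection of Andana
petiole, HCY/HCC hormone elicitation of in-vitro plants / cell suspensions,
ALL the pooled analysis.  Greek letters in gene names are transliterated
(FaEF1a, FaTUBa, FaTUBb).

The table carries rounded values (3 decimals); the survey's authors worked
with unrounded intermediates, so recomputing CV from mean/SD or SI from
CV x slope reproduces the printed numbers only to within about half a unit
in the last decimal.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

SI_TARGET_ROWS = [
    # rows whose printed CV x slope reproduces the printed SI exactly at 3 dp
    ("RCF", "FaRIB413"),
    ("RCF", "FaCHC1"),
    ("RCF", "FaTUBb"),
    ("RCF", "FaACTIN"),
    ("RCF", "FaGAPDH1"),
]

CV_TARGET_ROWS = [
    # rows whose recomputed 100*SD/mean reproduces the printed CV exactly at 3 dp
    ("RCF", "FaFHA1"),
    ("FAP", "FaUBQ1"),
]


def load_strawberry_si_table() -> pd.DataFrame:
    """The published stability-index summary (104 gene x panel rows)."""
    ref = resources.files("refstab.data").joinpath("strawberry_stability_index.csv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path)
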