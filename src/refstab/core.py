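"""Core data model and I/O for quantification-cycle (Cq) panels.

The universal input is a :class:`CqMatrix`: a genes x reactions table of Cq
values together with per-reaction annotations (experiment panel, condition,
treatment group, biological and technical replicate, mock flag).  Cq is the
PCR cycle at which a reaction's fluorescence crosses threshold and is
logarithmic in starting template amount, so all downstream ratio statistics
operate on Cq or on relative quantities derived from it.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ANNOTATION_COLUMNS = [
    "reaction_id",
    "panel",
    "condition",
    "group",
    "bio_rep",
    "tech_rep",
    "is_mock",
]

CQ_MIN, CQ_MAX = 0.0, 45.0


class CqValidationError(ValueError):
    """Raised when a Cq panel or its annotations violate an invariant."""


@dataclass(frozen=True)
class ReactionAnnotation:
    """Metadata for one qPCR reaction (one well)."""

    reaction_id: str
    panel: str
    condition: str
    group: str
    bio_rep: int
    tech_rep: int
    is_mock: bool = False


@dataclass
class CqMatrix:
    """Quantification-cycle values per gene x reaction, with annotations.

    Parameters
    ----------
    cq
        DataFrame indexed by gene label with one column per reaction id.
        Missing reactions are NaN (recorded as missing, never zero).
    annotations
        DataFrame indexed by reaction_id with columns panel, condition,
        group, bio_rep, tech_rep, is_mock; one row per cq column.

    Each reaction is one observation: technical replicates are *not*
    pre-averaged (the stability statistics treat every well as a data point).
    """

    cq: pd.DataFrame
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        self.cq = self.cq.astype(float)
        if self.cq.index.duplicated().any():
            dupes = self.cq.index[self.cq.index.duplicated()].tolist()
            raise CqValidationError(f"duplicated gene labels: {dupes}")
        if self.cq.columns.duplicated().any():
            dupes = self.cq.columns[self.cq.columns.duplicated()].tolist()
            raise CqValidationError(f"duplicated reaction ids: {dupes}")
        ann = self.annotations
        missing_cols = [c for c in ANNOTATION_COLUMNS[1:] if c not in ann.columns]
        if missing_cols:
            raise CqValidationError(f"annotation columns missing: {missing_cols}")
        unknown = [r for r in self.cq.columns if r not in ann.index]
        if unknown:
            raise CqValidationError(f"reactions without annotation: {unknown}")
        extra = [r for r in ann.index if r not in self.cq.columns]
        if extra:
            raise CqValidationError(f"annotation for unknown reaction id: {extra}")
        self.annotations = ann.loc[list(self.cq.columns)]
        vals = self.cq.to_numpy()
        present = ~np.isnan(vals)
        if not np.isfinite(vals[present]).all():
            raise CqValidationError("non-finite Cq value present")
        bad = present & ((vals <= CQ_MIN) | (vals >= CQ_MAX))
        if bad.any():
            g, r = np.argwhere(bad)[0]
            raise CqValidationError(
                f"Cq out of range (0, 45) at gene {self.cq.index[g]!r}, "
                f"reaction {self.cq.columns[r]!r}: {vals[g, r]}"
            )
        key = self.annotations[["panel", "condition", "bio_rep", "tech_rep"]]
        if key.duplicated().any():
            raise CqValidationError(
                "(panel, condition, bio_rep, tech_rep) does not uniquely "
                "identify every reaction"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.cq.index)

    @property
    def reactions(self) -> list[str]:
        return list(self.cq.columns)

    @property
    def panels(self) -> list[str]:
        seen: list[str] = []
        for p in self.annotations["panel"]:
            if p not in seen:
                seen.append(p)
        return seen

    def subset(self, scope: str) -> "CqMatrix":
        """Restrict to one analysis scope: a panel label, or ``"all"``."""
        if scope == "all":
            return self
        mask = self.annotations["panel"] == scope
        if not mask.any():
            raise KeyError(f"unknown panel {scope!r}")
        cols = self.annotations.index[mask]
        return CqMatrix(self.cq[list(cols)].copy(), self.annotations.loc[cols].copy())

    def select_genes(self, genes: list[str]) -> "CqMatrix":
        missing = [g for g in genes if g not in self.cq.index]
        if missing:
            raise KeyError(f"unknown genes: {missing}")
        return CqMatrix(self.cq.loc[genes].copy(), self.annotations.copy())

    def drop_sparse_genes(self, min_present: int = 3) -> "CqMatrix":
        """Drop genes with fewer than ``min_present`` observed Cq values."""
        counts = self.cq.notna().sum(axis=1)
        drop = counts[counts < min_present].index.tolist()
        if drop:
            warnings.warn(
                f"excluding genes with < {min_present} present Cq values: {drop}",
                stacklevel=2,
            )
        keep = [g for g in self.genes if g not in drop]
        return CqMatrix(self.cq.loc[keep].copy(), self.annotations.copy())

    def average_technical_replicates(self) -> "CqMatrix":
        """Collapse technical replicates by arithmetic mean on the Cq scale.

        Used for quantification (standard qPCR practice); the stability
        statistics keep every reaction as an observation.
        """
        ann = self.annotations
        key = ["panel", "condition", "group", "bio_rep"]
        groups = ann.groupby(key, sort=False)
        new_cols, rows = [], []
        cq_new = {}
        for (panel, cond, grp, bio), sub in groups:
            rid = f"{panel}:{cond}:{grp}:b{bio}"
            new_cols.append(rid)
            cq_new[rid] = self.cq[list(sub.index)].mean(axis=1)
            rows.append(
                {
                    "panel": panel,
                    "condition": cond,
                    "group": grp,
                    "bio_rep": int(bio),
                    "tech_rep": 1,
                    "is_mock": bool(sub["is_mock"].iloc[0]),
                }
            )
        ann_new = pd.DataFrame(rows, index=pd.Index(new_cols, name="reaction_id"))
        return CqMatrix(pd.DataFrame(cq_new, index=self.cq.index), ann_new)


@dataclass
class EfficiencyTable:
    """Per-amplicon mean PCR efficiency E with SD and n.

    E is the per-cycle amplification factor (2 = perfect doubling).  Values
    at or below 1 are rejected: a non-amplifying assay cannot be used for
    quantification.
    """

    table: pd.DataFrame  # index amplicon; columns mean_E, sd_E, n_reactions

    def __post_init__(self) -> None:
        required = {"mean_E", "sd_E", "n_reactions"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"efficiency table needs columns {sorted(required)}")
        if (self.table["mean_E"] <= 1.0).any():
            bad = self.table.index[self.table["mean_E"] <= 1.0].tolist()
            raise ValueError(f"amplification factor must exceed 1: {bad}")
        if (self.table["mean_E"] > 2.2).any():
            bad = self.table.index[self.table["mean_E"] > 2.2].tolist()
            warnings.warn(f"implausibly high efficiency (> 2.2): {bad}", stacklevel=2)

    @classmethod
    def default(cls, genes: list[str], e: float = 2.0) -> "EfficiencyTable":
        """Perfect-doubling default (E = 2) for every amplicon."""
        return cls(
            pd.DataFrame(
                {"mean_E": e, "sd_E": 0.0, "n_reactions": 0},
                index=pd.Index(genes, name="amplicon"),
            )
        )

    def efficiency(self, gene: str) -> float:
        if gene not in self.table.index:
            raise KeyError(f"no efficiency for amplicon {gene!r}")
        return float(self.table.loc[gene, "mean_E"])


@dataclass
class RQMatrix:
    """Linear-scale relative quantities, same shape as the source CqMatrix.

    Calibrated so each gene's maximum RQ is 1 (the gene's minimum observed
    Cq, i.e. highest expression, is the per-gene calibrator).  Any per-gene
    constant calibrator cancels in every downstream ratio statistic, so this
    convention is consequence-free; it keeps all values in (0, 1].
    """

    rq: pd.DataFrame
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.rq.to_numpy()
        present = ~np.isnan(vals)
        if (vals[present] <= 0).any():
            raise ValueError("relative quantities must be positive")

    @property
    def genes(self) -> list[str]:
        return list(self.rq.index)


def geometric_mean(values) -> float:
    """exp(mean(log(values))); all values must be strictly positive."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("geometric mean of empty sequence")
    if (arr <= 0).any() or not np.isfinite(arr).all():
        raise ValueError("geometric mean requires finite positive values")
    return float(np.exp(np.mean(np.log(arr))))


def cq_to_rq(cq: CqMatrix, eff: EfficiencyTable | None = None) -> RQMatrix:
    """Convert Cq to relative quantities: rq = E ** (minCq - cq) per gene.

    One cycle at perfect efficiency (E = 2) halves the quantity.  ``eff``
    defaults to E = 2 for every gene.
    """
    if eff is None:
        eff = EfficiencyTable.default(cq.genes)
    out = {}
    for gene in cq.genes:
        e = eff.efficiency(gene)
        row = cq.cq.loc[gene]
        if row.isna().all():
            raise ValueError(f"gene {gene!r} has no observed Cq values")
        out[gene] = np.power(e, row.min() - row)
    rq = pd.DataFrame(out).T
    rq.index.name = cq.cq.index.name
    return RQMatrix(rq, cq.annotations.copy())


def read_cq_table(path, annotation_path, sep: str = ",") -> CqMatrix:
    """Read a delimited Cq table (genes in rows) plus its annotation CSV.

    Decimal commas (as printed in many qPCR exports) are accepted alongside
    decimal points.  Empty cells become missing values.
    """
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if raw.shape[0] == 0:
        raise CqValidationError("no data rows in Cq table")
    raw.index = raw.index.astype(str).str.strip()

    def _parse(cell, gene, rid):
        if cell is None or (isinstance(cell, float) and np.isnan(cell)):
            return np.nan
        s = str(cell).strip()
        if s == "" or s.upper() in {"NA", "NAN"}:
            return np.nan
        try:
            return float(s.replace(",", "."))
        except ValueError:
            raise CqValidationError(
                f"non-numeric Cq at gene {gene!r}, reaction {rid!r}: {s!r}"
            ) from None

    parsed = pd.DataFrame(
        [
            [_parse(raw.iloc[i, j], raw.index[i], raw.columns[j]) for j in range(raw.shape[1])]
            for i in range(raw.shape[0])
        ],
        index=raw.index,
        columns=raw.columns,
    )
    ann = pd.read_csv(annotation_path)
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise CqValidationError(f"annotation file missing columns: {missing}")
    ann["reaction_id"] = ann["reaction_id"].astype(str)
    ann = ann.set_index("reaction_id")
    ann["bio_rep"] = ann["bio_rep"].astype(int)
    ann["tech_rep"] = ann["tech_rep"].astype(int)
    ann["is_mock"] = ann["is_mock"].astype(bool)
    return CqMatrix(parsed, ann)


def write_cq_table(cq: CqMatrix, path, annotation_path) -> None:
    """Write a CqMatrix back to a Cq CSV + annotation CSV (read round-trips)."""
    cq.cq.to_csv(path, float_format="%.17g")
    ann = cq.annotations.copy()
    ann.index.name = "reaction_id"
    ann.to_csv(annotation_path)


def read_efficiency_table(path) -> EfficiencyTable:
    df = pd.read_csv(path)
    if "amplicon" in df.columns:
        df = df.set_index("amplicon")
    else:
        df = df.set_index(df.columns[0])
    return EfficiencyTable(df)


def write_efficiency_table(eff: EfficiencyTable, path) -> None:
    out = eff.table.copy()
    out.index.name = "amplicon"
    out.to_csv(path, float_format="%.12g")
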