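import numpy as np
import pandas as pd
import pytest

from refstab.core import CqMatrix


def make_cq(values, genes=None, panel="P", groups=None, conditions=None) -> CqMatrix:
    """Small CqMatrix from a 2-D array; one condition per reaction by default."""
    values = np.asarray(values, dtype=float)
    n_genes, n_rxn = values.shape
    genes = genes or [f"g{i + 1}" for i in range(n_genes)]
    cols = [f"r{i + 1}" for i in range(n_rxn)]
    ann = pd.DataFrame(
        {
            "panel": panel,
            "condition": conditions or [f"c{i + 1}" for i in range(n_rxn)],
            "group": groups or ["grp"] * n_rxn,
            "bio_rep": 1,
            "tech_rep": list(range(1, n_rxn + 1)),
            "is_mock": False,
        },
        index=pd.Index(cols, name="reaction_id"),
    )
    # distinct conditions keep the (panel, condition, bio, tech) key unique
    if conditions is not None:
        ann["tech_rep"] = 1
        ann["bio_rep"] = (
            ann.groupby(["panel", "condition"], sort=False).cumcount() + 1
        )
    return CqMatrix(pd.DataFrame(values, index=genes, columns=cols), ann)


@pytest.fixture
def toy_cq() -> CqMatrix:
    """3 genes x 4 reactions with visible structure."""
    return make_cq(
        [
            [20.0, 21.0, 22.0, 23.0],
            [18.0, 19.0, 20.0, 21.0],
            [25.0, 25.0, 25.0, 25.0],
        ]
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
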