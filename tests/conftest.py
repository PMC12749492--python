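import numpy as np
import pandas as pd
import pytest

from forelandeco import community_structure as cs
from forelandeco import zeta_diversity as zd


@pytest.fixture
def worked_incidence() -> zd.IncidenceMatrix:
    """Three sites with compositions {A,B,C}, {B,C,D}, {C,D,E} — small
    enough that every zeta order is hand-enumerable."""
    pres = pd.DataFrame(False, index=list("ABCDE"),
                        columns=["s1", "s2", "s3"])
    for site, taxa in [("s1", "ABC"), ("s2", "BCD"), ("s3", "CDE")]:
        pres.loc[list(taxa), site] = True
    return zd.IncidenceMatrix(pres)


@pytest.fixture
def eight_taxon_table() -> pd.DataFrame:
    """SI vector whose quartiles are hand-computable: Q1 = 0.275,
    Q3 = 1.625 under linear-interpolation quantiles."""
    si = [0.1, 0.2, 0.3, 0.4, 1.0, 1.5, 2.0, 2.5]
    return pd.DataFrame({
        "si": si,
        "occupancy": 1.0,
        "mean_rel_abundance": 1.0 / 8,
        "absent": False,
    }, index=[f"t{i}" for i in range(8)])


def singleton_matrix(n_samples: int, value: float = 6.0) -> cs.AbundanceMatrix:
    """One taxon present in exactly one of n samples, plus a constant
    background taxon so columns are normalisable."""
    counts = pd.DataFrame(
        np.vstack([np.eye(1, n_samples, 0)[0] * value,
                   np.full(n_samples, 10.0)]),
        index=["singleton", "background"],
        columns=[f"s{i}" for i in range(n_samples)])
    return cs.AbundanceMatrix(counts)
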