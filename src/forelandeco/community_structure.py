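"""Abundance tables and the habitat specialisation index.

The central ecological statistic here is the habitat specialisation index
(SI): the coefficient of variation (sample standard deviation / mean) of a
taxon's relative abundance across a set of samples. Taxa with evenly
spread, low-variance distributions score low (habitat generalists); taxa
with patchy, high-variance distributions score high (habitat specialists).
Classification is quartile-based: SI below the first quartile of the
community SI distribution -> generalist, above the third quartile ->
specialist, otherwise intermediate.

A supporting utility implements the iterative collinearity pre-filter
(Pearson |r| >= 0.9) used to reduce physicochemical predictor sets before
downstream driver modelling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

GENERALIST = "generalist"
INTERMEDIATE = "intermediate"
SPECIALIST = "specialist"
HABITAT_CLASSES = (GENERALIST, INTERMEDIATE, SPECIALIST)

#: Default abundance floor for amplicon-style tables: mean relative
#: abundance must exceed 0.005% for a taxon to enter classification.
DEFAULT_ABUNDANCE_FLOOR = 0.005 / 100.0


@dataclass
class AbundanceMatrix:
    """Taxon-by-sample abundance table with per-sample metadata.

    ``counts`` holds taxa as rows and samples as columns (raw counts or
    relative abundances). ``metadata`` is indexed by sample id and may
    carry glacier, age_class, age_years, depth, coordinates and named
    physicochemical variables.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate taxon labels in abundance matrix")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample labels in abundance matrix")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative abundances are not allowed")
        if self.metadata is not None:
            missing = set(self.counts.columns) - set(self.metadata.index)
            if missing:
                raise ValueError(
                    f"metadata missing for samples: {sorted(missing)}")

    @property
    def taxa(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    @classmethod
    def read_tsv(cls, counts_path: str | Path,
                 metadata_path: str | Path | None = None) -> "AbundanceMatrix":
        """Read a taxon-by-sample TSV (first column taxon id, header
        sample ids), optionally with a metadata TSV keyed by sample id."""
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        meta = None
        if metadata_path is not None:
            meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
        return cls(counts, meta)

    def write_tsv(self, counts_path: str | Path,
                  metadata_path: str | Path | None = None) -> None:
        self.counts.to_csv(counts_path, sep="\t")
        if metadata_path is not None and self.metadata is not None:
            self.metadata.to_csv(metadata_path, sep="\t")


def to_relative(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Convert counts to relative abundance (each sample column sums to 1).

    Raises on all-zero samples, naming the offending sample.
    """
    totals = matrix.counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(
            f"cannot normalise all-zero sample(s): {list(zero.index)}")
    rel = matrix.counts.div(totals, axis=1)
    return AbundanceMatrix(rel, matrix.metadata)


def specialisation_index(matrix: AbundanceMatrix,
                         sample_subset: list[str] | None = None,
                         abundance_floor: float = 0.0) -> pd.DataFrame:
    """Per-taxon habitat specialisation index and occupancy.

    The matrix is converted to relative abundance internally; SI is the
    coefficient of variation (sd with n-1 denominator over mean) of each
    taxon's relative abundance across the chosen samples. Taxa with zero
    mean abundance are flagged ``absent`` and carry NaN SI. An optional
    ``abundance_floor`` (mean relative abundance) additionally flags rare
    taxa as absent, excluding them from classification.

    Returns a DataFrame indexed by taxon with columns
    ``si, occupancy, mean_rel_abundance, absent``.
    """
    counts = matrix.counts
    if sample_subset is not None:
        counts = counts.loc[:, list(sample_subset)]
    if counts.shape[1] < 3:
        raise ValueError("specialisation index requires >= 3 samples")
    rel = to_relative(AbundanceMatrix(counts)).counts
    mean = rel.mean(axis=1)
    sd = rel.std(axis=1, ddof=1)
    occupancy = (rel > 0).mean(axis=1)
    absent = (mean <= 0) | (mean <= abundance_floor)
    n_absent = int(absent.sum())
    if n_absent:
        warnings.warn(
            f"{n_absent} taxa with mean relative abundance <= "
            f"{max(abundance_floor, 0.0):g} excluded from classification",
            stacklevel=2)
    si = sd / mean
    si[absent] = np.nan
    return pd.DataFrame({
        "si": si,
        "occupancy": occupancy,
        "mean_rel_abundance": mean,
        "absent": absent,
    })


def classify_specialisation(table: pd.DataFrame) -> pd.DataFrame:
    """Assign generalist/intermediate/specialist classes by SI quartiles.

    Q1 and Q3 are linear-interpolation quantiles of the defined SI values;
    classification uses strict inequalities (SI < Q1 generalist,
    SI > Q3 specialist, ties intermediate). Thresholds are recorded in the
    output columns ``q1``/``q3``. Requires >= 8 taxa with defined SI.
    """
    defined = table["si"].dropna()
    if len(defined) < 8:
        raise ValueError(
            f"need >= 8 taxa with defined si to classify, got {len(defined)}")
    q1, q3 = np.quantile(defined.to_numpy(), [0.25, 0.75])
    out = table.copy()
    cls = pd.Series(pd.NA, index=table.index, dtype="object")
    cls[table["si"] < q1] = GENERALIST
    cls[table["si"] > q3] = SPECIALIST
    cls[(table["si"] >= q1) & (table["si"] <= q3)] = INTERMEDIATE
    out["habitat_class"] = cls
    out["q1"] = q1
    out["q3"] = q3
    return out


def class_proportions(matrix: AbundanceMatrix, table: pd.DataFrame,
                      group_by: str,
                      classes: tuple[str, ...] = HABITAT_CLASSES
                      ) -> pd.DataFrame:
    """Per-group summed relative abundance of each habitat class.

    For each sample, sums the relative abundances of taxa in each habitat
    class, then averages over the samples of each metadata group. The
    ``residual`` column is the abundance carried by absent/unclassified
    taxa, so the class fractions sum to <= 1 per group. ``classes`` may
    be overridden to summarise any labelling carried in the
    ``habitat_class`` column (e.g. planted guilds).
    """
    if "habitat_class" not in table:
        raise ValueError("classes not assigned; run classify_specialisation")
    if matrix.metadata is None or group_by not in matrix.metadata.columns:
        raise KeyError(f"unknown metadata key: {group_by!r}")
    rel = to_relative(matrix).counts
    groups = matrix.metadata.loc[rel.columns, group_by]
    rows = {}
    for group, samples in groups.groupby(groups).groups.items():
        sub = rel.loc[:, list(samples)]
        if sub.shape[1] == 0:
            warnings.warn(f"group {group!r} empty after filtering; omitted",
                          stacklevel=2)
            continue
        per_class = {}
        for hc in classes:
            taxa = table.index[table["habitat_class"] == hc]
            per_class[hc] = float(
                sub.loc[sub.index.intersection(taxa)].sum(axis=0).mean())
        per_class["residual"] = 1.0 - sum(per_class.values())
        rows[group] = per_class
    return pd.DataFrame.from_dict(rows, orient="index")


def collinearity_filter(physico: pd.DataFrame, priority: list[str],
                        r_threshold: float = 0.9) -> list[str]:
    """Iteratively drop the lower-priority member of highly correlated pairs.

    While any pair of retained variables has absolute Pearson r >= the
    threshold, the worst-offending pair is found and its lower-priority
    member (later in ``priority``) removed. Constant variables, whose
    correlation is undefined, are removed first with a warning. The result
    is deterministic given the priority ordering.
    """
    if physico.shape[0] < 3:
        raise ValueError("collinearity filter requires >= 3 samples")
    missing = set(physico.columns) - set(priority)
    if missing:
        raise ValueError(f"priority list does not cover: {sorted(missing)}")
    rank = {v: i for i, v in enumerate(priority)}
    retained = sorted(physico.columns, key=rank.__getitem__)
    constant = [v for v in retained if physico[v].nunique() <= 1]
    if constant:
        warnings.warn(
            f"constant variable(s) removed (correlation undefined): "
            f"{constant}", stacklevel=2)
        retained = [v for v in retained if v not in constant]
    while len(retained) > 1:
        corr = physico[retained].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        if corr[i, j] < r_threshold:
            break
        # drop the lower-priority (higher-rank) member of the worst pair
        drop = max(retained[i], retained[j], key=rank.__getitem__)
        retained.remove(drop)
    return retained


def write_specialisation_tsv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a classified specialisation table as TSV
    (taxon, si, occupancy, class, q1, q3)."""
    out = table.reset_index(names="taxon")
    cols = ["taxon", "si", "occupancy", "habitat_class", "q1", "q3"]
    out[[c for c in cols if c in out.columns]].to_csv(
        path, sep="\t", index=False)
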