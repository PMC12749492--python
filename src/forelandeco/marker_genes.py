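"""Metabolic marker-gene profiling from homology-search hit tables.

Takes DIAMOND/BLAST-style tabular hits against curated metabolic marker
protein families and turns them into community metabolic profiles:

* per-family identity/coverage filtering with family-specific thresholds
  (separate threshold sets for short metagenomic reads and for predicted
  MAG proteins);
* RPKM normalisation against mean reference protein length;
* "average gene copy per organism" — family RPKM divided by the mean RPKM
  of universal single-copy ribosomal protein families, interpretable as
  the fraction of cells carrying the gene;
* MAG signature-gene counts corrected for genome completeness and
  summarised per habitat class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

#: BLAST/DIAMOND outfmt-6 columns plus the two appended coverage columns.
HIT_COLUMNS = [
    "query_id", "family", "pct_identity", "alignment_length_aa",
    "mismatches", "gap_openings", "q_start", "q_end", "s_start", "s_end",
    "evalue", "bitscore", "query_cov_pct", "subject_cov_pct",
]

DEFAULT_IDENTITY_PCT = 50.0
DEFAULT_QUERY_COV_PCT = 80.0

# Read-mode identity overrides (short-read search against marker proteins).
READ_IDENTITY_OVERRIDES = {
    "rho": 40.0,
    "nuoF": 60.0, "group4_NiFe": 60.0, "mmoX": 60.0, "FeFe": 60.0,
    "coxL": 60.0, "amoA": 60.0, "nxrA": 60.0, "rbcL": 60.0,
    "psaA": 80.0,
    "psbA": 70.0, "isoA": 70.0, "atpA": 70.0, "aro": 70.0, "ygfK": 70.0,
    "hbsT": 75.0,
}

# MAG-mode (predicted protein) identity overrides on top of the read-mode
# set.
MAG_IDENTITY_OVERRIDES = {
    "atpA": 60.0, "psbA": 60.0, "rdhA": 45.0, "cyc2": 35.0, "rho": 30.0,
}

#: Universal single-copy ribosomal protein families used as the
#: per-organism normaliser (the databases carry 15 such families).
RIBOSOMAL_FAMILIES = [f"rplP_S3_{i}" for i in range(1, 16)]


def default_manifest(extra_families: dict[str, float] | None = None
                     ) -> pd.DataFrame:
    """Build the marker manifest: per-family thresholds, mean reference
    protein length (aa) and flags.

    ``extra_families`` maps additional family names to mean reference
    lengths; they take the default thresholds.
    """
    families: dict[str, dict] = {}
    named = set(READ_IDENTITY_OVERRIDES) | set(MAG_IDENTITY_OVERRIDES) | {
        "hhyL", "sqr", "dsrA", "soxB", "narG", "nifH", "pmoA", "cooS",
    }
    for fam in sorted(named):
        families[fam] = {"mean_ref_length_aa": 500.0,
                         "is_single_copy_ribosomal": False}
    for fam in RIBOSOMAL_FAMILIES:
        families[fam] = {"mean_ref_length_aa": 200.0,
                         "is_single_copy_ribosomal": True}
    for fam, length in (extra_families or {}).items():
        families.setdefault(fam, {"is_single_copy_ribosomal": False})[
            "mean_ref_length_aa"] = float(length)
    rows = []
    for fam, info in families.items():
        rows.append({
            "family": fam,
            "min_identity_pct": READ_IDENTITY_OVERRIDES.get(
                fam, DEFAULT_IDENTITY_PCT),
            "min_identity_pct_protein": MAG_IDENTITY_OVERRIDES.get(
                fam, READ_IDENTITY_OVERRIDES.get(fam, DEFAULT_IDENTITY_PCT)),
            "min_query_cov_pct": DEFAULT_QUERY_COV_PCT,
            "mean_ref_length_aa": info["mean_ref_length_aa"],
            "is_single_copy_ribosomal": info["is_single_copy_ribosomal"],
        })
    return pd.DataFrame(rows).set_index("family")


def read_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="family")


def read_hit_table(path: str | Path) -> pd.DataFrame:
    """Read a 14-column tabular hit file (outfmt 6 + qcov/scov)."""
    return pd.read_csv(path, sep="\t", header=None, names=HIT_COLUMNS)


def _check_families(hits: pd.DataFrame, manifest: pd.DataFrame) -> None:
    unknown = sorted(set(hits["family"]) - set(manifest.index))
    if unknown:
        raise KeyError(f"families absent from manifest: {unknown}")


def best_hit_per_query(hits: pd.DataFrame) -> pd.DataFrame:
    """Resolve multiple hits per query to the highest-bitscore one.

    Ties break deterministically to the first row after a stable sort by
    family then query id.
    """
    ordered = hits.sort_values(["family", "query_id"], kind="stable")
    idx = ordered.groupby("query_id")["bitscore"].idxmax()
    return hits.loc[sorted(idx)].reset_index(drop=True)


def filter_read_hits(hits: pd.DataFrame, manifest: pd.DataFrame
                     ) -> pd.DataFrame:
    """Short-read mode: query coverage >= 80% and family identity
    threshold (default 50%, per-family overrides). Best hit per read is
    resolved by bitscore first."""
    _check_families(hits, manifest)
    hits = best_hit_per_query(hits)
    thr = manifest["min_identity_pct"].reindex(hits["family"]).to_numpy()
    qcov = manifest["min_query_cov_pct"].reindex(hits["family"]).to_numpy()
    keep = ((hits["query_cov_pct"].to_numpy() >= qcov)
            & (hits["pct_identity"].to_numpy() >= thr))
    return hits[keep].reset_index(drop=True)


def filter_mag_hits(hits: pd.DataFrame, manifest: pd.DataFrame
                    ) -> pd.DataFrame:
    """MAG-protein mode: (alignment >= 40 aa OR query cov >= 80% OR
    subject cov >= 80%) AND family identity threshold (MAG-mode
    overrides)."""
    _check_families(hits, manifest)
    hits = best_hit_per_query(hits)
    thr = manifest["min_identity_pct_protein"].reindex(
        hits["family"]).to_numpy()
    length_ok = hits["alignment_length_aa"].to_numpy() >= 40
    cov_ok = ((hits["query_cov_pct"].to_numpy() >= 80.0)
              | (hits["subject_cov_pct"].to_numpy() >= 80.0))
    keep = (length_ok | cov_ok) & (hits["pct_identity"].to_numpy() >= thr)
    return hits[keep].reset_index(drop=True)


def rpkm(filtered_count: int, mean_ref_length_aa: float,
         total_reads: int) -> float:
    """Reads per kilobase (of reference, protein length x 3 nt) per
    million sequenced reads."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if mean_ref_length_aa <= 0:
        raise ValueError("zero-length reference family")
    kb = mean_ref_length_aa * 3.0 / 1000.0
    return filtered_count / (kb * (total_reads / 1e6))


def gene_profile(filtered_hits: pd.DataFrame, manifest: pd.DataFrame,
                 total_reads: int) -> pd.DataFrame:
    """Per-family filtered hit counts and RPKM (no ribosomal
    normalisation yet); families with no hits get zero rows."""
    counts = filtered_hits["family"].value_counts()
    rows = []
    for fam, info in manifest.iterrows():
        c = int(counts.get(fam, 0))
        rows.append({"family": fam, "filtered_hit_count": c,
                     "rpkm": rpkm(c, info["mean_ref_length_aa"], total_reads),
                     "is_single_copy_ribosomal":
                         bool(info["is_single_copy_ribosomal"])})
    return pd.DataFrame(rows).set_index("family")


def copies_per_organism(profile: pd.DataFrame) -> pd.DataFrame:
    """Average gene copy per organism: family RPKM over the mean RPKM of
    the single-copy ribosomal families.

    ``percent_of_cells`` is 100 x copies, uncapped; values above 100
    indicate multi-copy genes and set the ``multicopy_flag``.
    """
    ribo = profile[profile["is_single_copy_ribosomal"]]
    if ribo.empty or not (ribo["rpkm"] > 0).any():
        raise ValueError("no ribosomal family with positive RPKM; cannot "
                         "normalise per organism")
    denom = float(ribo["rpkm"].mean())
    out = profile.copy()
    out["ribosomal_mean_rpkm"] = denom
    out["copies_per_organism"] = out["rpkm"] / denom
    out["percent_of_cells"] = 100.0 * out["copies_per_organism"]
    out["multicopy_flag"] = out["percent_of_cells"] > 100.0
    return out


@dataclass
class MagAnnotation:
    """Signature-gene content of one metagenome-assembled genome."""

    mag_id: str
    completeness_pct: float
    contamination_pct: float
    families_present: frozenset[str]

    def __post_init__(self) -> None:
        if not 0 < self.completeness_pct <= 100:
            raise ValueError("completeness must be in (0, 100]")

    @property
    def signature_gene_count_raw(self) -> int:
        return len(self.families_present)

    @property
    def signature_gene_count_corrected(self) -> float:
        """Raw count divided by completeness fraction — an estimate of
        content in the complete genome."""
        return self.signature_gene_count_raw / (self.completeness_pct / 100.0)


def mag_signature_summary(annotations: list[MagAnnotation],
                          specialisation: pd.DataFrame,
                          glacier: pd.Series | None = None) -> pd.DataFrame:
    """Mean completeness-corrected signature-gene count per habitat class
    (optionally per glacier).

    ``specialisation`` is a classified table indexed by MAG id with a
    ``habitat_class`` column; unmatched MAG ids raise a warning with the
    count."""
    ann = pd.DataFrame({
        "mag_id": [a.mag_id for a in annotations],
        "corrected": [a.signature_gene_count_corrected for a in annotations],
        "raw": [a.signature_gene_count_raw for a in annotations],
    }).set_index("mag_id")
    unmatched = set(ann.index) ^ set(specialisation.index)
    if unmatched:
        warnings.warn(f"{len(unmatched)} MAG id(s) unmatched between "
                      "annotations and specialisation table", stacklevel=2)
    joined = ann.join(specialisation[["habitat_class"]], how="inner")
    keys = ["habitat_class"]
    if glacier is not None:
        joined = joined.join(glacier.rename("glacier"), how="left")
        keys = ["glacier", "habitat_class"]
    return joined.groupby(keys)[["corrected", "raw"]].mean()
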