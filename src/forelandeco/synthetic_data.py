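"""Synthetic two-glacier chronosequence generator.

Emulates the study design that the analysis stages consume — an Antarctic
foreland with three soil-age classes (three topsoil sites each) and a
Swiss alpine foreland with four age classes (15 topsoils plus 10-cm depth
profiles to 50 cm) — with known ground truth for every planted quantity:

* communities with planted low-CV habitat generalists, high-CV early
  "opportunists" peaking in the youngest soils, and late specialists
  peaking in the oldest;
* per-taxon marker-gene content and homology-hit tables with controllable
  threshold violations;
* first-order trace-gas consumption with heat-killed controls;
* linear/exponential nutrient dynamics; and
* qPCR Cp tables with standard dilution series.

All randomness flows from one integer seed through named sub-streams, so
adding a stage never perturbs the draws of another.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .biogeochem_rates import ChamberSeries, GasTimeSeries, NutrientTimeSeries
from .community_structure import AbundanceMatrix
from .zeta_diversity import IncidenceMatrix

GUILDS = ("generalist", "early_opportunist", "late_specialist")


def stream(seed: int, name: str) -> np.random.Generator:
    """Named random sub-stream derived from one global seed."""
    return np.random.default_rng([seed, zlib.crc32(name.encode())])


# ---------------------------------------------------------------------------
# Study design
# ---------------------------------------------------------------------------

@dataclass
class ChronosequenceDesign:
    """Sampling layout of one glacier foreland."""

    glacier_id: str
    age_classes: list[tuple[str, float, float]]   # (label, min_yr, max_yr)
    n_sites_per_class: list[int]
    depth_intervals: list[tuple[float, float]] = field(
        default_factory=lambda: [(0.0, 10.0)])
    origin_lat: float = 0.0
    origin_lon: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.n_sites_per_class, int):
            self.n_sites_per_class = [self.n_sites_per_class] * len(
                self.age_classes)
        prev_max = -np.inf
        for label, lo, hi in self.age_classes:
            if lo > hi or lo < prev_max:
                raise ValueError("age classes must be ordered and "
                                 "non-overlapping")
            prev_max = hi
        if sum(self.n_sites_per_class) < 2:
            raise ValueError("need >= 2 sites in total")
        prev_bottom = 0.0
        for top, bottom in self.depth_intervals:
            if top >= bottom or top < prev_bottom:
                raise ValueError("depth intervals must be ordered and "
                                 "non-overlapping")
            prev_bottom = bottom

    def site_metadata(self) -> pd.DataFrame:
        """Per-sample metadata: sites laid out along a transect from the
        glacier front (older classes further away), topsoil interval
        first, with age-correlated physicochemistry."""
        rng = stream(self.seed, f"{self.glacier_id}/sites")
        rows = []
        for ci, ((label, lo, hi), n_sites) in enumerate(
                zip(self.age_classes, self.n_sites_per_class)):
            for s in range(n_sites):
                age = float(rng.uniform(lo, max(hi, lo + 1e-9)))
                # ~150 m between classes, ~30 m scatter within
                north_km = 0.15 * (ci + 1) + float(rng.normal(0, 0.03))
                east_km = 0.05 * s + float(rng.normal(0, 0.02))
                for top, bottom in self.depth_intervals:
                    sid = (f"{self.glacier_id}_{label}_s{s + 1}"
                           + ("" if top == 0 else f"_d{int(top)}"))
                    rows.append({
                        "sample": sid,
                        "glacier": self.glacier_id,
                        "age_class": label,
                        "age_class_index": ci,
                        "age_years": age,
                        "depth_top_cm": top,
                        "depth_bottom_cm": bottom,
                        "lat": self.origin_lat + north_km / 111.32,
                        "lon": self.origin_lon + east_km / 111.32,
                        # age-linked physicochemistry with noise
                        "ph": 7.8 - 0.008 * age + float(rng.normal(0, 0.1)),
                        "total_carbon_pct": 0.1 + 0.01 * age
                        + float(rng.normal(0, 0.05)),
                        "sulfur_mg_kg": max(
                            5.0, 60.0 - 0.4 * age + float(rng.normal(0, 4.0))),
                        "ammonium_mg_kg": float(rng.lognormal(0.0, 0.4)),
                    })
        return pd.DataFrame(rows).set_index("sample")


def antarctic_design(seed: int = 0) -> ChronosequenceDesign:
    """Maritime Antarctic foreland: classes <5 / 10 / 21 yr, three topsoil
    sites each."""
    return ChronosequenceDesign(
        glacier_id="antarctic",
        age_classes=[("A", 0, 5), ("B", 8, 12), ("C", 19, 23)],
        n_sites_per_class=[3, 3, 3],
        origin_lat=-62.6996, origin_lon=-60.4156, seed=seed)


def swiss_design(seed: int = 0, with_depth_profile: bool = False
                 ) -> ChronosequenceDesign:
    """Swiss alpine foreland: classes 0-7 / 8-27 / 28-57 / 58-127 yr,
    15 topsoil sites; optionally 10-cm depth intervals to 50 cm."""
    depths = [(0.0, 10.0)]
    if with_depth_profile:
        depths = [(d, d + 10.0) for d in (0.0, 10.0, 20.0, 30.0, 40.0)]
    return ChronosequenceDesign(
        glacier_id="swiss",
        age_classes=[("A", 0, 7), ("B", 8, 27), ("C", 28, 57),
                     ("D", 58, 127)],
        n_sites_per_class=[4, 4, 4, 3],
        depth_intervals=depths,
        origin_lat=46.84299, origin_lon=8.82746, seed=seed)


# ---------------------------------------------------------------------------
# Community generator
# ---------------------------------------------------------------------------

@dataclass
class CommunityTruth:
    """Planted parameters of one taxon."""

    taxon_id: str
    guild: str
    mean_relative_abundance: float
    cv_target: float
    marker_genes: frozenset = frozenset()
    genes_per_genome: int = 4000

    def __post_init__(self) -> None:
        if self.guild not in GUILDS:
            raise ValueError(f"unknown guild: {self.guild!r}")
        if not 0 < self.mean_relative_abundance < 1:
            raise ValueError("mean_relative_abundance must be in (0, 1)")
        if self.cv_target < 0:
            raise ValueError("cv_target must be >= 0")
        self.marker_genes = frozenset(self.marker_genes)


def default_truths(n_generalists: int = 8, n_early: int = 6,
                   n_late: int = 6, cv_generalist: float = 0.3,
                   cv_specialist: float = 2.0) -> list[CommunityTruth]:
    """A planted community: generalists carry more marker families (the
    metabolic-flexibility signal), opportunists/specialists fewer."""
    generalist_pool = ["hhyL", "coxL", "sqr", "rbcL", "soxB", "rho"]
    early_pool = ["sqr", "soxB", "hhyL"]
    late_pool = ["pmoA", "amoA", "nxrA"]
    truths = []
    for i in range(n_generalists):
        truths.append(CommunityTruth(
            f"gen_{i + 1}", "generalist", 0.04, cv_generalist,
            frozenset(generalist_pool[:4 + (i % 3)]), 4400))
    for i in range(n_early):
        truths.append(CommunityTruth(
            f"early_{i + 1}", "early_opportunist", 0.02, cv_specialist,
            frozenset(early_pool[:2 + (i % 2)]), 4100))
    for i in range(n_late):
        truths.append(CommunityTruth(
            f"late_{i + 1}", "late_specialist", 0.02, cv_specialist,
            frozenset(late_pool[:2 + (i % 2)]), 4000))
    return truths


def generate_community(design: ChronosequenceDesign,
                       truths: list[CommunityTruth],
                       total_reads_per_sample: int = 100_000,
                       trend_fold: float = 10.0,
                       require_all_guilds: bool = True
                       ) -> tuple[AbundanceMatrix, dict]:
    """Multinomial count table with planted guild structure.

    Expected relative abundances start from each taxon's planted mean,
    are bent by the guild trend (opportunists peak in the youngest age
    class, late specialists in the oldest, both with a ``trend_fold``
    young:old ratio), multiplied by lognormal noise calibrated to the
    taxon's target CV, renormalised per sample, and sampled multinomially
    at ``total_reads_per_sample`` reads. Returns the matrix and a truth
    registry recording every planted parameter.
    """
    if total_reads_per_sample < 1000:
        raise ValueError("total_reads_per_sample must be >= 1000")
    if require_all_guilds:
        present = {t.guild for t in truths}
        missing = set(GUILDS) - present
        if missing:
            raise ValueError(f"guild(s) missing from truths: {sorted(missing)}")
    base_sum = sum(t.mean_relative_abundance for t in truths)
    if base_sum > 1.0 + 1e-12:
        raise ValueError(
            f"planted mean abundances sum to {base_sum:.3f} > 1")
    meta = design.site_metadata()
    n_classes = len(design.age_classes)
    rng = stream(design.seed, f"{design.glacier_id}/community")
    taxa = [t.taxon_id for t in truths]
    counts = np.zeros((len(taxa), len(meta)), dtype=np.int64)
    for j, (sid, row) in enumerate(meta.iterrows()):
        # position of the sample's age class on a 0..1 young->old axis
        x = (row["age_class_index"] / (n_classes - 1)) if n_classes > 1 else 0.0
        expected = np.empty(len(taxa))
        for i, t in enumerate(truths):
            if t.guild == "early_opportunist":
                trend = trend_fold ** (-x)
            elif t.guild == "late_specialist":
                trend = trend_fold ** (x - 1.0)
            else:
                trend = 1.0
            if t.cv_target > 0:
                sigma = np.sqrt(np.log1p(t.cv_target ** 2))
                noise = rng.lognormal(-0.5 * sigma ** 2, sigma)
            else:
                noise = 1.0
            expected[i] = t.mean_relative_abundance * trend * noise
        expected /= expected.sum()
        counts[:, j] = rng.multinomial(total_reads_per_sample, expected)
    matrix = AbundanceMatrix(
        pd.DataFrame(counts, index=taxa, columns=meta.index), meta)
    registry = {
        "design": {"glacier_id": design.glacier_id,
                   "age_classes": design.age_classes,
                   "n_sites_per_class": design.n_sites_per_class,
                   "seed": design.seed,
                   "total_reads_per_sample": total_reads_per_sample,
                   "trend_fold": trend_fold},
        "taxa": {t.taxon_id: {
            "guild": t.guild,
            "mean_relative_abundance": t.mean_relative_abundance,
            "cv_target": t.cv_target,
            "marker_genes": sorted(t.marker_genes),
            "genes_per_genome": t.genes_per_genome,
        } for t in truths},
    }
    return matrix, registry


def write_registry(registry: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(registry, fh, indent=1, default=list)


def guild_recovery(registry: dict, classified: pd.DataFrame) -> dict:
    """Precision/recall of quartile classification against planted guilds.

    Planted generalists should be classified ``generalist``; planted
    opportunists/specialists count as true ``specialist``. Precision is
    over assigned labels, recall over planted taxa.
    """
    truth = {t: ("generalist" if info["guild"] == "generalist"
                 else "specialist")
             for t, info in registry["taxa"].items()}
    out = {}
    for label in ("generalist", "specialist"):
        assigned = [t for t in classified.index
                    if classified.loc[t, "habitat_class"] == label]
        planted = [t for t, g in truth.items() if g == label]
        tp = sum(1 for t in assigned if truth.get(t) == label)
        out[f"precision_{label}"] = tp / len(assigned) if assigned else np.nan
        out[f"recall_{label}"] = tp / len(planted) if planted else np.nan
    return out


# ---------------------------------------------------------------------------
# Marker-gene hit generator
# ---------------------------------------------------------------------------

def generate_marker_hits(community: AbundanceMatrix, registry: dict,
                         manifest: pd.DataFrame, reads_total: int = 1_000_000,
                         rpkm_scale: float = 500.0,
                         fail_fraction: float = 0.0,
                         seed: int = 0) -> pd.DataFrame:
    """Tabular homology hits whose filtered per-family profile recovers
    the planted gene content.

    Expected hit counts are Poisson with mean
    ``carrier_fraction x reference kb x (reads_total / 1e6) x rpkm_scale``
    so that, after RPKM normalisation against the single-copy ribosomal
    families (carried by every taxon), copies-per-organism estimates the
    community carrier fraction. A ``fail_fraction`` of rows is emitted
    with identity 10 points below the family threshold (and is exactly
    what read-mode filtering must remove).
    """
    taxa_info = registry["taxa"]
    unknown = {f for info in taxa_info.values()
               for f in info["marker_genes"]} - set(manifest.index)
    if unknown:
        raise KeyError(f"marker families absent from manifest: "
                       f"{sorted(unknown)}")
    rel = community.counts.div(community.counts.sum(axis=0), axis=1)
    mean_ab = rel.mean(axis=1)
    mean_ab /= mean_ab.sum()
    carrier = {}
    for fam, info in manifest.iterrows():
        if info["is_single_copy_ribosomal"]:
            carrier[fam] = 1.0
        else:
            carrier[fam] = float(sum(
                mean_ab.get(t, 0.0) for t, ti in taxa_info.items()
                if fam in ti["marker_genes"]))
    rng = stream(seed, "marker_hits")
    rows = []
    qid = 0
    for fam, info in manifest.iterrows():
        kb = info["mean_ref_length_aa"] * 3.0 / 1000.0
        mu = carrier[fam] * kb * (reads_total / 1e6) * rpkm_scale
        n_hits = int(rng.poisson(mu))
        thr = float(info["min_identity_pct"])
        for _ in range(n_hits):
            qid += 1
            fails = rng.random() < fail_fraction
            identity = (thr - 10.0 if fails
                        else min(thr + float(rng.uniform(1.0, 30.0)), 100.0))
            rows.append({
                "query_id": f"read_{qid}", "family": fam,
                "pct_identity": round(identity, 2),
                "alignment_length_aa": int(rng.integers(25, 60)),
                "mismatches": 0, "gap_openings": 0,
                "q_start": 1, "q_end": 33, "s_start": 1, "s_end": 33,
                "evalue": 1e-10, "bitscore": round(float(
                    rng.uniform(60, 200)), 1),
                "query_cov_pct": round(float(rng.uniform(85, 100)), 1),
                "subject_cov_pct": round(float(rng.uniform(5, 20)), 1),
            })
    return pd.DataFrame(rows, columns=[
        "query_id", "family", "pct_identity", "alignment_length_aa",
        "mismatches", "gap_openings", "q_start", "q_end", "s_start",
        "s_end", "evalue", "bitscore", "query_cov_pct", "subject_cov_pct"])


# ---------------------------------------------------------------------------
# Gas, nutrient and qPCR generators
# ---------------------------------------------------------------------------

@dataclass
class KineticsTruth:
    """Planted microcosm kinetics for one gas."""

    gas: str
    k_true_per_h: float
    c_atm_ppmv: float
    k_abiotic_per_h: float = 0.0
    noise_sd_ppmv: float = 0.01

    def __post_init__(self) -> None:
        if self.k_true_per_h < 0 or self.k_abiotic_per_h < 0:
            raise ValueError("rate constants must be >= 0")
        if self.c_atm_ppmv <= 0:
            raise ValueError("c_atm must be positive")
        if self.noise_sd_ppmv < 0:
            raise ValueError("noise_sd must be >= 0")


#: Microcosm defaults mirroring the incubation setup: 120 mL serum vials
#: at the atmospheric mixing ratios of the three gases.
DEFAULT_KINETICS = {
    "H2": KineticsTruth("H2", 0.10, 0.5),
    "CO": KineticsTruth("CO", 0.10, 0.6),
    "CH4": KineticsTruth("CH4", 0.05, 1.8),
}


def generate_gas_timeseries(truth: KineticsTruth,
                            times_h=(0.0, 6.0, 12.0, 18.0, 24.0),
                            replicates: int = 1,
                            include_killed: bool = True,
                            seed: int = 0) -> list[GasTimeSeries]:
    """Headspace series: live vials decay at k_true + k_abiotic,
    heat-killed controls at k_abiotic only; Gaussian noise truncated at
    zero (detector floor)."""
    times = np.asarray(times_h, float)
    if len(times) < 5:
        raise ValueError("need >= 5 sampling points")
    if np.any(times < 0) or np.any(np.diff(times) <= 0):
        raise ValueError("times must be non-negative and strictly increasing")
    rng = stream(seed, f"gas/{truth.gas}")
    out = []
    treatments = [("live", truth.k_true_per_h + truth.k_abiotic_per_h)]
    if include_killed:
        treatments.append(("heat_killed", truth.k_abiotic_per_h))
    for treatment, k in treatments:
        for _ in range(replicates):
            c = truth.c_atm_ppmv * np.exp(-k * times)
            c = np.maximum(c + rng.normal(0, truth.noise_sd_ppmv,
                                          len(times)), 0.0)
            out.append(GasTimeSeries(
                gas=truth.gas, times_h=times, mixing_ratios_ppmv=c,
                treatment=treatment))
    return out


#: Nine-point chamber schedule: four samples at nearly regular intervals
#: within the first ten minutes, then five at increasingly long intervals
#: out to 90 minutes.
CHAMBER_TIMES_MIN = (0.0, 3.0, 6.0, 10.0, 20.0, 35.0, 50.0, 70.0, 90.0)


def generate_chamber_series(gas: str, slope_ppmv_per_min: float,
                            c0_ppmv: float, height_m: float = 0.1,
                            noise_sd_ppmv: float = 0.005,
                            times_min=CHAMBER_TIMES_MIN,
                            seed: int = 0) -> ChamberSeries:
    """Static-chamber concentration series with a linear trend (negative
    slope = uptake) plus Gaussian noise, truncated at zero."""
    rng = stream(seed, f"chamber/{gas}")
    times = np.asarray(times_min, float)
    c = c0_ppmv + slope_ppmv_per_min * times
    c = np.maximum(c + rng.normal(0, noise_sd_ppmv, len(times)), 0.0)
    return ChamberSeries(gas=gas, times_min=times, mixing_ratios_ppmv=c,
                         height_m=height_m)


def generate_nutrient_series(model: str, params: dict,
                             times_d=(0, 2, 4, 7, 10, 14, 18, 22),
                             noise_sd_um: float = 0.0,
                             analyte: str = "ammonium",
                             seed: int = 0
                             ) -> tuple[NutrientTimeSeries, dict]:
    """Slurry concentration trajectory from a linear or exponential model.

    linear: c = c0 + slope * t; exponential: c = c_inf +
    (c0 - c_inf) e^(-lam * t). Returns the series plus the recorded truth
    (including the generating initial rate).
    """
    times = np.asarray(times_d, float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    rng = stream(seed, f"nutrient/{analyte}")
    if model == "linear":
        c = params["c0"] + params["slope"] * times
        rate0 = params["slope"]
    elif model == "exponential":
        c = (params["c_inf"] + (params["c0"] - params["c_inf"])
             * np.exp(-params["lam"] * times))
        rate0 = -params["lam"] * (params["c0"] - params["c_inf"])
    else:
        raise ValueError(f"unknown model: {model!r}")
    if np.any(c < -1e-9):
        raise ValueError("parameters drive concentration negative")
    c = np.maximum(c + rng.normal(0, noise_sd_um, len(times)), 0.0)
    series = NutrientTimeSeries(analyte=analyte, times_d=times,
                                concentrations_um=c)
    return series, {"model": model, "params": dict(params),
                    "initial_rate_um_per_d": rate0}


def generate_qpcr(true_copies: list[float], slope: float = -3.3219,
                  intercept: float = 38.0, noise_sd_cp: float = 0.0,
                  standard_decades=(3, 4, 5, 6, 7, 8),
                  replicates: int = 3, seed: int = 0
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cp tables: a standard dilution series spanning >= 5 decades plus
    unknowns at the given true copy numbers, with
    Cp = intercept + slope * log10(copies) + noise."""
    if slope >= 0:
        raise ValueError("standard-curve slope must be negative")
    copies_arr = np.asarray(true_copies, float)
    if np.any(copies_arr <= 0):
        raise ValueError("copy numbers must be positive")
    rng = stream(seed, "qpcr")
    std_rows = []
    for dec in standard_decades:
        for _ in range(2):
            cp = (intercept + slope * dec
                  + float(rng.normal(0, noise_sd_cp)))
            std_rows.append({"copies": 10.0 ** dec, "cp": cp})
    unk_rows = []
    for i, copies in enumerate(copies_arr):
        for _ in range(replicates):
            cp = (intercept + slope * np.log10(copies)
                  + float(rng.normal(0, noise_sd_cp)))
            unk_rows.append({"sample": f"unk_{i + 1}", "cp": cp,
                             "true_copies": copies})
    return pd.DataFrame(std_rows), pd.DataFrame(unk_rows)


# ---------------------------------------------------------------------------
# Incidence generators for assembly-model contrasts
# ---------------------------------------------------------------------------

def random_incidence(n_taxa: int = 50, n_sites: int = 10, p: float = 0.3,
                     seed: int = 0) -> IncidenceMatrix:
    """Stochastic assembly: every taxon present at every site
    independently with probability p (zeta declines exponentially)."""
    rng = stream(seed, "incidence/random")
    pres = rng.random((n_taxa, n_sites)) < p
    return _as_incidence(pres)


def niche_gradient_incidence(n_taxa: int = 50, n_sites: int = 10,
                             max_width: int | None = None,
                             seed: int = 0) -> IncidenceMatrix:
    """Deterministic niche assembly: each taxon occupies a contiguous
    range of sites along the gradient, with range widths uniform on
    1..max_width (default n_sites).

    At full width the expected zeta of order i is proportional to
    C(n+1, i+1)/C(n, i) ~ 1/(i+1), a power-law decline, in contrast to
    the exponential decline of independent random placement. Narrower
    ranges (max_width ~ n_sites/2) leave higher-order zeta close to zero
    everywhere, so the pairwise distance-decay coefficient is steeper
    than the four-way one."""
    rng = stream(seed, "incidence/niche")
    if max_width is None:
        max_width = n_sites
    pres = np.zeros((n_taxa, n_sites), bool)
    for t in range(n_taxa):
        width = int(rng.integers(1, max_width + 1))
        start = int(rng.integers(0, n_sites - width + 1))
        pres[t, start:start + width] = True
    return _as_incidence(pres)


def _as_incidence(pres: np.ndarray) -> IncidenceMatrix:
    n_taxa, n_sites = pres.shape
    sites = [f"site_{j + 1}" for j in range(n_sites)]
    presence = pd.DataFrame(pres,
                            index=[f"taxon_{i + 1}" for i in range(n_taxa)],
                            columns=sites)
    # sites laid out every ~1.1 km along a line (for distance decay)
    coords = pd.DataFrame({
        "lat": np.zeros(n_sites),
        "lon": np.arange(n_sites) * 0.01,
    }, index=sites)
    return IncidenceMatrix(presence, coords=coords)
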