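"""Multi-site zeta diversity from first principles.

Zeta diversity of order i is the mean number of taxa jointly present
across i sites; order 1 is mean site richness, and the rate at which zeta
declines with order distinguishes stochastic from deterministic community
assembly. Implemented here:

* ``zeta_order`` — exhaustive or Monte-Carlo evaluation of any order, raw
  or Jaccard-normalised (intersection / union per site combination);
* ``zeta_decline`` — orders 1..i_max with power-law and exponential fits
  compared by AIC;
* ``zeta_distance_decay`` — regression of per-combination zeta on mean
  pairwise great-circle distance;
* ``zeta_varpart`` — two-group variation partitioning of pairwise zeta
  using adjusted R² of nested linear models.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import EARTH_RADIUS_KM

EXHAUSTIVE_CAP = 100_000  # max combinations enumerated exhaustively


@dataclass
class IncidenceMatrix:
    """Taxon-by-site presence/absence with optional coordinates and
    per-site environmental vectors."""

    presence: pd.DataFrame                 # taxa x sites, boolean
    coords: pd.DataFrame | None = None     # site -> lat, lon (degrees)
    env: pd.DataFrame | None = None        # site -> named numeric variables

    def __post_init__(self) -> None:
        self.presence = self.presence.astype(bool)
        if self.presence.shape[1] < 2:
            raise ValueError("incidence matrix needs >= 2 sites")
        for tbl, name in ((self.coords, "coords"), (self.env, "env")):
            if tbl is not None:
                missing = set(self.presence.columns) - set(tbl.index)
                if missing:
                    raise ValueError(f"{name} missing sites: {sorted(missing)}")

    @property
    def sites(self) -> pd.Index:
        return self.presence.columns

    @classmethod
    def from_abundance(cls, counts: pd.DataFrame,
                       coords: pd.DataFrame | None = None,
                       env: pd.DataFrame | None = None) -> "IncidenceMatrix":
        """Any abundance value > 0 marks the taxon present at the site."""
        return cls(counts > 0, coords, env)


@dataclass
class ZetaOrderResult:
    order: int
    mean: float
    sd: float
    n_evaluated: int
    mode: str
    normalization: str


@dataclass
class ZetaDecline:
    orders: pd.DataFrame          # per-order raw and normalised zeta
    fits: dict                    # model -> {slope, intercept, aic, r2}
    selected_model: str
    indistinguishable: bool       # |delta AIC| < 2


@dataclass
class ZetaDecayResult:
    order: int
    records: pd.DataFrame         # per-combination zeta and mean distance
    slope_per_km: float
    intercept: float
    r2: float


@dataclass
class VarpartResult:
    fractions: dict               # a, b, c, d after flooring/renormalising
    raw_fractions: dict           # before flooring
    adj_r2_full: float


def _combo_stats(presence: np.ndarray, combos: np.ndarray,
                 normalization: str) -> np.ndarray:
    """Zeta value for each site combination (rows of ``combos``)."""
    inter = presence[:, combos].all(axis=2).sum(axis=0)
    if normalization == "none":
        return inter.astype(float)
    if normalization == "jaccard":
        union = presence[:, combos].any(axis=2).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
        return vals.astype(float)
    raise ValueError(f"unknown normalization: {normalization!r}")


def zeta_order(inc: IncidenceMatrix, i: int, mode: str = "auto",
               n_subsamples: int = 1000, normalization: str = "none",
               seed: int | None = None) -> ZetaOrderResult:
    """Mean (and sd) zeta of order i over site combinations.

    ``mode`` is "exhaustive", "monte_carlo" or "auto" (exhaustive when the
    number of combinations is below a cap). Monte-Carlo draws sample i
    distinct sites uniformly per draw, with replacement across draws.
    """
    n_sites = inc.presence.shape[1]
    if i < 1:
        raise ValueError("zeta order must be >= 1")
    if i > n_sites:
        raise ValueError(f"order {i} exceeds number of sites ({n_sites})")
    n_combos = math.comb(n_sites, i)
    if mode == "auto":
        mode = "exhaustive" if n_combos <= EXHAUSTIVE_CAP else "monte_carlo"
    presence = inc.presence.to_numpy()
    if mode == "exhaustive":
        if n_combos > EXHAUSTIVE_CAP:
            raise ValueError(
                f"{n_combos} combinations exceed the exhaustive cap "
                f"({EXHAUSTIVE_CAP}); use monte_carlo")
        combos = np.array(list(combinations(range(n_sites), i)))
    elif mode == "monte_carlo":
        rng = np.random.default_rng(seed)
        combos = np.array([rng.choice(n_sites, size=i, replace=False)
                           for _ in range(n_subsamples)])
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    vals = _combo_stats(presence, combos, normalization)
    return ZetaOrderResult(order=i, mean=float(vals.mean()),
                           sd=float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                           n_evaluated=len(vals), mode=mode,
                           normalization=normalization)


def _gaussian_aic(resid: np.ndarray, k: int = 3) -> float:
    """AIC from a Gaussian likelihood with ML variance; k counts slope,
    intercept and variance."""
    n = len(resid)
    rss = float(np.sum(resid ** 2))
    sigma2 = max(rss / n, 1e-300)
    loglik = -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)
    return 2 * k - 2 * loglik


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, np.ndarray]:
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    return float(slope), float(intercept), resid


def zeta_decline(inc: IncidenceMatrix, i_max: int = 6, mode: str = "auto",
                 n_subsamples: int = 1000, seed: int | None = None) -> ZetaDecline:
    """Zeta orders 1..i_max with power-law vs exponential decline fits.

    Both models are fitted to the raw mean zeta values by ordinary least
    squares on the log scale (exponential: ln zeta ~ order; power law:
    ln zeta ~ ln order) and compared by AIC; zeta values of zero are
    dropped from fitting with a warning.
    """
    rows = []
    for i in range(1, i_max + 1):
        raw = zeta_order(inc, i, mode, n_subsamples, "none",
                         None if seed is None else seed + i)
        norm = zeta_order(inc, i, mode, n_subsamples, "jaccard",
                          None if seed is None else seed + i)
        rows.append({"order": i, "zeta_raw": raw.mean, "zeta_raw_sd": raw.sd,
                     "zeta_jaccard": norm.mean, "zeta_jaccard_sd": norm.sd,
                     "n_evaluated": raw.n_evaluated, "mode": raw.mode})
    orders = pd.DataFrame(rows)
    zvals = orders["zeta_raw"].to_numpy()
    keep = zvals > 0
    if keep.sum() < len(zvals):
        warnings.warn(f"{int((~keep).sum())} zero zeta value(s) dropped "
                      "from decline fitting", stacklevel=2)
    if keep.sum() < 3:
        raise ValueError("need >= 3 positive zeta values to fit decline")
    i_arr = orders["order"].to_numpy(float)[keep]
    lnz = np.log(zvals[keep])
    fits = {}
    for model, x in (("exponential", i_arr), ("power", np.log(i_arr))):
        slope, intercept, resid = _ols(x, lnz)
        ss_tot = float(np.sum((lnz - lnz.mean()) ** 2))
        fits[model] = {"slope": slope, "intercept": intercept,
                       "aic": _gaussian_aic(resid),
                       "r2": 1.0 - float(np.sum(resid ** 2)) / ss_tot
                       if ss_tot > 0 else float("nan")}
    selected = min(fits, key=lambda m: fits[m]["aic"])
    delta = abs(fits["power"]["aic"] - fits["exponential"]["aic"])
    return ZetaDecline(orders=orders, fits=fits, selected_model=selected,
                       indistinguishable=delta < 2.0)


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km on the WGS84 mean sphere."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    a = (np.sin((lat2 - lat1) / 2) ** 2
         + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2)
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def _site_distances(inc: IncidenceMatrix, planar: bool) -> np.ndarray:
    if inc.coords is None:
        raise ValueError("site coordinates required for distance decay")
    coords = inc.coords.loc[inc.sites, ["lat", "lon"]].to_numpy(float)
    n = len(coords)
    d = np.zeros((n, n))
    for a in range(n):
        if planar:
            d[a] = np.hypot(coords[:, 0] - coords[a, 0],
                            coords[:, 1] - coords[a, 1])
        else:
            d[a] = haversine_km(coords[a, 0], coords[a, 1],
                                coords[:, 0], coords[:, 1])
    return d


def zeta_distance_decay(inc: IncidenceMatrix, i: int = 2,
                        n_subsamples: int = 1000, seed: int | None = None,
                        planar: bool = False) -> ZetaDecayResult:
    """Regress Jaccard-normalised zeta of order i on mean pairwise distance.

    For each sampled combination of i sites, records the normalised zeta
    and the mean pairwise distance between the sites, then fits an
    ordinary-least-squares line; the slope (per km) is the distance-decay
    coefficient.
    """
    if i < 2:
        raise ValueError("distance decay requires order >= 2")
    n_sites = inc.presence.shape[1]
    dist = _site_distances(inc, planar)
    n_combos = math.comb(n_sites, i)
    if n_combos <= n_subsamples:
        combos = np.array(list(combinations(range(n_sites), i)))
    else:
        rng = np.random.default_rng(seed)
        combos = np.array([rng.choice(n_sites, size=i, replace=False)
                           for _ in range(n_subsamples)])
    zvals = _combo_stats(inc.presence.to_numpy(), combos, "jaccard")
    pair_idx = list(combinations(range(i), 2))
    dists = np.array([np.mean([dist[c[a], c[b]] for a, b in pair_idx])
                      for c in combos])
    if np.allclose(dists.var(), 0.0):
        raise ValueError("all sites co-located: zero distance variance")
    slope, intercept, resid = _ols(dists, zvals)
    ss_tot = float(np.sum((zvals - zvals.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else float("nan")
    records = pd.DataFrame({"zeta": zvals, "mean_distance_km": dists})
    return ZetaDecayResult(order=i, records=records, slope_per_km=slope,
                           intercept=intercept, r2=r2)


def _adj_r2(X: np.ndarray, y: np.ndarray) -> float:
    """Adjusted R² with the effective number of predictors taken from the
    design-matrix rank, so shared variance between predictor groups does
    not inflate the parameter count."""
    n = X.shape[0]
    design = np.column_stack([np.ones(n), X])
    p = int(np.linalg.matrix_rank(design)) - 1
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 0.0
    r2 = 1.0 - ss_res / ss_tot
    if n - p - 1 <= 0:
        raise ValueError("too few site pairs for the number of predictors")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def zeta_varpart(inc: IncidenceMatrix, group1: list[str],
                 group2: list[str]) -> VarpartResult:
    """Partition pairwise (order 2) zeta variation between two predictor
    groups.

    The response is Jaccard-normalised zeta over all site pairs; each
    predictor is the absolute between-site difference of an environmental
    variable. Fractions: a = pure group 1, c = pure group 2, b = shared,
    d = unexplained, from adjusted R² of the two marginal models and the
    full model. Negative fractions are floored at zero and the set
    renormalised; raw values are retained.
    """
    if inc.env is None:
        raise ValueError("site environment table required")
    if not group1 or not group2 or set(group1) & set(group2):
        raise ValueError("predictor groups must be non-empty and disjoint")
    env = inc.env.loc[inc.sites]
    n_sites = len(inc.sites)
    pairs = list(combinations(range(n_sites), 2))
    if len(pairs) < 6:
        raise ValueError("need >= 6 site pairs")
    combos = np.array(pairs)
    y = _combo_stats(inc.presence.to_numpy(), combos, "jaccard")

    def diffs(variables: list[str]) -> np.ndarray:
        v = env[variables].to_numpy(float)
        return np.abs(v[combos[:, 0]] - v[combos[:, 1]])

    X1, X2 = diffs(list(group1)), diffs(list(group2))
    X_full = np.column_stack([X1, X2])
    for name, X in (("group1", X1), ("group2", X2)):
        if np.linalg.matrix_rank(np.column_stack([np.ones(len(y)), X])) \
                < X.shape[1] + 1:
            raise ValueError(
                f"{name} predictors are internally collinear; rerun "
                "collinearity_filter on that group and refit")
    adj1, adj2 = _adj_r2(X1, y), _adj_r2(X2, y)
    adj_full = _adj_r2(X_full, y)
    raw = {"a": adj_full - adj2, "b": adj1 + adj2 - adj_full,
           "c": adj_full - adj1, "d": 1.0 - adj_full}
    floored = {k: max(v, 0.0) for k, v in raw.items()}
    total = sum(floored.values())
    fractions = {k: v / total for k, v in floored.items()} if total > 0 \
        else dict(floored)
    return VarpartResult(fractions=fractions, raw_fractions=raw,
                         adj_r2_full=adj_full)
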