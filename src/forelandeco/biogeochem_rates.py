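"""Rate estimation for microcosm, chamber, slurry and qPCR measurements.

Covers four measurement types:

* trace-gas microcosms — first-order decay of headspace mixing ratio,
  log-linear and asymptotic exponential fits compared by AIC, heat-killed
  control subtraction at the rate-constant level, and conversion to an
  oxidation rate at atmospheric concentration (nmol per g dry weight per
  hour);
* static-chamber fluxes — initial slope of a 90-minute concentration
  series (linear vs saturating exponential by AIC) converted to
  nmol m^-2 s^-1, negative meaning uptake;
* slurry nutrient transformations — linear vs exponential fits by AIC,
  rate signed so accumulation is positive and uptake negative;
* qPCR — standard-curve quantification to gene copies per g dry soil.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .constants import (ATM_PA, R_J_PER_MOL_K, moles_in_headspace,
                        molar_density_air)


def _aic_from_residuals(resid: np.ndarray, k: int,
                        small_sample: bool = False) -> float:
    n = len(resid)
    rss = float(np.sum(resid ** 2))
    sigma2 = max(rss / n, 1e-300)
    loglik = -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)
    aic = 2 * k - 2 * loglik
    if small_sample and n - k - 1 > 0:
        aic += 2 * k * (k + 1) / (n - k - 1)
    return aic


@dataclass
class GasTimeSeries:
    """Headspace mixing-ratio trajectory of one microcosm."""

    gas: str
    times_h: np.ndarray
    mixing_ratios_ppmv: np.ndarray
    headspace_volume_l: float = 0.12
    soil_wet_g: float = 10.0
    moisture_fraction: float | None = None
    temperature_k: float = 298.15
    pressure_atm: float = 1.0
    treatment: str = "live"

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, float)
        self.mixing_ratios_ppmv = np.asarray(self.mixing_ratios_ppmv, float)
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.times_h < 0):
            raise ValueError("negative times")
        if np.any(self.mixing_ratios_ppmv < 0):
            raise ValueError("negative mixing ratios")

    @property
    def soil_dry_g(self) -> float:
        if self.moisture_fraction is None:
            warnings.warn("no gravimetric moisture supplied; using wet mass "
                          "as dry mass", stacklevel=2)
            return self.soil_wet_g
        return self.soil_wet_g * (1.0 - self.moisture_fraction)


@dataclass
class RateResult:
    gas: str
    k_per_h: float
    k_se: float
    c_inf_ppmv: float
    model: str
    aic: float
    r2: float
    rate_atm_nmol_per_gdw_h: float | None = None
    net_of_control: bool = False
    floored_at_zero: bool = False


def _fit_log_linear(t: np.ndarray, c: np.ndarray):
    """c(t) = c0 exp(-k t) via OLS of ln c on t. Returns k, se, resid on
    the concentration scale."""
    if np.any(c <= 0):
        raise ValueError("log-linear fit requires positive mixing ratios")
    y = np.log(c)
    A = np.column_stack([np.ones_like(t), -t])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    ln_c0, k = coef
    pred = np.exp(ln_c0 - k * t)
    resid = c - pred
    # standard error of the slope from the log-scale regression
    dof = len(t) - 2
    if dof > 0:
        s2 = float(np.sum((y - (ln_c0 - k * t)) ** 2)) / dof
        sxx = float(np.sum((t - t.mean()) ** 2))
        se = math.sqrt(s2 / sxx) if sxx > 0 else float("nan")
    else:
        se = float("nan")
    return float(k), se, resid


def _fit_asymptote(t: np.ndarray, c: np.ndarray):
    """c(t) = c_inf + (c0 - c_inf) exp(-k t), c_inf >= 0 (nonlinear LS)."""

    def model(tt, c0, c_inf, k):
        return c_inf + (c0 - c_inf) * np.exp(-k * tt)

    p0 = [max(c[0], 1e-9), max(min(c) * 0.5, 0.0), 0.1]
    popt, pcov = curve_fit(model, t, c, p0=p0,
                           bounds=([0, 0, 0], [np.inf, np.inf, np.inf]),
                           maxfev=10000)
    resid = c - model(t, *popt)
    k_se = float(np.sqrt(pcov[2, 2])) if np.isfinite(pcov[2, 2]) else float("nan")
    return popt, k_se, resid


def fit_first_order(series: GasTimeSeries,
                    control: GasTimeSeries | None = None,
                    c_atm_ppmv: float | None = None,
                    small_sample_aic: bool = False) -> RateResult:
    """First-order rate constant of headspace gas consumption.

    Fits both the pure-exponential model (log-linear OLS) and the
    asymptotic exponential (nonlinear least squares, floor c_inf >= 0) and
    keeps the AIC-preferred one. If a heat-killed ``control`` series is
    given, its rate constant is subtracted (net rate floored at zero,
    flagged). When ``c_atm_ppmv`` is given, the rate at atmospheric
    concentration is reported as k_net x headspace moles at c_atm per g
    dry soil, in nmol g^-1 h^-1.
    """
    t, c = series.times_h, series.mixing_ratios_ppmv
    if len(t) < 4:
        raise ValueError("need >= 4 time points")
    candidates = {}
    if np.all(c > 0):
        k, se, resid = _fit_log_linear(t, c)
        candidates["first_order"] = (k, se, 0.0,
                                     _aic_from_residuals(resid, 3,
                                                         small_sample_aic))
    try:
        (c0, c_inf, k_a), se_a, resid_a = _fit_asymptote(t, c)
        candidates["first_order_asymptote"] = (
            k_a, se_a, c_inf, _aic_from_residuals(resid_a, 4,
                                                  small_sample_aic))
    except RuntimeError:
        warnings.warn("asymptotic fit did not converge; falling back to "
                      "log-linear", stacklevel=2)
    if not candidates:
        raise ValueError("no model could be fitted (zeros in series and "
                         "asymptote fit failed)")
    model = min(candidates, key=lambda m: candidates[m][3])
    k, se, c_inf, aic = candidates[model]
    # r2 on the concentration scale for the chosen model
    if model == "first_order":
        _, _, resid = _fit_log_linear(t, c)
    else:
        _, _, resid = _fit_asymptote(t, c)
    ss_tot = float(np.sum((c - c.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else float("nan")

    net = False
    floored = False
    if control is not None:
        ctrl = fit_first_order(control, c_atm_ppmv=None,
                               small_sample_aic=small_sample_aic)
        k_net = k - ctrl.k_per_h
        net = True
        if k_net < 0:
            k_net = 0.0
            floored = True
    else:
        k_net = k

    rate_atm = None
    if c_atm_ppmv is not None:
        n_atm_mol = moles_in_headspace(c_atm_ppmv, series.headspace_volume_l,
                                       series.temperature_k,
                                       series.pressure_atm)
        rate_atm = k_net * n_atm_mol * 1e9 / series.soil_dry_g  # nmol/gdw/h
    return RateResult(gas=series.gas, k_per_h=k_net, k_se=se,
                      c_inf_ppmv=c_inf, model=model, aic=aic, r2=r2,
                      rate_atm_nmol_per_gdw_h=rate_atm,
                      net_of_control=net, floored_at_zero=floored)


@dataclass
class ChamberSeries:
    """Static-chamber concentration series (typically nine points over
    90 minutes)."""

    gas: str
    times_min: np.ndarray
    mixing_ratios_ppmv: np.ndarray
    height_m: float                      # chamber volume / footprint area
    temperature_k: float = 298.15
    pressure_atm: float = 1.0

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, float)
        self.mixing_ratios_ppmv = np.asarray(self.mixing_ratios_ppmv, float)
        if len(self.times_min) < 5:
            raise ValueError("chamber series needs >= 5 points")
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.height_m <= 0:
            raise ValueError("chamber height must be positive")


@dataclass
class FluxResult:
    gas: str
    flux_nmol_m2_s: float
    initial_slope_ppmv_per_min: float
    model: str
    aic: float


def fit_chamber_flux(series: ChamberSeries,
                     small_sample_aic: bool = False) -> FluxResult:
    """Soil-atmosphere flux from the initial slope of a chamber series.

    Fits a linear model and a saturating exponential
    c = c_inf + (c0 - c_inf) e^(-lambda t); the AIC-preferred model's
    slope at t=0 is converted to a flux with the ideal-gas molar density
    of air and the chamber's effective height. Negative flux = uptake.
    """
    t, c = series.times_min, series.mixing_ratios_ppmv
    slope_lin, intercept = np.polyfit(t, c, 1)
    resid_lin = c - (slope_lin * t + intercept)
    candidates = {"linear": (float(slope_lin),
                             _aic_from_residuals(resid_lin, 3,
                                                 small_sample_aic))}

    def sat(tt, c0, c_inf, lam):
        return c_inf + (c0 - c_inf) * np.exp(-lam * tt)

    try:
        popt, _ = curve_fit(sat, t, c,
                            p0=[c[0], c[-1], 0.05],
                            bounds=([0, 0, 1e-9],
                                    [np.inf, np.inf, np.inf]),
                            maxfev=10000)
        c0, c_inf, lam = popt
        resid_exp = c - sat(t, *popt)
        slope0 = float(-lam * (c0 - c_inf))  # d c / d t at t = 0
        candidates["saturating_exponential"] = (
            slope0, _aic_from_residuals(resid_exp, 4, small_sample_aic))
    except RuntimeError:
        pass
    model = min(candidates, key=lambda m: candidates[m][1])
    slope_ppmv_min, aic = candidates[model]
    mol_m3 = molar_density_air(series.temperature_k, series.pressure_atm)
    flux = slope_ppmv_min / 60.0 * 1e-6 * mol_m3 * series.height_m * 1e9
    return FluxResult(gas=series.gas, flux_nmol_m2_s=flux,
                      initial_slope_ppmv_per_min=slope_ppmv_min,
                      model=model, aic=aic)


@dataclass
class NutrientTimeSeries:
    analyte: str
    times_d: np.ndarray
    concentrations_um: np.ndarray
    treatment: str = "live"

    def __post_init__(self) -> None:
        self.times_d = np.asarray(self.times_d, float)
        self.concentrations_um = np.asarray(self.concentrations_um, float)
        if np.any(np.diff(self.times_d) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.concentrations_um < 0):
            raise ValueError("negative concentrations")


@dataclass
class NutrientRateResult:
    analyte: str
    model: str
    rate_um_per_d: float     # signed: accumulation +, uptake -
    aic_linear: float
    aic_exponential: float
    indistinguishable: bool


def fit_nutrient_rate(series: NutrientTimeSeries,
                      small_sample_aic: bool = False) -> NutrientRateResult:
    """Nutrient transformation rate with AIC model choice.

    Fits linear c = a + b t and exponential c = c_inf + (c0 - c_inf)
    e^(-lambda t); reports the initial slope of the preferred model,
    signed (accumulation positive, uptake negative).
    """
    t, c = series.times_d, series.concentrations_um
    if len(t) < 4:
        raise ValueError("need >= 4 time points")
    if np.allclose(t.var(), 0):
        raise ValueError("singular fit: no time variation")
    slope, intercept = np.polyfit(t, c, 1)
    resid_lin = c - (slope * t + intercept)
    aic_lin = _aic_from_residuals(resid_lin, 3, small_sample_aic)

    def expo(tt, c0, c_inf, lam):
        return c_inf + (c0 - c_inf) * np.exp(-lam * tt)

    aic_exp = float("inf")
    slope0_exp = None
    try:
        popt, _ = curve_fit(expo, t, c, p0=[c[0], c[-1], 0.2],
                            bounds=([0, 0, 1e-9], [np.inf, np.inf, np.inf]),
                            maxfev=10000)
        c0, c_inf, lam = popt
        resid_exp = c - expo(t, *popt)
        aic_exp = _aic_from_residuals(resid_exp, 4, small_sample_aic)
        slope0_exp = float(-lam * (c0 - c_inf))
    except RuntimeError:
        pass
    if aic_lin <= aic_exp:
        model, rate = "linear", float(slope)
    else:
        model, rate = "exponential", slope0_exp
    return NutrientRateResult(analyte=series.analyte, model=model,
                              rate_um_per_d=rate, aic_linear=aic_lin,
                              aic_exponential=aic_exp,
                              indistinguishable=abs(aic_lin - aic_exp) < 2.0)


@dataclass
class QpcrStandardCurve:
    slope: float          # Cp per log10(copies)
    intercept: float
    r2: float

    @property
    def efficiency_pct(self) -> float:
        return (10.0 ** (-1.0 / self.slope) - 1.0) * 100.0

    def copies_from_cp(self, cp: float | np.ndarray) -> float | np.ndarray:
        return 10.0 ** ((cp - self.intercept) / self.slope)


def fit_qpcr_standards(standards: pd.DataFrame) -> QpcrStandardCurve:
    """OLS of mean Cp on log10(copies) over a serial dilution.

    ``standards`` needs columns ``copies`` and ``cp``; replicate wells at
    the same copy number are averaged first. Requires >= 4 dilutions
    spanning >= 3 decades and a negative slope.
    """
    if (standards["copies"] <= 0).any():
        raise ValueError("standard copy numbers must be positive")
    mean_cp = standards.groupby("copies")["cp"].mean()
    if len(mean_cp) < 4:
        raise ValueError("need >= 4 standard dilutions")
    logc = np.log10(mean_cp.index.to_numpy(float))
    if logc.max() - logc.min() < 3:
        raise ValueError("standards must span >= 3 decades")
    slope, intercept = np.polyfit(logc, mean_cp.to_numpy(), 1)
    if slope >= 0:
        raise ValueError("invalid standard curve: slope >= 0")
    resid = mean_cp.to_numpy() - (slope * logc + intercept)
    ss_tot = float(np.sum((mean_cp - mean_cp.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else float("nan")
    return QpcrStandardCurve(float(slope), float(intercept), r2)


def quantify_qpcr(standards: pd.DataFrame, unknowns: pd.DataFrame,
                  soil_dry_g: float = 1.0,
                  scale_factor: float = 1.0
                  ) -> tuple[pd.DataFrame, QpcrStandardCurve]:
    """Absolute quantification of unknown samples against a standard curve.

    ``unknowns`` needs columns ``sample`` and ``cp`` (replicates averaged).
    ``scale_factor`` collects elution/dilution factors from reaction to
    extract. Returns copies per g dry soil, with an extrapolation flag for
    Cp values outside the standard range.
    """
    curve = fit_qpcr_standards(standards)
    mean_cp = unknowns.groupby("sample")["cp"].mean()
    copies_rxn = curve.copies_from_cp(mean_cp.to_numpy())
    cp_lo, cp_hi = (standards.groupby("copies")["cp"].mean().min(),
                    standards.groupby("copies")["cp"].mean().max())
    out = pd.DataFrame({
        "sample": mean_cp.index,
        "cp": mean_cp.to_numpy(),
        "copies_per_reaction": copies_rxn,
        "copies_per_gdw": copies_rxn * scale_factor / soil_dry_g,
        "extrapolated": (mean_cp.to_numpy() < cp_lo)
                        | (mean_cp.to_numpy() > cp_hi),
    }).set_index("sample")
    return out, curve
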