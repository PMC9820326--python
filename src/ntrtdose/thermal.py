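"""Linear-quadratic survival with hyperthermic radiosensitization (TER).

Cell survival follows the LQ model with temperature/time-dependent
coefficients,

    -ln S = alpha(T, t) * D + beta(T, t) * D^2 ,

and the thermal enhancement ratio is parameterized as

    TER(T, t) = TER0 + c1 * t * exp(c2 * (T - T_c)) ,

an offset (the unheated reference, TER0 ~ 1) plus a term linear in the
hyperthermia application time t (minutes) and exponential in temperature T
(degrees Celsius) relative to a critical/melting temperature T_c. c1 and c2
are fitted per cell line from survival or TER data.

TER is an iso-effect dose ratio. Because hyperthermia *sensitizes*, the dose
needed for a given survival level is smaller when heated; the enhancement
convention used here is

    TER = D(iso-effect, unheated) / D(iso-effect, heated)  >= 1 ,

with the reciprocal available for the raw heated/reference ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "LQParameters",
    "TERModel",
    "SurvivalDataset",
    "FitResult",
    "lq_survival",
    "ter_evaluate",
    "iso_effect_dose",
    "iso_effect_ter",
    "fit_ter_model",
]

T_REF_CELSIUS = 37.0


@dataclass(frozen=True)
class LQParameters:
    alpha: float  # Gy^-1
    beta: float  # Gy^-2
    temperature: float = T_REF_CELSIUS  # degC
    time: float = 0.0  # min

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")


@dataclass(frozen=True)
class TERModel:
    ter0: float = 1.0  # offset, reference (T_ref, t=0) value
    c1: float = 0.0  # min^-1
    c2: float = 0.0  # degC^-1
    t_c: float = 45.0  # degC, critical (melting) temperature
    t_ref: float = T_REF_CELSIUS

    def __post_init__(self) -> None:
        if self.ter0 < 1.0 - 1e-6:
            raise ValueError("TER0 below 1")
        if self.c1 < 0 or self.c2 <= 0:
            raise ValueError("require c1 >= 0 and c2 > 0")

    def __call__(self, temperature, time):
        return ter_evaluate(self, temperature, time)


@dataclass
class SurvivalDataset:
    """Records of (cell_type, T degC, t min, survival or TER, 1 s.d.)."""

    table: pd.DataFrame  # columns: cell_type, T_C, t_min, value, sigma
    value_kind: str = "ter"  # "ter" | "survival"

    REQUIRED = ("cell_type", "T_C", "t_min", "value", "sigma")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.table.columns)
        if missing:
            raise ValueError(f"dataset missing columns {sorted(missing)}")
        v = self.table["value"].to_numpy(float)
        if self.value_kind == "survival" and (np.any(v <= 0) or np.any(v > 1)):
            raise ValueError("survival fractions must lie in (0, 1]")
        if self.value_kind == "ter" and np.any(v <= 0):
            raise ValueError("TER values must be positive")

    def for_cell(self, cell_type: str) -> pd.DataFrame:
        sub = self.table[self.table["cell_type"] == cell_type]
        if sub.empty:
            raise KeyError(f"no records for cell type {cell_type!r}")
        return sub


@dataclass
class FitResult:
    model: TERModel
    r_squared: float
    residuals: np.ndarray
    covariance: np.ndarray
    converged: bool = True
    message: str = ""


def lq_survival(params: LQParameters, dose_gy) -> np.ndarray | float:
    """S = exp(-alpha D - beta D^2)."""
    d = np.asarray(dose_gy, dtype=float)
    if np.any(d < 0):
        raise ValueError("dose must be non-negative")
    s = np.exp(-params.alpha * d - params.beta * d**2)
    return float(s) if s.shape == () else s


def ter_evaluate(model: TERModel, temperature, time) -> np.ndarray | float:
    """TER = TER0 + c1 t exp(c2 (T - T_c)); t = 0 returns the offset."""
    t = np.asarray(time, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    temp = np.asarray(temperature, dtype=float)
    out = model.ter0 + model.c1 * t * np.exp(model.c2 * (temp - model.t_c))
    return float(out) if out.shape == () else out


def iso_effect_dose(params: LQParameters, survival_level: float) -> float:
    """Positive dose D solving alpha D + beta D^2 = -ln(S*)."""
    if not 0 < survival_level < 1:
        raise ValueError("survival level must lie in (0, 1)")
    effect = -np.log(survival_level)
    a, b = params.alpha, params.beta
    if b == 0:
        if a == 0:
            raise ValueError("alpha = beta = 0 never reaches the iso-effect")
        return effect / a
    disc = a * a + 4.0 * b * effect
    d = (-a + np.sqrt(disc)) / (2.0 * b)
    if d <= 0:
        raise ValueError("no positive iso-effect dose")
    return float(d)


def iso_effect_ter(
    reference: LQParameters, heated: LQParameters, survival_level: float = 0.1
) -> float:
    """Iso-effect dose ratio (unheated / heated), >= 1 for sensitization."""
    d_ref = iso_effect_dose(reference, survival_level)
    d_heat = iso_effect_dose(heated, survival_level)
    return d_ref / d_heat


def survival_dataset_to_ter(
    data: SurvivalDataset,
    reference_lq: LQParameters,
    survival_level: float = 0.1,
    reference_dose_gy: float | None = None,
) -> SurvivalDataset:
    """Convert survival-vs-temperature records to TER via LQ iso-effects.

    Observed survival at the assay dose is inverted for a joint scale factor
    k on the reference LQ coefficients (alpha and beta scaled together,
    preserving alpha/beta); the record's TER is then the iso-effect dose
    ratio between the reference and the k-scaled parameter sets at
    ``survival_level``. Note that because the LQ effect is quadratic in
    dose, this ratio is smaller than k itself unless beta = 0.
    Sigmas are propagated by numerical differentiation through the chain.
    """
    if data.value_kind == "ter":
        return data
    d0 = reference_dose_gy if reference_dose_gy is not None else iso_effect_dose(
        reference_lq, survival_level
    )
    effect_ref = reference_lq.alpha * d0 + reference_lq.beta * d0**2

    def _ter_of_scale(k: float) -> float:
        heated = LQParameters(reference_lq.alpha * k, reference_lq.beta * k)
        return iso_effect_ter(reference_lq, heated, survival_level)

    table = data.table.copy()
    survival = table["value"].to_numpy(float)
    sigmas = table["sigma"].to_numpy(float)
    scale = -np.log(survival) / effect_ref
    ters = np.array([_ter_of_scale(k) for k in scale])
    # d k / d S = -1 / (S * effect_ref); d TER / d k by central difference
    dk = 1e-6
    dter_dk = np.array(
        [(_ter_of_scale(k + dk) - _ter_of_scale(k - dk)) / (2 * dk) for k in scale]
    )
    table["sigma"] = np.abs(dter_dk) * sigmas / (survival * effect_ref)
    table["value"] = ters
    return SurvivalDataset(table=table, value_kind="ter")


def fit_ter_model(
    data: SurvivalDataset,
    t_c: float | None = 45.0,
    init: dict | None = None,
    bounds: dict | None = None,
    cell_type: str | None = None,
    t_ref: float = T_REF_CELSIUS,
) -> FitResult:
    """Nonlinear least squares of the TER expression to a TER dataset.

    ``t_c`` fixed (default) or None to fit it too (weakly identified with
    c2; opt-in). Inverse-variance weights are used when finite positive
    sigmas are present. Non-convergence is flagged on the result, never a
    silent partial fit.
    """
    if data.value_kind != "ter":
        raise ValueError("fit expects TER data; convert survival first")
    table = data.for_cell(cell_type) if cell_type else data.table
    temps = table["T_C"].to_numpy(float)
    times = table["t_min"].to_numpy(float)
    values = table["value"].to_numpy(float)
    sigmas = table["sigma"].to_numpy(float)
    if len(np.unique(temps)) < 3:
        raise ValueError("need >= 3 distinct temperatures to fit")
    use_sigma = np.all(np.isfinite(sigmas)) and np.all(sigmas > 0)
    init = init or {}
    p0 = [init.get("ter0", 1.0), init.get("c1", 0.01), init.get("c2", 0.3)]
    lower = [1.0 - 1e-9, 0.0, 1e-9]
    upper = [np.inf, np.inf, np.inf]
    if t_c is None:
        p0.append(init.get("t_c", 45.0))
        lower.append(0.0)
        upper.append(200.0)

    def _predict(x, *p):
        temp, tt = x
        if t_c is None:
            ter0, c1, c2, tc = p
        else:
            ter0, c1, c2 = p
            tc = t_c
        return ter0 + c1 * tt * np.exp(c2 * (temp - tc))

    if bounds:
        names = ["ter0", "c1", "c2"] + (["t_c"] if t_c is None else [])
        for i, nm in enumerate(names):
            if nm in bounds:
                lower[i], upper[i] = bounds[nm]
    try:
        popt, pcov = curve_fit(
            _predict,
            (temps, times),
            values,
            p0=p0,
            sigma=sigmas if use_sigma else None,
            absolute_sigma=use_sigma,
            bounds=(lower, upper),
            maxfev=20000,
        )
        converged = np.all(np.isfinite(popt)) and np.all(np.isfinite(np.diag(pcov)))
        message = ""
    except RuntimeError as exc:  # no silent partial fit
        return FitResult(
            model=TERModel(t_c=t_c if t_c is not None else 45.0, t_ref=t_ref),
            r_squared=float("nan"),
            residuals=np.full_like(values, np.nan),
            covariance=np.full((len(p0), len(p0)), np.nan),
            converged=False,
            message=str(exc),
        )
    fitted = TERModel(
        ter0=float(popt[0]),
        c1=float(popt[1]),
        c2=float(popt[2]),
        t_c=float(popt[3]) if t_c is None else float(t_c),
        t_ref=t_ref,
    )
    pred = _predict((temps, times), *popt)
    residuals = values - pred
    ss_res = float(np.sum(residuals**2))
    ss_tot = float(np.sum((values - values.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return FitResult(
        model=fitted,
        r_squared=r2,
        residuals=residuals,
        covariance=pcov,
        converged=bool(converged),
        message=message,
    )


def ter_with_uncertainty(fit: FitResult, temperature: float, time: float) -> tuple[float, float]:
    """TER central value and 1 s.d. from first-order propagation of the fit
    covariance at (T, t)."""
    m = fit.model
    ter = ter_evaluate(m, temperature, time)
    ex = np.exp(m.c2 * (temperature - m.t_c))
    grad = [1.0, time * ex, m.c1 * time * (temperature - m.t_c) * ex]
    if fit.covariance.shape[0] == 4:
        grad.append(-m.c1 * time * m.c2 * ex)
    g = np.asarray(grad)
    var = float(g @ fit.covariance @ g)
    return float(ter), float(np.sqrt(max(var, 0.0)))
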