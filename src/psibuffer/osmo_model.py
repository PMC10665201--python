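"""Non-ideal osmotic potential model and water-release statistics.

Vapour-pressure osmometers report osmolality (mOsm kg⁻¹), which is linear in
solute concentration for ideal (van't Hoff) solutes but diverges for
concentrated macromolecular solutions whose hydration layers sequester an
appreciable fraction of the solvent.  The empirical model used throughout this
package is

    -Psi_pi(C) = A * C / (1 - I_eff * C)

where ``A`` (mOsm kg⁻¹ per concentration unit) plays the role of the ideal
slope (``i*R*T`` in pressure units) and ``I_eff`` (per concentration unit)
measures the effective solute–water interaction: the larger ``I_eff``, the
more water is structured per unit solute and the steeper the departure from
linearity.  ``I_eff = 0`` recovers the linear law exactly.

On top of the model fit the module provides the two statistics used to
quantify free-water release by condensation:

* *deviation from additivity* — the percent shortfall of a co-solution's
  measured osmolality relative to the sum of its components';
* *dilution buffering index* — the relative departure of a neat extract's
  osmolality from the value extrapolated from the linear (dilute) part of its
  dilution curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "DilutionSeries",
    "OsmoticModelParams",
    "IdealSoluteSpec",
    "AdditivityResult",
    "BufferingResult",
    "FitError",
    "vant_hoff_osmolality",
    "osmolality_to_pressure",
    "predict_osmolality",
    "fit_nonideal",
    "ieff_temperature_profile",
    "additive_prediction",
    "deviation_from_additivity",
    "dilution_buffering_index",
]

R_GAS = 8.314  # J mol^-1 K^-1
WATER_DENSITY = 1000.0  # kg m^-3
KELVIN_OFFSET = 273.15


class FitError(RuntimeError):
    """Raised when the pooled nonlinear fit cannot converge."""


def _as_kelvin(temperature: float) -> float:
    """Accept °C or K; values below 150 are interpreted as °C."""
    t = float(temperature)
    if t < 150.0:
        t += KELVIN_OFFSET
    if t <= 0:
        raise ValueError(f"temperature must be > 0 K, got {t}")
    return t


@dataclass
class DilutionSeries:
    """One osmometry dilution curve: readings at increasing concentrations.

    ``temperature`` may be given in °C (converted to K on construction);
    ``conc_unit`` is either ``mg/ml`` or ``mmol/l``.  ``baseline_osmolality``
    is the buffer-only reading used for baseline correction.
    """

    solute_name: str
    temperature: float
    concentrations: np.ndarray
    osmolality: np.ndarray
    conc_unit: str = "mg/ml"
    sem: np.ndarray | None = None
    replicate_id: str = ""
    baseline_osmolality: float = 0.0

    def __post_init__(self) -> None:
        self.temperature = _as_kelvin(self.temperature)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.osmolality = np.asarray(self.osmolality, dtype=float)
        if self.sem is not None:
            self.sem = np.asarray(self.sem, dtype=float)
            if self.sem.shape != self.concentrations.shape:
                raise ValueError("sem must match concentrations in length")
        if self.concentrations.ndim != 1:
            raise ValueError("concentrations must be 1-D")
        if len(self.osmolality) != len(self.concentrations):
            raise ValueError("osmolality and concentrations differ in length")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be nonnegative")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if not np.all(np.isfinite(self.osmolality)):
            raise ValueError("osmolality readings must be finite")

    def baseline_corrected(self) -> "DilutionSeries":
        out = replace(
            self,
            osmolality=self.osmolality - self.baseline_osmolality,
            baseline_osmolality=0.0,
        )
        return out


@dataclass
class OsmoticModelParams:
    """Fitted (A, I_eff) with 95% confidence intervals."""

    A: float
    I_eff: float
    A_ci95: tuple[float, float] = (np.nan, np.nan)
    I_eff_ci95: tuple[float, float] = (np.nan, np.nan)
    n_curves: int = 0
    rss: float = np.nan

    def __post_init__(self) -> None:
        if self.A <= 0:
            raise ValueError("A must be positive")
        if self.I_eff < 0:
            raise ValueError("I_eff must be nonnegative")


@dataclass
class IdealSoluteSpec:
    """Ideal (van't Hoff) solute: dissociation factor and molar mass."""

    vant_hoff_factor: float = 1.0
    molar_mass: float = np.nan  # g/mol, for unit conversion only

    def __post_init__(self) -> None:
        if self.vant_hoff_factor <= 0:
            raise ValueError("van't Hoff factor must be positive")


@dataclass
class AdditivityResult:
    """Additive prediction for a co-solution and its deviation from observation.

    ``percent_deviation`` is 100·(predicted − observed)/predicted per point;
    positive values mean the observed osmolality fell below the additive
    prediction, i.e. free water was released.
    """

    concentrations: np.ndarray
    predicted: np.ndarray
    predicted_sem: np.ndarray | None = None
    observed: np.ndarray | None = None
    percent_deviation: np.ndarray | None = None
    summary_deviation: float = np.nan
    excluded: np.ndarray | None = None  # points where predicted <= 0


@dataclass
class BufferingResult:
    """Departure-from-linearity of an extract dilution curve.

    ``buffering_index`` = (linear extrapolation at neat − observed at neat) /
    linear extrapolation; positive means sub-linear (buffered) behaviour.
    """

    dilution_fractions: np.ndarray
    osmolality: np.ndarray
    linear_prediction: np.ndarray = field(default_factory=lambda: np.array([]))
    buffering_index: float = np.nan


# ---------------------------------------------------------------------------
# elementary relations


def vant_hoff_osmolality(conc: float, spec: IdealSoluteSpec) -> float:
    """Ideal osmolality i·C for a molar concentration (mmol/l → mOsm kg⁻¹)."""
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentration must be nonnegative")
    return spec.vant_hoff_factor * conc


def osmolality_to_pressure(osm: float, temperature: float) -> float:
    """Convert osmolality (mOsm kg⁻¹) to osmotic pressure (Pa) at T.

    Uses Π = c_osm · ρ_w · R · T with ρ_w = 1000 kg m⁻³ — the energy-unit
    bridge between instrument readings and -Psi_pi.
    """
    t = float(temperature)
    if t <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    osm = np.asarray(osm, dtype=float)
    out = osm * 1e-3 * WATER_DENSITY * R_GAS * t  # (mol/kg)(kg/m3)(J/mol/K)(K) = Pa
    return out if out.ndim else float(out)


def predict_osmolality(params: OsmoticModelParams | tuple[float, float], conc) -> np.ndarray | float:
    """Evaluate -Psi_pi = A·C/(1 − I_eff·C) on the valid domain I_eff·C < 1."""
    if isinstance(params, OsmoticModelParams):
        A, I_eff = params.A, params.I_eff
    else:
        A, I_eff = params
    conc = np.asarray(conc, dtype=float)
    if np.any(I_eff * conc >= 1.0):
        raise ValueError("I_eff*C >= 1: osmolality diverges at the model pole")
    out = A * conc / (1.0 - I_eff * conc)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# pooled fitting


def _pool(series: Sequence[DilutionSeries], baseline_correct: bool):
    if not series:
        raise ValueError("need at least one dilution series")
    temps = {round(s.temperature, 6) for s in series}
    units = {s.conc_unit for s in series}
    if len(temps) > 1:
        raise ValueError(f"series at mixed temperatures: {sorted(temps)}")
    if len(units) > 1:
        raise ValueError(f"series with mixed concentration units: {sorted(units)}")
    if baseline_correct:
        series = [s.baseline_corrected() for s in series]
    conc = np.concatenate([s.concentrations for s in series])
    osm = np.concatenate([s.osmolality for s in series])
    sems = [s.sem for s in series]
    sem = np.concatenate(sems) if all(s is not None for s in sems) else None
    if len(np.unique(conc)) < 3:
        raise ValueError("need >= 3 distinct pooled concentrations")
    return conc, osm, sem


def fit_nonideal(
    series: Sequence[DilutionSeries],
    baseline_correct: bool = False,
    weighting: str = "relative",
    ci_method: str = "covariance",
    n_bootstrap: int = 1000,
    seed: int | None = None,
) -> OsmoticModelParams:
    """Fit (A, I_eff) by pooled least squares over all curves simultaneously.

    All series share one (A, I_eff); residuals of every point of every
    replicate curve are minimized jointly.  Vapour-pressure readings carry
    noise roughly proportional to the reading, so the default ``weighting``
    is ``"relative"``: an unweighted pass followed by one pass weighted by
    the fitted curve, i.e. relative least squares.  ``"none"`` gives plain
    unweighted LSQ and ``"sem"`` weights by the per-point standard errors.
    ``I_eff`` is constrained nonnegative; 95% CIs come from the scaled fit
    covariance (t-quantile) or, with ``ci_method="bootstrap"``, from a seeded
    nonparametric bootstrap over curves.
    """
    conc, osm, sem = _pool(series, baseline_correct)
    if weighting not in {"relative", "none", "sem"}:
        raise ValueError(f"unknown weighting {weighting!r}")
    sigma = None
    if weighting == "sem":
        if sem is None or not np.all(sem > 0):
            raise ValueError("sem weighting requested but sem missing or nonpositive")
        sigma = sem

    cmax = conc.max()
    popt, pcov = _fit_pooled(conc, osm, sigma, cmax)
    if weighting == "relative":
        yhat = predict_osmolality(popt, conc)
        if np.all(yhat > 0):
            popt, pcov = _fit_pooled(conc, osm, yhat, cmax, p0=tuple(popt))
    resid = osm - predict_osmolality(popt, conc)
    rss = float(np.sum(resid**2))
    dof = max(len(conc) - 2, 1)
    tq = stats.t.ppf(0.975, dof)

    if ci_method == "bootstrap":
        if len(series) < 2:
            raise ValueError("bootstrap CIs need >= 2 curves to resample")
        rng = np.random.default_rng(seed)
        boots = []
        for _ in range(n_bootstrap):
            idx = rng.integers(0, len(series), size=len(series))
            bs = [series[i] for i in idx]
            c, o, s = _pool(bs, baseline_correct)
            try:
                p, _ = _fit_pooled(c, o, None, c.max())
                if weighting == "relative":
                    yh = predict_osmolality(p, c)
                    if np.all(yh > 0):
                        p, _ = _fit_pooled(c, o, yh, c.max(), p0=tuple(p))
                boots.append(p)
            except FitError:
                continue
        boots = np.asarray(boots)
        lo, hi = np.percentile(boots, [2.5, 97.5], axis=0)
        a_ci, i_ci = (lo[0], hi[0]), (lo[1], hi[1])
    else:
        se = np.sqrt(np.clip(np.diag(pcov), 0, None))
        a_ci = (popt[0] - tq * se[0], popt[0] + tq * se[0])
        i_ci = (max(popt[1] - tq * se[1], 0.0), popt[1] + tq * se[1])

    return OsmoticModelParams(
        A=float(popt[0]),
        I_eff=float(popt[1]),
        A_ci95=(float(a_ci[0]), float(a_ci[1])),
        I_eff_ci95=(float(i_ci[0]), float(i_ci[1])),
        n_curves=len(series),
        rss=rss,
    )


def _fit_pooled(conc, osm, sigma, cmax, p0=None):
    def model(c, A, I_eff):
        denom = 1.0 - I_eff * c
        denom = np.where(denom <= 1e-12, 1e-12, denom)
        return A * c / denom

    # A initialized from the slope of the two lowest-concentration points
    order = np.argsort(conc)
    c0, c1 = conc[order[0]], conc[order[1]]
    y0, y1 = osm[order[0]], osm[order[1]]
    slope = (y1 - y0) / (c1 - c0) if c1 > c0 else 1.0
    a0 = max(float(slope), 1e-9)
    upper_i = 0.999 / cmax
    starts = [(a0, 1e-8), (a0, 0.5 / cmax), (a0, 0.9 / cmax)]
    if p0 is not None:
        starts.insert(0, (p0[0], min(max(p0[1], 0.0), upper_i * 0.999)))
    last_err = None
    for p0 in starts:
        try:
            popt, pcov = optimize.curve_fit(
                model,
                conc,
                osm,
                p0=p0,
                sigma=sigma,
                bounds=([1e-12, 0.0], [np.inf, upper_i]),
                xtol=1e-12,
                ftol=1e-10,
                maxfev=20000,
            )
            return popt, pcov
        except (RuntimeError, ValueError) as err:  # pragma: no cover - rare
            last_err = err
    raise FitError(f"pooled fit failed after bounded restarts: {last_err}")


def ieff_temperature_profile(
    series_by_temperature: Mapping[float, Sequence[DilutionSeries]],
    **fit_kwargs,
) -> list[tuple[float, OsmoticModelParams | Exception]]:
    """Independent (A, I_eff) fit per temperature, ordered by temperature.

    Fit failures at one temperature are recorded as the exception object
    without aborting the remaining fits, so a partial temperature profile is
    still returned.
    """
    out: list[tuple[float, OsmoticModelParams | Exception]] = []
    for t in sorted(series_by_temperature):
        group = series_by_temperature[t]
        if not group:
            raise ValueError(f"temperature {t} has no series")
        try:
            out.append((_as_kelvin(t), fit_nonideal(group, **fit_kwargs)))
        except (FitError, ValueError) as err:
            out.append((_as_kelvin(t), err))
    return out


# ---------------------------------------------------------------------------
# additivity and buffering


def _interp_series(series: DilutionSeries, conc: np.ndarray, what: str) -> np.ndarray:
    c = series.concentrations
    if np.any(conc < c.min() - 1e-12) or np.any(conc > c.max() + 1e-12):
        raise ValueError(
            f"requested {what} concentrations outside the measured range "
            f"[{c.min()}, {c.max()}] of series {series.solute_name!r}; "
            "no silent extrapolation"
        )
    return np.interp(conc, c, series.osmolality)


def additive_prediction(
    series_a: DilutionSeries,
    series_b: DilutionSeries,
    mix_ratio: tuple[float, float],
    total_conc: np.ndarray | None = None,
) -> AdditivityResult:
    """Ideal-additivity prediction for an a:b co-solution.

    At total co-solution concentration C, component a sits at
    wa/(wa+wb)·C and b at wb/(wa+wb)·C; the prediction is the sum of each
    component's measured osmolality at its in-mixture concentration
    (interpolated on its own dilution curve).  Propagated error is
    sqrt(sem_a² + sem_b²).
    """
    wa, wb = mix_ratio
    if wa < 0 or wb < 0 or wa + wb <= 0:
        raise ValueError("mix ratio weights must be nonnegative and not both zero")
    fa, fb = wa / (wa + wb), wb / (wa + wb)
    if total_conc is None:
        cmax = min(
            series_a.concentrations.max() / fa if fa > 0 else np.inf,
            series_b.concentrations.max() / fb if fb > 0 else np.inf,
        )
        total_conc = np.linspace(0.0, cmax, 25)
    total_conc = np.asarray(total_conc, dtype=float)

    pred = np.zeros_like(total_conc)
    if fa > 0:
        pred = pred + _interp_series(series_a, fa * total_conc, "component a")
    if fb > 0:
        pred = pred + _interp_series(series_b, fb * total_conc, "component b")

    psem = None
    if series_a.sem is not None and series_b.sem is not None:
        sa = np.interp(fa * total_conc, series_a.concentrations, series_a.sem) if fa > 0 else 0.0
        sb = np.interp(fb * total_conc, series_b.concentrations, series_b.sem) if fb > 0 else 0.0
        psem = np.sqrt(np.asarray(sa) ** 2 + np.asarray(sb) ** 2)

    return AdditivityResult(concentrations=total_conc, predicted=pred, predicted_sem=psem)


def deviation_from_additivity(
    predicted: AdditivityResult,
    observed: DilutionSeries,
    conc_floor: float = 0.0,
) -> AdditivityResult:
    """Percent deviation of an observed co-solution from its additive prediction.

    Points where the prediction is <= 0 are excluded and flagged.  The summary
    is the mean per-point percent deviation over points with total
    concentration above ``conc_floor``.
    """
    obs = _interp_series(observed, predicted.concentrations, "observed co-solution")
    ok = predicted.predicted > 0
    dev = np.full_like(predicted.predicted, np.nan)
    dev[ok] = 100.0 * (predicted.predicted[ok] - obs[ok]) / predicted.predicted[ok]
    keep = ok & (predicted.concentrations >= conc_floor)
    summary = float(np.mean(dev[keep])) if np.any(keep) else np.nan
    return AdditivityResult(
        concentrations=predicted.concentrations,
        predicted=predicted.predicted,
        predicted_sem=predicted.predicted_sem,
        observed=obs,
        percent_deviation=dev,
        summary_deviation=summary,
        excluded=~ok,
    )


def dilution_buffering_index(
    dilution_fractions: Sequence[float],
    osmolality: Sequence[float],
    d_lin: float = 0.3,
) -> BufferingResult:
    """Buffering index of an extract dilution curve.

    A least-squares line through the origin-side points (fraction <= d_lin,
    the linear regime) is extrapolated to the neat sample (fraction 1.0); the
    index is the signed relative shortfall of the observed neat reading from
    that extrapolation.  0 for a perfectly linear curve, > 0 for sub-linear
    (buffered) behaviour; invariant to uniform scaling of the readings.
    """
    d = np.asarray(dilution_fractions, dtype=float)
    y = np.asarray(osmolality, dtype=float)
    if d.ndim != 1 or d.shape != y.shape:
        raise ValueError("dilution_fractions and osmolality must be matching 1-D")
    if np.any(np.diff(d) <= 0):
        raise ValueError("dilution_fractions must be strictly increasing")
    if len(d) < 4:
        raise ValueError("need >= 4 dilution points including the neat sample")
    if not np.isclose(d[-1], 1.0):
        raise ValueError("dilution series must include the neat sample (fraction 1.0)")
    in_lin = d <= d_lin + 1e-12
    if np.sum(in_lin) < 2:
        raise ValueError(
            f"only {int(np.sum(in_lin))} points at fraction <= d_lin={d_lin}; "
            "raise d_lin to cover the linear regime"
        )
    slope, intercept = np.polyfit(d[in_lin], y[in_lin], 1)
    linear = slope * d + intercept
    extrap_neat = slope * 1.0 + intercept
    observed_neat = y[-1]
    index = (extrap_neat - observed_neat) / extrap_neat
    return BufferingResult(
        dilution_fractions=d,
        osmolality=y,
        linear_prediction=linear,
        buffering_index=float(index),
    )
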