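"""Precursor-product kinetics of maple-toxin transformation in batch culture.

Hypoglycin B (HGB, the gamma-glutamyl dipeptide precursor) is hydrolysed to
hypoglycin A (HGA) with first-order rate constant ``k`` while HGA is cleared
with rate constant ``l``:

    dHGB/dt = -k * HGB
    dHGA/dt =  k * HGB - l * HGA

This is the classic two-compartment (Bateman) system.  For ``l != k`` the
initial-value problem has the closed form

    HGB(t) = HGB0 * exp(-k t)
    HGA(t) = (k/(l-k)) * HGB0 * exp(-k t) + (HGA0 - (k/(l-k)) * HGB0) * exp(-l t)

and in the confluent limit ``l == k``

    HGA(t) = (HGA0 + k * HGB0 * t) * exp(-k t).

The module provides the closed form, a fixed-step Runge-Kutta oracle, the
closed-form peak time of HGA, and two sklearn-style estimators:
:class:`ConversionClearanceModel` (joint fit of both analytes) and
:class:`ExponentialDecayModel` (single-analyte decay with half-life).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .datatypes import (
    ConcentrationSeries,
    DecayFit,
    FitResult,
    ToxinKineticParams,
    validate_concentration_frame,
)

__all__ = [
    "hgb_at",
    "hga_at",
    "simulate_numeric",
    "hga_peak_time",
    "ConversionClearanceModel",
    "ExponentialDecayModel",
    "fit_conversion_model",
    "fit_exponential_decay",
]

#: relative |l-k| below which the confluent (l == k) branch is used
CONFLUENT_RTOL = 1e-8


def _check_times(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("negative times are not allowed")
    return t


def hgb_at(params: ToxinKineticParams, t) -> np.ndarray | float:
    """Precursor concentration HGB0 * exp(-k t); scalar in, scalar out."""
    tt = _check_times(t)
    out = params.hgb0 * np.exp(-params.k * tt)
    return out if np.ndim(t) else float(out)


def _hga_closed(hga0: float, hgb0: float, k: float, l: float, t: np.ndarray) -> np.ndarray:
    if l >= 0 and abs(l - k) <= CONFLUENT_RTOL * max(k, abs(l)):
        return (hga0 + k * hgb0 * t) * np.exp(-k * t)
    a = k / (l - k) * hgb0
    return a * np.exp(-k * t) + (hga0 - a) * np.exp(-l * t)


def hga_at(params: ToxinKineticParams, t) -> np.ndarray | float:
    """Product concentration from the closed-form solution.

    Uses the confluent-limit branch when ``|l - k|`` is below
    ``CONFLUENT_RTOL`` relative, which keeps the result continuous across the
    ``l == k`` boundary instead of suffering catastrophic cancellation.
    """
    tt = _check_times(t)
    out = _hga_closed(params.hga0, params.hgb0, params.k, params.l, tt)
    return out if np.ndim(t) else float(out)


def simulate_numeric(
    params: ToxinKineticParams, grid, step: float = 1e-3
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the ODE system with fixed-step classical Runge-Kutta.

    Serves as the independent numerical oracle for the closed form.  Returns
    ``(hga, hgb)`` evaluated on ``grid`` (sorted, non-negative hours); the
    integrator lands exactly on every grid point by sub-dividing each
    interval into steps no longer than ``step``.
    """
    grid = _check_times(grid)
    if grid.size == 0:
        raise ValueError("empty time grid")
    if np.any(np.diff(grid) < 0):
        raise ValueError("grid must be sorted")

    k, l = params.k, params.l

    def deriv(y):
        hga, hgb = y
        return np.array([k * hgb - l * hga, -k * hgb])

    y = np.array([params.hga0, params.hgb0], dtype=float)
    t_now = 0.0
    hga_out = np.empty_like(grid)
    hgb_out = np.empty_like(grid)
    for i, t_next in enumerate(grid):
        span = t_next - t_now
        if span > 0:
            nsub = max(1, math.ceil(span / step))
            h = span / nsub
            for _ in range(nsub):
                k1 = deriv(y)
                k2 = deriv(y + 0.5 * h * k1)
                k3 = deriv(y + 0.5 * h * k2)
                k4 = deriv(y + h * k3)
                y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            t_now = t_next
        hga_out[i], hgb_out[i] = y
    return hga_out, hgb_out


def hga_peak_time(params: ToxinKineticParams) -> float | None:
    """Time of the interior maximum of HGA, or ``None`` if there is none.

    For ``l != k`` the stationary point solves
    ``t* = ln(-l B / (k A)) / (l - k)`` with ``A = k HGB0/(l-k)`` and
    ``B = HGA0 - A``; in the confluent case ``t* = (HGB0 - HGA0)/(k HGB0)``.
    ``None`` is returned when HGA is non-increasing from t=0 (the maximum
    sits at the boundary) or never decreases (``l == 0`` with precursor
    left), in which case no interior peak exists.
    """
    hga0, hgb0, k, l = params.hga0, params.hgb0, params.k, params.l
    # slope at t=0 decides whether the curve rises into an interior peak
    if k * hgb0 - l * hga0 <= 0:
        return None
    if l == 0:
        return None  # monotone non-decreasing; supremum at infinity
    if abs(l - k) <= CONFLUENT_RTOL * max(k, l):
        if hgb0 <= 0:
            return None
        t_star = (hgb0 - hga0) / (k * hgb0)
        return t_star if t_star > 0 and math.isfinite(t_star) else None
    a = k / (l - k) * hgb0
    b = hga0 - a
    arg = -(l * b) / (k * a)
    if arg <= 0:
        return None
    t_star = math.log(arg) / (l - k)
    if not (t_star > 0 and math.isfinite(t_star)):
        return None
    return t_star


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def _wald_ci95(popt, jac, resid, n, p):
    """Heteroscedasticity-robust Wald intervals at the optimum.

    Sandwich covariance (J'J)^-1 J' diag(r^2) J (J'J)^-1 with an n/(n-p)
    small-sample correction and a t quantile.  Concentration-like data have
    noise that scales with the signal, and the plain homoscedastic Wald
    covariance then under-covers the parameters tied to the high-signal
    region; the sandwich form stays calibrated under either noise shape.
    """
    resid = np.asarray(resid)
    dof = max(n - p, 1)
    try:
        bread = np.linalg.inv(jac.T @ jac)
        meat = jac.T @ (jac * (resid**2)[:, None])
        cov = bread @ meat @ bread * (n / dof)
        se = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(p, np.inf)
    tq = stats.t.ppf(0.975, dof)
    return [(est - tq * s, est + tq * s) for est, s in zip(popt, se)]


def _r_squared(y, resid):
    sst = float(np.sum((y - np.mean(y)) ** 2))
    ssr = float(np.sum(resid**2))
    if sst == 0:
        return float("nan")
    return 1.0 - ssr / sst


class ConversionClearanceModel(RegressorMixin, BaseEstimator):
    """Joint nonlinear least-squares fit of the conversion-clearance model.

    Parameters
    ----------
    n_restarts : int
        Number of seeded multistart perturbations (+/-50 % uniform) around
        the data-driven initial guess.
    random_state : int
        Seed for the multistart perturbations.

    The design matrix ``X`` has two columns: time in hours and a species
    code (0 = HGA/product, 1 = HGB/precursor); ``y`` holds the matching
    concentrations.  Residuals of both analytes are pooled unweighted, in
    raw concentration units.

    Attributes
    ----------
    hga0_, hgb0_, k_, l_ : float
        Point estimates of the four model parameters.
    params_ : ToxinKineticParams
    fit_result_ : FitResult
        Estimates, Wald 95 % intervals, RMSE, R-squared, convergence flag.
    """

    _PARAM_NAMES = ("hga0", "hgb0", "k", "l")

    def __init__(self, n_restarts: int = 10, random_state: int = 0, unit: str = "ug/mL"):
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.unit = unit

    # -- internal -----------------------------------------------------------
    @staticmethod
    def _model(theta, t, species):
        hga0, hgb0, k, l = theta
        out = np.empty_like(t)
        is_hgb = species == 1
        out[is_hgb] = hgb0 * np.exp(-k * t[is_hgb])
        out[~is_hgb] = _hga_closed(hga0, hgb0, k, l, t[~is_hgb])
        return out

    def _initial_guess(self, t, species, y):
        """Data-driven start: t=0 means for the initial values, log-slopes
        for the rate constants."""
        hga_t, hga_y = t[species == 0], y[species == 0]
        hgb_t, hgb_y = t[species == 1], y[species == 1]

        def mean_at(tt, yy, target):
            sel = tt == target
            return float(np.mean(yy[sel])) if sel.any() else float("nan")

        hga0 = mean_at(hga_t, hga_y, hga_t.min()) if hga_t.size else 0.0
        hgb0 = mean_at(hgb_t, hgb_y, hgb_t.min()) if hgb_t.size else 0.0

        # k from the two-point log slope of mean HGB
        k0 = 0.1
        tb = np.unique(hgb_t)
        if tb.size >= 2:
            m0 = mean_at(hgb_t, hgb_y, tb[0])
            m1 = mean_at(hgb_t, hgb_y, tb[1])
            if m0 > 0 and m1 > 0 and m1 < m0 and tb[1] > tb[0]:
                k0 = math.log(m0 / m1) / (tb[1] - tb[0])
        # l from the post-peak log slope of mean HGA
        l0 = k0 / 2
        ta = np.unique(hga_t)
        if ta.size >= 2:
            means = np.array([mean_at(hga_t, hga_y, u) for u in ta])
            ipk = int(np.argmax(means))
            if ipk < ta.size - 1:
                m0, m1 = means[ipk], means[-1]
                if m0 > 0 and m1 > 0 and m1 < m0:
                    l0 = math.log(m0 / m1) / (ta[-1] - ta[ipk])
        hga0 = max(hga0, 1e-6) if not math.isnan(hga0) else 1e-6
        hgb0 = max(hgb0, 1e-6) if not math.isnan(hgb0) else 1e-6
        return np.array([hga0, hgb0, max(k0, 1e-4), max(l0, 1e-6)])

    # -- API ----------------------------------------------------------------
    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n, 2): [time_h, species_code]")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        t, species = X[:, 0], X[:, 1].astype(int)
        if np.any(t < 0):
            raise ValueError("negative times")
        if not np.all(np.isin(species, (0, 1))):
            raise ValueError("species code must be 0 (HGA) or 1 (HGB)")

        n = y.size
        if np.unique(t).size < 4:
            raise ValueError("need >= 4 distinct time points for 4 free parameters")
        if not np.any(y[species == 1] > 0):
            # precursor never observed above zero: k cannot be identified
            self.fit_result_ = FitResult(
                estimates={}, ci95={}, rmse=float("nan"), r2=float("nan"),
                converged=False, n_obs=int(n),
                message="HGB series has no positive observations; conversion rate k is not identifiable",
            )
            self.converged_ = False
            return self

        def resid(theta):
            return self._model(theta, t, species) - y

        theta0 = self._initial_guess(t, species, y)
        rng = np.random.default_rng(self.random_state)
        starts = [theta0]
        for _ in range(self.n_restarts):
            starts.append(theta0 * rng.uniform(0.5, 1.5, size=4))

        best = None
        lb = np.zeros(4)
        lb[2] = 1e-10  # k strictly positive
        ub = np.full(4, np.inf)
        for s in starts:
            try:
                sol = optimize.least_squares(
                    resid, np.clip(s, lb + 1e-12, None), bounds=(lb, ub),
                    method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12,
                )
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol

        if best is None or not best.success:
            self.fit_result_ = FitResult(
                estimates={}, ci95={}, rmse=float("nan"), r2=float("nan"),
                converged=False, n_obs=int(n), message="optimizer failed to converge",
            )
            self.converged_ = False
            return self

        popt = best.x
        ssr = float(np.sum(best.fun**2))
        cis = _wald_ci95(popt, best.jac, best.fun, n, 4)
        self.hga0_, self.hgb0_, self.k_, self.l_ = (float(v) for v in popt)
        self.params_ = ToxinKineticParams(
            hga0=self.hga0_, hgb0=self.hgb0_, k=max(self.k_, 1e-10), l=self.l_, unit=self.unit
        )
        self.fit_result_ = FitResult(
            estimates=dict(zip(self._PARAM_NAMES, (float(v) for v in popt))),
            ci95=dict(zip(self._PARAM_NAMES, cis)),
            rmse=math.sqrt(ssr / n),
            r2=_r_squared(y, best.fun),
            converged=True,
            n_obs=int(n),
        )
        self.converged_ = True
        return self

    def predict(self, X):
        check_is_fitted(self, "fit_result_")
        if not self.converged_:
            raise ValueError("model did not converge; no predictions available")
        X = np.asarray(X, dtype=float)
        return self._model(
            [self.hga0_, self.hgb0_, self.k_, self.l_], X[:, 0], X[:, 1].astype(int)
        )

    def peak_time(self) -> float | None:
        """Closed-form time of maximal product concentration."""
        check_is_fitted(self, "params_")
        return hga_peak_time(self.params_)


class ExponentialDecayModel(RegressorMixin, BaseEstimator):
    """First-order decay fit C(t) = C0 * exp(-k t) with half-life ln(2)/k.

    ``X`` is a single column of times (hours); ``y`` the concentrations.
    Non-decreasing data yields ``k <= 0`` at the optimum and is flagged as an
    invalid fit rather than raising.
    """

    def __init__(self, unit: str = "ng/mL"):
        self.unit = unit

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, 0]
        y = np.asarray(y, dtype=float)
        t = X
        if np.any(t < 0):
            raise ValueError("negative times")
        mask = y > 0
        if np.unique(t[mask]).size < 2:
            raise ValueError("need >= 2 distinct time points with positive values")
        t, y = t[mask], y[mask]
        n = y.size

        # log-linear start, then unconstrained Gauss-Newton refinement
        slope, intercept = np.polyfit(t, np.log(y), 1)
        theta0 = np.array([math.exp(intercept), -slope])

        def resid(theta):
            c0, k = theta
            return c0 * np.exp(-k * t) - y

        sol = optimize.least_squares(resid, theta0, xtol=1e-14, ftol=1e-14, gtol=1e-14)
        c0, k = (float(v) for v in sol.x)
        ssr = float(np.sum(sol.fun**2))
        valid = sol.success and k > 0 and c0 > 0
        cis = _wald_ci95(sol.x, sol.jac, sol.fun, n, 2)
        self.c0_, self.k_ = c0, k
        self.half_life_ = math.log(2) / k if k > 0 else float("inf")
        self.fit_result_ = FitResult(
            estimates={"c0": c0, "k": k},
            ci95=dict(zip(("c0", "k"), cis)),
            rmse=math.sqrt(ssr / n),
            r2=_r_squared(y, sol.fun),
            converged=bool(valid),
            n_obs=int(n),
            message="" if valid else "non-positive rate constant: data do not decay",
        )
        self.converged_ = bool(valid)
        return self

    def predict(self, X):
        check_is_fitted(self, "fit_result_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, 0]
        return self.c0_ * np.exp(-self.k_ * X)


# ---------------------------------------------------------------------------
# tidy-table wrappers
# ---------------------------------------------------------------------------

def _series_to_xy(df: pd.DataFrame, censoring: str):
    """Flatten an already-validated concentration frame into (X, y)."""
    if censoring == "drop":
        df = df[~df["censored"]]
    elif censoring == "half_limit":
        df = df.copy()
        df.loc[df["censored"], "value"] = df.loc[df["censored"], "value"] / 2.0
    else:
        raise ValueError(f"unknown censoring policy {censoring!r}")
    return df


def fit_conversion_model(
    hga: ConcentrationSeries,
    hgb: ConcentrationSeries,
    mode: str = "individual",
    censoring: str = "drop",
    n_restarts: int = 10,
    random_state: int = 0,
) -> FitResult:
    """Fit the conversion-clearance model to tidy HGA and HGB tables.

    ``mode='means'`` first averages replicate fermenters per time point, the
    alternative estimation route in which the initial-value problem is solved
    against per-time-point mean values; ``mode='individual'`` pools all
    individual measurements.
    """
    if mode not in ("individual", "means"):
        raise ValueError("mode must be 'individual' or 'means'")
    frames = []
    for code, df in ((0, hga), (1, hgb)):
        df = validate_concentration_frame(df)
        df = _series_to_xy(df, censoring)
        if mode == "means":
            df = (
                df.groupby("time_h", as_index=False)["value"].mean()
                .assign(censored=False)
            )
        part = pd.DataFrame({"time_h": df["time_h"], "species": code, "value": df["value"]})
        frames.append(part)
    data = pd.concat(frames, ignore_index=True)
    if data.empty:
        raise ValueError("all observations censored; nothing to fit")
    est = ConversionClearanceModel(n_restarts=n_restarts, random_state=random_state)
    est.fit(data[["time_h", "species"]].to_numpy(), data["value"].to_numpy())
    est.fit_result_.mode = mode
    return est.fit_result_


def fit_exponential_decay(series: ConcentrationSeries, censoring: str = "drop") -> DecayFit:
    """Fit first-order decay to one analyte's tidy concentration table.

    Censored observations are excluded from the objective; the number
    excluded is recorded in the fit message.
    """
    df = validate_concentration_frame(series)
    n_censored = int(df["censored"].sum())
    df = _series_to_xy(df, censoring)
    est = ExponentialDecayModel()
    est.fit(df["time_h"].to_numpy(), df["value"].to_numpy())
    res = est.fit_result_
    if n_censored and censoring == "drop":
        note = f"{n_censored} censored observation(s) excluded"
        res.message = f"{res.message}; {note}" if res.message else note
    return DecayFit(c0=est.c0_, k=est.k_, half_life=est.half_life_, fit=res)
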