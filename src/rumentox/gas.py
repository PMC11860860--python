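"""Gas-production processing and Gompertz kinetics for batch cultures.

Automated modules record cumulative headspace pressure (psi) at a 5-minute
native interval.  The processing chain is: blank correction in the pressure
domain (mean of the blank fermenters), downsampling to a coarser analysis
grid, ideal-gas conversion of pressure to gas volume, per-gram-dry-matter
normalisation, and a nonlinear fit of the re-parameterised Gompertz curve

    G(t) = a * exp(-exp(-(t - m)/s))

where the interpretable triple (a, b, c) fixes the internal location/scale
pair (m, s) through two constraints: one third of the asymptote ``a`` is
produced at t = b, and 70 % of ``a`` at t = b + c.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .datatypes import FitResult, GasCurve, GompertzParams
from .kinetics import _r_squared, _wald_ci95

__all__ = [
    "pressure_to_volume",
    "volume_to_pressure",
    "blank_correct",
    "downsample",
    "abc_to_shape",
    "gompertz_value",
    "GompertzGasModel",
    "fit_gompertz",
]

PSI_TO_PA = 6894.757293168
R_GAS = 8.314462618          # J / (mol K)
MOLAR_VOLUME_STP_ML = 22414.0  # mL/mol at standard temperature and pressure
P_ATM_PA = 101325.0

#: ln(ln 3 / ln(10/7)) — spacing constant of the (b, c) parameterisation
_LN_RATIO = math.log(math.log(3.0) / math.log(10.0 / 7.0))
_LN_LN3 = math.log(math.log(3.0))


def _moles(pressure_psi, headspace_ml: float, temp_c: float):
    if headspace_ml <= 0:
        raise ValueError("headspace volume must be positive")
    if temp_c <= -273.15:
        raise ValueError("temperature below absolute zero")
    t_kelvin = temp_c + 273.15
    return (np.asarray(pressure_psi) * PSI_TO_PA) * (headspace_ml * 1e-6) / (R_GAS * t_kelvin)


def pressure_to_volume(
    pressure_psi,
    headspace_ml: float = 106.0,
    temp_c: float = 39.0,
    reference: str = "STP",
):
    """Convert accumulated headspace pressure to gas volume (mL).

    The pressure increment corresponds to n = P V / (R T) moles of gas in the
    fixed headspace; Avogadro's law turns moles into volume, by default at
    standard temperature and pressure (22,414 mL/mol).  ``reference=
    'incubation'`` instead reports the volume the same moles occupy at the
    incubation temperature and 1 atm.  Linear and homogeneous in pressure.
    """
    p = np.asarray(pressure_psi, dtype=float)
    if np.any(p < 0):
        raise ValueError("negative pressure")
    n = _moles(p, headspace_ml, temp_c)
    if reference == "STP":
        out = n * MOLAR_VOLUME_STP_ML
    elif reference == "incubation":
        out = n * R_GAS * (temp_c + 273.15) / P_ATM_PA * 1e6
    else:
        raise ValueError("reference must be 'STP' or 'incubation'")
    return out if np.ndim(pressure_psi) else float(out)


def volume_to_pressure(
    volume_ml,
    headspace_ml: float = 106.0,
    temp_c: float = 39.0,
    reference: str = "STP",
):
    """Inverse of :func:`pressure_to_volume` (used by the simulator)."""
    one_psi = pressure_to_volume(1.0, headspace_ml, temp_c, reference)
    out = np.asarray(volume_ml, dtype=float) / one_psi
    return out if np.ndim(volume_ml) else float(out)


def blank_correct(curves: list[GasCurve], blanks: list[GasCurve]) -> list[GasCurve]:
    """Subtract the pointwise mean blank pressure from each test curve.

    Blank curves recorded on different grids are linearly interpolated onto
    each test curve's grid; the overlap must cover the test curve.  Corrected
    values may go negative and are preserved as such.
    """
    if not blanks:
        raise ValueError("no blank curves supplied")
    out = []
    for curve in curves:
        lo = max(b.times[0] for b in blanks)
        hi = min(b.times[-1] for b in blanks)
        if curve.times[0] < lo - 1e-9 or curve.times[-1] > hi + 1e-9:
            raise ValueError(
                f"blank curves do not cover the time range of fermenter {curve.fermenter}"
            )
        blank_mean = np.mean(
            [np.interp(curve.times, b.times, b.values) for b in blanks], axis=0
        )
        out.append(curve.replace(values=curve.values - blank_mean))
    return out


def downsample(curve: GasCurve, resolution_h: float) -> GasCurve:
    """Thin a native-resolution curve to a coarser regular grid.

    Keeps, for each multiple of ``resolution_h``, the last observation at or
    before that grid point; t = 0 is always preserved.  With 5-minute native
    data and a 0.5 h resolution this yields 97 points over 0-48 h.
    """
    native = np.min(np.diff(curve.times)) if curve.times.size > 1 else 0.0
    if resolution_h <= native:
        raise ValueError("resolution must exceed the native sampling interval")
    targets = np.arange(0.0, curve.times[-1] + 1e-9, resolution_h)
    idx = np.searchsorted(curve.times, targets + 1e-9, side="right") - 1
    idx = np.unique(idx[idx >= 0])
    return curve.replace(times=curve.times[idx], values=curve.values[idx])


def abc_to_shape(b: float, c: float) -> tuple[float, float]:
    """Map the interpretable (b, c) pair to the internal (m, s) pair.

    Solves the two defining constraints G(b) = a/3 and G(b + c) = 0.70 a of
    the base curve G(t) = a exp(-exp(-(t - m)/s)), giving

        s = c / ln(ln 3 / ln(10/7)),    m = b + s * ln(ln 3).
    """
    if b <= 0 or c <= 0:
        raise ValueError("b and c must be positive")
    s = c / _LN_RATIO
    m = b + s * _LN_LN3
    return m, s


def gompertz_value(params: GompertzParams, t):
    """Cumulative gas production (mL/g DM) at time ``t`` (hours)."""
    tt = np.asarray(t, dtype=float)
    if np.any(tt < 0):
        raise ValueError("negative times")
    m, s = abc_to_shape(params.b, params.c)
    out = params.a * np.exp(-np.exp(-(tt - m) / s))
    return out if np.ndim(t) else float(out)


def time_to_fraction(params: GompertzParams, fraction: float) -> float:
    """Time at which the curve reaches ``fraction`` of its asymptote.

    Solved numerically by bracketing root finding on G(t) - fraction*a.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    m, s = abc_to_shape(params.b, params.c)
    hi = m + 20 * abs(s) + params.b + params.c
    return float(
        optimize.brentq(lambda t: gompertz_value(params, t) - fraction * params.a, 1e-12, hi)
    )


class GompertzGasModel(RegressorMixin, BaseEstimator):
    """Least-squares fit of the re-parameterised Gompertz gas curve.

    ``X`` is one column of times (h); ``y`` cumulative gas volumes, normally
    blank-corrected and normalised to mL/g DM.  Fitted attributes ``a_``,
    ``b_``, ``c_`` follow the interpretable parameterisation; ``fit_result_``
    carries Wald 95 % intervals, RMSE and R-squared.
    """

    _PARAM_NAMES = ("a", "b", "c")

    def __init__(self, theta0: tuple[float, float, float] | None = None):
        self.theta0 = theta0

    @staticmethod
    def _model(theta, t):
        a, b, c = theta
        s = c / _LN_RATIO
        m = b + s * _LN_LN3
        return a * np.exp(-np.exp(-(t - m) / s))

    @staticmethod
    def _default_start(t, y):
        """Quantile heuristic: asymptote from the maximum, b and c from the
        empirical one-third and 70 % crossing times."""
        a0 = max(float(np.max(y)) * 1.05, 1e-6)
        t3 = t[np.searchsorted(y, a0 / 3.0, side="left").clip(0, t.size - 1)]
        t70 = t[np.searchsorted(y, 0.70 * a0, side="left").clip(0, t.size - 1)]
        b0 = float(t3) if t3 > 0 else float(np.median(t))
        c0 = max(float(t70) - b0, 1e-2)
        return np.array([a0, b0, c0])

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, 0]
        t = X
        y = np.asarray(y, dtype=float)
        if np.unique(t).size < 5:
            raise ValueError("need >= 5 distinct time points for a 3-parameter sigmoid")
        n = y.size
        if np.ptp(y) <= 0:
            self.fit_result_ = FitResult(
                estimates={}, ci95={}, rmse=float("nan"), r2=float("nan"),
                converged=False, n_obs=int(n), message="flat gas curve: nothing to fit",
            )
            self.converged_ = False
            return self

        theta0 = np.asarray(self.theta0, dtype=float) if self.theta0 is not None else self._default_start(t, y)

        def resid(theta):
            return self._model(theta, t) - y

        sol = optimize.least_squares(
            resid, np.clip(theta0, 1e-9, None),
            bounds=(np.full(3, 1e-9), np.full(3, np.inf)),
            method="trf", xtol=1e-13, ftol=1e-13, gtol=1e-13,
        )
        a, b, c = (float(v) for v in sol.x)
        ssr = float(np.sum(sol.fun**2))
        cis = _wald_ci95(sol.x, sol.jac, sol.fun, n, 3)
        self.a_, self.b_, self.c_ = a, b, c
        self.params_ = GompertzParams(a=a, b=b, c=c)
        self.fit_result_ = FitResult(
            estimates=dict(zip(self._PARAM_NAMES, sol.x.astype(float))),
            ci95=dict(zip(self._PARAM_NAMES, cis)),
            rmse=math.sqrt(ssr / n),
            r2=_r_squared(y, sol.fun),
            converged=bool(sol.success),
            n_obs=int(n),
            message="" if sol.success else "optimizer failed to converge",
        )
        self.converged_ = bool(sol.success)
        return self

    def predict(self, X):
        check_is_fitted(self, "fit_result_")
        if not self.converged_:
            raise ValueError("model did not converge; no predictions available")
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, 0]
        return self._model([self.a_, self.b_, self.c_], X)


def fit_gompertz(curve: GasCurve, theta0=None) -> FitResult:
    """Fit the Gompertz model to one (already processed) gas curve.

    The curve is expected in volume units; if ``substrate_dm_g`` is set and
    the unit is ``mL``, values are normalised to mL/g DM before fitting.
    """
    y = curve.values
    if curve.value_unit == "mL" and curve.substrate_dm_g > 0:
        y = y / curve.substrate_dm_g
    est = GompertzGasModel(theta0=theta0)
    est.fit(curve.times, y)
    return est.fit_result_
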