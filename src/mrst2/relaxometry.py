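"""Per-subject T2 estimation.

Metabolite amplitudes a(TE) are fitted with the two-parameter
mono-exponential ``S0 * exp(-TE/T2)`` by trust-region nonlinear least
squares; unsuppressed-water integrals are fitted with the
two-compartment biexponential

    S(TE) = S0 * [(1 - f) * exp(-TE/T2_tissue) + f * exp(-TE/T2_CSF)]

where the cerebrospinal-fluid T2 is held fixed (default 1500 ms) and
the free parameters are S0, the tissue-water T2 and the CSF fraction f
of the voxel.  Fits are unweighted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator

__all__ = [
    "T2Fit",
    "WaterFit",
    "MonoExponentialT2",
    "BiexponentialWaterModel",
    "fit_monoexp",
    "fit_biexp_water",
    "goodness_of_fit",
    "FitFailure",
]


class FitFailure(RuntimeError):
    """Nonlinear fit did not converge from any start of the restart grid."""


@dataclass
class T2Fit:
    s0: float
    t2: float
    r_squared: float
    cov: np.ndarray | None
    residuals: np.ndarray
    te: np.ndarray
    exact: bool = False  # two-point closed-form solution

    @property
    def max_fractional_residual(self) -> float:
        return float(np.max(np.abs(self.residuals)) / self.s0)


@dataclass
class WaterFit:
    s0: float
    t2_tissue: float
    f_csf: float
    t2_csf_fixed: float
    r_squared: float
    residuals: np.ndarray


def _monoexp(te, s0, t2):
    return s0 * np.exp(-te / t2)


def _r_squared(y, yhat):
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    ss_res = float(np.sum((y - yhat) ** 2))
    if ss_tot == 0.0:
        return np.nan
    return 1.0 - ss_res / ss_tot


class MonoExponentialT2(BaseEstimator):
    """Two-parameter mono-exponential decay fit, sklearn-style.

    ``fit(te_ms, amplitudes)`` sets ``s0_``, ``t2_`` (ms),
    ``r_squared_``, ``cov_`` (2x2, from the Jacobian), ``residuals_``
    and ``exact_`` (True for the two-point closed form).  Starting
    values come from the closed-form two-point T2 of the first and last
    TE; on failure a restart grid of T2 starts is tried before
    :class:`FitFailure` is raised.
    """

    def __init__(self, restart_t2_grid: tuple[float, ...] = (50.0, 100.0, 200.0, 400.0),
                 t2_bounds: tuple[float, float] = (0.1, 1e5)):
        self.restart_t2_grid = restart_t2_grid
        self.t2_bounds = t2_bounds

    def fit(self, te_ms, amplitudes):
        te = np.asarray(te_ms, float)
        y = np.asarray(amplitudes, float)
        if te.shape != y.shape or te.ndim != 1:
            raise ValueError("te_ms and amplitudes must be 1-D arrays of equal length")
        if len(te) < 2:
            raise ValueError("at least two points are required")
        if len(te) == 2:
            if np.any(y <= 0) or y[0] == y[1]:
                raise ValueError("two-point solution needs distinct positive amplitudes")
            t2 = (te[1] - te[0]) / np.log(y[0] / y[1])
            s0 = y[0] * np.exp(te[0] / t2)
            self._set(s0, t2, te, y, cov=None, exact=True)
            return self

        # closed-form two-point T2 from first/last TE, S0 inflated back to TE=0
        i0, i1 = np.argmin(te), np.argmax(te)
        if y[i0] > 0 and y[i1] > 0 and y[i0] != y[i1]:
            t2_init = (te[i1] - te[i0]) / np.log(y[i0] / y[i1])
            t2_init = float(np.clip(t2_init, *self.t2_bounds))
        else:
            t2_init = 150.0
        s0_init = max(y[i0], 1e-12) * np.exp(te[i0] / t2_init)

        starts = [(s0_init, t2_init)] + [(s0_init, t) for t in self.restart_t2_grid]
        for s0g, t2g in starts:
            try:
                popt, pcov = curve_fit(
                    _monoexp, te, y, p0=(s0g, t2g),
                    bounds=((0.0, self.t2_bounds[0]), (np.inf, self.t2_bounds[1])),
                    maxfev=10000,
                )
            except (RuntimeError, ValueError):
                continue
            self._set(popt[0], popt[1], te, y, cov=pcov, exact=False)
            return self
        raise FitFailure("mono-exponential fit failed from every start")

    def _set(self, s0, t2, te, y, cov, exact):
        yhat = _monoexp(te, s0, t2)
        self.s0_ = float(s0)
        self.t2_ = float(t2)
        self.cov_ = cov
        self.residuals_ = y - yhat
        self.r_squared_ = 1.0 if exact else _r_squared(y, yhat)
        self.exact_ = exact
        self.te_ = te

    def result(self) -> T2Fit:
        return T2Fit(s0=self.s0_, t2=self.t2_, r_squared=self.r_squared_, cov=self.cov_,
                     residuals=self.residuals_, te=self.te_, exact=self.exact_)


class BiexponentialWaterModel(BaseEstimator):
    """Tissue/CSF water decay fit with fixed CSF T2.

    Free parameters: S0, T2 of tissue water and the CSF fraction
    (box-constrained to [0, 1]).  ``t2_csf`` defaults to 1500 ms.
    """

    def __init__(self, t2_csf: float = 1500.0):
        self.t2_csf = t2_csf

    def _model(self, te, s0, t2_t, f):
        return s0 * ((1 - f) * np.exp(-te / t2_t) + f * np.exp(-te / self.t2_csf))

    def fit(self, te_ms, integrals):
        te = np.asarray(te_ms, float)
        y = np.asarray(integrals, float)
        if te.shape != y.shape or len(te) < 4:
            raise ValueError("need >= 4 (TE, integral) points")
        if np.all(y == 0):
            raise ValueError("degenerate all-zero water data")
        if self.t2_csf <= 0:
            raise ValueError("t2_csf must be positive")

        s0_init = float(np.max(y))
        # tail (TE >> tissue T2) isolates the CSF term
        tail = te > 5 * 100.0
        f_init = 0.15
        if tail.any() and s0_init > 0:
            f_init = float(np.clip(
                np.max(y[tail] / (s0_init * np.exp(-te[tail] / self.t2_csf))), 0.01, 0.9))
        popt, pcov = curve_fit(
            self._model, te, y, p0=(s0_init, 60.0, f_init),
            bounds=((0.0, 1.0, 0.0), (np.inf, self.t2_csf * 0.99, 1.0)),
            maxfev=20000,
        )
        yhat = self._model(te, *popt)
        self.s0_, self.t2_tissue_, self.f_csf_ = map(float, popt)
        self.cov_ = pcov
        self.residuals_ = y - yhat
        self.r_squared_ = _r_squared(y, yhat)
        self.te_ = te
        return self

    def result(self) -> WaterFit:
        return WaterFit(s0=self.s0_, t2_tissue=self.t2_tissue_, f_csf=self.f_csf_,
                        t2_csf_fixed=self.t2_csf, r_squared=self.r_squared_,
                        residuals=self.residuals_)


def fit_monoexp(te_ms, amplitudes) -> T2Fit:
    """Functional wrapper: mono-exponential T2 fit returning :class:`T2Fit`."""
    return MonoExponentialT2().fit(te_ms, amplitudes).result()


def fit_biexp_water(te_ms, integrals, t2_csf_fixed: float = 1500.0) -> WaterFit:
    """Functional wrapper: biexponential water fit returning :class:`WaterFit`."""
    return BiexponentialWaterModel(t2_csf=t2_csf_fixed).fit(te_ms, integrals).result()


def goodness_of_fit(fit: T2Fit) -> tuple[float, float]:
    """(R^2, max fractional residual) of a completed fit.

    The max fractional residual ``max_i |a_i - yhat_i| / S0`` is the
    noise bound handed to the Monte Carlo TE assessment.
    """
    return fit.r_squared, fit.max_fractional_residual
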