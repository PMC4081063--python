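"""Single-site binding isotherm fitting and biphasic-deviation detection.

The workhorse is the hyperbolic single-site model

    P([T]) = P_min + (P_max - P_min) * [T] / ([T] + K_D)

with [T] the *total* TBP concentration (probe DNA is dilute relative to
K_D, so free ~ total).  ``SingleSiteBindingModel(conc, response).fit()``
returns a results object with estimates, standard errors, AIC and a
``summary()`` table.

Titrations on constructs with flanking DNA can be biphasic: hyperbolic
rise at low concentration, then a sharp decline to a lower plateau as
cooperative non-specific binding outcompetes the specific complex.
``detect_biphasic`` fits both the single-site model and a
rise-minus-Hill-decline composite and flags the curve as biphasic when the
composite wins by more than 10 AIC units AND the fitted decline amplitude
exceeds 3x the residual noise.  The composite model and decision rule are
diagnostics of this package, not a mechanistic fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import lmfit
import numpy as np
import pandas as pd

from .errors import FitError, InputError

MIN_FIT_ROWS = 6
MIN_BIPHASIC_ROWS = 8
_RSS_FLOOR_PER_POINT = 1e-8**2  # numerical floor so noiseless fits can't win on log(0)


def single_site(conc, p_min: float, p_max: float, kd: float):
    """Hyperbolic single-site binding curve."""
    conc = np.asarray(conc, dtype=float)
    return p_min + (p_max - p_min) * conc / (conc + kd)


def _validate_series(conc: np.ndarray, response: np.ndarray, min_rows: int) -> None:
    if conc.shape != response.shape or conc.ndim != 1:
        raise InputError("concentration and response must be matching 1-D arrays")
    if conc.size < min_rows:
        raise InputError(f"need at least {min_rows} titration rows, got {conc.size}")
    if (conc < 0).any():
        raise InputError("concentrations must be >= 0")


class SingleSiteBindingModel:
    """Weighted nonlinear least squares for the single-site isotherm.

    Initialisation is deterministic: p_min from the first response, p_max
    from the last, K_D from the concentration whose response is nearest the
    half-amplitude point.
    """

    def __init__(self, conc, response, sigma=None) -> None:
        self.conc = np.asarray(conc, dtype=float)
        self.response = np.asarray(response, dtype=float)
        _validate_series(self.conc, self.response, MIN_FIT_ROWS)
        self.sigma = None if sigma is None else np.asarray(sigma, dtype=float)
        if self.sigma is not None and (self.sigma <= 0).any():
            raise InputError("sigma values must be positive")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SingleSiteBindingModel":
        sigma = df["sigma"].to_numpy() if "sigma" in df.columns else None
        return cls(df["conc_nM"].to_numpy(), df["proximity_ratio"].to_numpy(), sigma)

    def _initial_params(self) -> lmfit.Parameters:
        c, y = self.conc, self.response
        p_min0, p_max0 = float(y[0]), float(y[-1])
        half = p_min0 + 0.5 * (p_max0 - p_min0)
        pos = c[c > 0]
        kd0 = float(c[np.argmin(np.abs(y - half))]) or (float(pos.min()) if pos.size else 1.0)
        params = lmfit.Parameters()
        params.add("p_min", value=p_min0)
        params.add("p_max", value=p_max0)
        params.add("kd", value=max(kd0, 1e-9), min=1e-12)
        return params

    def fit(self) -> "SingleSiteBindingResults":
        weights = None if self.sigma is None else 1.0 / self.sigma

        def residual(params: lmfit.Parameters) -> np.ndarray:
            resid = single_site(self.conc, params["p_min"].value,
                                params["p_max"].value, params["kd"].value) - self.response
            return resid if weights is None else resid * weights

        try:
            out = lmfit.minimize(residual, self._initial_params(), method="leastsq")
        except Exception as exc:  # pragma: no cover
            raise FitError(f"isotherm fit failed: {exc}") from exc
        if not out.success:
            raise FitError(f"isotherm fit did not converge: {out.message}")
        return SingleSiteBindingResults(self, out)


class SingleSiteBindingResults:
    """Estimates and diagnostics from a single-site isotherm fit."""

    def __init__(self, model: SingleSiteBindingModel, minimizer_result) -> None:
        self.model = model
        self._result = minimizer_result
        p = minimizer_result.params
        self.p_min = float(p["p_min"].value)
        self.p_max = float(p["p_max"].value)
        self.kd_nM = float(p["kd"].value)
        self.bse = {
            name: (None if p[name].stderr is None else float(p[name].stderr))
            for name in ("p_min", "p_max", "kd")
        }
        self.residuals = minimizer_result.residual
        self.residual_sumsq = float(np.sum(minimizer_result.residual**2))
        self.aic = float(minimizer_result.aic)
        self.nobs = model.conc.size

    @property
    def amplitude(self) -> float:
        return self.p_max - self.p_min

    def predict(self, conc=None) -> np.ndarray:
        c = self.model.conc if conc is None else np.asarray(conc, dtype=float)
        return single_site(c, self.p_min, self.p_max, self.kd_nM)

    def to_dict(self) -> dict:
        return {
            "p_min": self.p_min,
            "p_max": self.p_max,
            "kd_nM": self.kd_nM,
            "kd_stderr_nM": self.bse["kd"],
            "amplitude": self.amplitude,
            "residual_sumsq": self.residual_sumsq,
            "aic": self.aic,
            "n_points": int(self.nobs),
        }

    def summary(self) -> str:
        lines = [
            f"Single-site binding fit ({self.nobs} points)",
            f"{'param':<10}{'value':>14}{'stderr':>14}",
        ]
        for name, val in (("p_min", self.p_min), ("p_max", self.p_max), ("kd_nM", self.kd_nM)):
            err = self.bse["kd" if name == "kd_nM" else name]
            err_s = "n/a" if err is None else f"{err:.4g}"
            lines.append(f"{name:<10}{val:>14.6g}{err_s:>14}")
        lines.append(f"RSS = {self.residual_sumsq:.4g}, AIC = {self.aic:.2f}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Data and fitted curve on a log-x axis (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c = self.model.conc
        grid = np.geomspace(max(c[c > 0].min(), 1e-3), c.max(), 200) if (c > 0).any() else c
        ax.plot(c, self.model.response, "o", label="data")
        ax.plot(grid, self.predict(grid), "-", label=f"Kd = {self.kd_nM:.2g} nM")
        ax.set_xscale("log")
        ax.set_xlabel("[TBP] total (nM)")
        ax.set_ylabel("proximity ratio")
        ax.legend()
        return ax


def fit_single_site(series: pd.DataFrame) -> SingleSiteBindingResults:
    """Fit a titration table (conc_nM, proximity_ratio[, sigma])."""
    return SingleSiteBindingModel.from_dataframe(series).fit()


def _composite(conc, p_min, p_max, kd, a_dec, midpoint, hill):
    rise = single_site(conc, p_min, p_max, kd)
    conc = np.asarray(conc, dtype=float)
    with np.errstate(invalid="ignore"):
        decline = np.where(
            conc > 0, a_dec * conc**hill / (conc**hill + midpoint**hill), 0.0
        )
    return rise - decline


@dataclass(frozen=True)
class BiphasicAssessment:
    """Outcome of the biphasic-deviation diagnostic."""

    is_biphasic: bool
    kd_rise_nM: float
    rise_amplitude: float
    decline_midpoint_nM: float
    decline_amplitude: float
    decline_steepness: float
    delta_aic: float
    residual_noise: float


def _floored_aic(rss: float, n: int, k: int) -> float:
    rss = max(rss, n * _RSS_FLOOR_PER_POINT)
    return n * np.log(rss / n) + 2 * k


def detect_biphasic(series: pd.DataFrame) -> BiphasicAssessment:
    """Compare single-site and rise-plus-decline fits of a titration.

    Requires >= 8 rows spanning >= 2 decades of positive concentration.
    """
    conc = series["conc_nM"].to_numpy(dtype=float)
    y = series["proximity_ratio"].to_numpy(dtype=float)
    _validate_series(conc, y, MIN_BIPHASIC_ROWS)
    pos = conc[conc > 0]
    if pos.size < 2 or pos.max() / pos.min() < 100:
        raise InputError("biphasic detection needs >= 2 decades of concentration span")

    single_res = SingleSiteBindingModel(conc, y).fit()

    data_range = float(y.max() - y.min())
    params = lmfit.Parameters()
    params.add("p_min", value=single_res.p_min)
    params.add("p_max", value=max(single_res.p_max, float(y.max())))
    params.add("kd", value=max(single_res.kd_nM, 1e-9), min=1e-12)
    peak_conc = float(conc[np.argmax(y)])
    params.add("a_dec", value=max(float(y.max() - y[-1]), 1e-4),
               min=0.0, max=max(1.5 * data_range, 1e-3))
    params.add("midpoint", value=max(3.0 * peak_conc, 1e-6), min=1e-9)
    params.add("hill", value=2.0, min=0.5, max=6.0)

    def residual(p: lmfit.Parameters) -> np.ndarray:
        return _composite(conc, p["p_min"].value, p["p_max"].value, p["kd"].value,
                          p["a_dec"].value, p["midpoint"].value, p["hill"].value) - y

    out = lmfit.minimize(residual, params, method="leastsq")
    # lmfit can flag success=False purely because error bars were not
    # estimable on a near-degenerate composite; only the residuals matter
    # for the AIC comparison, so require finiteness instead.
    if not np.isfinite(out.residual).all():
        raise FitError(f"composite fit did not converge: {out.message}")

    n = conc.size
    rss_comp = float(np.sum(out.residual**2))
    aic_single = _floored_aic(single_res.residual_sumsq, n, 3)
    aic_comp = _floored_aic(rss_comp, n, 6)
    delta_aic = aic_single - aic_comp
    noise = float(np.sqrt(max(rss_comp, n * _RSS_FLOOR_PER_POINT) / max(n - 6, 1)))
    a_dec = float(out.params["a_dec"].value)
    return BiphasicAssessment(
        is_biphasic=bool(delta_aic > 10.0 and a_dec > 3.0 * noise),
        kd_rise_nM=float(out.params["kd"].value),
        rise_amplitude=float(out.params["p_max"].value - out.params["p_min"].value),
        decline_midpoint_nM=float(out.params["midpoint"].value),
        decline_amplitude=a_dec,
        decline_steepness=float(out.params["hill"].value),
        delta_aic=float(delta_aic),
        residual_noise=noise,
    )
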