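"""Branched association/dissociation kinetics and competitor-chase analysis.

State space: {unbound} plus one state per active register, under the
single-occupancy approximation appropriate for a minimal TATA fragment.
Association to every register proceeds with a uniform pseudo-first-order
rate k_on * [TBP]; dissociation is k_off_specific from the TATA register and
k_off_nonspecific elsewhere; sliding hops between bp-adjacent registers at
k_slide, with hop rates biased by sqrt(k_off_i / k_off_j) so that sliding
satisfies detailed balance against the register well depths and leaves the
equilibrium distribution unchanged while opening a dissociation-free route
to the stable site.  The chase experiment incubates the DNA with TBP, then floods the
reaction with unlabeled competitor, modelled as an instantaneous and
irreversible shut-off of re-association to the labeled DNA (the competitor
is a ~2000-fold sink).  The observable is the ensemble-mean proximity ratio
of the state distribution versus time, which for k_slide = 0 is an exact
multi-exponential with rates equal to the k_off values.

Decay fitting follows the statsmodels Model/Results pattern:
``ExponentialDecayModel(times, values, phases=2).fit()`` returns a
``DecayResults`` carrying rates, amplitudes, standard errors, AIC and a
``summary()`` table.  Initialisation is deterministic and documented: rate
guesses are a log-spaced decade split of the observation window
(k_j = 3 * 10**j / span), amplitudes an even split of the endpoint
difference, offset the final value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import lmfit
import numpy as np
import pandas as pd
from scipy.linalg import expm

from . import fret as _fret
from .errors import FitError, InputError, UndefinedResultError
from .lattice import LatticeConfiguration, LatticeSpec


@dataclass(frozen=True)
class KineticScheme:
    """Rate parameters of the branched binding scheme on one construct."""

    lattice: LatticeSpec
    k_on_per_M_s: float = 2e6
    k_off_specific_per_s: float = 0.0014
    k_off_nonspecific_per_s: float = 0.02
    k_slide_per_s: float = 0.0
    tbp_nM: float = 30.0
    competitor_nM: float = 2000.0
    incubation_s: float = 60.0
    observation_s: float = 1800.0

    def __post_init__(self) -> None:
        for name in (
            "k_on_per_M_s",
            "k_off_specific_per_s",
            "k_off_nonspecific_per_s",
            "k_slide_per_s",
            "tbp_nM",
            "competitor_nM",
        ):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be >= 0")
        if self.incubation_s < 0 or self.observation_s <= 0:
            raise InputError("incubation must be >= 0 and observation > 0")

    @property
    def states(self) -> tuple[int, ...]:
        """Register indices of the bound states (state 0 is unbound)."""
        return self.lattice.active_registers


def build_rate_matrix(scheme: KineticScheme, association: bool = True) -> np.ndarray:
    """Generator matrix A with A[i, j] = rate from state j to state i.

    Columns sum to zero (probability conservation); dp/dt = A @ p.
    State 0 is unbound; states 1..m are the active registers in bp order.
    [TBP] is treated as constant (pseudo-first-order) during incubation.
    """
    regs = scheme.states
    m = len(regs)
    a = np.zeros((m + 1, m + 1))
    k_on = scheme.k_on_per_M_s * scheme.tbp_nM * 1e-9 if association else 0.0
    pos_to_state = {reg: i + 1 for i, reg in enumerate(regs)}

    def off_rate(reg: int) -> float:
        return (
            scheme.k_off_specific_per_s
            if reg == scheme.lattice.specific_register
            else scheme.k_off_nonspecific_per_s
        )

    for reg in regs:
        s = pos_to_state[reg]
        a[s, 0] += k_on
        a[0, s] += off_rate(reg)
        if scheme.k_slide_per_s > 0:
            # sliding must respect detailed balance against the register
            # well depths (stationary p_i ~ k_on / k_off_i), so hops into
            # the more stable register are proportionally faster:
            # rate(i -> j) = k_slide * sqrt(k_off_i / k_off_j).
            for nb in (reg - 1, reg + 1):
                if nb in pos_to_state:
                    a[pos_to_state[nb], s] += scheme.k_slide_per_s * np.sqrt(
                        off_rate(reg) / max(off_rate(nb), 1e-300)
                    )
    np.fill_diagonal(a, a.diagonal() - a.sum(axis=0))
    return a


def propagate(a: np.ndarray, p0: np.ndarray, t: float) -> np.ndarray:
    """Evolve a probability vector for time t under generator a."""
    return expm(a * t) @ p0


def state_proximities(
    scheme: KineticScheme,
    bend: Optional[_fret.BendModel] = None,
    fret_params: Optional[_fret.FretParameters] = None,
    corrected: bool = True,
) -> np.ndarray:
    """Proximity ratio of each kinetic state (unbound first)."""
    bend = bend or _fret.BendModel()
    fret_params = fret_params or _fret.FretParameters()
    lat = scheme.lattice
    p = [_fret.configuration_proximity(lat, LatticeConfiguration(()), bend, fret_params, corrected)]
    for reg in scheme.states:
        p.append(
            _fret.configuration_proximity(
                lat, LatticeConfiguration((reg,)), bend, fret_params, corrected
            )
        )
    return np.array(p)


@dataclass(frozen=True)
class ChaseTrace:
    """Time course of the mean proximity ratio after competitor addition."""

    times: np.ndarray
    proximity_ratio: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.proximity_ratio, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise InputError("times and proximity_ratio must be matching 1-D arrays")
        if t.size >= 2 and not (np.diff(t) > 0).all():
            raise InputError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "proximity_ratio", y)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "proximity_ratio": self.proximity_ratio})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ChaseTrace":
        return cls(df["time_s"].to_numpy(), df["proximity_ratio"].to_numpy())


def simulate_chase(
    scheme: KineticScheme,
    bend: Optional[_fret.BendModel] = None,
    fret_params: Optional[_fret.FretParameters] = None,
    bin_s: float = 1.0,
) -> ChaseTrace:
    """Deterministic (master-equation) simulation of the chase protocol.

    All-unbound initial condition, association active for ``incubation_s``,
    then association shut off (competitor sink) and the mean proximity ratio
    recorded on equal ``bin_s`` time bins for ``observation_s``.
    """
    if bin_s <= 0:
        raise InputError("bin_s must be positive")
    m = len(scheme.states)
    p = np.zeros(m + 1)
    p[0] = 1.0
    if scheme.incubation_s > 0:
        p = propagate(build_rate_matrix(scheme, association=True), p, scheme.incubation_s)
    a_chase = build_rate_matrix(scheme, association=False)
    step = expm(a_chase * bin_s)
    n_bins = int(np.floor(scheme.observation_s / bin_s)) + 1
    p_states = state_proximities(scheme, bend, fret_params)
    times = np.arange(n_bins) * bin_s
    means = np.empty(n_bins)
    for k in range(n_bins):
        means[k] = float(p @ p_states)
        p = step @ p
    return ChaseTrace(times, means)


def gillespie_occupancy(
    scheme: KineticScheme,
    t_grid: np.ndarray,
    n_traj: int,
    seed: int,
    association: bool = True,
    p0: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Monte-Carlo state-probability estimates on a time grid.

    Vectorised Gillespie over ``n_traj`` independent trajectories of the
    continuous-time Markov chain; returns an array (len(t_grid), n_states)
    of occupation frequencies.  Used as a stochastic oracle for the
    matrix-exponential propagation.
    """
    rng = np.random.default_rng(seed)
    a = build_rate_matrix(scheme, association=association)
    n_states = a.shape[0]
    rates_out = -np.diag(a)
    jump = a.copy()
    np.fill_diagonal(jump, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        jump_p = np.where(rates_out[None, :] > 0, jump / rates_out[None, :], 0.0)
    cum_jump = np.cumsum(jump_p, axis=0)  # cum over destination, per source column

    t_grid = np.asarray(t_grid, dtype=float)
    t_max = t_grid.max()
    if p0 is None:
        state = np.zeros(n_traj, dtype=np.int64)
    else:
        state = rng.choice(n_states, size=n_traj, p=p0)
    t_now = np.zeros(n_traj)
    out = np.zeros((t_grid.size, n_states))
    recorded = np.zeros(n_traj, dtype=np.int64)  # next grid index to record

    active = np.arange(n_traj)
    while active.size:
        lam = rates_out[state[active]]
        dt = np.where(lam > 0, rng.exponential(1.0, size=active.size) / np.where(lam > 0, lam, 1.0), np.inf)
        t_next = t_now[active] + dt
        # record every grid point passed before the next jump
        for idx, traj in enumerate(active):
            k = recorded[traj]
            while k < t_grid.size and t_grid[k] <= t_next[idx]:
                out[k, state[traj]] += 1
                k += 1
            recorded[traj] = k
        t_now[active] = t_next
        jumping = np.isfinite(t_next) & (t_next <= t_max)
        jump_traj = active[jumping]
        if jump_traj.size:
            u = rng.random(jump_traj.size)
            cols = cum_jump[:, state[jump_traj]]
            state[jump_traj] = (u[None, :] < cols).argmax(axis=0)
        active = jump_traj
    return out / n_traj


def _decay_func(t: np.ndarray, offset: float, amplitudes: np.ndarray, rates: np.ndarray) -> np.ndarray:
    return offset + (amplitudes[:, None] * np.exp(-np.outer(rates, t))).sum(axis=0)


class ExponentialDecayModel:
    """One- or two-phase exponential decay, P(t) = offset + sum_k a_k exp(-k_k t).

    Parameters
    ----------
    times, values : array-like
        The chase trace; at least 8 points.
    phases : {1, 2}
        Number of exponential components.
    """

    def __init__(self, times, values, phases: int = 2) -> None:
        self.times = np.asarray(times, dtype=float)
        self.values = np.asarray(values, dtype=float)
        if self.times.size < 8:
            raise InputError("need at least 8 time points for a decay fit")
        if phases not in (1, 2):
            raise InputError("phases must be 1 or 2")
        self.phases = phases

    @classmethod
    def from_trace(cls, trace: ChaseTrace, phases: int = 2) -> "ExponentialDecayModel":
        return cls(trace.times, trace.proximity_ratio, phases=phases)

    def _initial_params(self) -> lmfit.Parameters:
        t, y = self.times, self.values
        span = max(t[-1] - t[0], np.finfo(float).tiny)
        total_amp = max(y[0] - y[-1], 1e-6)
        params = lmfit.Parameters()
        params.add("offset", value=float(y[-1]))
        for j in range(self.phases):
            params.add(f"a{j}", value=total_amp / self.phases, min=0.0)
            params.add(f"k{j}", value=3.0 * 10.0**j / span, min=0.0)
        return params

    def fit(self) -> "DecayResults":
        t, y = self.times, self.values

        def residual(params: lmfit.Parameters) -> np.ndarray:
            amps = np.array([params[f"a{j}"].value for j in range(self.phases)])
            rates = np.array([params[f"k{j}"].value for j in range(self.phases)])
            return _decay_func(t, params["offset"].value, amps, rates) - y

        try:
            out = lmfit.minimize(residual, self._initial_params(), method="leastsq")
        except Exception as exc:  # pragma: no cover - lmfit raises rarely
            raise FitError(f"decay fit failed: {exc}") from exc
        if not out.success:
            raise FitError(f"decay fit did not converge: {out.message}")
        return DecayResults(self, out)


class DecayResults:
    """Results of an exponential decay fit; phases are sorted fast-first."""

    def __init__(self, model: ExponentialDecayModel, minimizer_result) -> None:
        self.model = model
        self._result = minimizer_result
        params = minimizer_result.params
        comps = sorted(
            (
                (params[f"k{j}"].value, params[f"a{j}"].value,
                 params[f"k{j}"].stderr, params[f"a{j}"].stderr)
                for j in range(model.phases)
            ),
            reverse=True,
        )
        self.rates = np.array([c[0] for c in comps])
        self.amplitudes = np.array([c[1] for c in comps])
        self.rate_stderr = np.array([np.nan if c[2] is None else c[2] for c in comps])
        self.amplitude_stderr = np.array([np.nan if c[3] is None else c[3] for c in comps])
        self.offset = params["offset"].value
        self.offset_stderr = params["offset"].stderr
        self.residuals = minimizer_result.residual
        self.residual_sumsq = float(np.sum(minimizer_result.residual**2))
        self.aic = float(minimizer_result.aic)
        self.nobs = model.times.size

    @property
    def k_fast(self) -> float:
        return float(self.rates[0])

    @property
    def k_slow(self) -> float:
        return float(self.rates[-1])

    @property
    def a_fast(self) -> float:
        return float(self.amplitudes[0])

    @property
    def a_slow(self) -> float:
        return float(self.amplitudes[-1])

    @property
    def fast_fraction(self) -> float:
        """Mole fraction of the fast phase, a_fast / (a_fast + a_slow)."""
        if self.model.phases != 2:
            raise UndefinedResultError("fast_fraction requires a two-phase fit")
        total = self.a_fast + self.a_slow
        if total <= 0:
            raise UndefinedResultError("total decay amplitude is zero")
        return self.a_fast / total

    def predict(self, times=None) -> np.ndarray:
        t = self.model.times if times is None else np.asarray(times, dtype=float)
        return _decay_func(t, self.offset, self.amplitudes, self.rates)

    def to_dict(self) -> dict:
        d = {
            "phases": self.model.phases,
            "offset": self.offset,
            "residual_sumsq": self.residual_sumsq,
            "aic": self.aic,
            "n_points": int(self.nobs),
        }
        labels = ["fast", "slow"] if self.model.phases == 2 else ["single"]
        for lab, k, a, ks, as_ in zip(
            labels, self.rates, self.amplitudes, self.rate_stderr, self.amplitude_stderr
        ):
            d[f"k_{lab}_per_s"] = float(k)
            d[f"a_{lab}"] = float(a)
            d[f"k_{lab}_stderr"] = None if np.isnan(ks) else float(ks)
            d[f"a_{lab}_stderr"] = None if np.isnan(as_) else float(as_)
        if self.model.phases == 2:
            d["fast_fraction"] = self.fast_fraction
        return d

    def summary(self) -> str:
        lines = [
            f"Exponential decay fit ({self.model.phases} phase(s), "
            f"{self.nobs} points)",
            f"{'param':<12}{'value':>14}{'stderr':>14}",
        ]
        rows = [("offset", self.offset, self.offset_stderr)]
        labels = ["fast", "slow"] if self.model.phases == 2 else ["single"]
        for lab, k, a, ks, as_ in zip(
            labels, self.rates, self.amplitudes, self.rate_stderr, self.amplitude_stderr
        ):
            rows.append((f"k_{lab} [1/s]", k, ks))
            rows.append((f"a_{lab}", a, as_))
        for name, val, err in rows:
            err_s = "n/a" if err is None or (isinstance(err, float) and np.isnan(err)) else f"{err:.4g}"
            lines.append(f"{name:<12}{val:>14.6g}{err_s:>14}")
        lines.append(f"RSS = {self.residual_sumsq:.4g}, AIC = {self.aic:.2f}")
        if self.model.phases == 2:
            lines.append(f"fast fraction = {self.fast_fraction:.4f}")
        return "\n".join(lines)


def fit_exponential(trace: ChaseTrace, phases: int = 2) -> DecayResults:
    """Convenience wrapper: fit a chase trace with 1 or 2 decay phases."""
    return ExponentialDecayModel.from_trace(trace, phases=phases).fit()


def fast_fraction(fit: DecayResults) -> float:
    """Fast-phase mole fraction of a two-phase decay fit."""
    return fit.fast_fraction
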