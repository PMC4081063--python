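"""Diffusing-molecule photon-burst simulation and histogram analysis.

Freely diffusing labeled DNA produces well-separated photon bursts; each
burst is assigned to one species of the mixture (by weight), given a total
detected photon count from a lognormal burst-size distribution, and its
acceptor count drawn binomially with the apparent per-photon acceptor
probability implied by the species' FRET efficiency and the detection
artifacts (gamma, crosstalk, direct excitation).  Poisson background counts
are added to both channels.  Per-burst proximity ratios use the
gamma-uncorrected convention P = A / (D + A), the single-molecule standard.

Downstream analysis mirrors the classic workflow: total-photon burst
selection, relative-frequency histograms, a single-Gaussian width fit that
excludes the donor-only peak (molecules with a missing or inactive
acceptor, centered near P = 0), and per-concentration titration summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from . import fret as _fret
from .errors import FitError, InputError
from .lattice import (
    BindingEnergetics,
    LatticeSpec,
    configuration_weight,
    enumerate_configurations,
)

DEFAULT_BINS = 40
DEFAULT_RANGE = (-0.1, 1.1)
DEFAULT_DONOR_ONLY_BOUND = 0.05


@dataclass(frozen=True)
class SpeciesMixture:
    """FRET species present in solution.

    ``species`` holds (true proximity ratio, weight) pairs; weights plus
    ``donor_only_fraction`` must sum to 1.  The "true" proximity ratio is
    on the ideal (gamma = 1, artifact-free) scale, i.e. it equals the FRET
    efficiency of the species.
    """

    species: tuple[tuple[float, float], ...]
    donor_only_fraction: float = 0.0

    def __post_init__(self) -> None:
        species = tuple((float(p), float(w)) for p, w in self.species)
        object.__setattr__(self, "species", species)
        if not 0.0 <= self.donor_only_fraction <= 1.0:
            raise InputError("donor_only_fraction must be in [0, 1]")
        for p, w in species:
            if not 0.0 <= p <= 1.0:
                raise InputError(f"species proximity ratio {p} outside [0, 1]")
            if w < 0:
                raise InputError("species weights must be >= 0")
        total = sum(w for _, w in species) + self.donor_only_fraction
        if abs(total - 1.0) > 1e-6:
            raise InputError(f"species weights + donor_only must sum to 1, got {total}")

    @classmethod
    def from_occupancy(
        cls,
        lattice: LatticeSpec,
        energetics: BindingEnergetics,
        bend: _fret.BendModel,
        fret_params: _fret.FretParameters,
        free_tbp_nM: float,
        donor_only_fraction: float = 0.0,
    ) -> "SpeciesMixture":
        """Species from the equilibrium configuration distribution.

        Each lattice configuration becomes one species whose true proximity
        ratio is its ideal (corrected) value.
        """
        configs = enumerate_configurations(lattice)
        weights = np.array(
            [configuration_weight(c, lattice, energetics, free_tbp_nM) for c in configs]
        )
        weights = weights / weights.sum() * (1.0 - donor_only_fraction)
        species = tuple(
            (_fret.configuration_proximity(lattice, c, bend, fret_params, corrected=True), w)
            for c, w in zip(configs, weights)
        )
        return cls(species, donor_only_fraction)


@dataclass(frozen=True)
class BurstSet:
    """Photon counts per burst, and the seed that generated them."""

    donor: np.ndarray
    acceptor: np.ndarray
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        d = np.asarray(self.donor, dtype=np.int64)
        a = np.asarray(self.acceptor, dtype=np.int64)
        if d.shape != a.shape or d.ndim != 1:
            raise InputError("donor and acceptor must be matching 1-D count arrays")
        if (d < 0).any() or (a < 0).any():
            raise InputError("photon counts must be non-negative")
        object.__setattr__(self, "donor", d)
        object.__setattr__(self, "acceptor", a)

    def __len__(self) -> int:
        return self.donor.size

    @property
    def total(self) -> np.ndarray:
        return self.donor + self.acceptor

    @property
    def proximity_ratios(self) -> np.ndarray:
        """Per-burst gamma-uncorrected proximity ratio A / (D + A)."""
        tot = self.total
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, self.acceptor / tot, 0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "burst_id": np.arange(len(self)),
                "donor_counts": self.donor,
                "acceptor_counts": self.acceptor,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, seed: Optional[int] = None) -> "BurstSet":
        return cls(df["donor_counts"].to_numpy(), df["acceptor_counts"].to_numpy(), seed)


def simulate_bursts(
    mixture: SpeciesMixture,
    n_bursts: int,
    fret_params: Optional[_fret.FretParameters] = None,
    mean_burst_size: float = 60.0,
    sigma_log: float = 0.5,
    background_donor: float = 0.0,
    background_acceptor: float = 0.0,
    seed: int = 0,
) -> BurstSet:
    """Draw a reproducible set of shot-noise-limited photon bursts.

    Burst sizes are lognormal with the given arithmetic mean; the acceptor
    count of each burst is binomial with the apparent acceptor probability
    of its species; backgrounds are Poisson counts per burst and channel.
    """
    if n_bursts < 1:
        raise InputError("n_bursts must be >= 1")
    fret_params = fret_params or _fret.FretParameters()
    rng = np.random.default_rng(seed)

    probs = [w for _, w in mixture.species] + [mixture.donor_only_fraction]
    e_values = [p for p, _ in mixture.species] + [0.0]
    p_app = np.array([_fret.apparent_acceptor_probability(e, fret_params) for e in e_values])
    which = rng.choice(len(probs), size=n_bursts, p=np.asarray(probs) / np.sum(probs))

    mu = np.log(mean_burst_size) - 0.5 * sigma_log**2
    sizes = np.maximum(1, np.rint(rng.lognormal(mu, sigma_log, size=n_bursts))).astype(np.int64)
    acceptor = rng.binomial(sizes, p_app[which])
    donor = sizes - acceptor
    if background_donor > 0:
        donor = donor + rng.poisson(background_donor, size=n_bursts)
    if background_acceptor > 0:
        acceptor = acceptor + rng.poisson(background_acceptor, size=n_bursts)
    return BurstSet(donor, acceptor, seed)


def select_bursts(bursts: BurstSet, threshold: int) -> BurstSet:
    """Retain bursts with at least ``threshold`` total photons."""
    if threshold < 0:
        raise InputError("threshold must be >= 0")
    keep = bursts.total >= threshold
    return BurstSet(bursts.donor[keep], bursts.acceptor[keep], bursts.seed)


@dataclass(frozen=True)
class HistogramResult:
    """Relative-frequency proximity-ratio histogram."""

    bin_edges: np.ndarray
    rel_freq: np.ndarray
    n_bursts: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "rel_freq": self.rel_freq,
            }
        )


def proximity_histogram(
    bursts: BurstSet,
    bins: int = DEFAULT_BINS,
    hist_range: tuple[float, float] = DEFAULT_RANGE,
) -> HistogramResult:
    """Relative-frequency histogram of per-burst proximity ratios."""
    if len(bursts) < 1:
        raise InputError("cannot histogram an empty burst set")
    counts, edges = np.histogram(bursts.proximity_ratios, bins=bins, range=hist_range)
    return HistogramResult(edges, counts / counts.sum(), len(bursts))


@dataclass(frozen=True)
class GaussianFit:
    """Single-Gaussian description of the FRET-active population."""

    mean: float
    width: float
    amplitude: float
    donor_only_exclusion_bound: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise InputError("Gaussian width must be positive")


def _gaussian(x: np.ndarray, amp: float, mu: float, sigma: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def fit_width(
    hist: HistogramResult,
    exclude_below: float = DEFAULT_DONOR_ONLY_BOUND,
) -> GaussianFit:
    """Least-squares single-Gaussian fit above the donor-only exclusion bound."""
    centers = hist.bin_centers
    mask = centers > exclude_below
    x, y = centers[mask], hist.rel_freq[mask]
    if np.count_nonzero(y) < 5:
        raise FitError("fewer than 5 occupied bins above the exclusion bound")
    w = y / y.sum()
    mu0 = float(np.sum(w * x))
    sig0 = float(np.sqrt(np.sum(w * (x - mu0) ** 2))) or (x[1] - x[0])
    try:
        popt, _ = curve_fit(
            _gaussian,
            x,
            y,
            p0=[float(y.max()), mu0, sig0],
            bounds=([0.0, x.min(), 1e-4], [np.inf, x.max(), np.inf]),
            maxfev=10_000,
        )
    except RuntimeError as exc:
        raise FitError(f"Gaussian width fit failed: {exc}") from exc
    return GaussianFit(float(popt[1]), float(popt[2]), float(popt[0]), exclude_below)


def titration_summary(
    burst_sets: Sequence[BurstSet],
    concentrations: Iterable[float],
    threshold: int = 0,
    bins: int = DEFAULT_BINS,
    exclude_below: float = DEFAULT_DONOR_ONLY_BOUND,
) -> pd.DataFrame:
    """Whole-population mean proximity ratio and Gaussian width per point.

    The mean includes every selected burst (donor-only included, matching
    the whole-population averaging convention); the width comes from the
    single-Gaussian fit excluding the donor-only peak.
    """
    concs = list(concentrations)
    if len(concs) < 2:
        raise InputError("a titration summary needs at least 2 concentrations")
    if len(concs) != len(burst_sets):
        raise InputError("burst_sets and concentrations differ in length")
    rows = []
    for conc, bs in zip(concs, burst_sets):
        sel = select_bursts(bs, threshold)
        hist = proximity_histogram(sel, bins=bins)
        width = fit_width(hist, exclude_below=exclude_below).width
        rows.append(
            {
                "conc_nM": conc,
                "mean_proximity_ratio": float(sel.proximity_ratios.mean()),
                "gaussian_width": width,
                "n_bursts": len(sel),
            }
        )
    return pd.DataFrame(rows)
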