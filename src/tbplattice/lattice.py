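"""Equilibrium statistical mechanics of TBP on a finite DNA lattice.

The model: a DNA of ``l`` base pairs offers one binding *register* per base
pair (the footprint center; it may overhang the ends with unchanged
affinity).  One register is the specific TATA-box site with dissociation
constant ``kd_specific``; every other register binds non-specifically with
``kd_nonspecific``.  Two bound proteins must keep a center separation of at
least the footprint ``n``; a pair at separation exactly ``n`` is "in
contact" and its statistical weight is multiplied by the cooperativity
``omega``.  The grand-canonical weight of a configuration at free ligand
concentration c is

    w(config) = prod_i (c / Kd_i) * omega**(number of contact pairs)

which for a homogeneous lattice with omega = 1 is the McGhee-von Hippel
hard-rod lattice gas.  Partition functions and occupancies are computed two
ways: brute-force enumeration (small lattices; the oracle) and a linear
transfer recursion in extended precision (any lattice).

Salt dependence follows a log-log (Record-style) law,
``Kd(salt) = Kd_ref * (salt / ref)**z``, with a steeper exponent for
non-specific sites so that non-specific binding is preferentially lost at
physiological ionic strength.  TFIIA is modelled as two multipliers: a
specificity boost on the TATA register and a suppression of non-specific
affinity.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import fret as _fret
from .errors import InputError, LatticeSizeError, NonConvergenceError

MAX_LATTICE_BP = 5000
MAX_ENUMERATION_REGISTERS = 30
_AUTO_ENUMERATION_REGISTERS = 16

TATA_MOTIF = "TATAWAWR"

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def _iupac_regex(motif: str) -> re.Pattern[str]:
    try:
        return re.compile("".join(f"[{_IUPAC[ch]}]" for ch in motif.upper()))
    except KeyError as exc:  # pragma: no cover - motifs are package constants
        raise InputError(f"invalid IUPAC code in motif: {exc}") from exc


def locate_specific_site(sequence: str, motif: str = TATA_MOTIF) -> Optional[int]:
    """Center bp index of the first forward-strand motif match, or None.

    The center of an even-length motif is the left-of-middle base,
    ``offset + (len(motif) - 1) // 2``.
    """
    seq = sequence.upper()
    bad = set(seq) - set(_IUPAC)
    if bad:
        raise InputError(f"invalid IUPAC DNA characters: {sorted(bad)}")
    match = _iupac_regex(motif).search(seq)
    if match is None:
        return None
    return match.start() + (len(motif) - 1) // 2


@dataclass(frozen=True)
class LatticeSpec:
    """A DNA construct seen as a 1-D binding lattice.

    Parameters
    ----------
    length_bp : int
        Number of base pairs (= number of candidate registers before
        removing ``inactive_registers``).
    sequence : str, optional
        IUPAC DNA sequence; if given its length must equal ``length_bp``.
    specific_register : int, optional
        0-based footprint-center index of the TATA box.
    footprint_bp : int
        Exclusion length n (default 8, the TATAWAWR length).
    contact_span_bp : int
        Furthest protein-DNA contact span m; stored for reporting.
    inactive_registers : frozenset[int]
        Registers removed from the lattice (e.g. a single-stranded
        extension that supports no duplex binding).
    """

    length_bp: int
    sequence: Optional[str] = None
    specific_register: Optional[int] = None
    footprint_bp: int = 8
    contact_span_bp: int = 8
    inactive_registers: frozenset = frozenset()
    dye_donor: Optional[_fret.DyeSite] = None
    dye_acceptor: Optional[_fret.DyeSite] = None
    name: str = ""

    def __post_init__(self) -> None:
        l = self.length_bp
        if not 1 <= l <= MAX_LATTICE_BP:
            raise InputError(f"length_bp must be in [1, {MAX_LATTICE_BP}], got {l}")
        if not 1 <= self.contact_span_bp <= self.footprint_bp <= max(l, self.footprint_bp):
            # m <= n is required; n may exceed l (a footprint larger than the
            # DNA still defines a single-occupancy lattice).
            raise InputError("need 1 <= contact_span_bp <= footprint_bp")
        if self.specific_register is not None and not 0 <= self.specific_register < l:
            raise InputError("specific_register outside the lattice")
        if self.sequence is not None:
            seq = self.sequence.upper()
            if len(seq) != l:
                raise InputError("sequence length does not match length_bp")
            bad = set(seq) - set(_IUPAC)
            if bad:
                raise InputError(f"invalid IUPAC DNA characters: {sorted(bad)}")
            object.__setattr__(self, "sequence", seq)
        object.__setattr__(self, "inactive_registers", frozenset(self.inactive_registers))
        for bad_reg in self.inactive_registers:
            if not 0 <= bad_reg < l:
                raise InputError("inactive register outside the lattice")
        for dye in (self.dye_donor, self.dye_acceptor):
            if dye is not None and not 0 <= dye.bp_index < l:
                raise InputError("dye position outside the lattice")

    @property
    def active_registers(self) -> tuple[int, ...]:
        return tuple(i for i in range(self.length_bp) if i not in self.inactive_registers)

    @classmethod
    def from_sequence(cls, sequence: str, specific_register="auto", **kwargs) -> "LatticeSpec":
        """Build a lattice from a sequence; 'auto' scans for TATAWAWR."""
        if specific_register == "auto":
            specific_register = locate_specific_site(sequence)
        return cls(length_bp=len(sequence), sequence=sequence,
                   specific_register=specific_register, **kwargs)


@dataclass(frozen=True)
class BindingEnergetics:
    """Affinities, cooperativity and their salt/TFIIA modifiers.

    ``kd_specific_nM`` (K1) and ``kd_nonspecific_nM`` (K2) are referenced to
    ``reference_salt_mM``.  ``cooperativity_omega`` multiplies the weight of
    every bound pair at contact separation (the K4/K5 enhancement).  TFIIA
    divides the specific Kd by ``tfiia_specificity_boost`` and multiplies
    the non-specific Kd by ``tfiia_ns_suppression``.
    """

    kd_specific_nM: float = 2.0
    kd_nonspecific_nM: float = 30.0
    cooperativity_omega: float = 20.0
    salt_mM: float = 50.0
    reference_salt_mM: float = 50.0
    salt_exponent_specific: float = 0.5
    salt_exponent_nonspecific: float = 2.5
    tfiia: bool = False
    tfiia_specificity_boost: float = 10.0
    tfiia_ns_suppression: float = 10.0

    def __post_init__(self) -> None:
        if self.kd_specific_nM <= 0 or self.kd_nonspecific_nM <= 0:
            raise InputError("dissociation constants must be positive")
        if self.cooperativity_omega < 0:
            raise InputError("cooperativity omega must be >= 0")
        if self.salt_mM <= 0 or self.reference_salt_mM <= 0:
            raise InputError("salt concentrations must be positive")
        if self.tfiia_specificity_boost < 1 or self.tfiia_ns_suppression < 1:
            raise InputError("TFIIA multipliers must be >= 1")

    def _salt_factor(self, exponent: float) -> float:
        return (self.salt_mM / self.reference_salt_mM) ** exponent

    @property
    def kd_specific_eff_nM(self) -> float:
        kd = self.kd_specific_nM * self._salt_factor(self.salt_exponent_specific)
        if self.tfiia:
            kd /= self.tfiia_specificity_boost
        return kd

    @property
    def kd_nonspecific_eff_nM(self) -> float:
        kd = self.kd_nonspecific_nM * self._salt_factor(self.salt_exponent_nonspecific)
        if self.tfiia:
            kd *= self.tfiia_ns_suppression
        return kd

    def register_kd(self, lattice: LatticeSpec) -> np.ndarray:
        """Effective Kd (nM) per register; inf at inactive registers."""
        kd = np.full(lattice.length_bp, self.kd_nonspecific_eff_nM)
        if lattice.specific_register is not None:
            kd[lattice.specific_register] = self.kd_specific_eff_nM
        if lattice.inactive_registers:
            kd[list(lattice.inactive_registers)] = np.inf
        return kd


@dataclass(frozen=True)
class LatticeConfiguration:
    """One microstate: the sorted bp indices of bound footprint centers."""

    bound_registers: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "bound_registers", tuple(sorted(self.bound_registers)))

    def __len__(self) -> int:
        return len(self.bound_registers)


@dataclass(frozen=True)
class OccupancyResult:
    """Equilibrium probabilities over bound configurations.

    ``register_occupancy[i]`` is the probability register i is occupied;
    ``multi_occupancy_fractions[k]`` the probability exactly k proteins are
    bound; both follow from the same partition function Z.
    """

    partition_function: float
    register_occupancy: np.ndarray
    p_specific_bound: Optional[float]
    multi_occupancy_fractions: np.ndarray
    free_tbp_nM: float
    method: str

    @property
    def mean_bound(self) -> float:
        return float(self.register_occupancy.sum())


def count_binding_registers(lattice: LatticeSpec) -> int:
    """Number of active registers under the one-register-per-bp convention."""
    return len(lattice.active_registers)


def enumerate_configurations(lattice: LatticeSpec) -> list[LatticeConfiguration]:
    """All configurations with pairwise center separation >= footprint.

    Includes the empty configuration.  Refuses lattices with more than
    MAX_ENUMERATION_REGISTERS active registers; use the transfer-matrix path
    of :func:`equilibrium_occupancy` for those.
    """
    active = lattice.active_registers
    if len(active) > MAX_ENUMERATION_REGISTERS:
        raise LatticeSizeError(
            f"{len(active)} registers exceed the enumeration limit of "
            f"{MAX_ENUMERATION_REGISTERS}; use the transfer-matrix path"
        )
    n = lattice.footprint_bp
    configs: list[tuple[int, ...]] = []

    def extend(prefix: tuple[int, ...], start: int) -> None:
        configs.append(prefix)
        for idx in range(start, len(active)):
            reg = active[idx]
            if not prefix or reg - prefix[-1] >= n:
                extend(prefix + (reg,), idx + 1)

    extend((), 0)
    return [LatticeConfiguration(c) for c in configs]


def configuration_weight(
    config: LatticeConfiguration,
    lattice: LatticeSpec,
    energetics: BindingEnergetics,
    free_tbp_nM: float,
) -> float:
    """Statistical weight of one configuration relative to empty DNA."""
    if free_tbp_nM < 0:
        raise InputError(f"free TBP concentration must be >= 0, got {free_tbp_nM}")
    kd = energetics.register_kd(lattice)
    regs = config.bound_registers
    weight = 1.0
    for reg in regs:
        weight *= free_tbp_nM / kd[reg]
    n_contacts = sum(1 for a, b in itertools.pairwise(regs) if b - a == lattice.footprint_bp)
    return weight * energetics.cooperativity_omega**n_contacts


def _occupancy_by_enumeration(
    lattice: LatticeSpec,
    energetics: BindingEnergetics,
    free_tbp_nM: float,
) -> OccupancyResult:
    configs = enumerate_configurations(lattice)
    weights = np.array(
        [configuration_weight(c, lattice, energetics, free_tbp_nM) for c in configs]
    )
    z = weights.sum()
    occ = np.zeros(lattice.length_bp)
    max_k = max(len(c) for c in configs)
    counts = np.zeros(max_k + 1)
    for cfg, w in zip(configs, weights):
        counts[len(cfg)] += w
        for reg in cfg.bound_registers:
            occ[reg] += w
    occ /= z
    counts /= z
    nz = np.nonzero(counts)[0]
    counts = counts[: (nz[-1] + 1)] if nz.size else counts[:1]
    p_spec = (
        float(occ[lattice.specific_register])
        if lattice.specific_register is not None
        else None
    )
    return OccupancyResult(float(z), occ, p_spec, counts, free_tbp_nM, "enumeration")


def _occupancy_by_transfer(
    lattice: LatticeSpec,
    energetics: BindingEnergetics,
    free_tbp_nM: float,
) -> OccupancyResult:
    """Linear forward/backward recursion over registers, extended precision.

    Forward: a(i) = w_i * (z(i-n) + omega * a(i-n)), z(i+1) = z(i) + a(i),
    where z(j) is the partition function over registers < j (z = 1 for
    j <= 0).  The backward pass mirrors it; occupancy(i) combines both.
    A parallel recursion with a bound-count dimension yields the
    multi-occupancy distribution.  Weights can span hundreds of decades on
    long lattices, hence np.longdouble throughout.
    """
    if free_tbp_nM < 0:
        raise InputError(f"free TBP concentration must be >= 0, got {free_tbp_nM}")
    L = lattice.length_bp
    n = lattice.footprint_bp
    omega = np.longdouble(energetics.cooperativity_omega)
    kd = energetics.register_kd(lattice)
    w = np.where(np.isfinite(kd), free_tbp_nM / kd, 0.0).astype(np.longdouble)

    max_b = (L + n - 1) // n
    # count-resolved forward pass
    zc = np.zeros((L + 1, max_b + 1), dtype=np.longdouble)
    ac = np.zeros((L, max_b + 1), dtype=np.longdouble)
    zc[0, 0] = 1.0
    e0 = np.zeros(max_b + 1, dtype=np.longdouble)
    e0[0] = 1.0
    for i in range(L):
        z_prev = zc[i - n] if i - n >= 0 else e0
        a_prev = ac[i - n] if i - n >= 0 else np.zeros(max_b + 1, dtype=np.longdouble)
        ac[i, 1:] = w[i] * (z_prev[:-1] + omega * a_prev[:-1])
        zc[i + 1] = zc[i] + ac[i]
    counts_unnorm = zc[L]
    z_total = counts_unnorm.sum()

    af = ac.sum(axis=1)  # marginal forward weights

    # marginal backward pass
    zb = np.ones(L + 1, dtype=np.longdouble)  # zb[j] = partition over registers >= j
    ab = np.zeros(L, dtype=np.longdouble)
    for i in range(L - 1, -1, -1):
        z_next = zb[i + n + 1] if i + n + 1 <= L else np.longdouble(1.0)
        a_next = ab[i + n] if i + n < L else np.longdouble(0.0)
        ab[i] = w[i] * (z_next + omega * a_next)
        zb[i] = zb[i + 1] + ab[i]

    occ = np.empty(L, dtype=np.longdouble)
    for i in range(L):
        z_next = zb[i + n + 1] if i + n + 1 <= L else np.longdouble(1.0)
        a_next = ab[i + n] if i + n < L else np.longdouble(0.0)
        occ[i] = af[i] * (z_next + omega * a_next)
    occ /= z_total

    counts = (counts_unnorm / z_total).astype(float)
    # trim trailing zero counts beyond the largest reachable occupancy
    nz = np.nonzero(counts)[0]
    counts = counts[: (nz[-1] + 1)] if nz.size else counts[:1]
    p_spec = (
        float(occ[lattice.specific_register])
        if lattice.specific_register is not None
        else None
    )
    return OccupancyResult(
        float(z_total), occ.astype(float), p_spec, counts, free_tbp_nM, "transfer"
    )


def equilibrium_occupancy(
    lattice: LatticeSpec,
    energetics: BindingEnergetics,
    free_tbp_nM: float,
    method: str = "auto",
) -> OccupancyResult:
    """Equilibrium occupancy of every register at a free TBP concentration.

    method='auto' enumerates small lattices and falls back to the transfer
    recursion otherwise; the two agree to ~1e-12 relative wherever both run.
    """
    if method == "auto":
        method = (
            "enumeration"
            if len(lattice.active_registers) <= _AUTO_ENUMERATION_REGISTERS
            else "transfer"
        )
    if method == "enumeration":
        return _occupancy_by_enumeration(lattice, energetics, free_tbp_nM)
    if method == "transfer":
        return _occupancy_by_transfer(lattice, energetics, free_tbp_nM)
    raise InputError(f"unknown method {method!r}")


def mcghee_von_hippel_density(c_over_kd: float, n: int) -> float:
    """Closed-form bound density (proteins per lattice residue) for a long
    homogeneous non-cooperative lattice with footprint ``n``.

    Solves  K*L = nu / ((1 - n*nu) * ((1 - n*nu)/(1 - (n-1)*nu))**(n-1))
    for nu on [0, 1/n); the standard infinite-lattice isotherm used as an
    independent oracle for the transfer recursion.
    """
    from scipy.optimize import brentq

    kl = c_over_kd
    if kl == 0:
        return 0.0

    def f(nu: float) -> float:
        free = 1.0 - n * nu
        gap = 1.0 - (n - 1) * nu
        return kl * free * (free / gap) ** (n - 1) - nu

    return brentq(f, 0.0, (1.0 - 1e-12) / n, xtol=1e-14)


@dataclass(frozen=True)
class CompetitorSpec:
    """Unlabeled competitor DNA co-present in the binding reaction.

    mode='equimolar' ties the competitor concentration to the total TBP at
    every titration point (the co-titration protocol); a fixed ``conc_nM``
    models a constant chase/competitor pool.
    """

    lattice: LatticeSpec
    energetics: Optional[BindingEnergetics] = None
    mode: str = "equimolar"
    conc_nM: float = 0.0

    def concentration(self, total_tbp_nM: float) -> float:
        return total_tbp_nM if self.mode == "equimolar" else self.conc_nM


def solve_free_tbp(
    total_tbp_nM: float,
    binders: Sequence[tuple[LatticeSpec, BindingEnergetics, float]],
    tol_nM: float = 1e-9,
    max_iter: int = 10_000,
    damping: float = 0.5,
) -> float:
    """Free TBP satisfying mass balance against one or more DNA lattices.

    ``binders`` is a sequence of (lattice, energetics, dna_conc_nM); the
    excess function  h(free) = free + sum_j dna_j * <n_bound>_j(free) - total
    is strictly increasing, so its root is bracketed on [0, total] and
    refined by bisection to < tol_nM.  Cooperative lattices make the naive
    damped fixed point free <- total - bound oscillate (the bound-ligand
    derivative can exceed 1 by orders of magnitude), hence the bracketed
    iteration.
    """
    if total_tbp_nM < 0:
        raise InputError("total TBP must be >= 0")
    if total_tbp_nM == 0:
        return 0.0

    def excess(free: float) -> float:
        bound = sum(
            dna * equilibrium_occupancy(lat, en, free).mean_bound
            for lat, en, dna in binders
            if dna > 0
        )
        return free + bound - total_tbp_nM

    lo, hi = 0.0, total_tbp_nM
    for _ in range(max_iter):
        if hi - lo < tol_nM:
            return 0.5 * (lo + hi)
        mid = 0.5 * (lo + hi)
        if excess(mid) > 0:
            hi = mid
        else:
            lo = mid
    raise NonConvergenceError(
        f"mass balance did not converge within {max_iter} iterations"
    )


def predicted_isotherm(
    lattice: LatticeSpec,
    energetics: BindingEnergetics,
    bend: _fret.BendModel,
    fret_params: _fret.FretParameters,
    conc_grid: Iterable[float],
    competitor: Optional[CompetitorSpec] = None,
    dna_nM: float = 0.0,
    corrected: bool = True,
) -> pd.DataFrame:
    """Ensemble-mean proximity ratio over a TBP titration.

    For each concentration the configuration distribution is computed by
    enumeration and averaged over each configuration's dye geometry.
    ``dna_nM > 0`` activates labeled-DNA depletion in the mass balance;
    a competitor always activates it.  Returns a DataFrame with columns
    ``conc_nM`` and ``proximity_ratio``.
    """
    conc = np.asarray(list(conc_grid), dtype=float)
    if conc.size and ((conc < 0).any() or (np.diff(conc) < 0).any()):
        raise InputError("conc_grid must be non-negative and ascending")
    configs = enumerate_configurations(lattice)
    p_config = np.array(
        [
            _fret.configuration_proximity(lattice, c, bend, fret_params, corrected)
            for c in configs
        ]
    )
    ratios = np.empty_like(conc)
    for k, total in enumerate(conc):
        if competitor is not None or dna_nM > 0:
            binders = [(lattice, energetics, dna_nM)]
            if competitor is not None:
                comp_en = competitor.energetics or energetics
                binders.append(
                    (competitor.lattice, comp_en, competitor.concentration(total))
                )
            free = solve_free_tbp(total, binders)
        else:
            free = total
        weights = np.array(
            [configuration_weight(c, lattice, energetics, free) for c in configs]
        )
        ratios[k] = float(np.average(p_config, weights=weights))
    return pd.DataFrame({"conc_nM": conc, "proximity_ratio": ratios})
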