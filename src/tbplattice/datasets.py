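"""Seeded synthetic-data generator for every input the pipeline consumes.

All fixtures live in ``data/fixtures.yaml``; each names a generator kind
(titration | chase | bursts | nucleosome), a parameter set with per-key
provenance (printed experimental value vs package calibration) and is
reproducible bit-exactly from (fixture name, seed).
"""

from __future__ import annotations

import functools
from importlib import resources
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import bursts as _bursts
from . import fret as _fret
from . import nucleosome as _nuc
from .errors import CatalogError
from .isotherm import single_site
from .lattice import (
    BindingEnergetics,
    CompetitorSpec,
    LatticeSpec,
    predicted_isotherm,
)


@functools.cache
def _catalog() -> dict:
    text = resources.files("tbplattice").joinpath("data/fixtures.yaml").read_text()
    return yaml.safe_load(text)


def list_fixtures() -> list[str]:
    """Names of all catalogued fixtures."""
    return sorted(_catalog()["fixtures"])


def fixture_info(name: str) -> dict[str, Any]:
    """Full catalog entry (kind, params, provenance, notes) for a fixture."""
    try:
        return _catalog()["fixtures"][name]
    except KeyError as exc:
        raise CatalogError(f"unknown fixture {name!r}; see list_fixtures()") from exc


def get_construct(name: str) -> LatticeSpec:
    """One of the catalogued DNA constructs as a LatticeSpec."""
    try:
        entry = _catalog()["constructs"][name]
    except KeyError as exc:
        raise CatalogError(f"unknown construct {name!r}") from exc
    donor = entry.get("dye_donor")
    acceptor = entry.get("dye_acceptor")
    spec = LatticeSpec.from_sequence(
        entry["sequence"],
        specific_register=entry.get("specific_register", "auto") or None,
        dye_donor=None if donor is None else _fret.DyeSite(donor),
        dye_acceptor=None if acceptor is None else _fret.DyeSite(acceptor),
        name=name,
    )
    inactive = entry.get("inactive_registers")
    if inactive == "nonspecific":
        inactive = [i for i in range(spec.length_bp) if i != spec.specific_register]
    if inactive:
        from dataclasses import replace

        spec = replace(spec, inactive_registers=frozenset(inactive))
    return spec


def _conc_grid(grid: dict) -> np.ndarray:
    if grid.get("spacing", "log") == "log":
        return np.geomspace(grid["min_nM"], grid["max_nM"], grid["points"])
    return np.linspace(grid["min_nM"], grid["max_nM"], grid["points"])


def _titration_curve(entry: dict) -> pd.DataFrame:
    params = entry["params"]
    conc = _conc_grid(entry["grid"])
    if entry["model"] == "single_site":
        curve = single_site(conc, params["p_min"], params["p_max"], params["kd_nM"])
        return pd.DataFrame({"conc_nM": conc, "proximity_ratio": curve})
    if entry["model"] == "lattice":
        construct = get_construct(params["construct"])
        energetics = BindingEnergetics(
            cooperativity_omega=params.get("omega", 5.0),
            salt_mM=params["salt_mM"],
            tfiia=params.get("tfiia", False),
        )
        competitor = None
        if params.get("competitor", False):
            competitor = CompetitorSpec(get_construct("competitor25"), mode="equimolar")
        return predicted_isotherm(
            construct,
            energetics,
            _fret.BendModel(),
            _fret.FretParameters(),
            conc,
            competitor=competitor,
        )
    raise CatalogError(f"unknown titration model {entry['model']!r}")


def _nucleosome_curve(entry: dict) -> pd.DataFrame:
    params = entry["params"]
    scenario = _nuc.NucleosomeScenario(
        histone_state=params["histone_state"],
        salt_mM=params["salt_mM"],
        tfiia=params.get("tfiia", False),
    )
    result = _nuc.nucleosome_isotherm(
        scenario,
        _nuc.AccessibilityModel(),
        BindingEnergetics(),
        _conc_grid(entry["grid"]),
    )
    return result.isotherm


def generate_titration(name: str, seed: int) -> pd.DataFrame:
    """Noisy titration table (conc_nM, proximity_ratio, sigma) for a fixture."""
    entry = fixture_info(name)
    if entry["kind"] == "titration":
        table = _titration_curve(entry)
    elif entry["kind"] == "nucleosome":
        table = _nucleosome_curve(entry)
    else:
        raise CatalogError(f"fixture {name!r} is not a titration (kind={entry['kind']})")
    sigma = entry["params"].get("sigma_p", 0.01)
    rng = np.random.default_rng(seed)
    noisy = table["proximity_ratio"].to_numpy() + rng.normal(0.0, sigma, len(table))
    return pd.DataFrame(
        {"conc_nM": table["conc_nM"], "proximity_ratio": noisy, "sigma": sigma}
    )


def generate_chase(name: str, seed: int) -> pd.DataFrame:
    """Noisy biexponential chase trace (time_s, proximity_ratio) for a fixture."""
    entry = fixture_info(name)
    if entry["kind"] != "chase":
        raise CatalogError(f"fixture {name!r} is not a chase trace")
    p = entry["params"]
    times = np.arange(0.0, p["duration_s"] + 0.5 / p["rate_hz"], 1.0 / p["rate_hz"])
    ff = p["fast_fraction"]
    decay = p["offset"] + p["amplitude"] * (
        ff * np.exp(-p["k_fast_per_s"] * times)
        + (1.0 - ff) * np.exp(-p["k_slow_per_s"] * times)
    )
    rng = np.random.default_rng(seed)
    noisy = decay + rng.normal(0.0, p.get("sigma_p", 0.01), times.size)
    return pd.DataFrame({"time_s": times, "proximity_ratio": noisy})


def generate_burst_stream(name: str, seed: int) -> _bursts.BurstSet:
    """Simulated photon-burst set for a fixture, via the equilibrium mixture."""
    entry = fixture_info(name)
    if entry["kind"] != "bursts":
        raise CatalogError(f"fixture {name!r} is not a burst stream")
    p = entry["params"]
    construct = get_construct(p["construct"])
    energetics = BindingEnergetics(
        cooperativity_omega=p.get("omega", 5.0), salt_mM=p["salt_mM"]
    )
    mixture = _bursts.SpeciesMixture.from_occupancy(
        construct,
        energetics,
        _fret.BendModel(),
        _fret.FretParameters(),
        p["conc_nM"],
        donor_only_fraction=p.get("donor_only_fraction", 0.0),
    )
    return _bursts.simulate_bursts(
        mixture,
        n_bursts=p.get("n_bursts", 4000),
        mean_burst_size=p.get("mean_burst_size", 60.0),
        seed=seed,
    )


def make(name: str, seed: int):
    """Dispatch on fixture kind; returns a DataFrame or BurstSet."""
    kind = fixture_info(name)["kind"]
    if kind in ("titration", "nucleosome"):
        return generate_titration(name, seed)
    if kind == "chase":
        return generate_chase(name, seed)
    if kind == "bursts":
        return generate_burst_stream(name, seed)
    raise CatalogError(f"unknown fixture kind {kind!r}")  # pragma: no cover
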