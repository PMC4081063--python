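"""Table/config I/O and run manifests.

Conventions: comma-separated CSV, '.' decimal, UTF-8, mandatory header row
(columns may appear in any order); concentrations in nM, time in s,
distances in Å, angles in degrees, 0-based bp indices.  Every pipeline run
writes a JSON manifest with the resolved configuration, seed and package
version so outputs are reproducible.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import fret as _fret
from .errors import ConfigError, ParseError
from .lattice import LatticeSpec, locate_specific_site

SCHEMAS: dict[str, dict[str, Any]] = {
    "titration": {"required": ["conc_nM", "proximity_ratio"], "optional": ["sigma"]},
    "chase": {"required": ["time_s", "proximity_ratio"], "optional": []},
    "bursts": {"required": ["burst_id", "donor_counts", "acceptor_counts"], "optional": []},
}

_CONFIG_BLOCKS = {
    "construct": {"name", "sequence", "fasta", "length_bp", "specific_register",
                  "footprint_bp", "contact_span_bp", "inactive_registers",
                  "dye_donor", "dye_acceptor"},
    "energetics": {"kd_specific_nM", "kd_nonspecific_nM", "cooperativity_omega",
                   "salt_mM", "reference_salt_mM", "salt_exponent_specific",
                   "salt_exponent_nonspecific", "tfiia", "tfiia_specificity_boost",
                   "tfiia_ns_suppression"},
    "fret": {"r0", "gamma", "donor_crosstalk_fraction", "direct_excitation_fraction",
             "background_donor", "background_acceptor"},
    "bend": {"bend_angle_specific", "bend_angle_nonspecific", "rise_per_bp",
             "dye_offset"},
    "kinetics": {"k_on_per_M_s", "k_off_specific_per_s", "k_off_nonspecific_per_s",
                 "k_slide_per_s", "tbp_nM", "competitor_nM", "incubation_s",
                 "observation_s"},
    "nucleosome": {"construct_length_bp", "wrapped_bp", "tata_depth_bp",
                   "histone_state", "salt_mM", "tfiia"},
    "fixture": None,  # free-form overrides
    "output_dir": None,
    "seed": None,
    "log_level": None,
}


def read_table(path, schema: str) -> pd.DataFrame:
    """Read and validate a CSV table against a named schema.

    Errors name the offending 1-based data row.  Columns are header-keyed,
    so their order does not matter.
    """
    if schema not in SCHEMAS:
        raise ParseError(f"unknown schema {schema!r}; choose from {sorted(SCHEMAS)}")
    spec = SCHEMAS[schema]
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"cannot read {path}: {exc}") from exc
    missing = [c for c in spec["required"] if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    keep = spec["required"] + [c for c in spec["optional"] if c in df.columns]
    df = df[keep]
    for col in keep:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 1
            raise ParseError(f"{path}: non-numeric value in column {col!r} at row {row}")
        if numeric.isna().any():
            row = int(np.flatnonzero(numeric.isna())[0]) + 1
            raise ParseError(f"{path}: missing value in column {col!r} at row {row}")
        df[col] = numeric
    if schema == "titration":
        neg = df["conc_nM"] < 0
        if neg.any():
            row = int(np.flatnonzero(neg)[0]) + 1
            raise ParseError(f"{path}: negative concentration at row {row}")
    if schema == "chase":
        dt = df["time_s"].diff().iloc[1:]
        if (dt <= 0).any():
            row = int(np.flatnonzero(dt.to_numpy() <= 0)[0]) + 2
            raise ParseError(f"{path}: time not strictly increasing at row {row}")
    if schema == "bursts":
        for col in ("donor_counts", "acceptor_counts"):
            neg = df[col] < 0
            if neg.any():
                row = int(np.flatnonzero(neg)[0]) + 1
                raise ParseError(f"{path}: negative count in {col!r} at row {row}")
    return df


def load_config(path) -> dict:
    """Load a YAML run configuration, rejecting unknown keys."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    for block, value in cfg.items():
        if block not in _CONFIG_BLOCKS:
            raise ConfigError(f"{path}: unknown config block {block!r}")
        allowed = _CONFIG_BLOCKS[block]
        if allowed is not None and isinstance(value, dict):
            unknown = set(value) - allowed
            if unknown:
                raise ConfigError(
                    f"{path}: unknown key(s) {sorted(unknown)} in block {block!r}"
                )
    return cfg


def construct_from_config(block: dict) -> LatticeSpec:
    """Build a LatticeSpec from a config block (sequence, FASTA or length)."""
    sequence: Optional[str] = block.get("sequence")
    if sequence is None and block.get("fasta"):
        from Bio import SeqIO

        record = next(SeqIO.parse(block["fasta"], "fasta"))
        sequence = str(record.seq)
    specific = block.get("specific_register", "auto")
    if specific == "auto":
        specific = locate_specific_site(sequence) if sequence else None
    kwargs = {
        "specific_register": specific,
        "footprint_bp": block.get("footprint_bp", 8),
        "contact_span_bp": block.get("contact_span_bp", 8),
        "inactive_registers": frozenset(block.get("inactive_registers", ())),
        "name": block.get("name", ""),
    }
    if block.get("dye_donor") is not None:
        kwargs["dye_donor"] = _fret.DyeSite(int(block["dye_donor"]))
    if block.get("dye_acceptor") is not None:
        kwargs["dye_acceptor"] = _fret.DyeSite(int(block["dye_acceptor"]))
    if sequence is not None:
        return LatticeSpec(length_bp=len(sequence), sequence=sequence, **kwargs)
    if "length_bp" not in block:
        raise ConfigError("construct block needs a sequence, fasta or length_bp")
    return LatticeSpec(length_bp=int(block["length_bp"]), **kwargs)


def write_manifest(out_path, config: dict, seed: Optional[int]) -> Path:
    """Write the run manifest next to an output artifact."""
    out_path = Path(out_path)
    manifest = {
        "package": "tbplattice",
        "version": __version__,
        "seed": seed,
        "config": config,
    }
    manifest_path = out_path.with_name(out_path.name + ".manifest.json")
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest_path


def write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
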