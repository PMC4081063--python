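"""Exception hierarchy shared across the package."""


class TbpLatticeError(Exception):
    """Base class for all package errors."""


class InputError(TbpLatticeError, ValueError):
    """Invalid user-supplied value (negative concentration, bad sequence, ...)."""


class LatticeSizeError(TbpLatticeError):
    """Lattice too large for brute-force enumeration; use the transfer-matrix path."""


class FitError(TbpLatticeError):
    """Nonlinear fit failed or did not converge."""


class NonConvergenceError(TbpLatticeError):
    """Iterative numerical scheme (e.g. mass balance) did not converge."""


class CatalogError(TbpLatticeError, KeyError):
    """Unknown fixture name in the synthetic-data catalog."""


class ParseError(TbpLatticeError, ValueError):
    """Malformed input table; the message names the offending row."""


class ConfigError(TbpLatticeError, ValueError):
    """Invalid or unknown key in a run configuration."""


class UndefinedResultError(TbpLatticeError, ArithmeticError):
    """A requested quantity is undefined for these inputs (e.g. 0/0 amplitude)."""
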