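"""Exception and warning types shared across the package."""


class RibomechError(Exception):
    """Base class for all package errors."""


class StructureError(RibomechError):
    """Unreadable, unwritable, or empty structure input."""


class SelectionError(RibomechError):
    """A selection resolved to nothing against the given structure."""


class CoarseGrainError(RibomechError):
    """No mappable residues, or conflicting component labels."""


class DegenerateGeometryError(RibomechError):
    """Coincident nodes make the elastic network ill-defined."""


class InsufficientModesError(RibomechError):
    """Only rigid-body (zero) modes available; covariance undefined."""


class UndefinedCorrelationError(RibomechError):
    """A node with zero fluctuation makes normalized correlation undefined."""


class DeletionError(RibomechError):
    """A deletion spec is unresolvable or would remove protected nodes."""


class MissingBFactorError(RibomechError):
    """B-factors requested from a source that does not provide them."""


class FixtureError(RibomechError):
    """Invalid synthetic-fixture specification."""


class ConfigError(RibomechError):
    """Invalid run configuration."""


class NumericalError(RibomechError):
    """Eigensolver or other numerical failure."""


class DisconnectedNetworkWarning(UserWarning):
    """Contact network has more than one connected component."""


class MissingAtomWarning(UserWarning):
    """A residue lacks one of its mapped coarse-grain atoms."""
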