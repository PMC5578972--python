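"""Exception and warning types shared across the package.

Exit-code mapping used by the CLI: :class:`InputError` -> 2,
:class:`DegenerateSampleError` -> 3.
"""


class RocshapeError(Exception):
    """Base class for all package-specific errors."""


class InputError(RocshapeError):
    """Malformed or unusable input (bad file, missing column, empty data)."""


class ConfigurationError(RocshapeError):
    """Invalid configuration: bad transform spec, unknown preset, bad model."""


class DegenerateSampleError(RocshapeError):
    """Sample cannot support ROC analysis (only one outcome class present)."""


class InvariantViolationError(RocshapeError):
    """A domain object violates its structural invariants (e.g. non-monotone ROC)."""


class RocshapeWarning(UserWarning):
    """Base class for package warnings."""


class DegenerateCIWarning(RocshapeWarning):
    """AUROC is 0 or 1: the Hanley-McNeil SE collapses to zero and the Wald
    interval degenerates; a bootstrap interval is recommended instead."""


class NadirWarning(RocshapeWarning):
    """Nadir estimate is suspect: extreme bin selected (monotone risk?) or
    bin event rates too flat to identify a minimum."""
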