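"""Error classes shared across the package."""


class NpmsmError(Exception):
    """Base class for all package errors."""


class CycleError(NpmsmError):
    """The transition structure contains a directed cycle (or self-loop)."""


class UnknownStateError(NpmsmError):
    """A transition or observation references an undeclared state."""


class UnknownTransitionError(NpmsmError):
    """A (from, to) pair is not an allowed direct transition."""


class ConstraintError(NpmsmError):
    """Intensity jumps violate the simplex-type constraint region."""


class FormatError(NpmsmError):
    """Malformed input file (missing columns, non-numeric time, ...)."""


class ConsistencyError(NpmsmError):
    """Panel observations are internally inconsistent."""


class ZeroPathError(NpmsmError):
    """An observed state pair has probability zero under the current
    intensities; signals bad initialization or inconsistent data."""


class DimensionError(NpmsmError):
    """Problem instance exceeds a size cap (brute-force oracle)."""


class UnsupportedError(NpmsmError):
    """Requested computation is not defined for this configuration."""


class ShapeError(NpmsmError):
    """Mismatched shapes/grids between objects that must align."""


class MaxIterWarning(UserWarning):
    """Iteration limit reached before the convergence criterion."""
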