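"""Exception hierarchy shared across the package."""


class EnergySplitError(Exception):
    """Base class for every error raised by this package."""


class ParameterBlockError(EnergySplitError):
    """Malformed Gaussian-style MM parameter text."""


class PrmtopFormatError(EnergySplitError):
    """Missing or inconsistent PRMTOP/PARM7 content."""


class CoordinateFormatError(EnergySplitError):
    """Unreadable or mismatched coordinate file."""


class MissingParameterError(EnergySplitError):
    """A bond/angle/torsion term has no force-field parameters."""


class EvaluationError(EnergySplitError):
    """Degenerate geometry encountered while evaluating an energy term."""


class FragmentError(EnergySplitError):
    """Invalid fragment selection (overlap, bad index, reserved label)."""


class FragmentSpecError(FragmentError):
    """Unparseable fragment-selection specification string."""


class GenerationError(EnergySplitError):
    """A synthetic fixture could not be generated under its constraints."""
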