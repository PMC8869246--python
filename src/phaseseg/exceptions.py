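"""Exception hierarchy for phaseseg."""


class PhasesegError(Exception):
    """Base class for all phaseseg errors."""


class InputFileError(PhasesegError, OSError):
    """An input file is missing, unreadable, or not a decodable image."""


class FormatError(PhasesegError, ValueError):
    """An image has an unsupported layout or bit depth."""


class ParameterError(PhasesegError, ValueError):
    """An operation received an out-of-contract parameter."""


class GenerationError(PhasesegError, RuntimeError):
    """The synthetic scene generator could not satisfy its spec."""


class MetricUndefinedError(PhasesegError, ValueError):
    """A metric is undefined for the given inputs (e.g. zero true area)."""
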