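"""Exception hierarchy for mncount."""


class MNCountError(Exception):
    """Base class for all mncount errors."""


class InputError(MNCountError):
    """A file is missing or cannot be decoded."""


class FormatError(MNCountError):
    """A file decodes but violates the expected format."""


class ValidationError(MNCountError):
    """An argument or parameter value is out of range."""


class PlacementError(MNCountError):
    """The synthetic scene could not be laid out at the requested density."""


class StateError(MNCountError):
    """A workflow step requires artifacts that do not exist yet."""
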