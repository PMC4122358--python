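"""Exception hierarchy shared across the package."""


class OrthointronError(Exception):
    """Base class for all package errors."""


class FormatError(OrthointronError):
    """Unparseable or malformed input file."""


class CoordinateError(OrthointronError):
    """Feature coordinates inconsistent with the sequence they refer to."""


class UndefinedValueError(OrthointronError):
    """A statistic is undefined for the given input (e.g. GC of an all-N sequence)."""


class QualityError(OrthointronError):
    """Input fails a quality-control rule (e.g. rising oxygen trace)."""


class ParameterError(OrthointronError):
    """Parameter outside its valid domain."""


class LookupMissError(OrthointronError):
    """A referenced identifier is absent from the dataset."""
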