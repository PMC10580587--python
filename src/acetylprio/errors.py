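"""Exception hierarchy for the pipeline."""


class AcetylprioError(Exception):
    """Base class for all package errors."""


class FormatError(AcetylprioError):
    """Malformed file header or structure."""


class ParseError(AcetylprioError):
    """Unparseable cell or line; message carries coordinates."""


class ValidationError(AcetylprioError):
    """Invalid configuration or simulation spec; message lists fields."""


class EmptySetError(AcetylprioError):
    """Gene set empty after intersection with the measured genes."""


class DegenerateComplementError(AcetylprioError):
    """Gene set covers every measured gene; no complement to walk against."""


class InsufficientSamplesError(AcetylprioError):
    """A comparison group has fewer samples than the test requires."""


class DegenerateInputError(AcetylprioError):
    """Constant vector where a correlation needs variation."""


class AlignmentError(AcetylprioError):
    """Sample identifiers of two inputs do not match; message lists offenders."""


class DomainError(AcetylprioError):
    """Numeric argument outside its mathematical domain."""
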