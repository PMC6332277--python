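"""Exception hierarchy for the qNMR pipeline."""


class QnmrError(ValueError):
    """Base class for all qnmr domain errors."""


class InvalidParameterError(QnmrError):
    """A physical or configuration parameter is out of its valid domain."""


class ConfigurationError(QnmrError):
    """An assay configuration is internally inconsistent."""


class DivisionGuardError(QnmrError):
    """A quantification denominator (area, mass) is zero or negative."""


class SpectrumParseError(QnmrError):
    """A spectrum file could not be parsed."""
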