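"""Exception hierarchy shared across the package."""


class MGScreenError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(MGScreenError, ValueError):
    """A value violates an operation's domain (non-positive creatinine, etc.)."""


class MissingAnalyteError(InvalidInputError):
    """A required laboratory value is absent from a patient record."""

    def __init__(self, record_id, fields):
        self.record_id = record_id
        self.fields = tuple(fields)
        super().__init__(
            f"record {record_id!r}: missing required analyte(s): {', '.join(self.fields)}"
        )


class IncompleteResultsError(MGScreenError, ValueError):
    """An assay result needed by a decision or combination was not performed."""


class InvalidConfigError(MGScreenError, ValueError):
    """A configuration object (ranges, throughputs, cohort spec) is inconsistent."""
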