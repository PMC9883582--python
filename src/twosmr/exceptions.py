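"""Exception hierarchy for twosmr."""


class TwosmrError(Exception):
    """Base class for all package errors."""


class ValidationError(TwosmrError, ValueError):
    """A record or value violates a domain invariant."""


class ConfigurationError(TwosmrError, ValueError):
    """A column map, config file, or parameter set is unusable."""


class DataError(TwosmrError, ValueError):
    """A table-level defect such as a duplicate SNP identifier."""


class CollinearityError(TwosmrError, ValueError):
    """The multivariable exposure matrix is rank deficient."""

    def __init__(self, columns, message=None):
        self.columns = list(columns)
        super().__init__(
            message or f"exposure matrix is rank deficient; offending columns: {self.columns}"
        )
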