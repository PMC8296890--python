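"""Exception hierarchy shared across the pipeline."""


class AdalertError(Exception):
    """Base class for all package-specific errors."""


class FormatError(AdalertError):
    """An input file does not conform to the expected tabular layout."""


class PatternError(AdalertError):
    """One or more SMARTS alert patterns failed to compile."""

    def __init__(self, message: str, alert_ids: tuple[str, ...] = ()):
        super().__init__(message)
        self.alert_ids = alert_ids


class StructureError(AdalertError):
    """A SMILES string could not be parsed into a molecule."""

    def __init__(self, message: str, drug_id: str | None = None):
        super().__init__(message)
        self.drug_id = drug_id


class ConfigError(AdalertError):
    """A run configuration is invalid or incomplete."""


class DataError(AdalertError):
    """Input data violate a statistical precondition (e.g. a single-class label vector)."""
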