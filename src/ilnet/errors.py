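"""Exception types shared across the pipeline."""


class ConfigError(ValueError):
    """A configuration value violates its contract; the message names the field."""


class EmptyInputError(ValueError):
    """An operation received an empty table where at least one record is required."""


class AnnotationCoverageError(KeyError):
    """Traits present in the data are missing from the annotation; offenders listed."""

    def __init__(self, missing):
        self.missing = sorted(missing)
        super().__init__(f"unannotated traits: {', '.join(self.missing)}")


class AlignmentError(ValueError):
    """Two matrices share no (or too few) genotype lines."""


class InsufficientReplicationError(ValueError):
    """A group comparison needs at least two replicate values per group."""
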