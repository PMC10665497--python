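"""Exception hierarchy for the triage pipeline."""


class ExotriageError(Exception):
    """Base class for all pipeline errors."""


class InputError(ExotriageError):
    """Malformed or unreadable input data (VCF, panel file, manifest)."""


class UnsupportedInputError(InputError):
    """Structurally valid input outside the supported scope (e.g. multi-sample VCF)."""


class ConfigError(ExotriageError):
    """Invalid pipeline configuration (thresholds, missing panels, bad specs)."""


class EvidenceParseError(ExotriageError):
    """An ACMG/AMP evidence-code token could not be parsed."""


class DataInconsistencyError(ExotriageError):
    """Mutually contradictory data, e.g. a hemizygous genotype in a female case."""


class UndefinedYieldError(ExotriageError):
    """Diagnostic yield requested for an empty cohort."""
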