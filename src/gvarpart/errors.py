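"""Exception hierarchy for gvarpart."""


class GvarpartError(Exception):
    """Base class for all package errors."""


class ConfigError(GvarpartError):
    """Invalid configuration values."""


class PedigreeError(GvarpartError):
    """Structurally invalid pedigree (cycles, unknown/duplicate ids)."""


class InputError(GvarpartError):
    """Invalid user input to an operation (bad ids, mismatched objects)."""


class QCError(GvarpartError):
    """Marker quality control produced an unusable panel."""


class DegeneracyError(GvarpartError):
    """A matrix or regression is degenerate (zero heterozygosity, zero variance)."""


class NumericalError(GvarpartError):
    """Numerical failure in the likelihood machinery (singular V, etc.)."""


class SamplingError(GvarpartError):
    """A requested random sample is impossible (e.g. 2N exceeds marker count)."""
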