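"""Exception hierarchy shared across the pipeline stages."""


class CibmutError(Exception):
    """Base class for all pipeline errors."""


class FormatError(CibmutError):
    """A file did not conform to its declared format."""


class ValidationError(CibmutError):
    """A record violated a structural invariant (e.g. CDS outside exon)."""


class ReferenceMismatchError(CibmutError):
    """A variant's REF allele disagrees with the loaded reference genome."""


class ConfigurationError(CibmutError):
    """Inconsistent or incomplete run configuration."""


class InvalidVariantError(CibmutError):
    """A variant fails the preconditions of an operation (e.g. SBS passed
    to an InDel-only analysis)."""
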