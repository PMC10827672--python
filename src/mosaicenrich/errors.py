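"""Exception hierarchy shared across the pipeline."""


class MosaicEnrichError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(MosaicEnrichError, ValueError):
    """Arguments violate a documented precondition (wrong type, range, shape)."""


class DegenerateInputError(MosaicEnrichError, ValueError):
    """Input is structurally valid but carries no information (all-zero table,
    zero-depth site, empty comparison group)."""


class DataIntegrityError(MosaicEnrichError):
    """Input contradicts the reference data it claims to describe
    (e.g. a variant whose REF base does not match the reference sequence)."""


class BoundaryError(MosaicEnrichError):
    """A genomic position lacks the flanking context an operation requires."""


class FormatError(MosaicEnrichError):
    """A file does not conform to the minimal dialect this package reads."""


class ConfigurationError(MosaicEnrichError):
    """A run configuration is inconsistent (unknown gene, duplicate set name,
    impossible proportion)."""


class StratificationError(MosaicEnrichError):
    """A permutation stratum has no eligible sites."""

    def __init__(self, key, message=None):
        self.key = key
        super().__init__(message or f"no eligible sites for stratum {key!r}")


class GenerationError(MosaicEnrichError):
    """The synthetic-data generator cannot satisfy the requested configuration."""
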