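"""Exception types shared across the pipeline."""


class ExopopError(Exception):
    """Base class for all pipeline errors."""


class VcfFormatError(ExopopError):
    """The input file is not a parseable VCF."""


class MissingGenotypeError(ExopopError):
    """A VCF record lacks the GT field required for dosage decoding."""


class GeneModelError(ExopopError):
    """A transcript model violates its structural invariants."""


class ReferenceMismatchError(ExopopError):
    """A variant's REF allele disagrees with the reference sequence."""


class ReferenceMissingError(ExopopError):
    """A gene model references a chromosome absent from the reference."""


class GenerationError(ExopopError):
    """The synthetic-data generator could not satisfy the requested mix."""


class ConfigError(ExopopError):
    """A pipeline or screen configuration is invalid."""
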