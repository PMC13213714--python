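"""Exception types shared across the pipeline."""


class SigsubtypeError(Exception):
    """Base class for all pipeline errors."""


class MalformedRecordError(SigsubtypeError):
    """A variant record contains a non-ACGT base or other unparseable field."""


class InconsistentContextError(SigsubtypeError):
    """The middle base of a trinucleotide context disagrees with the reference allele."""


class FormatError(SigsubtypeError):
    """An input file is missing required columns or is otherwise malformed."""


class AlignmentError(SigsubtypeError):
    """Channel labels of two matrices cannot be aligned."""


class UndefinedSimilarityError(SigsubtypeError):
    """Cosine similarity requested against a zero vector."""


class EmptyFilterError(SigsubtypeError):
    """The prevalence filter removed every signature; thresholds need review."""


class RankError(SigsubtypeError):
    """Requested factorization rank is incompatible with the matrix dimensions."""


class DegenerateClusteringError(SigsubtypeError):
    """Every factorization run assigned all samples to a single cluster."""


class ConfigError(SigsubtypeError):
    """A simulation or pipeline configuration value is invalid."""


class UndefinedStatisticError(SigsubtypeError):
    """A test statistic is undefined for the given data (e.g. zero events)."""
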