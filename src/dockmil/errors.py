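"""Exception hierarchy for structure parsing, bag assembly and modeling."""


class DockmilError(Exception):
    """Base class for all package errors."""


class StructureFormatError(DockmilError):
    """File does not parse in the named dialect."""


class ElementError(DockmilError):
    """Unknown chemical element symbol."""


class EmptyInputError(DockmilError):
    """Structure contains no atoms (or ligand has no heavy atoms)."""


class MissingPoseError(DockmilError):
    """Entity has a label but zero poses."""


class DuplicateRankError(DockmilError):
    """Two poses of one entity share a pose_rank."""


class DimensionError(DockmilError):
    """Embedding dimension mismatch within a store."""


class MissingKeyError(DockmilError, KeyError):
    """Unknown entity in a store."""


class ChargeError(DockmilError):
    """Partial charges missing and the charge model is disabled."""


class GraphTypeError(DockmilError):
    """A backbone received a graph built for the other architecture."""


class DegenerateGraphError(DockmilError):
    """Fewer than two nodes; no graph can be built."""


class AtomMatchingError(DockmilError):
    """Pose pair cannot be matched atom-by-atom (count mismatch)."""


class ConfigurationError(DockmilError):
    """Inconsistent model or training configuration."""


class DataError(DockmilError):
    """Empty or misaligned training data."""
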