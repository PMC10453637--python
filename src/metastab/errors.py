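"""Exception hierarchy shared across the pipeline stages."""


class MetastabError(Exception):
    """Base class for all package-specific errors."""


class PDBParseError(MetastabError):
    """Malformed or inconsistent multi-model PDB input."""


class EmptyStructureError(PDBParseError):
    """File contains no ATOM records."""


class UnknownResidueError(MetastabError, KeyError):
    """A requested residue position is absent from the topology."""


class DegenerateResidueError(MetastabError):
    """A residue has no heavy atoms and cannot be featurized."""


class FrozenCoordinateError(MetastabError):
    """A feature column has (numerically) zero variance."""


class DimensionalityError(MetastabError, ValueError):
    """Requested more components than features allow."""


class InfeasibleClusteringError(MetastabError, ValueError):
    """K or the elbow scan range is infeasible for the number of frames."""


class ScoreTableFormatError(MetastabError, ValueError):
    """Malformed per-residue score table."""


class CoverageError(MetastabError, KeyError):
    """A neighborhood position is missing from the score table."""


class ComparabilityError(MetastabError, ValueError):
    """Two summaries are not defined over the same neighborhood."""


class AlignmentFormatError(MetastabError, ValueError):
    """Ragged or otherwise invalid multiple sequence alignment."""


class ValidationError(MetastabError, ValueError):
    """A numeric input violates its documented domain."""
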