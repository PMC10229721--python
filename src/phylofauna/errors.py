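"""Exception hierarchy shared across the package."""


class PhylofaunaError(Exception):
    """Base class for all package-specific errors."""


class NewickParseError(PhylofaunaError, ValueError):
    """Malformed Newick input."""


class TreeValidationError(PhylofaunaError, ValueError):
    """Tree violates an invariant (duplicate tips, negative branch lengths, ...)."""


class MissingSpeciesError(PhylofaunaError, KeyError):
    """Requested species are not tips of the tree / rows of a table."""

    def __init__(self, missing):
        self.missing = sorted(missing)
        super().__init__(f"species not found: {', '.join(self.missing)}")


class GenusResolutionError(PhylofaunaError, LookupError):
    """No congeneric tip available for a genus-level record."""


class ValidationError(PhylofaunaError, ValueError):
    """Input value outside its documented domain."""


class EmptyCommunityError(PhylofaunaError, ValueError):
    """A site has no species with positive abundance."""


class DegenerateScalingError(PhylofaunaError, ValueError):
    """Scaling a constant vector is undefined."""


class VocabularyError(PhylofaunaError, ValueError):
    """Annotation value outside the closed vocabulary for its grouping."""


class RankDeficiencyError(PhylofaunaError, ValueError):
    """Design matrix is singular; names the collinear terms."""


class PipelineStageError(PhylofaunaError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage, cause):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {cause}")
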