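"""Exception hierarchy used across the package."""


class CleavedockError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CleavedockError):
    """A configuration value is missing, inconsistent or infeasible."""


class StructureError(CleavedockError):
    """A structure lacks atoms or residues required by the analysis."""

class PoseFormatError(CleavedockError):
    """A pose file or ensemble violates the expected format."""


class EmptyInputError(CleavedockError):
    """An operation received an empty collection where data is required."""


class ValidationError(CleavedockError):
    """Input data contradicts its own declared content (e.g. mutant specs)."""


class MutantParseError(ValidationError):
    """A mutant construct name does not follow the supported grammar."""


class ComparisonError(CleavedockError):
    """Two structures cannot be compared atom-by-atom."""
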