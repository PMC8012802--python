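"""Exception hierarchy."""


class FoldcompareError(Exception):
    """Base class for all package errors."""


class ParseError(FoldcompareError):
    """A structure file failed to parse; message names the offending source."""


class FormatError(FoldcompareError):
    """Unknown or unsupported file format."""


class EmptyStructureError(FoldcompareError):
    """A parsed model contains no atoms."""


class ChainLookupError(FoldcompareError, KeyError):
    """Requested chain id absent from the model."""


class EmptySelectionError(FoldcompareError):
    """A residue-range slice selected nothing."""


class UnsupportedStructureError(FoldcompareError):
    """Operation needs unit cell / symmetry operators the model lacks."""


class SerializationError(FoldcompareError):
    """Coordinates or fields overflow the fixed-width PDB format."""


class TraceError(FoldcompareError):
    """A Cα trace violates a precondition (too short, bad interval, ...)."""


class AlignmentError(FoldcompareError):
    """Structural alignment failed or is undefined for the inputs."""


class TreeError(FoldcompareError):
    """Tree construction / comparison precondition violated."""


class InterfaceError(FoldcompareError):
    """Interface-analysis precondition violated (selections, radii, ...)."""


class SyntheticError(FoldcompareError):
    """Invalid synthetic-generator specification."""
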