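"""Exception hierarchy shared across the package."""


class GlycotreeError(Exception):
    """Base class for all package errors."""


class BuildError(GlycotreeError):
    """A structure could not be constructed (dangling reference, bad row)."""


class DegenerateFrameError(GlycotreeError):
    """A local geometric frame is singular (collinear reference atoms)."""


class NotRotatableError(GlycotreeError):
    """The requested bond does not separate the molecular graph."""


class TopologyError(GlycotreeError):
    """Invalid oligomer topology (consumed position, cyclic linkage graph)."""


class CatalogError(GlycotreeError):
    """Unknown or invalid residue/motif catalog entry."""


class ChainNotationError(GlycotreeError):
    """Invalid hydrogen-bond chain notation."""


class ChainRoleError(ChainNotationError):
    """An acceptor-only site appears in a donor position."""


class ChainVocabularyError(ChainNotationError):
    """A chain token is not a known site label."""


class ReversalError(GlycotreeError):
    """Attempted to reverse a chain flagged as irreversible."""


class DoubleDonationError(GlycotreeError):
    """One site is asked to donate in two different chains."""


class AnnotationError(GlycotreeError):
    """A conformer record lacks the requested annotation."""


class ScaleFactorError(GlycotreeError):
    """No scale factor available for a vibrational mode type."""


class EmptySpectrumError(GlycotreeError):
    """Spectrum operation received no modes."""


class TableFormatError(GlycotreeError):
    """A plain-text table failed to parse."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class SelectionError(GlycotreeError):
    """Block selection produced an empty set."""
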