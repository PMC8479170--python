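"""Exception types raised by plastdiv."""


class PlastdivError(Exception):
    """Base class for all plastdiv errors."""


class RaggedAlignmentError(PlastdivError):
    """Alignment records do not all share the same length."""


class DuplicateIdError(PlastdivError):
    """Two alignment records share an accession id."""


class MissingReferenceError(PlastdivError):
    """The designated reference accession is absent from the alignment."""


class OutOfRangeError(PlastdivError):
    """An annotation interval extends beyond the genome."""


class FrameError(PlastdivError):
    """A CDS whose concatenated length is not divisible by three."""


class NoInvertedRepeatError(PlastdivError):
    """No inverted-repeat pair of the required length was found."""


class NotProteinCodingError(PlastdivError):
    """Effect classification requested for a site outside a CDS."""


class UndefinedStatisticError(PlastdivError):
    """A statistic is undefined for the given input (e.g. n < 2, m = 0)."""


class DegenerateTreeError(PlastdivError):
    """Tree construction requested with fewer than three taxa."""


class SimulationError(PlastdivError):
    """Infeasible simulator configuration (e.g. gene packing does not fit)."""
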