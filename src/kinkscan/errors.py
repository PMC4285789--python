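"""Exception types raised across the package."""


class KinkscanError(Exception):
    """Base class for all package-specific errors."""


class StructureParseError(KinkscanError):
    """A structure file could not be read; the message names the offending record."""


class DsspAlignmentError(KinkscanError):
    """Residues in a DSSP file could not be matched to the chain."""


class DegenerateGeometryError(KinkscanError):
    """Points are collinear or otherwise unsuitable for a cylinder fit."""


class UndefinedWobbleError(KinkscanError):
    """Wobble angle requested where the kink angle is (numerically) zero."""


class MotifParseError(KinkscanError):
    """A motif expression could not be parsed; carries the failing position."""


class LengthMatchError(KinkscanError):
    """The pool cannot cover the target length distribution; lists deficient lengths."""


class ProfileMappingError(KinkscanError):
    """A structure sequence could not be located in the supplied alignment."""
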