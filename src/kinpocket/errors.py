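"""Exception hierarchy for the annotation pipeline."""


class KinpocketError(Exception):
    """Base class for all package errors."""


class InputError(KinpocketError, ValueError):
    """Invalid argument values (negative e-values, bad indices, ...)."""


class FormatError(KinpocketError):
    """Unparseable structure or dictionary file."""


class EmptyEntryError(KinpocketError):
    """Structure file contains no protein chain."""


class NotKinaseDomainError(KinpocketError):
    """Sequence does not align to the master profile above the score floor."""


class PocketUnresolvedError(KinpocketError):
    """More than half of the 85 pocket slots are unmapped."""


class InsufficientAnchorsError(KinpocketError):
    """Fewer than three anchor residues available for superposition."""


class UndefinedDescriptorError(KinpocketError):
    """A conformational descriptor cannot be computed (gap / missing atoms)."""


class FixtureSpecError(KinpocketError):
    """Contradictory or unrealizable synthetic-complex specification."""


class QueryError(KinpocketError):
    """Malformed search clause; the message names the offending clause."""
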