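"""Exception hierarchy."""


class PinnevoError(Exception):
    """Base class for all package errors."""


class AlignmentFormatError(PinnevoError):
    """Malformed alignment input (ragged rows, bad alphabet, duplicate taxa)."""


class FrameError(PinnevoError):
    """Reading-frame violation: length not divisible by 3, or internal stop."""


class ConsistencyError(PinnevoError):
    """Paired inputs disagree (e.g. CDS does not translate to its protein row)."""


class TaxonMismatchError(PinnevoError):
    """Tree and alignment (or two trees) name different taxon sets."""


class InvalidParameterError(PinnevoError):
    """Model or config parameter outside its domain."""


class DegenerateInputError(PinnevoError):
    """Input carries no usable signal (e.g. zero countable codons)."""


class NumericalError(PinnevoError):
    """Non-finite likelihood or failed decomposition, with diagnostics."""


class UnconvergedFitError(PinnevoError):
    """An operation required a converged fit but got an unconverged one."""
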