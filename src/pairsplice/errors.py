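"""Exception types shared across the package."""


class PairspliceError(Exception):
    """Base class for package errors."""


class ValidationError(PairspliceError):
    """An input value or configuration violates a documented invariant."""


class GenerationError(PairspliceError):
    """The synthetic generator could not honour its constraints for a gene."""


class ParseError(PairspliceError):
    """A text input file is malformed; message carries the line number."""
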