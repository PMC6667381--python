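"""Exception hierarchy shared by all rostrack modules."""


class RostrackError(Exception):
    """Base class for all errors raised by rostrack."""


class DomainError(RostrackError, ValueError):
    """A physical quantity is outside its admissible domain."""


class FitError(RostrackError, ValueError):
    """A regression or segmentation problem is degenerate or unsolvable."""


class NoPlateauError(FitError):
    """No three-phase partition with a valid plateau could be found."""


class SchemaError(RostrackError, ValueError):
    """Tabular input does not conform to the expected schema."""


class ChecksumError(RostrackError, ValueError):
    """A bundled fixture failed its integrity check."""
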