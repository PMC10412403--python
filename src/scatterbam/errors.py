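"""Exception hierarchy shared across the package."""


class ScatterbamError(Exception):
    """Base class for all scatterbam errors."""


class MalformedBlockError(ScatterbamError):
    """Bytes at the given offset are not a BGZF block (bad magic / framing)."""


class TruncatedBlockError(ScatterbamError):
    """A BGZF block's declared size extends past the end of the data."""


class BlockCorruptionError(ScatterbamError):
    """A BGZF block inflated but its CRC32 or ISIZE did not match."""


class BlockSizeError(ScatterbamError):
    """Payload too large to fit a single BGZF block."""


class NotABamError(ScatterbamError):
    """Data does not start with the BAM magic."""


class NotABaiError(ScatterbamError):
    """Data does not start with the BAI magic."""


class TruncationError(ScatterbamError):
    """Declared lengths extend past the available data."""


class InvalidRecordError(ScatterbamError):
    """An alignment record's fields are internally inconsistent."""


class UndefinedCoordinateError(ScatterbamError):
    """A coordinate operation was applied to an unmapped record."""


class UnsortedInputError(ScatterbamError):
    """Records violate coordinate order where sorted input is required."""


class RangeError(ScatterbamError, ValueError):
    """A numeric argument is outside its permitted range."""


class ConfigError(ScatterbamError):
    """Invalid simulation or pileup configuration."""


class JobError(ScatterbamError):
    """A scatter/gather worker raised; carries the failing job ordinal."""

    def __init__(self, ordinal: int, message: str = ""):
        self.ordinal = ordinal
        super().__init__(f"worker failed on job ordinal {ordinal}" + (f": {message}" if message else ""))
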