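"""Exception hierarchy shared across the toolkit."""


class IgtlError(Exception):
    """Base class for all igtplan errors."""


class FramingError(IgtlError):
    """Byte stream does not contain a well-formed message frame."""


class IntegrityError(IgtlError):
    """Body checksum does not match the header CRC."""


class MessageTypeError(IgtlError):
    """Message type name differs from the one the decoder expects."""


class UnsupportedTypeError(IgtlError):
    """Scalar type code outside the supported set."""


class ValidationError(IgtlError):
    """Domain object violates one of its invariants."""


class GeometryError(IgtlError):
    """Degenerate or inconsistent geometry input."""


class TimeoutError_(IgtlError):
    """Blocking receive exceeded its timeout."""
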