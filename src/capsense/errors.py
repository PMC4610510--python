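"""Exception hierarchy.

Plain argument mistakes (inverted bounds, bad enum values, out-of-order
updates) raise :class:`ValueError`; everything that reflects a property of
the *data* gets a dedicated class so callers can branch on it.
"""


class CapsenseError(Exception):
    """Base class for capsense-specific errors."""


class FormatError(CapsenseError):
    """A CSV or serialized model does not conform to the expected schema."""


class SchemaError(CapsenseError):
    """Input array is missing required frequency columns."""


class InsufficientDataError(CapsenseError):
    """Too few samples for the requested operation."""


class DegenerateDataError(CapsenseError):
    """Data is degenerate (constant column, non-positive denominator, ...)."""


class RankError(CapsenseError):
    """More latent components requested than the predictor matrix supports."""


class TransferError(CapsenseError):
    """Model transfer failed (e.g. non-positive attenuation factor)."""
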