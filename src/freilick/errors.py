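"""Exception types shared across the toolbox."""


class FreilickError(Exception):
    """Base class for all package errors."""


class ParameterError(FreilickError, ValueError):
    """A supplied parameter violates its contract."""


class DataError(FreilickError, ValueError):
    """Input data violate a structural invariant (ordering, finiteness)."""


class DegenerateTraceError(DataError):
    """A trace has zero robust scale (MAD = 0) and cannot be normalized."""


class ProtocolError(FreilickError, RuntimeError):
    """An agent returned a malformed action during a simulated session."""
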