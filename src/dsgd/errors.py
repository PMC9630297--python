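"""Exception hierarchy for the toolkit.

All errors raised by the library derive from :class:`DsgdError` so callers
can catch toolkit failures with one handler while tests can assert precise
failure modes.
"""


class DsgdError(Exception):
    """Base class for all toolkit errors."""


class SizingError(DsgdError, ValueError):
    """Input lengths violate a scheme precondition (randomness/secret mismatch,
    empty key-lifecycle component, chunk size <= 0, ...)."""


class PairingError(DsgdError, ValueError):
    """Two shares with the same identifier were offered for reconstruction."""


class IntegrityError(DsgdError):
    """Metadata or checksum mismatch between share containers."""


class ContainerCorruptError(IntegrityError):
    """A share container is truncated or structurally invalid."""


class KeyExhaustionError(DsgdError):
    """Not enough unconsumed key material to complete the operation.

    Contract: the failing operation consumes nothing."""


class KeyReuseError(DsgdError):
    """An attempt to use single-use key material (OTP bytes, Wegman-Carter
    (hash key, mask) pair) more than once."""


class ErasedKeyError(DsgdError):
    """Access to key material that has been erased."""


class TopologyError(DsgdError, ValueError):
    """Unknown node or link in a key network."""


class RoutingError(DsgdError):
    """No usable relay path between two nodes."""


class PolicyError(DsgdError, ValueError):
    """Invalid access-policy configuration."""


class VcfParseError(DsgdError, ValueError):
    """Malformed VCF record; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        super().__init__(message)
        self.line_number = line_number


class AuthenticationError(DsgdError):
    """Peer authentication failed or is unavailable; the session is refused."""


class ProtectedAreaError(DsgdError):
    """Protected-area discipline violated (capacity exceeded or TTL expired)."""


class PlacementError(DsgdError, ValueError):
    """Could not place simulated variants (over-dense truth set)."""
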