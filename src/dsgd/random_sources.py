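"""Randomness sources behind the ``rng(n) -> bytes`` contract.

The secure-storage design calls for keys from a physical/quantum random
number source without periodicity; in this toolkit that role is played by
the simulated key network.  Standalone operation uses the operating system
CSPRNG, and tests use a seeded deterministic stream (a SHAKE-256
extendable-output function in counter mode) so every artifact is bit-exactly
reproducible.
"""

from __future__ import annotations

import hashlib
import os
from typing import Callable

from .errors import KeyExhaustionError

RngLike = Callable[[int], bytes]


def system_rng(n: int) -> bytes:
    """Operating-system CSPRNG."""
    return os.urandom(n)


class SeededRng:
    """Deterministic cryptographic byte stream from an integer seed.

    Each call squeezes SHAKE-256 keyed by ``(seed, call counter)``; the
    counter gives domain separation so successive calls never overlap.
    """

    def __init__(self, seed: int):
        self._key = hashlib.sha256(b"dsgd-seed:" + str(int(seed)).encode()).digest()
        self._counter = 0

    def __call__(self, n: int) -> bytes:
        if n < 0:
            raise ValueError("cannot draw a negative number of bytes")
        block = self._counter.to_bytes(8, "big")
        self._counter += 1
        return hashlib.shake_256(self._key + block).digest(n) if n else b""


class PoolRng:
    """Draws from a finite pool of key material (e.g. a QKD key supply).

    Raises :class:`KeyExhaustionError` when the pool cannot cover a request;
    nothing is consumed on failure.
    """

    def __init__(self, supply: Callable[[int], bytes] | bytes):
        if isinstance(supply, (bytes, bytearray)):
            buf = bytes(supply)
            pos = 0

            def _draw(n: int) -> bytes:
                nonlocal pos
                if pos + n > len(buf):
                    raise KeyExhaustionError(
                        f"key pool exhausted: need {n}, have {len(buf) - pos}"
                    )
                out = buf[pos : pos + n]
                pos += n
                return out

            self._draw = _draw
        else:
            self._draw = supply

    def __call__(self, n: int) -> bytes:
        return self._draw(n)


def zero_rng(n: int) -> bytes:
    """All-zero 'randomness' for algebraic identity tests only."""
    return b"\x00" * n
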