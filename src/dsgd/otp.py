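"""One-time-pad transport, Wegman-Carter authentication, key lifecycle.

Three pieces of the service layer's cryptography live here:

* **OTP (Vernam) encryption** — XOR with an equal-length single-use key.
  :class:`OtpKeystream` enforces the single-use contract: consumed bytes are
  zeroized and the offset only moves forward.

* **Wegman-Carter authentication** — an information-theoretically secure MAC
  from a polynomial-evaluation universal hash over GF(2^w).  A message is
  zero-padded into w-bit blocks m_1..m_n and hashed as H = sum m_i h^i; the
  tag is H XOR a fresh one-time mask.  With single-use (h, mask) pairs the
  forgery probability for same-length messages is at most n/2^w.  Callers
  framing variable-length messages should bind the length into the message
  (the pipeline does).

* **Key generation-and-erasure lifecycle** — a key K0 from the key supply
  splits into a long-term part K1 (disk-class storage) and a short seed K2
  (memory-class storage); K2 expands through AES-128 in counter mode into a
  keystream K3 with size(K3) = size(K1); the OTP key is K4 = K1 XOR K3.
  Erasing the memory-class components first and the disk-class part second
  leaves nothing from which K4 can be recomputed — in particular K1 alone
  (e.g. recovered forensically from a disk) does not determine K4.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Dict, List, Literal

from ._aes import ctr_keystream
from .errors import ErasedKeyError, KeyExhaustionError, KeyReuseError, SizingError

__all__ = [
    "OtpKeystream",
    "otp_encrypt",
    "otp_decrypt",
    "gf_mul",
    "AuthTag",
    "wc_tag",
    "wc_verify",
    "reset_wc_usage",
    "KeyLifecycle",
    "lifecycle_derive",
    "lifecycle_erase",
    "GF_POLYS",
]

# Reducing polynomials (low part; the implicit x^w term is added on reduce):
#   w=8   AES polynomial x^8+x^4+x^3+x+1
#   w=64  x^64+x^4+x^3+x+1
#   w=128 x^128+x^7+x^2+x+1
GF_POLYS: Dict[int, int] = {8: 0x1B, 64: 0x1B, 128: 0x87}


# ---------------------------------------------------------------------------
# One-time pad
# ---------------------------------------------------------------------------


class OtpKeystream:
    """Single-use keystream over a finite key buffer.

    The offset increases monotonically; bytes behind it are zeroized and can
    never be drawn again.  ``clone()`` copies the *unconsumed* remainder so a
    receiver can decrypt what the sender encrypted — cloning models the two
    endpoints of a QKD link holding identical key material, not key reuse by
    one party.
    """

    def __init__(self, key_material: bytes):
        self._buf = bytearray(key_material)
        self._offset = 0

    @property
    def offset(self) -> int:
        return self._offset

    @property
    def remaining(self) -> int:
        return len(self._buf) - self._offset

    def clone(self) -> "OtpKeystream":
        return OtpKeystream(bytes(self._buf[self._offset :]))

    def take(self, n: int) -> bytes:
        if n > self.remaining:
            raise KeyExhaustionError(
                f"keystream exhausted: need {n}, have {self.remaining}"
            )
        out = bytes(self._buf[self._offset : self._offset + n])
        # best-effort erasure of the consumed bytes
        self._buf[self._offset : self._offset + n] = b"\x00" * n
        self._offset += n
        return out


def _xor_bytes(a: bytes, b: bytes) -> bytes:
    return bytes(x ^ y for x, y in zip(a, b)) if len(a) < 1024 else _np_xor(a, b)


def _np_xor(a: bytes, b: bytes) -> bytes:
    import numpy as np

    return (np.frombuffer(a, np.uint8) ^ np.frombuffer(b, np.uint8)).tobytes()


def otp_encrypt(plaintext: bytes, ks: OtpKeystream) -> bytes:
    """Vernam encryption: ciphertext = plaintext XOR next key bytes.

    Raises :class:`KeyExhaustionError` without consuming anything if the
    keystream cannot cover the plaintext.
    """
    if len(plaintext) > ks.remaining:
        raise KeyExhaustionError(
            f"insufficient key: need {len(plaintext)}, have {ks.remaining}"
        )
    return _xor_bytes(plaintext, ks.take(len(plaintext)))


def otp_decrypt(ciphertext: bytes, ks: OtpKeystream) -> bytes:
    """Symmetric to :func:`otp_encrypt` (XOR is an involution)."""
    return otp_encrypt(ciphertext, ks)


# ---------------------------------------------------------------------------
# GF(2^w) arithmetic and Wegman-Carter tags
# ---------------------------------------------------------------------------


def gf_mul(a: int, b: int, width: int = 128) -> int:
    """Multiply in GF(2^width) with the module's reducing polynomial."""
    try:
        poly = (1 << width) | GF_POLYS[width]
    except KeyError:
        raise ValueError(f"unsupported field width {width}; use one of {sorted(GF_POLYS)}")
    # carry-less product
    p = 0
    while b:
        if b & 1:
            p ^= a
        a <<= 1
        b >>= 1
    # polynomial reduction
    while p.bit_length() > width:
        p ^= poly << (p.bit_length() - 1 - width)
    return p


@dataclass(frozen=True)
class AuthTag:
    """A w-bit authentication tag with identifiers of the one-time keys."""

    tag: bytes
    hash_key_id: str
    mask_id: str


def _key_ids(width: int, hash_key: int, mask: bytes) -> tuple[str, str]:
    h = hashlib.sha256(f"{width}:{hash_key}".encode()).hexdigest()[:16]
    m = hashlib.sha256(mask).hexdigest()[:16]
    return h, m


def _poly_hash(message: bytes, hash_key: int, width: int) -> int:
    """H = sum_{i=1..n} m_i h^i over zero-padded w-bit blocks (Horner)."""
    bs = width // 8
    n = -(-len(message) // bs)
    padded = message + b"\x00" * (n * bs - len(message))
    acc = 0
    for i in range(n - 1, -1, -1):
        block = int.from_bytes(padded[i * bs : (i + 1) * bs], "big")
        acc = gf_mul(acc ^ block, hash_key, width)
    return acc


_used_wc_pairs: set = set()


def reset_wc_usage() -> None:
    """Forget recorded (hash key, mask) usage (test isolation only)."""
    _used_wc_pairs.clear()


def wc_tag(message: bytes, hash_key: int, mask: bytes, width: int = 128) -> AuthTag:
    """Tag a message with a one-time (hash key, mask) pair.

    ``hash_key`` is a field element of GF(2^width); ``mask`` is width/8 fresh
    OTP bytes.  Reusing a pair raises :class:`KeyReuseError` — universal-hash
    MACs lose their information-theoretic guarantee under key reuse.
    """
    bs = width // 8
    if len(mask) != bs:
        raise SizingError(f"mask must be {bs} bytes for width {width}")
    if not 0 <= hash_key < (1 << width):
        raise ValueError("hash_key outside field range")
    pair = (width, hash_key, bytes(mask))
    if pair in _used_wc_pairs:
        raise KeyReuseError("(hash_key, mask) pair already used")
    _used_wc_pairs.add(pair)
    h = _poly_hash(message, hash_key, width)
    tag = (h ^ int.from_bytes(mask, "big")).to_bytes(bs, "big")
    ids = _key_ids(width, hash_key, mask)
    return AuthTag(tag=tag, hash_key_id=ids[0], mask_id=ids[1])


def wc_verify(
    message: bytes, tag: AuthTag | bytes, hash_key: int, mask: bytes, width: int = 128
) -> bool:
    """Recompute the tag and compare in constant time."""
    bs = width // 8
    if len(mask) != bs:
        return False
    h = _poly_hash(message, hash_key, width)
    expected = (h ^ int.from_bytes(mask, "big")).to_bytes(bs, "big")
    given = tag.tag if isinstance(tag, AuthTag) else bytes(tag)
    if len(given) != bs:
        return False
    diff = 0
    for x, y in zip(expected, given):
        diff |= x ^ y
    return diff == 0


# ---------------------------------------------------------------------------
# Key generation-and-erasure lifecycle
# ---------------------------------------------------------------------------

_SEED_BYTES = 16  # AES-128 seed for the expander


@dataclass
class KeyLifecycle:
    """The K0 -> (K1, K2) -> K3 -> K4 record with per-component erasure.

    Components carry a store class: K1 is long_term (disk-like), K2/K3/K4
    short_term (memory-like).  Accessors raise :class:`ErasedKeyError` once
    a component is erased; the audit log records erase order.
    """

    _components: Dict[str, bytearray | None] = field(default_factory=dict)
    store_class: Dict[str, str] = field(default_factory=dict)
    audit_log: List[str] = field(default_factory=list)

    def _get(self, name: str) -> bytes:
        if name not in self._components:
            raise KeyError(name)
        buf = self._components[name]
        if buf is None:
            raise ErasedKeyError(f"{name} has been erased")
        return bytes(buf)

    @property
    def k1(self) -> bytes:
        return self._get("k1")

    @property
    def k2(self) -> bytes:
        return self._get("k2")

    @property
    def k3(self) -> bytes:
        return self._get("k3")

    @property
    def k4(self) -> bytes:
        return self._get("k4")

    def expand(self) -> bytes:
        """Re-derive K3 from K2 (errors once either source is erased)."""
        return ctr_keystream(self.k2, len(self.k1))

    def erased(self, name: str) -> bool:
        return self._components.get(name, None) is None

    def _erase(self, name: str) -> None:
        buf = self._components.get(name)
        if buf is not None:
            for i in range(len(buf)):
                buf[i] = 0
        self._components[name] = None
        self.audit_log.append(f"erase:{name}")


def lifecycle_derive(k0: bytes, split_point: int | None = None) -> KeyLifecycle:
    """Derive the OTP key K4 from a supplied key K0.

    ``k0[:split_point]`` becomes K1 (long-term store); the remaining bytes —
    exactly 16, the expander seed size — become K2 (short-term store).  K3 is
    the AES-128-CTR keystream seeded by K2 with len(K3) = len(K1), and
    K4 = K1 XOR K3.  Default split keeps the final 16 bytes as K2, honouring
    size(K1) >> size(K2) for any reasonably long K0.
    """
    k0 = bytes(k0)
    if split_point is None:
        split_point = len(k0) - _SEED_BYTES
    if not 0 < split_point < len(k0):
        raise SizingError("split must leave both K1 and K2 non-empty")
    k1, k2 = k0[:split_point], k0[split_point:]
    if len(k2) != _SEED_BYTES:
        raise SizingError(
            f"expander seed K2 must be {_SEED_BYTES} bytes, got {len(k2)}"
        )
    k3 = ctr_keystream(k2, len(k1))
    k4 = _xor_bytes(k1, k3)
    lc = KeyLifecycle()
    lc._components = {
        "k1": bytearray(k1),
        "k2": bytearray(k2),
        "k3": bytearray(k3),
        "k4": bytearray(k4),
    }
    lc.store_class = {
        "k1": "long_term",
        "k2": "short_term",
        "k3": "short_term",
        "k4": "short_term",
    }
    lc.audit_log.append(f"derive:len_k1={len(k1)},len_k2={len(k2)}")
    return lc


def lifecycle_erase(lc: KeyLifecycle, step: Literal["short_term", "long_term"]) -> KeyLifecycle:
    """Execute an erase step of the lifecycle.

    ``short_term`` (step 4) zeroizes K2, K3 and K4; ``long_term`` (step 5)
    zeroizes K1 and requires the short-term step to have happened first —
    the ordering that makes a later read of the long-term medium useless.
    """
    if step == "short_term":
        for name in ("k2", "k3", "k4"):
            lc._erase(name)
    elif step == "long_term":
        if not (lc.erased("k2") and lc.erased("k3")):
            raise ErasedKeyError(
                "short-term components must be erased before the long-term store"
            )
        lc._erase("k1")
    else:
        raise ValueError(f"unknown erase step {step!r}")
    return lc
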