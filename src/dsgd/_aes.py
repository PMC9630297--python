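"""Minimal AES-128 (encrypt-only) and a counter-mode keystream.

Used solely as the deterministic key-expansion primitive of the key
generation-and-erasure lifecycle: a short seed key expands into a long
keystream via AES-128 in counter mode (counter starts at zero, big-endian).
Correctness is pinned to the FIPS-197 appendix vector in the test suite.
Pure Python; throughput is adequate for the short keys this role needs.
"""

from __future__ import annotations

# S-box generated from the multiplicative inverse in GF(2^8) followed by the
# affine transform, per the standard definition.


def _build_sbox() -> list[int]:
    # GF(2^8) inverse via exponentiation tables over generator 3
    exp = [0] * 512
    log = [0] * 256
    x = 1
    for i in range(255):
        exp[i] = x
        log[x] = i
        # multiply by 3 = x * 2 ^ x
        x ^= (x << 1) ^ (0x11B if x & 0x80 else 0)
        x &= 0xFF
    for i in range(255, 512):
        exp[i] = exp[i - 255]

    def inv(b: int) -> int:
        return 0 if b == 0 else exp[255 - log[b]]

    sbox = []
    for b in range(256):
        q = inv(b)
        f = q
        for _ in range(4):
            q = ((q << 1) | (q >> 7)) & 0xFF
            f ^= q
        sbox.append(f ^ 0x63)
    return sbox


_SBOX = _build_sbox()
_XTIME = [((b << 1) ^ 0x1B) & 0xFF if b & 0x80 else (b << 1) for b in range(256)]
_MUL3 = [_XTIME[b] ^ b for b in range(256)]
_RCON = [0x01, 0x02, 0x04, 0x08, 0x10, 0x20, 0x40, 0x80, 0x1B, 0x36]


def expand_key(key: bytes) -> list[list[int]]:
    """AES-128 key schedule: 11 round keys as flat 16-byte lists."""
    if len(key) != 16:
        raise ValueError("AES-128 requires a 16-byte key")
    w = [list(key[4 * i : 4 * i + 4]) for i in range(4)]
    for i in range(4, 44):
        t = list(w[i - 1])
        if i % 4 == 0:
            t = t[1:] + t[:1]
            t = [_SBOX[b] for b in t]
            t[0] ^= _RCON[i // 4 - 1]
        w.append([a ^ b for a, b in zip(w[i - 4], t)])
    return [sum(w[4 * r : 4 * r + 4], []) for r in range(11)]


def encrypt_block(block: bytes, round_keys: list[list[int]]) -> bytes:
    """Encrypt one 16-byte block. State is column-major (index r + 4c)."""
    s = [b ^ k for b, k in zip(block, round_keys[0])]
    for rnd in range(1, 11):
        # SubBytes + ShiftRows fused
        s = [
            _SBOX[s[(i + 4 * (i % 4)) % 16]]  # row r shifted left by r
            for i in range(16)
        ]
        if rnd < 10:
            t = []
            for c in range(4):
                a0, a1, a2, a3 = s[4 * c : 4 * c + 4]
                t += [
                    _XTIME[a0] ^ _MUL3[a1] ^ a2 ^ a3,
                    a0 ^ _XTIME[a1] ^ _MUL3[a2] ^ a3,
                    a0 ^ a1 ^ _XTIME[a2] ^ _MUL3[a3],
                    _MUL3[a0] ^ a1 ^ a2 ^ _XTIME[a3],
                ]
            s = t
        rk = round_keys[rnd]
        s = [b ^ k for b, k in zip(s, rk)]
    return bytes(s)


def ctr_keystream(key: bytes, n_bytes: int, counter_start: int = 0) -> bytes:
    """AES-128-CTR keystream: counter is a 16-byte big-endian block integer."""
    rks = expand_key(key)
    out = bytearray()
    counter = counter_start
    while len(out) < n_bytes:
        out += encrypt_block(counter.to_bytes(16, "big"), rks)
        counter += 1
    return bytes(out[:n_bytes])
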