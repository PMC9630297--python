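"""XOR-based (2,3)-threshold secret sharing.

A secret byte string ``S`` is padded to even length and viewed as the
concatenation of two equal halves ``S = S1.S2``.  With fresh uniform
randomness ``R = R1.R2`` of the same size, the three shares are

    A = A1.A2 = (S1 ^ R1) . (S2 ^ R2 ^ R1)
    B = B1.B2 = (S1 ^ R1 ^ R2) . (S2 ^ R2)
    C = C1.C2 =  R1 . R2

Any two shares reconstruct ``S`` exactly; any single share is uniformly
distributed independently of ``S`` (information-theoretic secrecy).  Unlike
arithmetic (2,3) schemes with replicated shares, each share here is exactly
the size of the (padded) secret — no expansion.

The module operates on in-memory blocks (:func:`split_block`,
:func:`reconstruct_block`) and on streams of chunks for large files
(:func:`split_stream`, :func:`reconstruct_stream`) with a bespoke container
format (see :data:`MAGIC`).  Randomness is injected as a callable
``rng(n) -> bytes`` so the same code can draw from a simulated QKD key
supply, a seeded deterministic stream, or the operating system.
"""

from __future__ import annotations

import io
import struct
import zlib
from dataclasses import dataclass
from typing import BinaryIO, Callable, Iterable, Tuple

import numpy as np

from .errors import (
    ContainerCorruptError,
    IntegrityError,
    PairingError,
    SizingError,
)
from .random_sources import RngLike, system_rng

__all__ = [
    "SecretBlock",
    "RandomPair",
    "Share",
    "ShareMeta",
    "ShareTriple",
    "split_block",
    "reconstruct_block",
    "verify_triple",
    "split_stream",
    "reconstruct_stream",
    "split_file",
    "reconstruct_file",
    "read_container_meta",
    "MAGIC",
    "SCHEME_VERSION",
    "DEFAULT_CHUNK_SIZE",
]

MAGIC = b"DSGD"
SCHEME_VERSION = 1
DEFAULT_CHUNK_SIZE = 64 * 1024 * 1024  # 64 MiB; files in the tens of GB split into few chunks

_HEADER = struct.Struct("<4sBBBQQLL")  # magic, version, share_id, flags, chunk_size, original_length, chunk_count, meta_crc

_SHARE_IDS = ("A", "B", "C")


def _xor(a: bytes, b: bytes) -> bytes:
    """Bytewise XOR of two equal-length byte strings (numpy-backed)."""
    if len(a) != len(b):
        raise SizingError(f"xor operands differ in length: {len(a)} vs {len(b)}")
    if not a:
        return b""
    return (
        np.frombuffer(a, dtype=np.uint8) ^ np.frombuffer(b, dtype=np.uint8)
    ).tobytes()


@dataclass(frozen=True)
class SecretBlock:
    """A secret with its pre-padding length.

    ``data`` holds the padded working buffer (even length, zero pad byte if
    the original was odd); ``original_length`` is the byte count before
    padding, used to truncate on reconstruction.
    """

    data: bytes
    original_length: int

    @classmethod
    def from_bytes(cls, raw: bytes) -> "SecretBlock":
        raw = bytes(raw)
        padded = raw + b"\x00" if len(raw) % 2 else raw
        return cls(data=padded, original_length=len(raw))

    @property
    def halves(self) -> Tuple[bytes, bytes]:
        h = len(self.data) // 2
        return self.data[:h], self.data[h:]

    @property
    def secret(self) -> bytes:
        """The original (unpadded) secret."""
        return self.data[: self.original_length]


@dataclass(frozen=True)
class RandomPair:
    """The randomness R = R1.R2; each half sized to half the padded secret."""

    r1: bytes
    r2: bytes

    def __post_init__(self):
        if len(self.r1) != len(self.r2):
            raise SizingError(
                f"randomness halves differ: {len(self.r1)} vs {len(self.r2)}"
            )

    @classmethod
    def draw(cls, half_length: int, rng: RngLike) -> "RandomPair":
        return cls(r1=rng(half_length), r2=rng(half_length))


@dataclass(frozen=True)
class ShareMeta:
    """Container metadata, identical across the three shares of one secret."""

    scheme_version: int
    original_length: int
    chunk_size: int
    chunk_count: int

    def __post_init__(self):
        if self.chunk_size <= 0:
            raise SizingError("chunk_size must be positive")
        expected = max(1, -(-self.original_length // self.chunk_size))
        if self.chunk_count != expected:
            raise IntegrityError(
                f"chunk_count {self.chunk_count} inconsistent with "
                f"original_length {self.original_length} / chunk_size {self.chunk_size}"
            )

    @property
    def checksum(self) -> int:
        packed = struct.pack(
            "<BQQL",
            self.scheme_version,
            self.chunk_size,
            self.original_length,
            self.chunk_count,
        )
        return zlib.crc32(packed) & 0xFFFFFFFF

    def chunk_lengths(self) -> Iterable[int]:
        """Pre-padding byte length of each chunk in order."""
        remaining = self.original_length
        for _ in range(self.chunk_count):
            yield min(self.chunk_size, remaining)
            remaining -= min(self.chunk_size, remaining)


@dataclass(frozen=True)
class Share:
    """One share (A, B, or C) as its two halves plus container metadata."""

    share_id: str
    half1: bytes
    half2: bytes
    meta: ShareMeta

    def __post_init__(self):
        if self.share_id not in _SHARE_IDS:
            raise ValueError(f"share_id must be one of {_SHARE_IDS}")
        if len(self.half1) != len(self.half2):
            raise SizingError("share halves differ in length")

    @property
    def payload(self) -> bytes:
        return self.half1 + self.half2


@dataclass(frozen=True)
class ShareTriple:
    a: Share
    b: Share
    c: Share

    def __iter__(self):
        return iter((self.a, self.b, self.c))


def _single_block_meta(original_length: int, chunk_size: int | None = None) -> ShareMeta:
    if chunk_size is None:
        chunk_size = max(original_length, 1)
    return ShareMeta(
        scheme_version=SCHEME_VERSION,
        original_length=original_length,
        chunk_size=chunk_size,
        chunk_count=max(1, -(-original_length // chunk_size)),
    )


def split_block(
    secret: SecretBlock | bytes,
    randomness: RandomPair | None = None,
    rng: RngLike | None = None,
) -> ShareTriple:
    """Split one secret block into the (2,3) shares A, B, C.

    Parameters
    ----------
    secret
        The secret, either raw bytes or a prepared :class:`SecretBlock`.
    randomness
        The pair (R1, R2); each half must match the padded secret halves in
        length.  If omitted, drawn from ``rng`` (default: OS randomness).
    rng
        ``rng(n) -> bytes`` used only when ``randomness`` is None.
    """
    if not isinstance(secret, SecretBlock):
        secret = SecretBlock.from_bytes(secret)
    s1, s2 = secret.halves
    if randomness is None:
        randomness = RandomPair.draw(len(s1), rng or system_rng)
    r1, r2 = randomness.r1, randomness.r2
    if len(r1) != len(s1):
        raise SizingError(
            f"randomness half length {len(r1)} does not match secret half {len(s1)}"
        )
    meta = _single_block_meta(secret.original_length)
    a = Share("A", _xor(s1, r1), _xor(_xor(s2, r2), r1), meta)
    b = Share("B", _xor(_xor(s1, r1), r2), _xor(s2, r2), meta)
    c = Share("C", r1, r2, meta)
    return ShareTriple(a, b, c)


def reconstruct_block(x: Share, y: Share) -> SecretBlock:
    """Reconstruct the secret from any two distinct shares.

    The reconstruction identities follow algebraically from the share
    formulas:

    - from (A, C): ``S1 = A1^C1``,        ``S2 = A2^C2^C1``
    - from (B, C): ``S1 = B1^C1^C2``,     ``S2 = B2^C2``
    - from (A, B): ``S1 = A1^A2^B2``,     ``S2 = A1^B1^B2``
    """
    if x.share_id == y.share_id:
        raise PairingError(f"need two distinct shares, got {x.share_id} twice")
    if x.meta != y.meta:
        raise IntegrityError("share metadata mismatch: shares are not from one split")
    by_id = {x.share_id: x, y.share_id: y}
    pair = frozenset(by_id)
    if pair == frozenset("AC"):
        a, c = by_id["A"], by_id["C"]
        s1 = _xor(a.half1, c.half1)
        s2 = _xor(_xor(a.half2, c.half2), c.half1)
    elif pair == frozenset("BC"):
        b, c = by_id["B"], by_id["C"]
        s1 = _xor(_xor(b.half1, c.half1), c.half2)
        s2 = _xor(b.half2, c.half2)
    else:  # (A, B)
        a, b = by_id["A"], by_id["B"]
        s1 = _xor(_xor(a.half1, a.half2), b.half2)
        s2 = _xor(_xor(a.half1, b.half1), b.half2)
    return SecretBlock(data=s1 + s2, original_length=x.meta.original_length)


def verify_triple(t: ShareTriple) -> bool:
    """Consistency check across all three shares.

    The share formulas force ``A1^B1 = R2 = C2`` and ``A2^B2 = R1 = C1`` at
    every byte position; any payload perturbation in a single share breaks
    at least one of the identities.
    """
    if not (t.a.meta == t.b.meta == t.c.meta):
        return False
    if t.a.share_id != "A" or t.b.share_id != "B" or t.c.share_id != "C":
        return False
    try:
        return (
            _xor(t.a.half1, t.b.half1) == t.c.half2
            and _xor(t.a.half2, t.b.half2) == t.c.half1
        )
    except SizingError:
        return False


# ---------------------------------------------------------------------------
# Streaming container format
#
# Header: magic "DSGD" | version u8 | share_id u8 (0x41/0x42/0x43) | flags u8
#         | chunk_size u64le | original_length u64le | chunk_count u32le
#         | meta crc32 u32le
# Body:   per chunk, half1 then half2, each ceil(padded_chunk_length / 2).
# Metadata is stored in the clear: share/OTP schemes inherently leak length.
# ---------------------------------------------------------------------------


def _write_header(sink: BinaryIO, share_id: str, meta: ShareMeta) -> None:
    sink.write(
        _HEADER.pack(
            MAGIC,
            meta.scheme_version,
            ord(share_id),
            0,
            meta.chunk_size,
            meta.original_length,
            meta.chunk_count,
            meta.checksum,
        )
    )


def _read_header(source: BinaryIO) -> Tuple[str, ShareMeta]:
    raw = source.read(_HEADER.size)
    if len(raw) != _HEADER.size:
        raise ContainerCorruptError("container shorter than header")
    magic, version, sid, _flags, chunk_size, orig_len, chunk_count, crc = _HEADER.unpack(raw)
    if magic != MAGIC:
        raise ContainerCorruptError("bad magic bytes: not a share container")
    try:
        meta = ShareMeta(version, orig_len, chunk_size, chunk_count)
    except (SizingError, IntegrityError) as exc:
        raise ContainerCorruptError(f"invalid container metadata: {exc}") from exc
    if meta.checksum != crc:
        raise IntegrityError("metadata checksum mismatch")
    share_id = chr(sid)
    if share_id not in _SHARE_IDS:
        raise ContainerCorruptError(f"unknown share id byte 0x{sid:02x}")
    return share_id, meta


def read_container_meta(source: BinaryIO | str) -> Tuple[str, ShareMeta]:
    """Read and validate the header of a share container."""
    if isinstance(source, str):
        with open(source, "rb") as fh:
            return _read_header(fh)
    return _read_header(source)


def split_stream(
    source: BinaryIO,
    sinks: Tuple[BinaryIO, BinaryIO, BinaryIO],
    chunk_size: int = DEFAULT_CHUNK_SIZE,
    rng: RngLike | None = None,
) -> ShareMeta:
    """Split a byte stream chunk-by-chunk into three share containers.

    Each chunk is split independently with fresh randomness; the three sinks
    receive containers with identical metadata.  Sinks must be seekable: the
    header is back-patched once the total length is known.
    """
    if chunk_size <= 0:
        raise SizingError("chunk_size must be positive")
    rng = rng or system_rng
    placeholders = {}
    for sid, sink in zip(_SHARE_IDS, sinks):
        placeholders[sid] = sink.tell()
        sink.write(b"\x00" * _HEADER.size)

    total = 0
    chunk_count = 0
    while True:
        chunk = source.read(chunk_size)
        if not chunk and chunk_count > 0:
            break
        triple = split_block(chunk, rng=rng)
        for share, sink in zip(triple, sinks):
            sink.write(share.half1)
            sink.write(share.half2)
        total += len(chunk)
        chunk_count += 1
        if len(chunk) < chunk_size:
            break

    meta = ShareMeta(SCHEME_VERSION, total, chunk_size, chunk_count)
    for sid, sink in zip(_SHARE_IDS, sinks):
        end = sink.tell()
        sink.seek(placeholders[sid])
        _write_header(sink, sid, meta)
        sink.seek(end)
    return meta


def reconstruct_stream(
    container_x: BinaryIO,
    container_y: BinaryIO,
    sink: BinaryIO,
) -> int:
    """Reconstruct the original stream from two share containers.

    Returns the number of bytes written.  Containers must come from the same
    split (equal metadata checksums) and carry distinct share ids.
    """
    sid_x, meta_x = _read_header(container_x)
    sid_y, meta_y = _read_header(container_y)
    if sid_x == sid_y:
        raise PairingError(f"need two distinct shares, got {sid_x} twice")
    if meta_x != meta_y or meta_x.checksum != meta_y.checksum:
        raise IntegrityError("containers are not from the same split")

    written = 0
    for chunk_len in meta_x.chunk_lengths():
        half_len = (chunk_len + 1) // 2
        shares = []
        for sid, src in ((sid_x, container_x), (sid_y, container_y)):
            h1 = src.read(half_len)
            h2 = src.read(half_len)
            if len(h1) != half_len or len(h2) != half_len:
                raise ContainerCorruptError("container truncated mid-chunk")
            shares.append(Share(sid, h1, h2, _single_block_meta(chunk_len)))
        block = reconstruct_block(*shares)
        sink.write(block.secret)
        written += len(block.secret)
    return written


def split_file(
    in_path: str,
    out_prefix: str,
    chunk_size: int = DEFAULT_CHUNK_SIZE,
    rng: RngLike | None = None,
) -> Tuple[str, str, str]:
    """Split a file into ``<prefix>.share-A/B/C`` containers; returns paths."""
    paths = tuple(f"{out_prefix}.share-{sid}" for sid in _SHARE_IDS)
    with open(in_path, "rb") as src, open(paths[0], "wb") as fa, open(
        paths[1], "wb"
    ) as fb, open(paths[2], "wb") as fc:
        split_stream(src, (fa, fb, fc), chunk_size=chunk_size, rng=rng)
    return paths


def reconstruct_file(share_x_path: str, share_y_path: str, out_path: str) -> int:
    """Reconstruct a file from two share container files."""
    with open(share_x_path, "rb") as fx, open(share_y_path, "rb") as fy, open(
        out_path, "wb"
    ) as out:
        return reconstruct_stream(fx, fy, out)


def split_bytes(
    data: bytes, chunk_size: int = DEFAULT_CHUNK_SIZE, rng: RngLike | None = None
) -> Tuple[bytes, bytes, bytes]:
    """Convenience: split in-memory bytes, returning three container blobs."""
    sinks = (io.BytesIO(), io.BytesIO(), io.BytesIO())
    split_stream(io.BytesIO(data), sinks, chunk_size=chunk_size, rng=rng)
    return tuple(s.getvalue() for s in sinks)


def reconstruct_bytes(container_x: bytes, container_y: bytes) -> bytes:
    """Convenience: reconstruct from two in-memory container blobs."""
    out = io.BytesIO()
    reconstruct_stream(io.BytesIO(container_x), io.BytesIO(container_y), out)
    return out.getvalue()
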