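"""Small I/O helpers shared across modules.

Gzip members are written with ``mtime=0`` and no filename so that
same-seed runs produce byte-identical ``.gz`` artifacts.
"""

from __future__ import annotations

import gzip
import io
from typing import IO

GZIP_MAGIC = b"\x1f\x8b"


def is_gzip_path(path: str) -> bool:
    with open(path, "rb") as fh:
        return fh.read(2) == GZIP_MAGIC


def open_maybe_gzip(path: str, mode: str = "rt") -> IO:
    """Open a file transparently whether or not it is gzip-compressed.

    Reading sniffs the magic bytes; writing compresses iff the path ends in
    ``.gz`` (deterministically: fixed mtime, no embedded name).
    """
    if "r" in mode:
        if is_gzip_path(path):
            return gzip.open(path, mode)
        return open(path, mode)
    if path.endswith(".gz"):
        return deterministic_gzip_writer(path, mode)
    return open(path, mode)


class _ClosesUnderlying(io.TextIOWrapper):
    """TextIOWrapper that also closes the raw file under the gzip member."""

    def __init__(self, buffer, raw, **kwargs):
        self._raw_file = raw
        super().__init__(buffer, **kwargs)

    def close(self):
        try:
            super().close()
        finally:
            if not self._raw_file.closed:
                self._raw_file.close()


class _ClosingGzipFile(gzip.GzipFile):
    """GzipFile that also closes the raw file it writes into."""

    def __init__(self, raw, **kwargs):
        self._raw_file = raw
        super().__init__(filename="", fileobj=raw, **kwargs)

    def close(self):
        try:
            super().close()
        finally:
            if not self._raw_file.closed:
                self._raw_file.close()


def deterministic_gzip_writer(path: str, mode: str = "wt") -> IO:
    raw = open(path, "wb")
    gz = _ClosingGzipFile(raw, mode="wb", mtime=0)
    if "t" in mode:
        return _ClosesUnderlying(gz, raw, encoding="utf-8", newline="")
    return gz


def gzip_bytes(data: bytes) -> bytes:
    """Deterministically gzip a byte string (fixed mtime)."""
    buf = io.BytesIO()
    with gzip.GzipFile(fileobj=buf, mode="wb", mtime=0) as gz:
        gz.write(data)
    return buf.getvalue()


def gunzip_bytes(data: bytes) -> bytes:
    return gzip.decompress(data)
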