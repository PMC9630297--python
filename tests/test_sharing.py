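"""XOR (2,3)-threshold secret sharing: formulas, round trips, secrecy."""

import io

import pytest
from hypothesis import given, settings, strategies as st

from dsgd.errors import ContainerCorruptError, IntegrityError, PairingError, SizingError
from dsgd.random_sources import SeededRng, zero_rng
from dsgd.sharing import (
    RandomPair,
    SecretBlock,
    Share,
    ShareTriple,
    reconstruct_block,
    reconstruct_bytes,
    reconstruct_stream,
    split_block,
    split_bytes,
    split_stream,
    verify_triple,
)


def oracle_split(s1: int, s2: int, r1: int, r2: int):
    """Independent brute-force evaluation of the printed share formulas
    on nibble-sized halves."""
    return {
        "A": (s1 ^ r1, s2 ^ r2 ^ r1),
        "B": (s1 ^ r1 ^ r2, s2 ^ r2),
        "C": (r1, r2),
    }


def _nibble_triple(s1, s2, r1, r2) -> ShareTriple:
    return split_block(
        SecretBlock(bytes([s1, s2]), 2), RandomPair(bytes([r1]), bytes([r2]))
    )


class TestSplitBlock:
    def test_worked_nibble_example(self):
        t = _nibble_triple(0xA, 0x6, 0x3, 0x5)
        assert (t.a.half1[0], t.a.half2[0]) == (0x9, 0x0)
        assert (t.b.half1[0], t.b.half2[0]) == (0xC, 0x3)
        assert (t.c.half1[0], t.c.half2[0]) == (0x3, 0x5)

    def test_zero_randomness_identity(self):
        secret = b"\xde\xad\xbe\xef"
        t = split_block(secret, rng=zero_rng)
        assert t.a.payload == secret and t.b.payload == secret
        assert t.c.payload == b"\x00" * 4

    def test_empty_secret(self):
        t = split_block(b"")
        assert t.a.payload == b"" and t.c.payload == b""
        assert t.a.meta.original_length == 0
        assert reconstruct_block(t.a, t.c).secret == b""

    def test_odd_length_padding_truncated_on_reconstruction(self):
        t = split_block(b"HELLO", rng=SeededRng(3))
        assert len(t.a.payload) == 6  # padded to even
        assert reconstruct_block(t.b, t.c).secret == b"HELLO"

    def test_randomness_size_mismatch_rejected(self):
        with pytest.raises(SizingError):
            split_block(b"ABCD", RandomPair(b"\x00", b"\x00"))

    def test_share_size_equals_padded_secret_size(self):
        # no expansion: each share is exactly the padded secret size
        for n in (2, 7, 100):
            t = split_block(b"x" * n, rng=SeededRng(n))
            padded = n + (n % 2)
            assert all(len(s.payload) == padded for s in t)


class TestReconstruction:
    @pytest.mark.parametrize("pair", ["AC", "BC", "AB"])
    def test_oracle_equivalence_exhaustive_nibbles(self, pair):
        """All 256 (secret, randomness) nibble combinations agree with the
        brute-force oracle for every reconstruction pair."""
        for s in range(16):
            s1, s2 = s >> 2, s & 0x3
            for r in range(16):
                r1, r2 = r >> 2, r & 0x3
                t = _nibble_triple(s1, s2, r1, r2)
                expected = oracle_split(s1, s2, r1, r2)
                for share, sid in ((t.a, "A"), (t.b, "B"), (t.c, "C")):
                    assert (share.half1[0], share.half2[0]) == expected[sid]
                by_id = {"A": t.a, "B": t.b, "C": t.c}
                got = reconstruct_block(by_id[pair[0]], by_id[pair[1]])
                assert got.secret == bytes([s1, s2])

    def test_order_insensitive(self):
        t = split_block(b"some secret", rng=SeededRng(0))
        assert reconstruct_block(t.c, t.a).secret == b"some secret"

    def test_same_share_twice_rejected(self):
        t = split_block(b"xy", rng=SeededRng(0))
        with pytest.raises(PairingError):
            reconstruct_block(t.a, t.a)

    def test_meta_mismatch_rejected(self):
        t1 = split_block(b"xy", rng=SeededRng(0))
        t2 = split_block(b"wxyz", rng=SeededRng(0))
        with pytest.raises(IntegrityError):
            reconstruct_block(t1.a, t2.c)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(secret=st.binary(max_size=2048), seed=st.integers(0, 2**31 - 1))
    def test_round_trip_property(self, secret, seed):
        t = split_block(secret, rng=SeededRng(seed))
        for x, y in ((t.a, t.b), (t.a, t.c), (t.b, t.c)):
            assert reconstruct_block(x, y).secret == secret


class TestPerfectSecrecy:
    def test_each_share_uniform_over_randomness(self):
        """For every fixed 4-bit secret, each single share takes each of its
        16 possible values exactly once as the randomness ranges over all 16
        values — the share alone carries no information about the secret."""
        for s in range(16):
            s1, s2 = s >> 2, s & 0x3
            counts = {"A": {}, "B": {}, "C": {}}
            for r in range(16):
                r1, r2 = r >> 2, r & 0x3
                t = _nibble_triple(s1, s2, r1, r2)
                for sid, share in (("A", t.a), ("B", t.b), ("C", t.c)):
                    v = (share.half1[0] << 2) | share.half2[0]
                    counts[sid][v] = counts[sid].get(v, 0) + 1
            for sid in "ABC":
                assert sorted(counts[sid]) == list(range(16))
                assert set(counts[sid].values()) == {1}


class TestVerifyTriple:
    def test_valid_split_verifies(self):
        t = split_block(b"payload bytes", rng=SeededRng(5))
        assert verify_triple(t)
        # hand-checked worked example: 0x9^0xC=0x5=C2 and 0x0^0x3=0x3=C1
        assert verify_triple(_nibble_triple(0xA, 0x6, 0x3, 0x5))

    def test_all_zero_shares_verify(self):
        t = split_block(b"\x00\x00", RandomPair(b"\x00", b"\x00"))
        assert verify_triple(t)

    @pytest.mark.parametrize("which", ["a", "b", "c"])
    def test_any_single_bit_flip_detected(self, which):
        t = split_block(b"0123456789", rng=SeededRng(9))
        share = getattr(t, which)
        for half_attr in ("half1", "half2"):
            half = bytearray(getattr(share, half_attr))
            for byte_i in (0, len(half) - 1):
                for bit in (0, 7):
                    mutated = bytearray(half)
                    mutated[byte_i] ^= 1 << bit
                    kwargs = {
                        "share_id": share.share_id,
                        "half1": share.half1,
                        "half2": share.half2,
                        "meta": share.meta,
                        half_attr: bytes(mutated),
                    }
                    bad = Share(**kwargs)
                    triple = ShareTriple(**{**{"a": t.a, "b": t.b, "c": t.c}, which: bad})
                    assert not verify_triple(triple)


class TestStreaming:
    def test_hello_zero_randomness_containers(self):
        containers = split_bytes(b"HELLO", chunk_size=1024, rng=zero_rng)
        # payload region after the fixed header: A carries the padded secret,
        # C carries the all-zero randomness
        from dsgd.sharing import _HEADER

        assert containers[0][_HEADER.size :] == b"HELLO\x00"
        assert containers[2][_HEADER.size :] == b"\x00" * 6

    @pytest.mark.parametrize("size,chunk", [(0, 1024), (5, 1024), (100_000, 2**14), (65_536, 2**16)])
    def test_round_trip_all_pairs(self, size, chunk):
        data = SeededRng(size + 1)(size)
        containers = split_bytes(data, chunk_size=chunk, rng=SeededRng(2))
        for i, j in ((0, 1), (0, 2), (1, 2)):
            assert reconstruct_bytes(containers[i], containers[j]) == data

    def test_empty_stream_single_empty_chunk(self):
        containers = split_bytes(b"", rng=SeededRng(0))
        from dsgd.sharing import read_container_meta

        _, meta = read_container_meta(io.BytesIO(containers[0]))
        assert meta.chunk_count == 1 and meta.original_length == 0
        assert reconstruct_bytes(containers[0], containers[1]) == b""

    def test_multi_chunk_split_counts(self):
        data = SeededRng(8)(100_000)
        containers = split_bytes(data, chunk_size=64_000, rng=SeededRng(8))
        from dsgd.sharing import read_container_meta

        _, meta = read_container_meta(io.BytesIO(containers[1]))
        assert meta.chunk_count == 2

    def test_same_container_pair_rejected(self):
        containers = split_bytes(b"HELLO", rng=SeededRng(0))
        with pytest.raises(PairingError):
            reconstruct_bytes(containers[1], containers[1])

    def test_truncated_container_detected(self):
        containers = split_bytes(b"0123456789" * 100, rng=SeededRng(0))
        with pytest.raises(ContainerCorruptError):
            reconstruct_bytes(containers[0][:-3], containers[1])

    def test_mixed_split_containers_detected(self):
        c1 = split_bytes(b"abcdef", rng=SeededRng(1))
        c2 = split_bytes(b"abcdefgh", rng=SeededRng(2))
        with pytest.raises(IntegrityError):
            reconstruct_bytes(c1[0], c2[2])

    def test_bad_magic_rejected(self):
        containers = split_bytes(b"abc", rng=SeededRng(1))
        with pytest.raises(ContainerCorruptError):
            reconstruct_bytes(b"XXXX" + containers[0][4:], containers[1])

    def test_invalid_chunk_size_rejected(self):
        with pytest.raises(SizingError):
            split_stream(io.BytesIO(b"x"), (io.BytesIO(), io.BytesIO(), io.BytesIO()), chunk_size=0)

    def test_file_round_trip(self, tmp_path):
        from dsgd.sharing import reconstruct_file, split_file

        data = SeededRng(77)(12_345)
        src = tmp_path / "input.bin"
        src.write_bytes(data)
        a, b, c = split_file(str(src), str(tmp_path / "input"), rng=SeededRng(7))
        out = tmp_path / "restored.bin"
        reconstruct_file(b, c, str(out))
        assert out.read_bytes() == data
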