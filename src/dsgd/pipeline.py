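"""End-to-end protocol: deposit, authenticated serving, metrics.

The service layer at desk scale.  A data owner (co-located with the
trusted server) splits a genomic file into three XOR shares, keeps share A
and sends B and C to holder nodes over one-time-pad links keyed by the
simulated QKD network.  When an authenticated user requests analysis, the
owner fetches one holder share back, reconstructs the FASTQ inside a
bounded protected area, runs a pluggable variant caller, filters the VCF
under the user's access policy, and delivers the compressed result over
OTP using a derive-then-erase key lifecycle.  Every stage is timed and the
five throughput metrics are computed from the recorded sizes and times:

    A       = (size(FASTQ) + size(VCF))       * 8 / (1e6 * t_A)
    B-1     = (size(VCF.gz) + size(VCF))      * 8 / (1e6 * t_B1)
    B-2     = (size(VCF) + size(F_VCF))       * 8 / (1e6 * t_B2)
    B-3     = (size(F_VCF) + size(F_VCF.gz))  * 8 / (1e6 * t_B3)
    Total   = size(FASTQ)                     * 8 / (1e6 * t_total)

in Mbit/s with MB = 10^6 bytes (the convention under which the published
total-throughput rows reconcile).  ``processing time`` includes format
transforms, and F_VCF denotes the filtered VCF released to the user.
"""

from __future__ import annotations

import hashlib
import io
import time
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Tuple

from . import sharing
from .disclosure import AccessPolicy, DisclosureResult, filter_vcf, normalize_policy
from .errors import (
    AuthenticationError,
    IntegrityError,
    KeyExhaustionError,
    ProtectedAreaError,
)
from .fixtures import ReadSimProfile, gen_reference, gen_truth_and_reads, gen_vcf, toy_call_variants
from .io_utils import gunzip_bytes, gzip_bytes
from .keynet import KeyNetwork, default_topology, generate_link_keys, supply_key
from .keynet import audit as keynet_audit
from .otp import (
    OtpKeystream,
    lifecycle_derive,
    lifecycle_erase,
    otp_decrypt,
    otp_encrypt,
    wc_tag,
    wc_verify,
)

__all__ = [
    "Session",
    "StageTiming",
    "ThroughputReport",
    "ProtectedArea",
    "InMemoryTransport",
    "TrustedPipeline",
    "compute_throughputs",
    "run_demo",
]

_WC_WIDTH = 128
_WC_BYTES = _WC_WIDTH // 8


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StageTiming:
    """One pipeline stage: label, bytes in/out, elapsed seconds."""

    stage: str  # one of: call (A), decompress (B-1), filter (B-2), compress (B-3), deliver (C)
    input_size: int
    output_size: int
    elapsed: float


@dataclass
class ThroughputReport:
    """Sizes, stage times and the five throughputs (Mbit/s, MB = 1e6 B)."""

    size_fastq: int
    size_vcf: int
    size_vcf_gz: int
    size_f_vcf: int
    size_f_vcf_gz: int
    t_a: float
    t_b1: float
    t_b2: float
    t_b3: float
    t_total: float
    throughput_a: float = 0.0
    throughput_b1: float = 0.0
    throughput_b2: float = 0.0
    throughput_b3: float = 0.0
    throughput_total: float = 0.0

    def recompute(self) -> Dict[str, float]:
        """Re-evaluate the metric formulas from the stored sizes and times."""
        return {
            "throughput_a": _mbit(self.size_fastq + self.size_vcf, self.t_a),
            "throughput_b1": _mbit(self.size_vcf_gz + self.size_vcf, self.t_b1),
            "throughput_b2": _mbit(self.size_vcf + self.size_f_vcf, self.t_b2),
            "throughput_b3": _mbit(self.size_f_vcf + self.size_f_vcf_gz, self.t_b3),
            "throughput_total": _mbit(self.size_fastq, self.t_total),
        }


def _mbit(n_bytes: int, seconds: float) -> float:
    return n_bytes * 8 / (1e6 * seconds)


def compute_throughputs(
    size_fastq: int,
    size_vcf: int,
    size_vcf_gz: int,
    size_f_vcf: int,
    size_f_vcf_gz: int,
    t_a: float,
    t_b1: float,
    t_b2: float,
    t_b3: float,
    t_total: float,
) -> ThroughputReport:
    """Evaluate the five throughput formulas; sizes in bytes, times in s."""
    for label, value in (("t_a", t_a), ("t_b1", t_b1), ("t_b2", t_b2),
                         ("t_b3", t_b3), ("t_total", t_total)):
        if value <= 0:
            raise ValueError(f"{label} must be positive, got {value}")
    for label, value in (("size_fastq", size_fastq), ("size_vcf", size_vcf),
                         ("size_vcf_gz", size_vcf_gz), ("size_f_vcf", size_f_vcf),
                         ("size_f_vcf_gz", size_f_vcf_gz)):
        if value < 0:
            raise ValueError(f"{label} must be non-negative, got {value}")
    report = ThroughputReport(
        size_fastq, size_vcf, size_vcf_gz, size_f_vcf, size_f_vcf_gz,
        t_a, t_b1, t_b2, t_b3, t_total,
    )
    for name, value in report.recompute().items():
        setattr(report, name, value)
    return report


# ---------------------------------------------------------------------------
# Protected area
# ---------------------------------------------------------------------------


class ProtectedArea:
    """Bounded transient plaintext store with a time-to-live.

    Models the trusted server's protected memory: plaintext may exist here
    only during analysis, within a capacity bound (default 1 GiB) and never
    longer than the TTL (default 24 h of simulated time).  The clock is
    injectable so TTL discipline is testable without waiting.
    """

    def __init__(
        self,
        capacity: int = 1 << 30,
        ttl_seconds: float = 24 * 3600,
        clock: Callable[[], float] | None = None,
    ):
        self.capacity = capacity
        self.ttl = ttl_seconds
        self._clock = clock or time.monotonic
        self._objects: Dict[str, Tuple[bytes, float]] = {}

    def resident_bytes(self) -> int:
        return sum(len(v) for v, _ in self._objects.values())

    def __len__(self) -> int:
        return len(self._objects)

    def put(self, name: str, data: bytes) -> None:
        self.sweep()
        projected = self.resident_bytes() - len(self._objects.get(name, (b"",))[0]) + len(data)
        if projected > self.capacity:
            raise ProtectedAreaError(
                f"protected area capacity exceeded: {projected} > {self.capacity}"
            )
        self._objects[name] = (data, self._clock())

    def get(self, name: str) -> bytes:
        self.sweep()
        if name not in self._objects:
            raise KeyError(name)
        return self._objects[name][0]

    def sweep(self) -> None:
        """Drop every object older than the TTL."""
        now = self._clock()
        expired = [k for k, (_, t) in self._objects.items() if now - t > self.ttl]
        for k in expired:
            del self._objects[k]
        if expired:
            raise ProtectedAreaError(
                f"plaintext outlived the TTL and was purged: {expired}"
            )

    def purge(self) -> None:
        self._objects.clear()


# ---------------------------------------------------------------------------
# Transport and sessions
# ---------------------------------------------------------------------------


@dataclass
class Message:
    src: str
    dst: str
    kind: str
    payload: bytes


class InMemoryTransport:
    """All nodes in one process; every transfer is recorded for inspection.

    ``tamper`` lets tests corrupt a message in flight to exercise the
    authentication path.
    """

    def __init__(self):
        self.messages: List[Message] = []
        self.tamper: Callable[[Message], Message] | None = None

    def send(self, src: str, dst: str, kind: str, payload: bytes) -> Message:
        msg = Message(src, dst, kind, payload)
        if self.tamper is not None:
            msg = self.tamper(msg)
        self.messages.append(msg)
        return msg


@dataclass
class Session:
    """One user request: who asks, which nodes serve, what was authorised."""

    user_id: str
    user_node: str
    owner_node: str
    holder_node: str | None = None
    policy: AccessPolicy | None = None
    authenticated: bool = False
    audit: List[str] = field(default_factory=list)
    seen_nonces: set = field(default_factory=set)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def default_caller(reference) -> Callable[[bytes, object], bytes]:
    """The toy caller as a plugin: FASTQ.gz bytes -> VCF.gz bytes."""

    def call(fastq_gz: bytes, _reference=None) -> bytes:
        import tempfile, os

        with tempfile.NamedTemporaryFile(suffix=".fastq.gz", delete=False) as fh:
            fh.write(fastq_gz)
            path = fh.name
        try:
            vcf_text = toy_call_variants(path, reference)
        finally:
            os.unlink(path)
        return gzip_bytes(vcf_text.encode("ascii"))

    return call


def replay_caller(vcf_gz: bytes) -> Callable[[bytes, object], bytes]:
    """A caller plugin that replays a fixed VCF.gz, standing in for an
    external calling engine whose output is already known."""

    def call(_fastq_gz: bytes, _reference=None) -> bytes:
        return vcf_gz

    return call


class TrustedPipeline:
    """Deposit shares, serve authenticated filtered-VCF requests."""

    def __init__(
        self,
        network: KeyNetwork | None = None,
        secure: bool = True,
        transport: InMemoryTransport | None = None,
        protected_area: ProtectedArea | None = None,
        chunk_size: int = sharing.DEFAULT_CHUNK_SIZE,
    ):
        self.network = network or default_topology()
        self.secure = secure
        self.transport = transport or InMemoryTransport()
        self.protected = protected_area or ProtectedArea()
        self.chunk_size = chunk_size
        self.stores: Dict[str, Dict[str, bytes]] = defaultdict(dict)
        self.audit: List[dict] = []

    # -- helpers ------------------------------------------------------------

    def _otp_transfer(self, src: str, dst: str, kind: str, payload: bytes) -> bytes:
        """Move bytes between nodes; OTP-encrypted and tagged in secure mode.

        Returns the payload as decrypted (and verified) at the destination.
        """
        if not self.secure:
            self.transport.send(src, dst, kind, payload)
            return payload
        key = supply_key(self.network, src, f"{kind}:{src}->{dst}", len(payload))
        sender_ks = OtpKeystream(key)
        receiver_ks = sender_ks.clone()  # the peer's identical QKD-supplied copy
        auth = supply_key(self.network, src, f"{kind}:auth", 2 * _WC_BYTES)
        hash_key = int.from_bytes(auth[:_WC_BYTES], "big")
        mask = auth[_WC_BYTES:]
        ciphertext = otp_encrypt(payload, sender_ks)
        tag = wc_tag(ciphertext, hash_key, mask, width=_WC_WIDTH)
        msg = self.transport.send(src, dst, kind, ciphertext)
        if not wc_verify(msg.payload, tag, hash_key, mask, width=_WC_WIDTH):
            raise IntegrityError(f"{kind}: authentication tag mismatch in transit")
        return otp_decrypt(msg.payload, receiver_ks)

    # -- protocol -----------------------------------------------------------

    def deposit(
        self,
        data: bytes,
        name: str,
        owner: str = "owner",
        holders: Tuple[str, str] = ("holder-b", "holder-c"),
    ) -> dict:
        """Split ``data`` and distribute: A stays at the owner, B and C go to
        the holders over OTP.  Returns a receipt with container checksums."""
        if len(set((owner,) + tuple(holders))) != 3:
            raise ValueError("deposit needs three distinct storage nodes")
        rng = (
            self.network.rng_for_node(owner, f"deposit:{name}")
            if self.secure
            else None
        )
        self.protected.put(f"deposit:{name}", data)
        try:
            containers = sharing.split_bytes(data, chunk_size=self.chunk_size, rng=rng)
            stored = {}
            self.stores[owner][f"{name}.share-A"] = containers[0]
            stored["A"] = owner
            for share_id, holder, container in zip(
                "BC", holders, containers[1:]
            ):
                received = self._otp_transfer(
                    owner, holder, f"deposit-share-{share_id}", container
                )
                self.stores[holder][f"{name}.share-{share_id}"] = received
                stored[share_id] = holder
            receipt = {
                "name": name,
                "owner": owner,
                "holders": stored,
                "chunk_size": self.chunk_size,
                "size": len(data),
                "checksums": {
                    sid: hashlib.sha256(c).hexdigest()
                    for sid, c in zip("ABC", containers)
                },
            }
            self.audit.append({"op": "deposit", "name": name, "size": len(data)})
            return receipt
        finally:
            self.protected.purge()

    def authenticate_peer(self, session: Session, corrupt_key: bool = False) -> bool:
        """Wegman-Carter challenge-response over a fresh nonce.

        Both parties hold the matching one-time (hash key, mask) pair from
        the key supply; a replayed nonce or a key mismatch fails closed.
        """
        try:
            material = supply_key(
                self.network, session.owner_node, f"auth:{session.user_id}", 2 * _WC_BYTES + 16
            )
        except KeyExhaustionError:
            raise AuthenticationError("authentication unavailable: key supply exhausted")
        hash_key = int.from_bytes(material[:_WC_BYTES], "big") or 1
        mask = material[_WC_BYTES : 2 * _WC_BYTES]
        nonce = material[2 * _WC_BYTES :]
        if nonce in session.seen_nonces:
            session.audit.append("auth:replayed-nonce")
            return False
        session.seen_nonces.add(nonce)
        prover_key = (hash_key ^ 1) if corrupt_key else hash_key
        tag = wc_tag(nonce, prover_key, mask, width=_WC_WIDTH)
        ok = wc_verify(nonce, tag, hash_key, mask, width=_WC_WIDTH)
        session.authenticated = bool(ok)
        session.audit.append(f"auth:{'ok' if ok else 'failed'}")
        return session.authenticated

    def serve_request(
        self,
        user_id: str,
        receipt: dict,
        policy: AccessPolicy | dict,
        caller: Callable[[bytes, object], bytes],
        reference=None,
        user_node: str = "user-1",
    ) -> Tuple[bytes, ThroughputReport, DisclosureResult, Session]:
        """Serve one authenticated request end to end.

        Returns the delivered F_VCF.gz bytes (as decrypted at the user),
        the throughput report, the disclosure stats and the session record.
        """
        policy = normalize_policy(policy)
        owner = receipt["owner"]
        session = Session(user_id=user_id, user_node=user_node, owner_node=owner,
                          policy=policy)
        if not self.authenticate_peer(session):
            raise AuthenticationError(f"user {user_id} failed authentication")
        try:
            # fetch one holder share (lowest node id holding B or C)
            holder_shares = sorted(
                (node, sid)
                for sid, node in receipt["holders"].items()
                if sid != "A"
            )
            holder, share_id = holder_shares[0]
            session.holder_node = holder
            container = self._otp_transfer(
                holder, owner, f"fetch-share-{share_id}",
                self.stores[holder][f"{receipt['name']}.share-{share_id}"],
            )
            share_a = self.stores[owner][f"{receipt['name']}.share-A"]
            for sid, blob in (("A", share_a), (share_id, container)):
                digest = hashlib.sha256(blob).hexdigest()
                if digest != receipt["checksums"][sid]:
                    raise IntegrityError(f"share {sid} checksum mismatch")
            fastq_gz = sharing.reconstruct_bytes(share_a, container)
            self.protected.put("fastq", fastq_gz)

            t0 = time.perf_counter()
            vcf_gz = caller(fastq_gz, reference)
            t_a = max(time.perf_counter() - t0, 1e-6)
            self.protected.put("vcf_gz", vcf_gz)

            t0 = time.perf_counter()
            vcf_text = gunzip_bytes(vcf_gz).decode("utf-8")
            t_b1 = max(time.perf_counter() - t0, 1e-6)
            self.protected.put("vcf", vcf_text.encode("utf-8"))

            t0 = time.perf_counter()
            out = io.StringIO()
            disclosure = filter_vcf(io.StringIO(vcf_text), policy, out)
            f_vcf = out.getvalue()
            t_b2 = max(time.perf_counter() - t0, 1e-6)

            t0 = time.perf_counter()
            f_vcf_gz = gzip_bytes(f_vcf.encode("utf-8"))
            t_b3 = max(time.perf_counter() - t0, 1e-6)

            t0 = time.perf_counter()
            delivered = self._deliver(owner, user_node, f_vcf_gz)
            t_c = max(time.perf_counter() - t0, 1e-6)

            report = compute_throughputs(
                size_fastq=len(fastq_gz),
                size_vcf=len(vcf_text.encode("utf-8")),
                size_vcf_gz=len(vcf_gz),
                size_f_vcf=len(f_vcf.encode("utf-8")),
                size_f_vcf_gz=len(f_vcf_gz),
                t_a=t_a, t_b1=t_b1, t_b2=t_b2, t_b3=t_b3,
                t_total=t_a + t_b1 + t_b2 + t_b3 + t_c,
            )
            session.audit.append(
                f"served:{disclosure.records_out}/{disclosure.records_in} records"
            )
            stages = [
                StageTiming("call (A)", len(fastq_gz), len(vcf_gz), t_a),
                StageTiming("decompress (B-1)", len(vcf_gz), report.size_vcf, t_b1),
                StageTiming("filter (B-2)", report.size_vcf, report.size_f_vcf, t_b2),
                StageTiming("compress (B-3)", report.size_f_vcf, len(f_vcf_gz), t_b3),
                StageTiming("deliver (C)", len(f_vcf_gz), len(delivered), t_c),
            ]
            self.audit.append({
                "op": "serve", "user": user_id,
                "records_out": disclosure.records_out,
                "stages": stages,
            })
            return delivered, report, disclosure, session
        finally:
            self.protected.purge()

    def _deliver(self, owner: str, user_node: str, f_vcf_gz: bytes) -> bytes:
        """OTP delivery under a derive-then-erase key lifecycle.

        The transmission key K4 = K1 xor K3 is derived from supplied key
        material; after use the short-term components are erased first,
        then the long-term part, so no stored medium retains K4.
        """
        if not self.secure:
            self.transport.send(owner, user_node, "deliver-f-vcf", f_vcf_gz)
            return f_vcf_gz
        k0 = supply_key(
            self.network, owner, f"deliver:{user_node}", len(f_vcf_gz) + 16
        )
        lc = lifecycle_derive(k0)
        sender_ks = OtpKeystream(lc.k4)
        receiver_ks = sender_ks.clone()
        auth = supply_key(self.network, owner, "deliver:auth", 2 * _WC_BYTES)
        hash_key = int.from_bytes(auth[:_WC_BYTES], "big")
        mask = auth[_WC_BYTES:]
        ciphertext = otp_encrypt(f_vcf_gz, sender_ks)
        tag = wc_tag(ciphertext, hash_key, mask, width=_WC_WIDTH)
        msg = self.transport.send(owner, user_node, "deliver-f-vcf", ciphertext)
        lifecycle_erase(lc, "short_term")
        lifecycle_erase(lc, "long_term")
        if not wc_verify(msg.payload, tag, hash_key, mask, width=_WC_WIDTH):
            raise IntegrityError("delivery authentication tag mismatch")
        return otp_decrypt(msg.payload, receiver_ks)


# ---------------------------------------------------------------------------
# One-command demo
# ---------------------------------------------------------------------------


def run_demo(
    seed: int = 0,
    scale: str = "tiny",
    secure: bool = True,
    n_vcf_records: int = 3000,
) -> dict:
    """Reproduce the deposit-and-serve scenario at desk scale.

    Builds a synthetic reference, 10,000 planted-variant reads (tiny scale)
    and a standalone VCF of ``n_vcf_records`` records; deposits the FASTQ.gz
    as three shares; then serves four requests whose count policies release
    0 / 1% / 50% / 100% of the records — the published disclosure scenarios
    scaled 1:1000.  The variant-calling stage for the scenario requests is a
    replay plugin carrying the pregenerated VCF (the calling engine is a
    black box to the protocol); a fifth request runs the toy caller for
    truth-set recovery.  Returns artifacts, reports and the audit bundle.
    """
    import tempfile, os

    from .otp import reset_wc_usage

    # a fresh demo models a fresh deployment with its own one-time keys
    reset_wc_usage()

    sizes = {"tiny": (50_000, 20.0), "small": (200_000, 30.0)}
    if scale not in sizes:
        raise ValueError(f"scale must be one of {sorted(sizes)}")
    length, coverage = sizes[scale]

    link_budget = 64 * 1024 * 1024 if scale == "small" else 16 * 1024 * 1024
    network = default_topology(seed=seed, link_budget=link_budget)
    pipeline = TrustedPipeline(network=network, secure=secure)

    ref = gen_reference(1, length, seed=seed)
    profile = ReadSimProfile(read_length=100, coverage=coverage, seed=seed)
    with tempfile.TemporaryDirectory() as tmp:
        fastq_path = os.path.join(tmp, "reads.fastq.gz")
        truth, _ = gen_truth_and_reads(ref, 50, profile, fastq_path)
        fastq_bytes = open(fastq_path, "rb").read()

    vcf_gz = gzip_bytes(gen_vcf(n_vcf_records, seed=seed).encode("ascii"))
    receipt = pipeline.deposit(fastq_bytes, "patient-1")

    scenarios = [0, n_vcf_records // 100, n_vcf_records // 2, n_vcf_records]
    deliveries = []
    for n in scenarios:
        policy = {"user_id": f"user-{n}", "mode": "count" if n else "none",
                  "max_records": n}
        delivered, report, disclosure, session = pipeline.serve_request(
            f"user-{n}", receipt, policy, caller=replay_caller(vcf_gz)
        )
        deliveries.append({
            "requested": n,
            "records_out": disclosure.records_out,
            "delivered_sha256": hashlib.sha256(delivered).hexdigest(),
            "delivered_bytes": delivered,
            "report": report,
        })

    delivered, report, disclosure, _ = pipeline.serve_request(
        "clinician", receipt, {"user_id": "clinician", "mode": "all"},
        caller=default_caller(ref),
    )
    from .fixtures import evaluate_calls

    called_text = gunzip_bytes(delivered).decode("utf-8")
    recovery = evaluate_calls(truth, called_text)

    return {
        "seed": seed,
        "secure": secure,
        "receipt": receipt,
        "scenarios": deliveries,
        "caller_delivery_sha256": hashlib.sha256(delivered).hexdigest(),
        "truth_recovery": recovery,
        "caller_report": report,
        "audit": pipeline.audit,
        "network_audit": keynet_audit(network),
    }
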