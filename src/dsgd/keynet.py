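"""Simulated QKD key-supply network with trusted-node key relay.

The quantum layer is modelled as seedable random-byte generation delivered
identically to both endpoints of each link — no photonic detail.  On top of
that sit the management roles of a metropolitan QKD network: each trusted
node holds its link keys (the key-management-agent role), a network-wide
view routes hop-by-hop key relays (the key-management-server role), and
:func:`supply_key` hands key material to service-layer consumers (the
key-supply-agent role), after which the network erases its copy and
responsibility moves to the consumer.

Accounting is byte-exact and auditable.  Per link,

    generated = available + reserved + consumed + erased

holds at all times; every operation either completes fully or leaves all
counters unchanged.  No key byte is ever handed out twice.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Sequence, Tuple

import networkx as nx

from .errors import (
    ErasedKeyError,
    KeyExhaustionError,
    TopologyError,
    RoutingError,
)
from .random_sources import PoolRng, RngLike, SeededRng, system_rng

__all__ = [
    "KeyBlock",
    "QkdLink",
    "TrustedNode",
    "KeyNetwork",
    "generate_link_keys",
    "relay_key",
    "supply_key",
    "erase_key",
    "audit",
    "default_topology",
]

_STATES = ("available", "reserved", "consumed", "erased")


@dataclass(eq=False)
class KeyBlock:
    """Accountable key material with a forward-only lifecycle.

    ``payload`` holds the unconsumed bytes.  Once ``state`` is ``erased`` the
    payload is gone and any read raises :class:`ErasedKeyError`.

    Link and relay keys exist as bitwise-identical copies at the two
    endpoints; ``peer`` ties the copies together so that consuming or
    erasing bytes on one side mirrors to the other — the pair is one logical
    key and is accounted (and single-use-guarded) exactly once.
    """

    block_id: str
    payload: bytearray | None
    origin: str
    owner_node: str
    state: str = "available"
    peer: "KeyBlock | None" = field(default=None, repr=False)

    def remaining(self) -> int:
        return 0 if self.payload is None else len(self.payload)

    def read(self) -> bytes:
        if self.state == "erased" or self.payload is None:
            raise ErasedKeyError(f"key block {self.block_id} has been erased")
        return bytes(self.payload)

    def _advance(self, new_state: str) -> None:
        if _STATES.index(new_state) < _STATES.index(self.state):
            raise ValueError(
                f"key block state may only move forward ({self.state} -> {new_state})"
            )
        self.state = new_state


@dataclass
class QkdLink:
    """A point-to-point QKD link with byte counters by lifecycle state."""

    endpoints: FrozenSet[str]
    generated: int = 0
    available: int = 0
    reserved: int = 0
    consumed: int = 0
    erased: int = 0

    def conserved(self) -> bool:
        return self.generated == self.available + self.reserved + self.consumed + self.erased


@dataclass
class TrustedNode:
    node_id: str
    roles: frozenset = frozenset()
    key_store: Dict[str, KeyBlock] = field(default_factory=dict)

    def available_bytes(self) -> int:
        return sum(
            b.remaining() for b in self.key_store.values() if b.state == "available"
        )


class KeyNetwork:
    """Nodes, links, routing and the audit log of a simulated key network."""

    def __init__(self, rng: RngLike | None = None):
        self.nodes: Dict[str, TrustedNode] = {}
        self.links: Dict[FrozenSet[str], QkdLink] = {}
        self.graph = nx.Graph()
        self.audit_log: List[dict] = []
        self._rng = rng or system_rng
        self._block_counter = itertools.count()

    # -- construction -------------------------------------------------------

    def add_node(self, node_id: str, roles: Iterable[str] = ()) -> TrustedNode:
        if node_id in self.nodes:
            raise TopologyError(f"duplicate node id {node_id!r}")
        node = TrustedNode(node_id=node_id, roles=frozenset(roles))
        self.nodes[node_id] = node
        self.graph.add_node(node_id)
        return node

    def add_link(self, a: str, b: str) -> QkdLink:
        for n in (a, b):
            if n not in self.nodes:
                raise TopologyError(f"unknown node {n!r}")
        key = frozenset((a, b))
        if a == b or key in self.links:
            raise TopologyError(f"invalid or duplicate link ({a}, {b})")
        link = QkdLink(endpoints=key)
        self.links[key] = link
        self.graph.add_edge(a, b)
        return link

    @classmethod
    def from_config(cls, config: dict, rng: RngLike | None = None) -> "KeyNetwork":
        """Build from a topology mapping: ``{"nodes": [...], "links": [...]}``.

        Node entries are ``{"id": ..., "roles": [...]}``; link entries
        ``{"a": ..., "b": ..., "initial_key_bytes": N}`` (budget optional).
        """
        net = cls(rng=rng)
        for n in config.get("nodes", []):
            net.add_node(n["id"], n.get("roles", ()))
        for l in config.get("links", []):
            net.add_link(l["a"], l["b"])
            budget = int(l.get("initial_key_bytes", 0))
            if budget > 0:
                generate_link_keys(net, (l["a"], l["b"]), budget)
        return net

    # -- internals ----------------------------------------------------------

    def _new_block_id(self) -> str:
        return f"kb{next(self._block_counter):06d}"

    def _link(self, endpoints: Tuple[str, str] | FrozenSet[str]) -> QkdLink:
        key = frozenset(endpoints)
        if key not in self.links:
            raise TopologyError(f"no link between {sorted(key)}")
        return self.links[key]

    def _link_blocks(self, node_id: str, link: QkdLink) -> List[KeyBlock]:
        """Available link-origin blocks at a node, oldest first."""
        origin = _link_origin(link)
        return [
            b
            for b in self.nodes[node_id].key_store.values()
            if b.origin == origin and b.state == "available" and b.remaining() > 0
        ]

    def _log(self, **entry) -> None:
        self.audit_log.append(entry)

    def rng_for_node(self, node_id: str, consumer_id: str) -> PoolRng:
        """An ``rng(n) -> bytes`` that draws through :func:`supply_key`."""
        return PoolRng(lambda n: supply_key(self, node_id, consumer_id, n))


def _link_origin(link: QkdLink) -> str:
    return "link:" + "|".join(sorted(link.endpoints))


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def generate_link_keys(
    network: KeyNetwork,
    link_endpoints: Tuple[str, str],
    n_bytes: int,
    rng: RngLike | None = None,
) -> Tuple[KeyBlock, KeyBlock]:
    """Generate ``n_bytes`` of link key, delivered identically to both ends."""
    link = network._link(link_endpoints)
    if n_bytes <= 0:
        raise ValueError("n_bytes must be positive")
    payload = (rng or network._rng)(n_bytes)
    blocks = []
    for node_id in sorted(link.endpoints):
        block = KeyBlock(
            block_id=network._new_block_id(),
            payload=bytearray(payload),
            origin=_link_origin(link),
            owner_node=node_id,
        )
        network.nodes[node_id].key_store[block.block_id] = block
        blocks.append(block)
    blocks[0].peer = blocks[1]
    blocks[1].peer = blocks[0]
    link.generated += n_bytes
    link.available += n_bytes
    network._log(op="generate", link=sorted(link.endpoints), n_bytes=n_bytes,
                 blocks=[b.block_id for b in blocks])
    return tuple(blocks)


def _route(network: KeyNetwork, src: str, dst: str) -> List[str]:
    """Shortest path by hop count; lexicographically smallest among ties."""
    for n in (src, dst):
        if n not in network.nodes:
            raise TopologyError(f"unknown node {n!r}")
    if src == dst:
        raise RoutingError("source and destination coincide")
    try:
        paths = list(nx.all_shortest_paths(network.graph, src, dst))
    except nx.NetworkXNoPath:
        raise RoutingError(f"no relay path from {src} to {dst}")
    return min(paths)


def _take_prefix(block: KeyBlock, step: int, final_state: str) -> bytes:
    """Consume a prefix of a block, mirroring to its peer copy."""
    data = bytes(block.payload[:step])
    targets = (block, block.peer) if block.peer is not None else (block,)
    for blk in targets:
        if blk.payload is not None:
            del blk.payload[:step]
            if blk.remaining() == 0:
                blk.payload = None
                blk._advance(final_state)
    return data


def _consume_link_bytes(network: KeyNetwork, u: str, v: str, n_bytes: int) -> bytes:
    """Consume (and erase network-side) n link-key bytes on one hop.

    Walks the oldest available blocks at ``u``; the peer mirror keeps the
    ``v``-side copies in lockstep.
    """
    link = network._link((u, v))
    taken = bytearray()
    need = n_bytes
    for block in network._link_blocks(u, link):
        if need == 0:
            break
        step = min(need, block.remaining())
        taken += _take_prefix(block, step, "consumed")
        need -= step
    if need:
        raise KeyExhaustionError("internal: hop consumed less than pre-checked")
    link.available -= n_bytes
    link.consumed += n_bytes
    return bytes(taken)


def relay_key(
    network: KeyNetwork,
    src_node: str,
    dst_node: str,
    n_bytes: int,
    rng: RngLike | None = None,
) -> Tuple[KeyBlock, KeyBlock]:
    """Relay a fresh key hop-by-hop from ``src_node`` to ``dst_node``.

    A fresh key K is generated at the source; on each hop it travels
    OTP-encrypted under that hop's link key, which is consumed and erased
    (n_bytes per hop).  Intermediate trusted nodes transiently see K — the
    trusted-node model.  On any failure nothing is consumed.
    """
    if n_bytes <= 0:
        raise ValueError("n_bytes must be positive")
    path = _route(network, src_node, dst_node)
    hops = list(zip(path, path[1:]))
    # atomicity: verify every hop before consuming anything
    for u, v in hops:
        link = network._link((u, v))
        if link.available < n_bytes:
            raise KeyExhaustionError(
                f"hop {u}-{v} has {link.available} key bytes, needs {n_bytes}"
            )
    key = (rng or network._rng)(n_bytes)
    for u, v in hops:
        pad = _consume_link_bytes(network, u, v, n_bytes)
        ciphertext = bytes(a ^ b for a, b in zip(key, pad))
        _ = bytes(a ^ b for a, b in zip(ciphertext, pad))  # decrypt at v
    blocks = []
    origin = "relay:" + "-".join(path)
    for node_id in (src_node, dst_node):
        block = KeyBlock(
            block_id=network._new_block_id(),
            payload=bytearray(key),
            origin=origin,
            owner_node=node_id,
        )
        network.nodes[node_id].key_store[block.block_id] = block
        blocks.append(block)
    blocks[0].peer = blocks[1]
    blocks[1].peer = blocks[0]
    network._log(op="relay", path=path, n_bytes=n_bytes,
                 consumed_per_hop=n_bytes, blocks=[b.block_id for b in blocks])
    return tuple(blocks)


def supply_key(
    network: KeyNetwork, node_id: str, consumer_id: str, n_bytes: int
) -> bytes:
    """Hand ``n_bytes`` of key material to a service-layer consumer.

    The returned bytes are marked consumed and erased from network-side
    storage; they can never be supplied again.  Fails atomically when the
    node holds less than requested.
    """
    if node_id not in network.nodes:
        raise TopologyError(f"unknown node {node_id!r}")
    node = network.nodes[node_id]
    if n_bytes < 0:
        raise ValueError("n_bytes must be non-negative")
    if node.available_bytes() < n_bytes:
        raise KeyExhaustionError(
            f"node {node_id} holds {node.available_bytes()} key bytes, "
            f"consumer {consumer_id} asked for {n_bytes}"
        )
    out = bytearray()
    need = n_bytes
    for block in list(node.key_store.values()):
        if need == 0:
            break
        if block.state != "available" or block.remaining() == 0:
            continue
        step = min(need, block.remaining())
        if block.origin.startswith("link:"):
            link = network._link(tuple(block.origin[5:].split("|")))
            link.available -= step
            link.consumed += step
        out += _take_prefix(block, step, "consumed")
        need -= step
    network._log(op="supply", node=node_id, consumer=consumer_id, n_bytes=n_bytes)
    return bytes(out)


def erase_key(network: KeyNetwork, block: KeyBlock) -> KeyBlock:
    """Erase a key block (and its peer copy): zeroize, mark erased, log."""
    if block.state == "erased":
        raise ErasedKeyError(f"key block {block.block_id} already erased")
    n = block.remaining()
    if block.state in ("available", "reserved") and block.origin.startswith("link:"):
        link = network._link(tuple(block.origin[5:].split("|")))
        if block.state == "available":
            link.available -= n
        else:
            link.reserved -= n
        link.erased += n
    targets = (block, block.peer) if block.peer is not None else (block,)
    for blk in targets:
        if blk.payload is not None:
            for i in range(len(blk.payload)):
                blk.payload[i] = 0
            blk.payload = None
        blk.state = "erased"
    network._log(op="erase", block=block.block_id, n_bytes=n)
    return block


def audit(network: KeyNetwork) -> dict:
    """Byte accounting per link and per node, with conservation checks."""
    links = {}
    all_conserved = True
    for key, link in network.links.items():
        ok = link.conserved()
        all_conserved &= ok
        links["-".join(sorted(key))] = {
            "generated": link.generated,
            "available": link.available,
            "reserved": link.reserved,
            "consumed": link.consumed,
            "erased": link.erased,
            "conserved": ok,
        }
    nodes = {}
    for node_id, node in network.nodes.items():
        by_state = {s: 0 for s in _STATES}
        for block in node.key_store.values():
            by_state[block.state] += block.remaining()
        nodes[node_id] = by_state
    return {
        "links": links,
        "nodes": nodes,
        "conserved": all_conserved,
        "log_entries": len(network.audit_log),
    }


def default_topology(seed: int | None = None, link_budget: int = 0) -> KeyNetwork:
    """The deployment of the reference experiment at desk scale.

    A data owner co-located with the trusted server (and holding share A),
    two share-holder nodes, and one user endpoint; every pair reachable in
    at most two hops.
    """
    rng = SeededRng(seed) if seed is not None else None
    config = {
        "nodes": [
            {"id": "owner", "roles": ["data_owner", "share_holder", "trusted_server"]},
            {"id": "holder-b", "roles": ["share_holder"]},
            {"id": "holder-c", "roles": ["share_holder"]},
            {"id": "user-1", "roles": ["user_endpoint"]},
        ],
        "links": [
            {"a": "owner", "b": "holder-b", "initial_key_bytes": link_budget},
            {"a": "owner", "b": "holder-c", "initial_key_bytes": link_budget},
            {"a": "holder-b", "b": "holder-c", "initial_key_bytes": link_budget},
            {"a": "owner", "b": "user-1", "initial_key_bytes": link_budget},
        ],
    }
    return KeyNetwork.from_config(config, rng=rng)
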