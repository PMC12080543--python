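"""Signed directed networks: data model, edge-list I/O, and synthetic generators.

A signed directed network has a fixed edge structure in which every directed
link ``u -> v`` carries a sign in ``{-1, +1}`` (like/respect vs.
dislike/disrespect).  The edge structure never changes during dynamics; only
the signs do.  Files follow the SNAP ``soc-sign`` dialect: whitespace- or
tab-separated ``source target sign`` records with optional ``#`` comment
lines.
"""

from __future__ import annotations

import dataclasses
import io
import os
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SignedDigraph",
    "GeneratorSpec",
    "read_signed_edgelist",
    "write_signed_edgelist",
    "generate",
]

_SIGN_TOKENS = {"1": 1, "+1": 1, "+": 1, "-1": -1, "-": -1}


class EdgeListParseError(ValueError):
    """Raised when a signed edge-list file cannot be parsed."""


class SignedDigraph:
    """A directed graph with ±1 signs on its edges.

    Nodes are the contiguous integers ``0..n-1``.  At most one edge exists
    per ordered pair and self-loops are forbidden.  ``labels`` optionally
    retains the original node identifiers of a parsed file (internal id
    ``i`` corresponds to ``labels[i]``).
    """

    __slots__ = ("n", "src", "dst", "sign", "labels", "_index")

    def __init__(
        self,
        n: int,
        src: Sequence[int],
        dst: Sequence[int],
        sign: Sequence[int],
        labels: Sequence[str] | None = None,
    ):
        self.n = int(n)
        self.src = np.asarray(src, dtype=np.int64)
        self.dst = np.asarray(dst, dtype=np.int64)
        self.sign = np.asarray(sign, dtype=np.int8)
        if not (len(self.src) == len(self.dst) == len(self.sign)):
            raise ValueError("src, dst and sign must have equal length")
        if len(self.src) and (self.src.min() < 0 or self.dst.min() < 0):
            raise ValueError("negative node id")
        if len(self.src) and max(self.src.max(), self.dst.max()) >= self.n:
            raise ValueError("node id out of range")
        if np.any(self.src == self.dst):
            raise ValueError("self-loops are not allowed")
        bad = np.setdiff1d(np.unique(self.sign), [-1, 1])
        if bad.size:
            raise ValueError(f"signs must be -1 or +1, got {bad.tolist()}")
        self.labels = list(labels) if labels is not None else None
        self._index: dict[tuple[int, int], int] | None = None

    # -- basic queries ---------------------------------------------------

    @property
    def num_nodes(self) -> int:
        return self.n

    @property
    def num_edges(self) -> int:
        return len(self.src)

    def edge_index(self) -> dict[tuple[int, int], int]:
        """Mapping ``(u, v) -> position`` into the edge arrays (built lazily)."""
        if self._index is None:
            idx = {}
            for k, (u, v) in enumerate(zip(self.src.tolist(), self.dst.tolist())):
                if (u, v) in idx:
                    raise ValueError(f"duplicate edge ({u}, {v})")
                idx[(u, v)] = k
            self._index = idx
        return self._index

    def has_edge(self, u: int, v: int) -> bool:
        return (u, v) in self.edge_index()

    def sign_of(self, u: int, v: int) -> int:
        return int(self.sign[self.edge_index()[(u, v)]])

    def set_sign(self, u: int, v: int, value: int) -> None:
        if value not in (-1, 1):
            raise ValueError("sign must be -1 or +1")
        self.sign[self.edge_index()[(u, v)]] = value

    def rho(self) -> float:
        """Density of positive links, ``#positive / #edges``."""
        if self.num_edges == 0:
            raise ValueError("rho undefined for an edgeless graph")
        return float(np.count_nonzero(self.sign == 1)) / self.num_edges

    def copy(self) -> "SignedDigraph":
        return SignedDigraph(self.n, self.src.copy(), self.dst.copy(),
                             self.sign.copy(), self.labels)

    def edges(self) -> Iterable[tuple[int, int, int]]:
        yield from zip(self.src.tolist(), self.dst.tolist(), self.sign.tolist())

    def out_neighbors(self, u: int) -> list[int]:
        return self.dst[self.src == u].tolist()

    def sign_matrix(self) -> np.ndarray:
        """Dense ``n x n`` int8 matrix: ±1 where an edge exists, 0 elsewhere.

        Intended for small/complete graphs; large sparse graphs should go
        through the sparse census path instead.
        """
        mat = np.zeros((self.n, self.n), dtype=np.int8)
        mat[self.src, self.dst] = self.sign
        return mat

    def __eq__(self, other) -> bool:
        if not isinstance(other, SignedDigraph):
            return NotImplemented
        return self.n == other.n and dict(
            ((u, v), s) for u, v, s in self.edges()
        ) == dict(((u, v), s) for u, v, s in other.edges())

    def __repr__(self) -> str:
        return (f"SignedDigraph(n={self.n}, edges={self.num_edges}, "
                f"rho={self.rho():.3f})" if self.num_edges else
                f"SignedDigraph(n={self.n}, edges=0)")


@dataclasses.dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of a synthetic signed-network generator.

    topology
        ``complete`` — all ``N(N-1)`` directed links; ``random_directed`` —
        each ordered pair present independently with probability
        ``edge_prob``; ``triangle_rich`` — a clustered Watts–Strogatz
        skeleton with per-pair reciprocation, emulating the sparse but
        highly clustered structure of empirical social networks.
    rho0
        Initial density of positive links; every sign is an independent
        Bernoulli(rho0) draw (+1 with probability rho0).
    """

    topology: str = "complete"
    n: int = 100
    rho0: float = 0.5
    seed: int | None = None
    edge_prob: float = 0.1
    skeleton_k: int = 6
    rewire_p: float = 0.1
    p_reciprocal: float = 0.5

    def __post_init__(self):
        if self.topology not in ("complete", "random_directed", "triangle_rich"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if not 0.0 <= self.rho0 <= 1.0:
            raise ValueError("rho0 must be in [0, 1]")
        if self.n < 3:
            raise ValueError("need at least 3 nodes to form a triad")


def read_signed_edgelist(path, duplicates: str = "error") -> SignedDigraph:
    """Read a SNAP-style signed edge list.

    Parameters
    ----------
    path
        File path or open text handle.  Lines starting with ``#`` are
        comments; data lines have at least three whitespace-separated
        fields ``source target sign`` with sign in {1, +1, -1, +, -}.
    duplicates
        Policy for repeated ordered pairs: ``"error"`` (default — repeated
        reports are time-stamped multi-votes the model does not represent)
        or ``"last"`` (last record wins).

    Node identifiers may be arbitrary strings; they are remapped to
    contiguous 0-based ids in order of first appearance, with the original
    labels retained in ``SignedDigraph.labels``.
    """
    if duplicates not in ("error", "last"):
        raise ValueError("duplicates policy must be 'error' or 'last'")
    close = False
    if isinstance(path, (str, os.PathLike)):
        fh = open(path, "r", encoding="utf-8")
        close = True
    else:
        fh = path
    try:
        ids: dict[str, int] = {}
        order: dict[tuple[int, int], int] = {}
        signs: dict[tuple[int, int], int] = {}
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise EdgeListParseError(
                    f"line {lineno}: expected at least 3 fields, got {len(fields)}")
            su, sv, st = fields[0], fields[1], fields[2]
            if st == "0":
                raise EdgeListParseError(
                    f"line {lineno}: sign 0 is not admitted; links carry only ±1")
            if st not in _SIGN_TOKENS:
                raise EdgeListParseError(
                    f"line {lineno}: unrecognised sign token {st!r}")
            u = ids.setdefault(su, len(ids))
            v = ids.setdefault(sv, len(ids))
            if u == v:
                raise EdgeListParseError(f"line {lineno}: self-loop on node {su!r}")
            key = (u, v)
            if key in signs and duplicates == "error":
                raise EdgeListParseError(
                    f"line {lineno}: duplicate edge {su!r} -> {sv!r} "
                    "(use duplicates='last' to keep the final record)")
            if key not in order:
                order[key] = len(order)
            signs[key] = _SIGN_TOKENS[st]
    finally:
        if close:
            fh.close()

    pairs = sorted(order, key=order.get)
    labels = [None] * len(ids)
    for s, i in ids.items():
        labels[i] = s
    return SignedDigraph(
        n=len(ids),
        src=[u for u, _ in pairs],
        dst=[v for _, v in pairs],
        sign=[signs[p] for p in pairs],
        labels=labels,
    )


def write_signed_edgelist(g: SignedDigraph, path, header: str | None = None) -> None:
    """Write ``g`` as a tab-separated signed edge list.

    Edges are emitted in lexicographic ``(u, v)`` order of the internal
    0-based ids, so identical graphs produce byte-identical files.
    """
    close = False
    if isinstance(path, (str, os.PathLike)):
        fh = open(path, "w", encoding="utf-8", newline="\n")
        close = True
    else:
        fh = path
    try:
        fh.write("# Signed directed edge list\n")
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write(f"# nodes={g.num_nodes} edges={g.num_edges}\n")
        fh.write("# FromNodeId\tToNodeId\tSign\n")
        rows = sorted(zip(g.src.tolist(), g.dst.tolist(), g.sign.tolist()))
        for u, v, s in rows:
            fh.write(f"{u}\t{v}\t{s}\n")
    finally:
        if close:
            fh.close()


def edgelist_to_string(g: SignedDigraph, header: str | None = None) -> str:
    buf = io.StringIO()
    write_signed_edgelist(g, buf, header=header)
    return buf.getvalue()


def generate(spec: GeneratorSpec) -> SignedDigraph:
    """Generate a synthetic signed directed network.

    Signs are i.i.d.: each directed edge is +1 with probability
    ``spec.rho0``.  The complete topology has exactly ``N(N-1)`` directed
    edges.  The ``triangle_rich`` topology builds a Watts–Strogatz ring
    skeleton (``skeleton_k`` neighbours, rewiring probability
    ``rewire_p``), then turns each undirected pair into two opposite
    directed edges with probability ``p_reciprocal`` and a single directed
    edge of uniform direction otherwise — sparse, but with the high
    clustering of empirical social networks.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    if spec.topology == "complete":
        grid = np.arange(n)
        src = np.repeat(grid, n)
        dst = np.tile(grid, n)
        keep = src != dst
        src, dst = src[keep], dst[keep]
    elif spec.topology == "random_directed":
        grid = np.arange(n)
        src = np.repeat(grid, n)
        dst = np.tile(grid, n)
        keep = (src != dst) & (rng.random(n * n) < spec.edge_prob)
        src, dst = src[keep], dst[keep]
    else:  # triangle_rich
        import networkx as nx

        k = min(spec.skeleton_k, n - 1)
        skel = nx.watts_strogatz_graph(n, k, spec.rewire_p,
                                       seed=int(rng.integers(2**31)))
        src_l: list[int] = []
        dst_l: list[int] = []
        for u, v in sorted(skel.edges()):
            if rng.random() < spec.p_reciprocal:
                src_l += [u, v]
                dst_l += [v, u]
            elif rng.random() < 0.5:
                src_l.append(u)
                dst_l.append(v)
            else:
                src_l.append(v)
                dst_l.append(u)
        src = np.asarray(src_l, dtype=np.int64)
        dst = np.asarray(dst_l, dtype=np.int64)
    sign = np.where(rng.random(len(src)) < spec.rho0, 1, -1).astype(np.int8)
    return SignedDigraph(n, src, dst, sign)
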