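"""Ego-based triad taxonomy and census statistics.

An *ego-based triad* consists of a focal agent A, two out-links A->B and
A->C, and one inner link B->C.  Its sign triple ``(s_AB, s_AC, s_BC)``
determines:

* **balance** — balanced iff the product of the three signs is positive
  (equivalently, the triad has 0 or 2 negative links);
* **hierarchy** — a positive link means the source ranks the target above
  itself; the triad is hierarchical iff the three order relations admit a
  consistent ranking of A, B, C.  Exactly two of the eight sign triples,
  ``(+,-,+)`` and ``(-,+,-)``, create a ranking cycle and are
  nonhierarchical.

Each triad class is labelled ``XY#``: X is B(alanced)/U(nbalanced), Y is
H(ierarchical)/N(onhierarchical), and # counts the negative links attached
to the focal agent (0, 1 or 2).

The census enumerates every ordered triple (A, B, C) whose three links
exist in the graph; when both inner directions B->C and C->B exist, both
ego-triads are counted, mirroring the fact that the dynamics samples one
of the two inner links uniformly.  Deviations are measured within the
groups of triads with one (``UH0, UN1, UH1``) or two (``BH1, BN1, BH2``)
negative links, against the uniform 1/3 expected under balance dynamics
alone.
"""

from __future__ import annotations

import dataclasses
import enum
import itertools
import math
from typing import Mapping

import numpy as np
import scipy.sparse as sp

from .signed_graph import SignedDigraph

__all__ = [
    "TriadClass",
    "EgoTriad",
    "CensusStats",
    "classify",
    "census",
    "enumerate_3node_patterns",
    "GROUP_ONE_NEGATIVE",
    "GROUP_TWO_NEGATIVE",
    "abundance_from_deviation",
]


class TriadClass(enum.Enum):
    """The eight ego-based triad classes."""

    BH0 = (1, 1, 1)
    UH0 = (1, 1, -1)
    UN1 = (1, -1, 1)
    BH1 = (1, -1, -1)
    UH1 = (-1, 1, 1)
    BN1 = (-1, 1, -1)
    BH2 = (-1, -1, 1)
    UH2 = (-1, -1, -1)

    @property
    def signs(self) -> tuple[int, int, int]:
        """Canonical sign triple ``(s_AB, s_AC, s_BC)``."""
        return self.value

    @property
    def balanced(self) -> bool:
        s1, s2, s3 = self.value
        return s1 * s2 * s3 > 0

    @property
    def hierarchical(self) -> bool:
        s1, s2, s3 = self.value
        # the only ranking cycles: A<B, C<A, B<C and B<A, A<C, C<B
        return not (s1 != s2 and s3 == s1)

    @property
    def focal_negatives(self) -> int:
        s1, s2, _ = self.value
        return int(s1 < 0) + int(s2 < 0)

    @property
    def negative_links(self) -> int:
        """Total number of negative links in the triad (0..3)."""
        return sum(1 for s in self.value if s < 0)


_BY_SIGNS: dict[tuple[int, int, int], TriadClass] = {c.value: c for c in TriadClass}

#: Classes with exactly one negative link (the "Delta-1" group).
GROUP_ONE_NEGATIVE = (TriadClass.UH0, TriadClass.UN1, TriadClass.UH1)
#: Classes with exactly two negative links (the "Delta-2" group).
GROUP_TWO_NEGATIVE = (TriadClass.BH1, TriadClass.BN1, TriadClass.BH2)


def classify(signs: tuple[int, int, int]) -> TriadClass:
    """Classify an ego-triad from its sign triple ``(s_AB, s_AC, s_BC)``."""
    key = tuple(int(s) for s in signs)
    try:
        return _BY_SIGNS[key]  # type: ignore[index]
    except KeyError:
        raise ValueError(f"signs must be a triple over {{-1, +1}}, got {signs!r}")


def abundance_from_deviation(deviation: float) -> float:
    """Absolute within-group abundance implied by a deviation from 1/3."""
    return deviation + 1.0 / 3.0


@dataclasses.dataclass(frozen=True)
class EgoTriad:
    """A focal agent A with out-links A->left, A->right and inner left->right."""

    focal: int
    left: int
    right: int
    signs: tuple[int, int, int]

    def __post_init__(self):
        if len({self.focal, self.left, self.right}) != 3:
            raise ValueError("triad nodes must be pairwise distinct")

    @property
    def triad_class(self) -> TriadClass:
        return classify(self.signs)


@dataclasses.dataclass(frozen=True)
class CensusStats:
    """Ego-triad census of a signed digraph.

    ``group1_rel``/``group2_rel`` are the relative densities of the
    one-negative / two-negative classes within their group; ``deviations``
    subtract the uniform 1/3.  When a group is empty the corresponding
    entries are NaN (undefined, never silently zero).
    """

    counts: Mapping[TriadClass, int]
    group1_rel: Mapping[TriadClass, float]
    group2_rel: Mapping[TriadClass, float]
    deviations: Mapping[TriadClass, float]
    rho: float

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def deviation_vector(self) -> np.ndarray:
        """The six group deviations, ordered UH0, UN1, UH1, BH1, BN1, BH2."""
        return np.array([self.deviations[c]
                         for c in GROUP_ONE_NEGATIVE + GROUP_TWO_NEGATIVE])

    def to_table(self) -> list[dict]:
        rows = []
        for c in TriadClass:
            group = {1: "one-negative", 2: "two-negative"}.get(c.negative_links, "-")
            rel = dict(self.group1_rel).get(c, dict(self.group2_rel).get(c, math.nan))
            rows.append({
                "triad": c.name,
                "count": self.counts[c],
                "group": group,
                "relative_density": rel,
                "deviation": self.deviations.get(c, math.nan),
            })
        return rows


def _relative(counts: Mapping[TriadClass, int],
              group: tuple[TriadClass, ...]) -> dict[TriadClass, float]:
    total = sum(counts[c] for c in group)
    if total == 0:
        return {c: math.nan for c in group}
    return {c: counts[c] / total for c in group}


def census(g: SignedDigraph) -> CensusStats:
    """Exact ego-triad census over all ordered focal triples.

    Enumerates every ordered (A, B, C) with edges A->B, A->C, B->C present
    and classifies the triad ``(s_AB, s_AC, s_BC)``.  Implemented with
    sparse indicator-matrix products: with P/M the positive/negative
    adjacency indicators, ``(X_a^T X_b)[B, C]`` counts focal agents A with
    ``s_AB = a`` and ``s_AC = b`` (self-pairings vanish because the
    diagonal is empty), and summing over inner edges of sign c yields the
    count of class ``(a, b, c)``.
    """
    n = g.num_nodes
    pos = sp.csr_matrix(
        (np.ones(np.count_nonzero(g.sign == 1)),
         (g.src[g.sign == 1], g.dst[g.sign == 1])), shape=(n, n))
    neg = sp.csr_matrix(
        (np.ones(np.count_nonzero(g.sign == -1)),
         (g.src[g.sign == -1], g.dst[g.sign == -1])), shape=(n, n))
    pair_counts = {
        (1, 1): pos.T @ pos,
        (1, -1): pos.T @ neg,
        (-1, 1): neg.T @ pos,
        (-1, -1): neg.T @ neg,
    }
    counts: dict[TriadClass, int] = {c: 0 for c in TriadClass}
    for (a, b), mat in pair_counts.items():
        for c_sign, inner in ((1, pos), (-1, neg)):
            total = int(round(mat.multiply(inner).sum()))
            counts[classify((a, b, c_sign))] += total

    group1 = _relative(counts, GROUP_ONE_NEGATIVE)
    group2 = _relative(counts, GROUP_TWO_NEGATIVE)
    deviations = {c: r - 1.0 / 3.0 if not math.isnan(r) else math.nan
                  for c, r in {**group1, **group2}.items()}
    return CensusStats(counts=counts, group1_rel=group1, group2_rel=group2,
                       deviations=deviations, rho=g.rho())


@dataclasses.dataclass(frozen=True)
class PatternClass:
    """One isomorphism class of unsigned 3-node digraphs."""

    canonical: frozenset
    size: int
    has_unconnected_pair: bool
    contains_ego_triad: bool


def _iso_canonical(edges: frozenset) -> frozenset:
    best = None
    for perm in itertools.permutations(range(3)):
        mapped = frozenset((perm[u], perm[v]) for u, v in edges)
        key = tuple(sorted(mapped))
        if best is None or key < best[0]:
            best = (key, mapped)
    return best[1]


def enumerate_3node_patterns() -> list[PatternClass]:
    """Brute-force the 3-node unsigned digraph census.

    All 64 labelled digraphs on 3 nodes are partitioned into isomorphism
    classes (the classic 16-class triad census).  Each class is flagged
    for whether some pair of nodes is unconnected in both directions, and
    whether the pattern contains an ego-based triad (a node with out-edges
    to both others plus at least one edge between those others).
    """
    all_pairs = [(u, v) for u in range(3) for v in range(3) if u != v]
    classes: dict[frozenset, list[frozenset]] = {}
    for bits in range(64):
        edges = frozenset(p for i, p in enumerate(all_pairs) if bits >> i & 1)
        classes.setdefault(_iso_canonical(edges), []).append(edges)

    result = []
    for canon, members in classes.items():
        unconnected = any(
            (u, v) not in canon and (v, u) not in canon
            for u, v in [(0, 1), (0, 2), (1, 2)])
        ego = False
        for a in range(3):
            b, c = [x for x in range(3) if x != a]
            if (a, b) in canon and (a, c) in canon and (
                    (b, c) in canon or (c, b) in canon):
                ego = True
                break
        result.append(PatternClass(canonical=canon, size=len(members),
                                   has_unconnected_pair=unconnected,
                                   contains_ego_triad=ego))
    return result
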