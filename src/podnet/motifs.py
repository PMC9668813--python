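"""Signed whole-group motif census with canonical labeling.

A motif here is the full group's signed configuration in one period (or one
aggregated snapshot reduced to its sign pattern): a complete graph on N
nodes whose N(N-1)/2 dyads each carry one of three states.  The code of a
configuration is a digit string over {0, 1, 2} -- 0 no interaction, 1
affiliative, 2 aggressive -- one digit per dyad in the fixed order
(1,2), (1,3), ..., (N-1,N).  Node identity is immaterial, so codes are
reduced to equivalence classes under node permutation; the canonical
representative is the lexicographic minimum over all N! relabelings.
"""
from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations, product
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

_SIGN_TO_DIGIT = {0: "0", 1: "1", -1: "2"}
_DIGIT_TO_SIGN = {"0": 0, "1": 1, "2": -1}


def n_nodes_of_code(code: str) -> int:
    """Recover N from a code of length N(N-1)/2."""
    L = len(code)
    n = int((1 + math.isqrt(1 + 8 * L)) // 2)
    if n * (n - 1) // 2 != L or n < 2:
        raise ValueError(f"code length {L} is not a triangular number")
    return n


def dyad_positions(n: int) -> list[tuple[int, int]]:
    """Digit positions: 0-based dyads (i, j), i < j, lexicographic."""
    return [(i, j) for i in range(n) for j in range(i + 1, n)]


def encode(matrix: np.ndarray) -> str:
    """Encode a symmetric {-1, 0, +1} matrix as its motif code."""
    m = np.asarray(matrix)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("motif input must be a square matrix")
    if (m != m.T).any():
        raise ValueError("motif input must be symmetric")
    if not np.isin(m, (-1, 0, 1)).all():
        raise ValueError("motif entries must be in {-1, 0, +1}")
    return "".join(_SIGN_TO_DIGIT[int(m[i, j])] for i, j in dyad_positions(m.shape[0]))


def decode(code: str) -> np.ndarray:
    """Inverse of :func:`encode`."""
    n = n_nodes_of_code(code)
    m = np.zeros((n, n), dtype=np.int8)
    for (i, j), digit in zip(dyad_positions(n), code):
        m[i, j] = m[j, i] = _DIGIT_TO_SIGN[digit]
    return m


@lru_cache(maxsize=None)
def _position_maps(n: int) -> tuple[tuple[int, ...], ...]:
    # For each permutation p of nodes, the induced index map on digit
    # positions: permuted_code[k] = code[map[k]] where position k holds the
    # new-label dyad (a, b) and map[k] the position of (p^-1 a, p^-1 b).
    pos = {d: k for k, d in enumerate(dyad_positions(n))}
    maps = []
    for p in permutations(range(n)):
        inv = [0] * n
        for old, new in enumerate(p):
            inv[new] = old
        m = []
        for (a, b) in dyad_positions(n):
            i, j = sorted((inv[a], inv[b]))
            m.append(pos[(i, j)])
        maps.append(tuple(m))
    return tuple(maps)


def permute_code(code: str, perm: Sequence[int]) -> str:
    """Relabel nodes: node i of the input becomes node perm[i]."""
    n = n_nodes_of_code(code)
    if sorted(perm) != list(range(n)):
        raise ValueError(f"perm must be a permutation of 0..{n - 1}")
    pos = {d: k for k, d in enumerate(dyad_positions(n))}
    out = [""] * len(code)
    for (i, j), digit in zip(dyad_positions(n), code):
        a, b = sorted((perm[i], perm[j]))
        out[pos[(a, b)]] = digit
    return "".join(out)


@lru_cache(maxsize=None)
def canonicalize(code: str) -> str:
    """Lexicographically smallest code over all node relabelings.

    Idempotent and invariant under any prior relabeling of the input.
    """
    n = n_nodes_of_code(code)
    if any(d not in "012" for d in code):
        raise ValueError(f"code digits must be in {{0,1,2}}: {code!r}")
    return min("".join(code[k] for k in m) for m in _position_maps(n))


def _burnside_class_count(n: int, n_states: int) -> int:
    # Orbit count of edge colorings of K_n under S_n, by Burnside's lemma
    # over the induced action on unordered pairs.
    pos = dyad_positions(n)
    index = {d: k for k, d in enumerate(pos)}
    total = 0
    for p in permutations(range(n)):
        seen = [False] * len(pos)
        cycles = 0
        for k0 in range(len(pos)):
            if seen[k0]:
                continue
            cycles += 1
            k = k0
            while not seen[k]:
                seen[k] = True
                i, j = pos[k]
                a, b = sorted((p[i], p[j]))
                k = index[(a, b)]
        total += n_states**cycles
    return total // math.factorial(n)


def count_classes(n_nodes: int, n_states: int = 3, cross_check: bool | None = None) -> int:
    """Number of permutation-equivalence classes of signed complete graphs.

    Computed by Burnside's lemma over the pair action; for small N
    (``cross_check`` defaults to True for N <= 4) the count is additionally
    verified by exhaustive canonicalization of all ``n_states**(N(N-1)/2)``
    configurations, and the two must agree.
    """
    if n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    burnside = _burnside_class_count(n_nodes, n_states)
    if cross_check is None:
        cross_check = n_nodes <= 4
    if cross_check:
        if n_states != 3:
            raise ValueError("exhaustive cross-check supports n_states=3 only")
        L = n_nodes * (n_nodes - 1) // 2
        reps = {canonicalize("".join(c)) for c in product("012", repeat=L)}
        if len(reps) != burnside:
            raise AssertionError(
                f"Burnside count {burnside} != enumeration count {len(reps)}"
            )
    return burnside


@dataclass
class MotifHistogram:
    """Counts of canonical motif classes from one source of configurations."""

    n_nodes: int
    counts: Counter = field(default_factory=Counter)
    source: str = "temporal"

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def add(self, canonical_code: str, k: int = 1) -> None:
        self.counts[canonical_code] += k

    def frequency(self, code: str) -> float:
        return self.counts.get(code, 0) / self.total if self.total else 0.0

    def to_frame(self) -> pd.DataFrame:
        return rank(self)


def census(
    matrices: Iterable[np.ndarray], source: str = "temporal"
) -> MotifHistogram:
    """Count canonical motif classes over whole-group sign matrices.

    Each input matrix (one per period, or one per snapshot reduced by
    :meth:`AggregatedSnapshot.sign_pattern`) contributes one observation.
    All inputs must share the same N.
    """
    hist: MotifHistogram | None = None
    for m in matrices:
        m = np.asarray(m)
        if hist is None:
            hist = MotifHistogram(n_nodes=m.shape[0], source=source)
        elif m.shape[0] != hist.n_nodes:
            raise ValueError(
                f"mixed group sizes in census: {m.shape[0]} vs {hist.n_nodes}"
            )
        hist.add(canonicalize(encode(m)))
    if hist is None:
        raise ValueError("census needs at least one network")
    return hist


def census_networks(networks, source: str = "temporal") -> MotifHistogram:
    """Census of per-period temporal networks."""
    def gen():
        for net in networks:
            yield from net.periods
    return census(gen(), source=source)


def census_snapshots(snapshots, source: str = "aggregated") -> MotifHistogram:
    """Census of aggregated snapshots by sign pattern (weights dropped)."""
    return census((s.sign_pattern() for s in snapshots), source=source)


def rank(histogram: MotifHistogram, top_k: int | None = None) -> pd.DataFrame:
    """Classes ordered by descending count, ties broken by ascending code.

    Returns columns ``canonical_code, count, frequency, rank`` with ranks
    1..k.  Tied counts share their frequency but receive consecutive ranks
    under the deterministic code order; average ranks for tied counts are
    applied separately at the comparison stage.
    """
    if histogram.total == 0:
        raise ValueError("cannot rank an empty histogram")
    if top_k is not None and top_k < 1:
        raise ValueError(f"top_k must be >= 1, got {top_k}")
    items = sorted(histogram.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if top_k is not None:
        items = items[:top_k]
    total = histogram.total
    return pd.DataFrame(
        [
            (code, count, count / total, r)
            for r, (code, count) in enumerate(items, start=1)
        ],
        columns=["canonical_code", "count", "frequency", "rank"],
    )
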