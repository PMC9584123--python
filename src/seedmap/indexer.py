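"""Exact-match seed index over the whole reference set.

The index is a plain hash table from every N-free k-mer of every reference
(forward strand only) to the ordered list of positions where it occurs.
Holding the full reference in one index, rather than mapping against genome
segments, is what lets hotspot prioritisation see the globally best locus
first; the price is RAM proportional to reference length, which is the
intended trade-off at this design point.

Seed length is restricted to the 6-14 range the mapper supports.  Reverse
strand hits are found by querying the reverse complement of the read, not by
indexing both strands.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass

from .io_formats import ReferenceSet

logger = logging.getLogger(__name__)

MIN_SEED = 6
MAX_SEED = 14

_MAGIC = "seedmap-index-v1"


class SeedLengthError(ValueError):
    """Seed length outside the supported [6, 14] range."""


@dataclass
class IndexStats:
    distinct_kmers: int
    total_positions: int
    max_positions_per_kmer: int


class SeedIndex:
    """k-mer -> [(reference_ordinal, position), ...] lookup table.

    The originating :class:`ReferenceSet` is kept on the index so that the
    mapper's verification step can reach the sequences being indexed.
    """

    def __init__(self, refs: ReferenceSet, seed_length: int,
                 table: dict[str, list[tuple[int, int]]],
                 total_positions: int):
        self.refs = refs
        self.seed_length = seed_length
        self.table = table
        self.total_positions = total_positions

    def query(self, kmer: str) -> list[tuple[int, int]]:
        """Exact-match positions of ``kmer``; empty if absent or N-containing."""
        if len(kmer) != self.seed_length:
            raise ValueError(
                f"query length {len(kmer)} != seed length {self.seed_length}"
            )
        return self.table.get(kmer, [])

    def save(self, path) -> None:
        with open(path, "wb") as out:
            pickle.dump(
                {"magic": _MAGIC, "seed_length": self.seed_length,
                 "refs": self.refs.entries, "table": self.table,
                 "total_positions": self.total_positions},
                out, protocol=pickle.HIGHEST_PROTOCOL)

    @classmethod
    def load(cls, path) -> "SeedIndex":
        with open(path, "rb") as handle:
            payload = pickle.load(handle)
        if not isinstance(payload, dict) or payload.get("magic") != _MAGIC:
            raise ValueError(f"{path} is not a seedmap index file")
        return cls(ReferenceSet(payload["refs"]), payload["seed_length"],
                   payload["table"], payload["total_positions"])


def build_index(refs: ReferenceSet, seed_length: int) -> SeedIndex:
    """Index every N-free k-mer of every reference on the forward strand.

    Position lists are ordered by (reference ordinal, position), which keeps
    downstream hotspot grouping deterministic.  References shorter than the
    seed length contribute nothing (with a warning).
    """
    if not (MIN_SEED <= seed_length <= MAX_SEED):
        raise SeedLengthError(
            f"seed length must be in [{MIN_SEED}, {MAX_SEED}], "
            f"got {seed_length}"
        )
    table: dict[str, list[tuple[int, int]]] = {}
    total = 0
    for ordinal, (name, seq) in enumerate(refs):
        n = len(seq)
        if n < seed_length:
            logger.warning(
                "reference %s (length %d) is shorter than the seed length %d "
                "and contributes no seeds", name, n, seed_length)
            continue
        # next_n[i] = position of the first N at or after i; windows that
        # contain an N are skipped without slicing them.
        next_n = n  # sentinel: no N at or beyond current scan point
        n_positions = [i for i, c in enumerate(seq) if c == "N"]
        n_iter = iter(n_positions + [n])
        next_n = next(n_iter)
        for pos in range(n - seed_length + 1):
            while next_n < pos:
                next_n = next(n_iter)
            if next_n < pos + seed_length:
                continue
            kmer = seq[pos:pos + seed_length]
            table.setdefault(kmer, []).append((ordinal, pos))
            total += 1
    return SeedIndex(refs, seed_length, table, total)


def query_seed(index: SeedIndex, kmer: str) -> list[tuple[int, int]]:
    return index.query(kmer)


def index_stats(index: SeedIndex) -> IndexStats:
    """Exact summary counts: distinct k-mers, stored positions, heaviest k-mer."""
    if not index.table:
        return IndexStats(0, 0, 0)
    sizes = [len(v) for v in index.table.values()]
    return IndexStats(len(index.table), sum(sizes), max(sizes))
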