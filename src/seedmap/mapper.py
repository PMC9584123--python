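"""Core seed-hash read mapping.

Each read is decomposed into non-overlapping fixed-length seeds (plus one
tail-anchored seed when the length is not a multiple of the seed length).
Exact seed hits against the whole-reference index vote for candidate read
start positions; hits whose implied starts agree within a small diagonal
band are merged into one hotspot, so short indels do not fragment a locus
("fuzzy" hotspot generation).  Hotspots are then verified in order of vote
count by a banded end-to-end dynamic-programming alignment under unit edit
cost, and the read is classified unique / multi / unmapped from the set of
locations achieving the minimal edit distance within the error allowance.

The vote ordering makes an exact early exit possible: a location whose
alignment has edit distance d must retain at least m - d exact seeds
(m = number of non-overlapping seeds), so once a best distance d* is known,
hotspots with fewer than m - d* votes can never tie it and the scan stops.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import floor
from typing import Iterable, Sequence

from .indexer import MAX_SEED, MIN_SEED, SeedIndex
from .io_formats import MappingRecord, Read, ReferenceSet

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_INF = 1 << 30


def reverse_complement(sequence: str) -> str:
    """Reverse complement over {A,C,G,T,N} (N maps to N)."""
    if not set(sequence) <= {"A", "C", "G", "T", "N"}:
        raise ValueError(
            f"invalid nucleotide characters: "
            f"{sorted(set(sequence) - set('ACGTN'))}"
        )
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MappingParams:
    """Tunable mapping parameters.

    Exactly one of ``max_errors`` (absolute edit budget per read) and
    ``error_percent`` (fraction of read length, floored per read — the mode
    meant for variable-length data) must be set.  ``indel_band`` is the
    maximum net indel length tolerated and is forced to 0 when indel
    detection is off.
    """

    seed_length: int = 10
    max_errors: int | None = 5
    error_percent: float | None = None
    allow_indels: bool = True
    indel_band: int = 5
    max_reported_locations: int = 100

    def __post_init__(self) -> None:
        if not (MIN_SEED <= self.seed_length <= MAX_SEED):
            raise ValueError(
                f"seed length must be in [{MIN_SEED}, {MAX_SEED}], "
                f"got {self.seed_length}"
            )
        if (self.max_errors is None) == (self.error_percent is None):
            raise ValueError(
                "exactly one of max_errors and error_percent must be set")
        if self.max_errors is not None and self.max_errors < 0:
            raise ValueError("max_errors must be >= 0")
        if self.error_percent is not None and not (
                0 <= self.error_percent < 1):
            raise ValueError("error_percent must be in [0, 1)")
        if self.indel_band < 0:
            raise ValueError("indel_band must be >= 0")
        if self.max_reported_locations < 1:
            raise ValueError("max_reported_locations must be >= 1")
        if not self.allow_indels:
            object.__setattr__(self, "indel_band", 0)

    def allowance(self, read_length: int) -> int:
        """Per-read error allowance (re-evaluated per read in percent mode)."""
        if self.max_errors is not None:
            return self.max_errors
        return floor(self.error_percent * read_length)


@dataclass(frozen=True)
class Seed:
    read_offset: int
    kmer: str


@dataclass(frozen=True)
class Hotspot:
    """A candidate mapping locus supported by agreeing seed hits."""

    reference_ordinal: int
    strand: str
    candidate_start: int  # modal seed-implied read start (0-based, may be <0)
    votes: int            # distinct read offsets among supporting seeds
    diagonal_spread: int  # max - min seed-implied start within the group


@dataclass(frozen=True)
class Alignment:
    """End-to-end placement of a full read (no clipping).

    ``alignment_string`` is a compact edit transcript against the forward
    reference strand: ``<n>=`` for n matching bases, a lowercase base for a
    mismatch (the base observed in the read, oriented to the reference),
    ``+<SEQ>`` for inserted read bases and ``-<SEQ>`` for deleted reference
    bases (both uppercase).  The transcript fully determines the observed
    bases, so pileups can be rebuilt from the native output alone.
    """

    reference_ordinal: int
    strand: str
    ref_start: int
    ref_end: int
    mismatches: int
    indel_events: tuple[tuple[str, int, int], ...]  # (type, ref offset, length)
    edit_distance: int
    alignment_string: str


@dataclass(frozen=True)
class RunSummary:
    total: int
    unique: int
    multi: int
    unmapped: int
    mapping_rate: float
    empty_input: bool = False


# ---------------------------------------------------------------------------
# Seeds and hotspots
# ---------------------------------------------------------------------------

def split_into_seeds(sequence: str, seed_length: int) -> list[Seed]:
    """Non-overlapping seeds at 0, s, 2s, ... plus a tail-anchored seed.

    If the read length is not a multiple of the seed length, one extra seed
    is anchored at L - s so the read tail is covered (it overlaps the last
    full seed).  Reads shorter than the seed length yield no seeds.
    """
    L = len(sequence)
    if L < seed_length:
        return []
    offsets = list(range(0, L - seed_length + 1, seed_length))
    if L % seed_length != 0:
        offsets.append(L - seed_length)
    return [Seed(o, sequence[o:o + seed_length]) for o in offsets]


def collect_hotspots(seeds: Sequence[Seed], index: SeedIndex,
                     indel_band: int, strand: str = "+") -> list[Hotspot]:
    """Group seed hits into hotspots, tolerating small diagonal offsets.

    Each hit at reference position p from a seed at read offset o implies a
    read start of p - o (clamped at -indel_band).  Implied starts on the
    same reference are grouped greedily in sorted order so that max - min
    within a group never exceeds ``indel_band``; one hotspot is emitted per
    group, voting once per distinct read offset, with the modal implied
    start as the candidate.
    """
    by_ref: dict[int, list[tuple[int, int]]] = {}
    for seed in seeds:
        if "N" in seed.kmer:
            continue  # never stored in the index
        for ref_ord, pos in index.query(seed.kmer):
            cand = pos - seed.read_offset
            if cand < -indel_band:
                cand = -indel_band
            by_ref.setdefault(ref_ord, []).append((cand, seed.read_offset))
    hotspots: list[Hotspot] = []
    for ref_ord in sorted(by_ref):
        items = sorted(by_ref[ref_ord])
        group: list[tuple[int, int]] = []
        for item in items:
            if group and item[0] - group[0][0] > indel_band:
                hotspots.append(_make_hotspot(ref_ord, strand, group))
                group = []
            group.append(item)
        if group:
            hotspots.append(_make_hotspot(ref_ord, strand, group))
    return hotspots


def _make_hotspot(ref_ord: int, strand: str,
                  group: list[tuple[int, int]]) -> Hotspot:
    starts = [c for c, _ in group]
    counts: dict[int, int] = {}
    for c in starts:
        counts[c] = counts.get(c, 0) + 1
    # modal implied start; ties broken toward the smaller coordinate
    best = min(counts, key=lambda c: (-counts[c], c))
    votes = len({o for _, o in group})
    return Hotspot(ref_ord, strand, best, votes, max(starts) - min(starts))


def prioritize_hotspots(hotspots: Iterable[Hotspot]) -> list[Hotspot]:
    """Total deterministic ordering: votes desc, then coordinate, + before -."""
    return sorted(
        hotspots,
        key=lambda h: (-h.votes, h.reference_ordinal, h.candidate_start,
                       0 if h.strand == "+" else 1),
    )


# ---------------------------------------------------------------------------
# Verification (final check)
# ---------------------------------------------------------------------------

def _ops_to_transcript(ops: list[tuple[str, object]]) -> str:
    parts = []
    for kind, payload in ops:
        if kind == "=":
            parts.append(f"{payload}=")
        elif kind == "X":
            parts.append(payload.lower())  # read base
        elif kind == "I":
            parts.append("+" + payload)
        elif kind == "D":
            parts.append("-" + payload)
        else:  # pragma: no cover
            raise ValueError(kind)
    return "".join(parts)


def parse_transcript(transcript: str) -> list[tuple[str, object]]:
    """Parse an alignment string back into (op, payload) tuples."""
    ops: list[tuple[str, object]] = []
    i = 0
    n = len(transcript)
    while i < n:
        c = transcript[i]
        if c.isdigit():
            j = i
            while j < n and transcript[j].isdigit():
                j += 1
            if j >= n or transcript[j] != "=":
                raise ValueError(f"bad transcript near {transcript[i:]!r}")
            ops.append(("=", int(transcript[i:j])))
            i = j + 1
        elif c in "acgtn":
            ops.append(("X", c.upper()))
            i += 1
        elif c in "+-":
            j = i + 1
            while j < n and transcript[j] in "ACGTN":
                j += 1
            if j == i + 1:
                raise ValueError(f"empty indel in {transcript!r}")
            ops.append(("I" if c == "+" else "D", transcript[i + 1:j]))
            i = j
        else:
            raise ValueError(f"bad transcript character {c!r}")
    return ops


def alignment_from_transcript(reference_ordinal: int, strand: str,
                              ref_start: int, transcript: str) -> Alignment:
    """Reconstruct a full :class:`Alignment` from its serialized fields."""
    pos = ref_start
    mismatches = 0
    edit = 0
    events: list[tuple[str, int, int]] = []
    for kind, payload in parse_transcript(transcript):
        if kind == "=":
            pos += payload
        elif kind == "X":
            mismatches += 1
            edit += 1
            pos += 1
        elif kind == "I":
            events.append(("ins", pos - 1, len(payload)))
            edit += len(payload)
        elif kind == "D":
            events.append(("del", pos, len(payload)))
            edit += len(payload)
            pos += len(payload)
    return Alignment(reference_ordinal, strand, ref_start, pos, mismatches,
                     tuple(events), edit, transcript)


def transcript_to_cigar(transcript: str) -> str:
    """Extended CIGAR (=/X/I/D) for SAM export."""
    out = []
    run_x = 0
    for kind, payload in parse_transcript(transcript):
        if kind == "X":
            run_x += 1
            continue
        if run_x:
            out.append(f"{run_x}X")
            run_x = 0
        if kind == "=":
            out.append(f"{payload}=")
        elif kind == "I":
            out.append(f"{len(payload)}I")
        else:
            out.append(f"{len(payload)}D")
    if run_x:
        out.append(f"{run_x}X")
    return "".join(out)


def _hamming_ops(read: str, window: str) -> tuple[int, list]:
    ops: list[tuple[str, object]] = []
    run = 0
    mism = 0
    for a, b in zip(read, window):
        if a == b and a != "N":
            run += 1
        else:
            if run:
                ops.append(("=", run))
                run = 0
            ops.append(("X", a))
            mism += 1
    if run:
        ops.append(("=", run))
    return mism, ops


def _banded_align(read: str, ref: str, cand_start: int, band: int,
                  allowance: int):
    """Banded end-to-end alignment of ``read`` near ``cand_start``.

    The read is aligned in full against the window
    [cand_start - band, cand_start + len(read) + band), truncated at the
    reference boundaries, with free reference overhangs on both sides and
    the alignment path confined to diagonals within ``band`` of the
    candidate diagonal.  Unit costs; N never matches.  Returns
    (edit_distance, ref_start, ops) or None when nothing within the
    allowance exists.
    """
    L = len(read)
    rl = len(ref)
    ws = max(0, cand_start - band)
    we = min(rl, cand_start + L + band)
    if we <= ws:
        return None
    W = ref[ws:we]
    wl = len(W)
    lpad = cand_start - ws
    dlo = lpad - band
    width = 2 * band + 1

    rows = [[_INF] * width for _ in range(L + 1)]
    row0 = rows[0]
    for t in range(width):
        j = dlo + t
        if 0 <= j <= wl:
            row0[t] = 0
    for i in range(1, L + 1):
        rc = read[i - 1]
        prev = rows[i - 1]
        cur = rows[i]
        base_j = i + dlo
        best_row = _INF
        for t in range(width):
            j = base_j + t
            if j < 0 or j > wl:
                continue
            best = _INF
            if j >= 1:
                d = prev[t]
                if d < _INF:
                    wc = W[j - 1]
                    d += 0 if (rc == wc and rc != "N") else 1
                    if d < best:
                        best = d
            if t + 1 < width:
                d = prev[t + 1] + 1  # insertion: read base, no ref base
                if d < best:
                    best = d
            if t >= 1:
                d = cur[t - 1] + 1  # deletion: ref base, no read base
                if d < best:
                    best = d
            cur[t] = best
            if best < best_row:
                best_row = best
        if best_row > allowance:
            return None

    # best end cell: minimal distance, then smallest window coordinate
    last = rows[L]
    best_t = -1
    best_d = _INF
    for t in range(width):
        j = L + dlo + t
        if 0 <= j <= wl and last[t] < best_d:
            best_d = last[t]
            best_t = t
    if best_t < 0 or best_d > allowance:
        return None

    # traceback; ties prefer extending the current gap (keeps indel events
    # contiguous), otherwise the diagonal, so co-optimal paths are chosen
    # consistently across reads
    ops_rev: list[tuple[str, object]] = []
    i, t = L, best_t
    in_gap: str | None = None
    while i > 0:
        j = i + dlo + t
        cur = rows[i][t]
        rc = read[i - 1]
        order = {"D": "DMI", "I": "IMD"}.get(in_gap, "MDI")
        moved = False
        for move in order:
            if move == "M" and j >= 1:
                wc = W[j - 1]
                step = 0 if (rc == wc and rc != "N") else 1
                if rows[i - 1][t] + step == cur:
                    ops_rev.append(("=", 1) if step == 0 else ("X", rc))
                    i -= 1
                    in_gap = None
                    moved = True
                    break
            elif move == "D" and t >= 1 and rows[i][t - 1] + 1 == cur:
                ops_rev.append(("D", W[j - 1]))
                t -= 1
                in_gap = "D"
                moved = True
                break
            elif move == "I" and t + 1 < width \
                    and rows[i - 1][t + 1] + 1 == cur:
                ops_rev.append(("I", rc))
                i -= 1
                t += 1
                in_gap = "I"
                moved = True
                break
        if not moved:
            raise AssertionError("traceback failed")  # pragma: no cover
    ref_start = ws + (i + dlo + t)

    # merge runs into compact ops
    ops: list[tuple[str, object]] = []
    for kind, payload in reversed(ops_rev):
        if ops and ops[-1][0] == kind and kind != "X":
            ops[-1] = (kind, ops[-1][1] + payload)  # int or str run
        else:
            ops.append((kind, payload))
    return best_d, ref_start, ops


def verify_candidate(read_seq: str, refs: ReferenceSet, hotspot: Hotspot,
                     allowance: int, params: MappingParams):
    """Final check: align the full read at a hotspot.

    Returns the minimum-edit-distance :class:`Alignment` if it is within
    the allowance, else None.  With indel detection off this degenerates to
    a Hamming comparison at the candidate start.
    """
    ref = refs.sequences[hotspot.reference_ordinal]
    cs = hotspot.candidate_start
    L = len(read_seq)

    if 0 <= cs and cs + L <= len(ref) and "N" not in read_seq \
            and ref[cs:cs + L] == read_seq:
        return Alignment(hotspot.reference_ordinal, hotspot.strand, cs,
                         cs + L, 0, (), 0, f"{L}=")

    if not params.allow_indels:
        if cs < 0 or cs + L > len(ref):
            return None  # read would overhang the reference
        mism, ops = _hamming_ops(read_seq, ref[cs:cs + L])
        if mism > allowance:
            return None
        return _build_alignment(hotspot, cs, mism, 0, ops)

    result = _banded_align(read_seq, ref, cs, params.indel_band, allowance)
    if result is None:
        return None
    edit, ref_start, ops = result
    return alignment_from_transcript(
        hotspot.reference_ordinal, hotspot.strand, ref_start,
        _ops_to_transcript(ops))


def _build_alignment(hotspot: Hotspot, ref_start: int, mismatches: int,
                     indel_bases: int, ops: list) -> Alignment:
    return alignment_from_transcript(
        hotspot.reference_ordinal, hotspot.strand, ref_start,
        _ops_to_transcript(ops))


# ---------------------------------------------------------------------------
# Per-read pipeline
# ---------------------------------------------------------------------------

def _same_location(a: Alignment, b: Alignment, band: int) -> bool:
    return (a.reference_ordinal == b.reference_ordinal
            and a.strand == b.strand
            and abs(a.ref_start - b.ref_start) <= band)


def map_read(read: Read, index: SeedIndex,
             params: MappingParams) -> MappingRecord:
    """Map one read: seeds, hotspots, prioritized verification, classification.

    All distinct locations achieving the minimal verified edit distance are
    retained (up to ``max_reported_locations``); two locations are distinct
    when they differ in reference, strand, or by more than ``indel_band`` in
    start coordinate.
    """
    seq = read.sequence
    L = len(seq)
    s = params.seed_length
    if L < s:
        return MappingRecord(read.id, "unmapped", (), reason="too_short")
    allowance = params.allowance(L)
    band = params.indel_band

    rc = reverse_complement(seq)
    hotspots = collect_hotspots(split_into_seeds(seq, s), index, band, "+")
    hotspots += collect_hotspots(split_into_seeds(rc, s), index, band, "-")
    ordered = prioritize_hotspots(hotspots)

    m = L // s  # non-overlapping seed count (pigeonhole denominator)
    d_star: int | None = None
    best: list[Alignment] = []
    for hotspot in ordered:
        if d_star is not None and hotspot.votes < m - d_star:
            break  # cannot tie or beat d* (pigeonhole on remaining votes)
        oriented = seq if hotspot.strand == "+" else rc
        aln = verify_candidate(oriented, index.refs, hotspot, allowance,
                               params)
        if aln is None:
            continue
        if d_star is None or aln.edit_distance < d_star:
            d_star = aln.edit_distance
            best = [aln]
        elif aln.edit_distance == d_star:
            if not any(_same_location(aln, other, band) for other in best):
                best.append(aln)

    if not best:
        return MappingRecord(read.id, "unmapped", ())
    best.sort(key=lambda a: (a.reference_ordinal, a.ref_start,
                             0 if a.strand == "+" else 1))
    best = best[:params.max_reported_locations]
    status = "unique" if len(best) == 1 else "multi"
    return MappingRecord(read.id, status, tuple(best))


def map_all(reads: Iterable[Read], index: SeedIndex,
            params: MappingParams) -> tuple[list[MappingRecord], RunSummary]:
    """Map reads independently, preserving input order.

    Paired-end data are handled as two independent single-end runs; reads
    never interact, so the output is invariant to read order up to the
    per-read lines themselves.
    """
    records = [map_read(read, index, params) for read in reads]
    counts = {"unique": 0, "multi": 0, "unmapped": 0}
    for rec in records:
        counts[rec.status] += 1
    total = len(records)
    mapped = counts["unique"] + counts["multi"]
    rate = mapped / total if total else 0.0
    return records, RunSummary(total, counts["unique"], counts["multi"],
                               counts["unmapped"], rate,
                               empty_input=(total == 0))


def estimate_mismap_probability(read_length: int, seed_length: int,
                                per_base_error_rate: float) -> float:
    """Probability that no seed of a read anchors its true locus.

    Under independent per-base errors at rate p, a seed of length s is
    error-free with probability (1-p)^s; with m = floor(L/s) non-overlapping
    seeds, the chance that every seed is corrupted — the only way the true
    locus can escape hotspot generation — is (1 - (1-p)^s)^m.  This bounds
    the mismapping rate contributed by seeding.
    """
    if not (0 <= per_base_error_rate < 1):
        raise ValueError("per-base error rate must be in [0, 1)")
    if seed_length > read_length:
        raise ValueError("seed length exceeds read length")
    m = read_length // seed_length
    q = 1.0 - (1.0 - per_base_error_rate) ** seed_length
    return q ** m
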