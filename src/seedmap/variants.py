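"""Pileup construction and variant calling.

Only uniquely mapped reads contribute to the pileup — the multimapped file
exists precisely so downstream analyses can ignore it.  At each site the
most frequent non-reference allele is compared against the expectation
under a flat sequencing-error rate with a two-sided Fisher's exact test;
insertion and deletion events, anchored at their reference positions, are
tested the same way.

The contingency table contrasts the observed (alt, non-alt) split with the
(round(eps*N), N - round(eps*N)) split expected from errors alone.  The
error rate, significance level and count thresholds are all exposed on
:class:`VariantCallingParams` so alternative constructions can be swapped
in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io_formats import MappingRecord, ReferenceSet
from .mapper import parse_transcript

_BASES = "ACGTN"
_BASE_ROW = {b: i for i, b in enumerate(_BASES)}
_DEL_ROW = 5


@dataclass
class VariantCallingParams:
    error_rate: float = 0.01   # flat per-base sequencing error expectation
    alpha: float = 0.01        # two-sided Fisher significance threshold
    min_depth: int = 10
    min_alt: int = 3
    min_fraction_factor: float = 5.0  # alt fraction must exceed factor*error_rate
    het_fraction: float = 0.2  # informational genotype flag boundaries
    hom_fraction: float = 0.8


@dataclass(frozen=True)
class VariantCall:
    reference: str
    position: int         # 1-based; anchor base position for indels
    ref_allele: str
    alt_allele: str
    type: str             # snv | ins | del
    alt_count: int
    depth: int
    p_value: float
    genotype: str         # "hom" / "het" / "lowfrac" informational flag

    def __post_init__(self) -> None:
        if not (0 < self.alt_count <= self.depth):
            raise ValueError("alt_count must be in (0, depth]")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must be in [0, 1]")


class Pileup:
    """Per-position base / deletion counts plus anchored indel events.

    ``counts[ref_ordinal]`` is a (6, L) integer array with rows A, C, G, T,
    N and deletion-spanning reads; depth at a position is the column sum.
    Insertions are anchored at the preceding reference position, deletions
    at their first deleted position, each with per-sequence/length counts.
    """

    def __init__(self, refs: ReferenceSet):
        self.refs = refs
        self.counts = [np.zeros((6, n), dtype=np.int32) for n in refs.lengths]
        self.insertions: list[dict[int, dict[str, int]]] = [
            {} for _ in refs.lengths]
        self.deletions: list[dict[int, dict[int, int]]] = [
            {} for _ in refs.lengths]

    def depth(self, ref_ordinal: int, pos: int) -> int:
        return int(self.counts[ref_ordinal][:, pos].sum())

    def at(self, reference_name: str, position_1based: int) -> dict[str, int]:
        """Counts snapshot at a 1-based position (for site inspection)."""
        ordinal = self.refs.ordinal(reference_name)
        length = self.refs.lengths[ordinal]
        if not (1 <= position_1based <= length):
            raise ValueError(
                f"position {position_1based} outside {reference_name} "
                f"(1..{length})"
            )
        col = self.counts[ordinal][:, position_1based - 1]
        out = {b: int(col[_BASE_ROW[b]]) for b in _BASES}
        out["del"] = int(col[_DEL_ROW])
        out["depth"] = int(col.sum())
        return out


def left_align_deletion(seq: str, pos: int, length: int) -> int:
    """Leftmost equivalent position for deleting seq[pos:pos+length]."""
    while pos > 0 and seq[pos - 1] == seq[pos + length - 1]:
        pos -= 1
    return pos


def left_align_insertion(seq: str, anchor: int, inserted: str
                         ) -> tuple[int, str]:
    """Leftmost equivalent (anchor, inserted) for an insertion after anchor."""
    while anchor >= 0 and seq[anchor] == inserted[-1]:
        inserted = inserted[-1] + inserted[:-1]
        anchor -= 1
    return anchor, inserted


def build_pileup(mapping_records, refs: ReferenceSet) -> Pileup:
    """Accumulate uniquely mapped reads into a pileup.

    Each read contributes one count at every reference position it covers,
    following its edit transcript: matches count toward the reference base,
    mismatches toward the observed base, deletions toward the deletion row
    at each deleted position, insertions as events anchored at the
    preceding position.  Non-unique records are ignored.
    """
    ref_codes = [np.frombuffer(seq.encode(), dtype=np.uint8)
                 for seq in refs.sequences]
    code_row = np.full(256, -1, dtype=np.int64)
    for b, i in _BASE_ROW.items():
        code_row[ord(b)] = i

    pile = Pileup(refs)
    for rec in mapping_records:
        if rec.status != "unique":
            continue
        aln = rec.alignments[0]
        r = aln.reference_ordinal
        counts = pile.counts[r]
        length = refs.lengths[r]
        if aln.ref_end > length or aln.ref_start < 0:
            raise ValueError(
                f"alignment of {rec.read_id} ({aln.ref_start}..{aln.ref_end}) "
                f"inconsistent with reference length {length}"
            )
        pos = aln.ref_start
        for kind, payload in parse_transcript(aln.alignment_string):
            if kind == "=":
                rows = code_row[ref_codes[r][pos:pos + payload]]
                np.add.at(counts, (rows, np.arange(pos, pos + payload)), 1)
                pos += payload
            elif kind == "X":
                counts[_BASE_ROW[payload], pos] += 1
                pos += 1
            elif kind == "D":
                # anchor the event at its left-normalized position so
                # equivalent gap placements from different reads aggregate
                dlen = len(payload)
                seq = refs.sequences[r]
                canon = left_align_deletion(seq, pos, dlen)
                counts[_DEL_ROW, canon:canon + dlen] += 1
                events = pile.deletions[r].setdefault(canon, {})
                events[dlen] = events.get(dlen, 0) + 1
                pos += dlen
            elif kind == "I":
                seq = refs.sequences[r]
                anchor, inserted = left_align_insertion(seq, pos - 1, payload)
                events = pile.insertions[r].setdefault(anchor, {})
                events[inserted] = events.get(inserted, 0) + 1
    return pile


def pileup_at(pileup: Pileup, reference_name: str,
              position_1based: int) -> dict[str, int]:
    return pileup.at(reference_name, position_1based)


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

_logfact = np.zeros(1)


def _log_factorials(n: int) -> np.ndarray:
    global _logfact
    if len(_logfact) <= n:
        m = max(n + 1, 2 * len(_logfact))
        _logfact = np.concatenate(
            [[0.0], np.cumsum(np.log(np.arange(1, m, dtype=np.float64)))])
    return _logfact


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p-value for the table [[a, b], [c, d]].

    Sums hypergeometric probabilities of all tables with the observed
    margins whose point probability does not exceed the observed one
    (within relative tolerance 1e-7), computed in log space.  Any zero
    margin gives p = 1 by convention.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    n = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if 0 in (r1, r2, c1, c2):
        return 1.0
    lf = _log_factorials(n)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    xs = np.arange(lo, hi + 1)
    logp = (lf[r1] - lf[xs] - lf[r1 - xs]
            + lf[r2] - lf[c1 - xs] - lf[r2 - c1 + xs]
            - (lf[n] - lf[c1] - lf[c2]))
    obs = logp[a - lo]
    keep = logp <= obs + math.log1p(1e-7)
    mx = logp[keep].max()
    p = math.exp(mx) * float(np.exp(logp[keep] - mx).sum())
    return min(1.0, p)


# ---------------------------------------------------------------------------
# Calling
# ---------------------------------------------------------------------------

def call_variants(pileup: Pileup, refs: ReferenceSet,
                  params: VariantCallingParams | None = None
                  ) -> list[VariantCall]:
    """Call SNVs and short indels from a pileup.

    At each site with depth >= min_depth, the most frequent non-reference
    base with count >= min_alt is tested against the error-rate expectation;
    anchored insertion/deletion events are tested identically with their
    event counts.  Emitted when p <= alpha and the alt fraction exceeds
    min_fraction_factor * error_rate; output is coordinate-sorted.
    """
    if params is None:
        params = VariantCallingParams()
    eps = params.error_rate
    calls: list[VariantCall] = []

    for ordinal, (name, seq) in enumerate(refs):
        counts = pileup.counts[ordinal]
        depths = counts.sum(axis=0)
        base_counts = counts[:4]  # A C G T rows; N never called as alt

        ref_rows = np.full(len(seq), -1, dtype=np.int64)
        for b, i in _BASE_ROW.items():
            if b == "N":
                continue
            ref_rows[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(b)] = i

        alt = base_counts.copy()
        valid = ref_rows >= 0
        cols = np.nonzero(valid)[0]
        alt[ref_rows[cols], cols] = -1  # mask the reference base
        alt_best = alt.max(axis=0)
        candidates = np.nonzero(
            (depths >= params.min_depth) & (alt_best >= params.min_alt))[0]

        for pos in candidates:
            depth = int(depths[pos])
            col = alt[:, pos]
            row = int(np.argmax(col))  # argmax ties -> lowest row = A<C<G<T
            k = int(col[row])
            call = _test_site(name, seq, int(pos), "snv", _BASES[row], k,
                              depth, eps, params)
            if call:
                calls.append(call)

        for pos, events in sorted(pileup.deletions[ordinal].items()):
            depth = int(depths[pos])
            if depth < params.min_depth:
                continue
            for length, k in sorted(events.items()):
                if k < params.min_alt:
                    continue
                call = _test_site(name, seq, pos, "del", length, k, depth,
                                  eps, params)
                if call:
                    calls.append(call)

        for pos, events in sorted(pileup.insertions[ordinal].items()):
            if pos < 0 or pos >= len(seq):
                continue
            depth = int(depths[pos])
            if depth < params.min_depth:
                continue
            for inserted, k in sorted(events.items()):
                if k < params.min_alt:
                    continue
                call = _test_site(name, seq, pos, "ins", inserted, k, depth,
                                  eps, params)
                if call:
                    calls.append(call)

    calls.sort(key=lambda c: (refs.ordinal(c.reference), c.position, c.type,
                              c.alt_allele))
    return calls


def _test_site(name: str, seq: str, pos: int, vtype: str, payload,
               k: int, depth: int, eps: float,
               params: VariantCallingParams) -> VariantCall | None:
    expected = round(eps * depth)
    p = fisher_exact_2x2(k, depth - k, expected, depth - expected)
    frac = k / depth
    if p > params.alpha or frac <= params.min_fraction_factor * eps:
        return None
    if frac >= params.hom_fraction:
        genotype = "hom"
    elif frac >= params.het_fraction:
        genotype = "het"
    else:
        genotype = "lowfrac"
    if vtype == "snv":
        return VariantCall(name, pos + 1, seq[pos], payload, "snv", k, depth,
                           p, genotype)
    if vtype == "del":
        length = payload
        if pos == 0:
            return None  # cannot anchor a deletion at the very first base
        anchor = seq[pos - 1]
        return VariantCall(name, pos, anchor + seq[pos:pos + length], anchor,
                           "del", k, depth, p, genotype)
    # insertion anchored at pos (payload = inserted sequence)
    anchor = seq[pos]
    return VariantCall(name, pos + 1, anchor, anchor + payload, "ins", k,
                       depth, p, genotype)
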