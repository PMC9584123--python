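"""Synthetic data generation and mapping evaluation.

The simulator produces the study conditions the rest of the package is
tested under: random (optionally repeat-containing) genomes, fixed-length
Illumina-like or variable-length IonTorrent-like reads with uniform
per-base substitution and geometric-length indel errors, planted variants
for calling experiments, and a ground-truth table that lets a mapping run
be scored for sensitivity and mismapping rate.

Everything is deterministic under an explicit seed (numpy PCG64).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io_formats import MappingRecord, Read, ReferenceSet
from .mapper import reverse_complement

_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}

#: geometric length parameter for indel events (mean length 1/p)
INDEL_LENGTH_P = 0.7


@dataclass(frozen=True)
class SimTruth:
    """Ground truth for one simulated read.

    ``true_start`` is the 0-based start of the originating reference window
    and ``indel_events`` records the applied events as (type, offset within
    the pre-indel read, length).
    """

    read_id: str
    true_reference: str
    true_start: int
    strand: str
    n_substitutions: int
    indel_events: tuple[tuple[str, int, int], ...]
    read_length: int


@dataclass(frozen=True)
class PlantedVariant:
    """A variant introduced into a donor genome, in VCF-style coordinates."""

    reference: str
    position: int  # 1-based; anchor base for indels
    ref_allele: str
    alt_allele: str
    type: str      # snv | ins | del


@dataclass(frozen=True)
class EvalReport:
    total: int
    mapped_unique: int
    mapped_multi: int
    unmapped: int
    correct_unique: int
    mismapped_unique: int
    multi_correct: int
    sensitivity: float   # correctly placed unique / simulated reads
    mismap_rate: float   # wrongly placed unique / mapped unique
    tolerance: int

    def as_dict(self) -> dict:
        return self.__dict__.copy()


# ---------------------------------------------------------------------------
# Genomes
# ---------------------------------------------------------------------------

def simulate_genome(length: int, gc: float = 0.5,
                    repeat_spec: tuple[int, int, int] | None = None,
                    seed: int | None = None,
                    name: str = "sim_genome") -> ReferenceSet:
    """Random genome with i.i.d. bases at the given GC content.

    ``repeat_spec = (n_repeats, unit_length, copies)`` pastes ``n_repeats``
    distinct random units, each ``copies`` times, at random non-overlapping
    positions (so the genome contains verbatim repeats).  Deterministic
    under ``seed``.
    """
    if not (0.0 <= gc <= 1.0):
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    arr = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length,
                     p=probs)
    if repeat_spec is not None:
        n_repeats, unit_length, copies = repeat_spec
        if length < unit_length * copies:
            raise ValueError("genome shorter than unit_length * copies")
        total = n_repeats * copies * unit_length
        if total > length:
            raise ValueError(
                f"repeat payload ({total} nt) does not fit in {length} nt")
        occupied: list[tuple[int, int]] = []
        units = [rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8),
                            size=unit_length, p=probs)
                 for _ in range(n_repeats)]
        for unit in units:
            for _ in range(copies):
                placed = False
                for _attempt in range(1000):
                    start = int(rng.integers(0, length - unit_length + 1))
                    end = start + unit_length
                    if all(end <= s or start >= e for s, e in occupied):
                        arr[start:end] = unit
                        occupied.append((start, end))
                        placed = True
                        break
                if not placed:
                    raise ValueError(
                        "could not place repeats without overlap; "
                        "repeat_spec is infeasible for this genome length")
    return ReferenceSet(((name, arr.tobytes().decode()),))


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

def simulate_reads(refs: ReferenceSet, n: int,
                   read_length: int | tuple[int, int],
                   sub_rate: float = 0.0, ins_rate: float = 0.0,
                   del_rate: float = 0.0, seed: int | None = None,
                   weights: Sequence[float] | None = None,
                   id_prefix: str = "r"
                   ) -> tuple[list[Read], list[SimTruth]]:
    """Draw reads uniformly from the references and corrupt them.

    Start positions and strands are uniform; each base substitutes to a
    uniformly different base with probability ``sub_rate``; insertion and
    deletion events occur per base at the stated rates with geometric
    (mean ~1.4 nt) lengths, so fixed-length requests still emit reads of
    exactly ``read_length`` whenever the indel rates are zero.

    ``weights`` biases the choice of reference (e.g. transcript abundances);
    the default weights references by usable start positions.  Returns the
    reads and a matching ground-truth table; deterministic under ``seed``.
    """
    for rate in (sub_rate, ins_rate, del_rate):
        if not (0.0 <= rate < 1.0):
            raise ValueError("error rates must be in [0, 1)")
    if isinstance(read_length, int):
        lmin = lmax = read_length
    else:
        lmin, lmax = read_length
        if lmin > lmax or lmin < 1:
            raise ValueError(f"bad read length range ({lmin}, {lmax})")
    if lmax > min(refs.lengths):
        raise ValueError("read length exceeds the shortest reference")

    rng = np.random.default_rng(seed)
    if weights is None:
        w = np.array([max(0, L - lmax + 1) for L in refs.lengths],
                     dtype=float)
    else:
        w = np.asarray(weights, dtype=float)
        if len(w) != len(refs) or w.sum() <= 0:
            raise ValueError("weights must be positive over all references")
    w = w / w.sum()

    reads: list[Read] = []
    truths: list[SimTruth] = []
    width = max(6, len(str(max(n - 1, 0))))
    for i in range(n):
        ordinal = int(rng.choice(len(refs), p=w))
        ref_seq = refs.sequences[ordinal]
        L0 = int(rng.integers(lmin, lmax + 1)) if lmin != lmax else lmin
        start = int(rng.integers(0, len(ref_seq) - L0 + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        template = ref_seq[start:start + L0]
        seq = template if strand == "+" else reverse_complement(template)

        seq, n_sub = _apply_substitutions(seq, sub_rate, rng)
        seq, events = _apply_indels(seq, ins_rate, del_rate, rng)
        if not seq:  # pathological rates can erase a read entirely
            seq = template[0]
            events = ()
        rid = f"{id_prefix}{i:0{width}d}"
        reads.append(Read(rid, seq, "I" * len(seq)))
        truths.append(SimTruth(rid, refs.names[ordinal], start, strand,
                               n_sub, tuple(events), len(seq)))
    return reads, truths


def _apply_substitutions(seq: str, rate: float, rng) -> tuple[str, int]:
    if rate <= 0:
        return seq, 0
    mask = rng.random(len(seq)) < rate
    if not mask.any():
        return seq, 0
    chars = list(seq)
    n_sub = 0
    for pos in np.nonzero(mask)[0]:
        base = chars[pos]
        if base == "N":
            continue
        chars[pos] = _BASES[(_BASE_IDX[base] + int(rng.integers(1, 4))) % 4]
        n_sub += 1
    return "".join(chars), n_sub


def _apply_indels(seq: str, ins_rate: float, del_rate: float, rng
                  ) -> tuple[str, list[tuple[str, int, int]]]:
    if ins_rate <= 0 and del_rate <= 0:
        return seq, []
    out: list[str] = []
    events: list[tuple[str, int, int]] = []
    i = 0
    L = len(seq)
    while i < L:
        r = rng.random()
        if r < ins_rate:
            length = int(rng.geometric(INDEL_LENGTH_P))
            ins = "".join(_BASES[int(b)]
                          for b in rng.integers(0, 4, size=length))
            out.append(ins)
            events.append(("ins", i, length))
            out.append(seq[i])
            i += 1
        elif r < ins_rate + del_rate:
            length = min(int(rng.geometric(INDEL_LENGTH_P)), L - i)
            events.append(("del", i, length))
            i += length
        else:
            out.append(seq[i])
            i += 1
    return "".join(out), events


# ---------------------------------------------------------------------------
# Planted variants
# ---------------------------------------------------------------------------

def plant_variants(refs: ReferenceSet, n_snv: int = 100, n_ins: int = 5,
                   n_del: int = 5, max_indel_len: int = 2,
                   min_separation: int = 150, seed: int | None = None
                   ) -> tuple[ReferenceSet, list[PlantedVariant]]:
    """Introduce homozygous SNVs and short indels into a donor genome.

    Variant sites are kept ``min_separation`` apart and away from the
    reference ends so that every event is independently recoverable.
    Returns the mutated references (to simulate reads from) and the planted
    truth in the same VCF-style coordinates the caller emits.
    """
    rng = np.random.default_rng(seed)
    n_total = n_snv + n_ins + n_del
    types = ["snv"] * n_snv + ["ins"] * n_ins + ["del"] * n_del

    lengths = refs.lengths
    margin = min_separation
    usable = sum(max(0, L - 2 * margin) for L in lengths)
    if usable < n_total * min_separation:
        raise ValueError("references too short for the requested variants")

    # (ordinal, 0-based pos, type, payload): payload is the alt base for a
    # SNV, the inserted sequence for an insertion, the length for a deletion
    variants: list[tuple[int, int, str, object]] = []
    taken: dict[int, list[int]] = {i: [] for i in range(len(refs))}
    for vtype in types:
        for _attempt in range(10000):
            ordinal = int(rng.integers(0, len(refs)))
            seq = refs.sequences[ordinal]
            L = lengths[ordinal]
            if L <= 2 * margin:
                continue
            pos = int(rng.integers(margin, L - margin))
            if any(abs(pos - q) < min_separation for q in taken[ordinal]):
                continue
            if vtype == "snv":
                ref_base = seq[pos]
                if ref_base == "N":
                    continue
                payload = _BASES[(_BASE_IDX[ref_base]
                                  + int(rng.integers(1, 4))) % 4]
            elif vtype == "del":
                length = int(rng.integers(1, max_indel_len + 1))
                # reject positions where the deletion could be placed
                # elsewhere (shiftable in either direction): recovery is
                # then coordinate-exact
                if (seq[pos - 1] == seq[pos + length - 1]
                        or seq[pos] == seq[pos + length]):
                    continue
                payload = length
            else:  # insertion between pos and pos + 1
                length = int(rng.integers(1, max_indel_len + 1))
                ins = "".join(_BASES[int(b)]
                              for b in rng.integers(0, 4, size=length))
                if ins[-1] == seq[pos] or ins[0] == seq[pos + 1]:
                    continue
                payload = ins
            taken[ordinal].append(pos)
            variants.append((ordinal, pos, vtype, payload))
            break
        else:
            raise ValueError("could not place variants with the requested "
                             "separation")

    truth: list[PlantedVariant] = []
    mutated = [list(seq) for seq in refs.sequences]
    # apply high-to-low so earlier coordinates keep their meaning
    for ordinal, pos, vtype, payload in sorted(
            variants, key=lambda v: (v[0], v[1]), reverse=True):
        seq = refs.sequences[ordinal]
        name = refs.names[ordinal]
        if vtype == "snv":
            mutated[ordinal][pos] = payload
            truth.append(PlantedVariant(name, pos + 1, seq[pos], payload,
                                        "snv"))
        elif vtype == "del":
            del mutated[ordinal][pos:pos + payload]
            truth.append(PlantedVariant(
                name, pos, seq[pos - 1:pos + payload], seq[pos - 1], "del"))
        else:
            mutated[ordinal][pos + 1:pos + 1] = list(payload)
            truth.append(PlantedVariant(
                name, pos + 1, seq[pos], seq[pos] + payload, "ins"))

    truth.sort(key=lambda v: (refs.ordinal(v.reference), v.position, v.type))
    mutated_refs = ReferenceSet(tuple(
        (name, "".join(chars))
        for name, chars in zip(refs.names, mutated)))
    return mutated_refs, truth


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def evaluate_mapping(records: Iterable[MappingRecord],
                     truth: Iterable[SimTruth], refs: ReferenceSet,
                     tolerance: int = 5) -> EvalReport:
    """Score a mapping run against simulator ground truth.

    A uniquely mapped read is correct iff it is on the true reference and
    strand within ``tolerance`` nt of the true start.  Multimapped reads
    are scored separately (correct if any reported location matches) and
    excluded from the mismap-rate denominator.
    """
    truth_by_id = {t.read_id: t for t in truth}
    records = list(records)
    record_ids = {r.read_id for r in records}
    orphans = record_ids.symmetric_difference(truth_by_id)
    if orphans:
        raise ValueError(
            f"records and truth disagree on read ids, e.g. "
            f"{sorted(orphans)[:5]}")

    unique = multi = unmapped = correct = wrong = multi_correct = 0
    for rec in records:
        t = truth_by_id[rec.read_id]
        if rec.status == "unmapped":
            unmapped += 1
            continue
        hits = [
            aln for aln in rec.alignments
            if refs.names[aln.reference_ordinal] == t.true_reference
            and aln.strand == t.strand
            and abs(aln.ref_start - t.true_start) <= tolerance
        ]
        if rec.status == "unique":
            unique += 1
            if hits:
                correct += 1
            else:
                wrong += 1
        else:
            multi += 1
            if hits:
                multi_correct += 1

    total = len(records)
    sensitivity = correct / total if total else 0.0
    mismap_rate = wrong / unique if unique else 0.0
    return EvalReport(total, unique, multi, unmapped, correct, wrong,
                      multi_correct, sensitivity, mismap_rate, tolerance)


# ---------------------------------------------------------------------------
# Truth table I/O
# ---------------------------------------------------------------------------

def write_truth(truths: Iterable[SimTruth], path) -> None:
    with open(path, "w") as out:
        out.write("#read_id\tref\tstart\tstrand\tn_sub\tindels\tlength\n")
        for t in truths:
            indels = ";".join(f"{k}:{o}:{l}" for k, o, l in t.indel_events)
            out.write(f"{t.read_id}\t{t.true_reference}\t{t.true_start}\t"
                      f"{t.strand}\t{t.n_substitutions}\t{indels or '.'}\t"
                      f"{t.read_length}\n")


def read_truth(path) -> list[SimTruth]:
    truths = []
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            rid, ref, start, strand, n_sub, indels, length = line.split("\t")
            events = ()
            if indels != ".":
                events = tuple(
                    (k, int(o), int(l))
                    for k, o, l in (part.split(":")
                                    for part in indels.split(";")))
            truths.append(SimTruth(rid, ref, int(start), strand, int(n_sub),
                                   events, int(length)))
    return truths
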