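"""Readers and writers for the formats the pipeline touches.

FASTA references and FASTQ reads come in through Biopython; mapping results
go out in a native tab-separated format that partitions reads into three
files (uniquely mapped, multimapped, unmapped), with an optional SAM export
for interoperability.  Variant calls are written as minimal VCF 4.2.

Coordinates are 0-based half-open everywhere in memory and 1-based in every
human-readable output file.
"""

from __future__ import annotations

import gzip
import io
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")

#: IUPAC ambiguity codes collapsed to N on load (everything that is not ACGTN).
_AMBIGUOUS = frozenset("RYSWKMBDHVU")

NATIVE_HEADER = "#read_id\tref\tpos\tstrand\tedits\talign"


class FormatError(ValueError):
    """Malformed input file."""


@dataclass(frozen=True)
class ReferenceSet:
    """Ordered collection of named reference sequences.

    Sequences are uppercase strings over {A,C,G,T,N}; names are unique.
    """

    entries: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        names = [name for name, _ in self.entries]
        if len(set(names)) != len(names):
            dup = next(n for n in names if names.count(n) > 1)
            raise FormatError(f"duplicate reference name: {dup!r}")
        for name, seq in self.entries:
            if not seq:
                raise FormatError(f"reference {name!r} has an empty sequence")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.entries)

    @property
    def sequences(self) -> tuple[str, ...]:
        return tuple(seq for _, seq in self.entries)

    @property
    def lengths(self) -> tuple[int, ...]:
        return tuple(len(seq) for _, seq in self.entries)

    def ordinal(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown reference: {name!r}") from None

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


@dataclass(frozen=True)
class Read:
    """A sequencing read; the quality string is carried but never scored."""

    id: str
    sequence: str
    quality: str | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise FormatError(f"read {self.id!r} has an empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise FormatError(
                f"read {self.id!r}: quality length {len(self.quality)} != "
                f"sequence length {len(self.sequence)}"
            )


@dataclass(frozen=True)
class MappingRecord:
    """Per-read mapping outcome: classification plus all best alignments."""

    read_id: str
    status: str  # unique | multi | unmapped
    alignments: tuple = ()
    reason: str | None = None  # set for some unmapped reads, e.g. "too_short"

    def __post_init__(self) -> None:
        if self.status not in ("unique", "multi", "unmapped"):
            raise ValueError(f"bad status {self.status!r}")
        if self.status == "unique" and len(self.alignments) != 1:
            raise ValueError("unique record must carry exactly one alignment")
        if self.status == "multi" and len(self.alignments) < 2:
            raise ValueError("multi record must carry at least two alignments")
        if self.status == "unmapped" and self.alignments:
            raise ValueError("unmapped record must carry no alignments")


def _open_text(path) -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path) -> ReferenceSet:
    """Load a (possibly gzipped) FASTA file into a :class:`ReferenceSet`.

    Multi-line sequences are concatenated, lowercase is uppercased, and any
    IUPAC ambiguity code other than N is replaced by N with a warning.
    Duplicate headers and empty files are errors.
    """
    entries: list[tuple[str, str]] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            name = rec.id
            if name in seen:
                raise FormatError(f"duplicate FASTA header: {name!r}")
            seen.add(name)
            seq = str(rec.seq).upper()
            bad = set(seq) - VALID_BASES
            if bad:
                if not bad <= _AMBIGUOUS:
                    raise FormatError(
                        f"reference {name!r} contains invalid characters: "
                        f"{sorted(bad)}"
                    )
                logger.warning(
                    "reference %s: replacing ambiguity codes %s with N",
                    name, sorted(bad),
                )
                seq = "".join(c if c in VALID_BASES else "N" for c in seq)
            entries.append((name, seq))
    if not entries:
        raise FormatError(f"no FASTA records in {path}")
    return ReferenceSet(tuple(entries))


def read_fastq(path) -> Iterator[Read]:
    """Stream reads from a (possibly gzipped) 4-line FASTQ file.

    Sequences are uppercased; characters outside {A,C,G,T,N} and
    sequence/quality length mismatches raise :class:`FormatError` with the
    record number.  An empty file yields an empty stream.
    """
    with _open_text(path) as handle:
        recno = 0
        try:
            for rid, seq, qual in FastqGeneralIterator(handle):
                recno += 1
                seq = seq.upper()
                if len(seq) != len(qual):
                    raise FormatError(
                        f"FASTQ record {recno} ({rid}): sequence/quality "
                        "length mismatch"
                    )
                if not set(seq) <= VALID_BASES:
                    raise FormatError(
                        f"FASTQ record {recno} ({rid}): invalid characters "
                        f"{sorted(set(seq) - VALID_BASES)}"
                    )
                yield Read(rid.split()[0], seq, qual)
        except ValueError as exc:  # Biopython signals truncation/mismatch
            if isinstance(exc, FormatError):
                raise
            raise FormatError(
                f"malformed FASTQ near record {recno + 1}: {exc}"
            ) from exc


def write_fasta(refs: ReferenceSet, path, width: int = 70) -> None:
    with open(path, "w") as out:
        for name, seq in refs:
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i:i + width] + "\n")


def write_fastq(reads: Iterable[Read], path) -> None:
    with open(path, "w") as out:
        for r in reads:
            qual = r.quality if r.quality is not None else "I" * len(r.sequence)
            out.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# Native mapping TSV
# ---------------------------------------------------------------------------

def write_mapping_records(records: Iterable[MappingRecord], unique_path,
                          multi_path, unmapped_path,
                          refs: ReferenceSet) -> None:
    """Partition classified records into three output files.

    Uniquely mapped records go to ``unique_path``, multimapped records (one
    line per best location) to ``multi_path``, and unmapped read ids to
    ``unmapped_path``.  The alignment files are tab-separated with a header
    line; positions are 1-based.
    """
    with open(unique_path, "w") as uq, open(multi_path, "w") as mu, \
            open(unmapped_path, "w") as um:
        uq.write(NATIVE_HEADER + "\n")
        mu.write(NATIVE_HEADER + "\n")
        um.write("#read_id\treason\n")
        for rec in records:
            if rec.status == "unmapped":
                um.write(f"{rec.read_id}\t{rec.reason or '.'}\n")
                continue
            out = uq if rec.status == "unique" else mu
            for aln in rec.alignments:
                out.write(
                    f"{rec.read_id}\t{refs.names[aln.reference_ordinal]}\t"
                    f"{aln.ref_start + 1}\t{aln.strand}\t"
                    f"{aln.edit_distance}\t{aln.alignment_string}\n"
                )


def read_mapping_records(unique_path, multi_path, unmapped_path,
                         refs: ReferenceSet) -> list[MappingRecord]:
    """Parse the three native output files back into records (round-trip)."""
    from .mapper import alignment_from_transcript

    records: list[MappingRecord] = []
    for path, status in ((unique_path, "unique"), (multi_path, "multi")):
        grouped: dict[str, list] = {}
        order: list[str] = []
        for line in _iter_tsv(path):
            rid, ref, pos, strand, edits, align = line
            aln = alignment_from_transcript(
                refs.ordinal(ref), strand, int(pos) - 1, align)
            if aln.edit_distance != int(edits):
                raise FormatError(
                    f"{path}: edit distance column {edits} disagrees with "
                    f"transcript {align!r}"
                )
            if rid not in grouped:
                grouped[rid] = []
                order.append(rid)
            grouped[rid].append(aln)
        for rid in order:
            records.append(MappingRecord(rid, status, tuple(grouped[rid])))
    for line in _iter_tsv(unmapped_path):
        rid = line[0]
        reason = line[1] if len(line) > 1 and line[1] != "." else None
        records.append(MappingRecord(rid, "unmapped", (), reason))
    return records


def read_unique_records(unique_path, refs: ReferenceSet) -> list[MappingRecord]:
    """Parse only the uniquely-mapped file (the downstream-analysis input)."""
    from .mapper import alignment_from_transcript

    records = []
    for rid, ref, pos, strand, edits, align in _iter_tsv(unique_path):
        aln = alignment_from_transcript(
            refs.ordinal(ref), strand, int(pos) - 1, align)
        records.append(MappingRecord(rid, "unique", (aln,)))
    return records


def _iter_tsv(path):
    with _open_text(path) as handle:
        for raw in handle:
            raw = raw.rstrip("\n")
            if not raw or raw.startswith("#"):
                continue
            yield raw.split("\t")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(calls: Sequence, reference_set: ReferenceSet, path) -> None:
    """Write variant calls as minimal VCF 4.2.

    QUAL is -10*log10(p) capped at 999; INFO carries depth (DP), alt count
    (AC), alt fraction (AF), the event type and the informational genotype
    flag.  Calls must be sorted by (reference, position).
    """
    import math

    with open(path, "w") as out:
        out.write("##fileformat=VCFv4.2\n")
        out.write('##INFO=<ID=DP,Number=1,Type=Integer,'
                  'Description="Pileup depth at the site">\n')
        out.write('##INFO=<ID=AC,Number=1,Type=Integer,'
                  'Description="Alternate allele observation count">\n')
        out.write('##INFO=<ID=AF,Number=1,Type=Float,'
                  'Description="Alternate allele fraction">\n')
        out.write('##INFO=<ID=TYPE,Number=1,Type=String,'
                  'Description="snv, ins or del">\n')
        out.write('##INFO=<ID=GT,Number=1,Type=String,'
                  'Description="Informational het/hom flag">\n')
        for name, seq in reference_set:
            out.write(f"##contig=<ID={name},length={len(seq)}>\n")
        out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for call in calls:
            ref_len = reference_set.lengths[
                reference_set.ordinal(call.reference)]
            if call.position > ref_len:
                raise FormatError(
                    f"call at {call.reference}:{call.position} exceeds "
                    f"reference length {ref_len}"
                )
            if call.p_value <= 0:
                qual = 999.0
            else:
                qual = min(999.0, -10.0 * math.log10(call.p_value))
            info = (f"DP={call.depth};AC={call.alt_count};"
                    f"AF={call.alt_count / call.depth:.4f};"
                    f"TYPE={call.type};GT={call.genotype}")
            out.write(
                f"{call.reference}\t{call.position}\t.\t{call.ref_allele}\t"
                f"{call.alt_allele}\t{qual:g}\tPASS\t{info}\n"
            )


# ---------------------------------------------------------------------------
# SAM export (optional interoperability path)
# ---------------------------------------------------------------------------

def write_sam(records: Iterable[MappingRecord], refs: ReferenceSet,
              reads: dict[str, Read], path) -> None:
    """Export records as unpaired single-end SAM via pysam.

    The native TSV remains the primary output; SAM is provided for tools
    that expect it.  Multimapped locations beyond the first are flagged
    secondary; CIGARs use =/X/I/D operators and NM carries the edit
    distance.
    """
    import pysam

    from .mapper import reverse_complement, transcript_to_cigar

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": length}
               for name, length in zip(refs.names, refs.lengths)],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            read = reads[rec.read_id]
            if rec.status == "unmapped":
                seg = pysam.AlignedSegment(out.header)
                seg.query_name = rec.read_id
                seg.flag = 4
                seg.query_sequence = read.sequence
                if read.quality:
                    seg.query_qualities = pysam.qualitystring_to_array(
                        read.quality)
                out.write(seg)
                continue
            for i, aln in enumerate(rec.alignments):
                seg = pysam.AlignedSegment(out.header)
                seg.query_name = rec.read_id
                seg.flag = (16 if aln.strand == "-" else 0) | (
                    256 if i > 0 else 0)
                seg.reference_id = aln.reference_ordinal
                seg.reference_start = aln.ref_start
                seg.mapping_quality = 60 if rec.status == "unique" else 0
                seg.cigarstring = transcript_to_cigar(aln.alignment_string)
                seq = read.sequence
                qual = read.quality
                if aln.strand == "-":
                    seq = reverse_complement(seq)
                    qual = qual[::-1] if qual else None
                seg.query_sequence = seq
                if qual:
                    seg.query_qualities = pysam.qualitystring_to_array(qual)
                seg.set_tag("NM", aln.edit_distance)
                out.write(seg)


def write_json(obj, path) -> None:
    with open(path, "w") as out:
        json.dump(obj, out, indent=2, sort_keys=True)
        out.write("\n")
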