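"""RNA-seq quantification against a spliced-transcript reference.

Reads are mapped directly to transcript sequences (no spliced alignment),
and expression is summarised as RPKM over uniquely mapped reads:

    rpkm = 1e9 * unique_count / (total_mapped * transcript_length)

Multimapped reads are excluded from counting by default; an optional
uniform-split mode divides each multimapped read equally among its best
locations.  Robustness across error allowances is measured as the Pearson
correlation of log10(rpkm + pseudo) profiles.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import MappingRecord, ReferenceSet


def count_unique(mapping_records, refs: ReferenceSet,
                 split_multi: bool = False) -> dict[str, float]:
    """Per-transcript read counts from uniquely mapped records.

    Multimapped and unmapped records are excluded unless ``split_multi`` is
    set, in which case each multi record adds 1/k to each of its k best
    locations.
    """
    counts: dict[str, float] = {}
    for rec in mapping_records:
        if rec.status == "unique":
            name = refs.names[rec.alignments[0].reference_ordinal]
            counts[name] = counts.get(name, 0) + 1
        elif rec.status == "multi" and split_multi:
            share = 1.0 / len(rec.alignments)
            for aln in rec.alignments:
                name = refs.names[aln.reference_ordinal]
                counts[name] = counts.get(name, 0) + share
    return counts


def compute_rpkm(count: float, length_nt: int, total_mapped: int) -> float:
    """Reads per kilobase of transcript per million mapped reads."""
    if length_nt <= 0:
        raise ValueError("transcript length must be positive")
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    return 1e9 * count / (total_mapped * length_nt)


def expression_table(mapping_records, refs: ReferenceSet,
                     total_mapped: int | None = None,
                     split_multi: bool = False) -> pd.DataFrame:
    """Expression summary over every transcript in the reference.

    ``total_mapped`` defaults to the number of mapped (unique + multi)
    records, the denominator RPKM conventionally uses.
    """
    records = list(mapping_records)
    if total_mapped is None:
        total_mapped = sum(1 for r in records if r.status in ("unique",
                                                              "multi"))
    counts = count_unique(records, refs, split_multi=split_multi)
    rows = []
    for name, length in zip(refs.names, refs.lengths):
        c = counts.get(name, 0)
        rpkm = compute_rpkm(c, length, total_mapped) if total_mapped else 0.0
        rows.append((name, length, c, rpkm))
    return pd.DataFrame(rows, columns=["transcript_id", "length_nt",
                                       "unique_count", "rpkm"])


def quant_correlation(table_a: pd.DataFrame, table_b: pd.DataFrame,
                      transform: str = "log10",
                      pseudo: float = 0.01) -> tuple[float, int]:
    """Pearson correlation of two RPKM profiles over detected transcripts.

    Transcripts with a positive count in at least one table enter the
    correlation; values are log10(rpkm + pseudo) transformed by default.
    Returns (r, n_transcripts_used).
    """
    merged = table_a.merge(table_b, on="transcript_id",
                           suffixes=("_a", "_b"))
    detected = merged[(merged.unique_count_a > 0)
                      | (merged.unique_count_b > 0)]
    n = len(detected)
    if n < 3:
        raise ValueError(
            f"only {n} shared detected transcripts; need at least 3")
    x = detected.rpkm_a.to_numpy(dtype=float)
    y = detected.rpkm_b.to_numpy(dtype=float)
    if transform == "log10":
        x = np.log10(x + pseudo)
        y = np.log10(y + pseudo)
    elif transform is not None and transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    r, _ = stats.pearsonr(x, y)
    return float(r), n
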