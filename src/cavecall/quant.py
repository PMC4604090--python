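"""Unique-read counting and RPKM per contig per sample.

A read counts toward a contig only if it aligns uniquely: exactly one
non-secondary, non-supplementary alignment record for its query name in the
whole SAM. Reads flagged secondary/supplementary, or whose name appears in
more than one primary record, contribute nothing. RPKM follows the standard
definition

    rpkm = raw_count * 1e9 / (length_bp * total_mapped_reads_in_sample)

so that sum_i rpkm_i * length_i = 1e9 whenever total_mapped equals the sum
of raw counts.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd
import pysam

logger = logging.getLogger(__name__)


class QuantInputError(ValueError):
    pass


@dataclass
class QuantRecord:
    contig_id: str
    sample_id: str
    raw_count: int
    length_bp: int
    rpkm: float


def count_unique_reads(sam_path: str | Path) -> dict[str, int]:
    """Per-contig counts of uniquely aligned reads in one sample's SAM.

    Uniqueness is per query name: any secondary/supplementary record, or a
    name occurring in two or more primary records (same or different
    contig), disqualifies the read entirely.
    """
    per_name_contig: dict[str, str] = {}
    multimapped: set[str] = set()
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for read in sam:
            if read.is_unmapped:
                continue
            name = read.query_name
            if read.is_secondary or read.is_supplementary:
                multimapped.add(name)
                continue
            if name in per_name_contig:
                multimapped.add(name)
            else:
                per_name_contig[name] = read.reference_name
    counts: Counter[str] = Counter()
    for name, contig in per_name_contig.items():
        if name not in multimapped:
            counts[contig] += 1
    return dict(counts)


def compute_rpkm(counts: Mapping[str, Mapping[str, int]],
                 lengths: Mapping[str, int]) -> pd.DataFrame:
    """RPKM table from per-sample per-contig unique counts.

    ``counts`` maps sample_id -> {contig_id: raw_count}; ``lengths`` maps
    contig_id -> bp. Every contig in ``lengths`` gets a row per sample
    (zero-count contigs included, rpkm 0). A sample with zero mapped reads
    gets all-zero rpkm with a warning rather than a division error.

    Returns a DataFrame with columns contig, sample, raw_count, length_bp,
    rpkm.
    """
    rows = []
    for sample, per_contig in counts.items():
        missing = set(per_contig) - set(lengths)
        if missing:
            raise QuantInputError(
                f"sample {sample!r}: counted contigs missing from lengths: "
                f"{sorted(missing)[:5]}")
        total = sum(per_contig.values())
        if total == 0:
            logger.warning("sample %s has zero mapped reads; rpkm set to 0",
                           sample)
        for contig, length in lengths.items():
            if length <= 0:
                raise QuantInputError(f"contig {contig!r} has length {length}")
            raw = int(per_contig.get(contig, 0))
            rpkm = raw * 1e9 / (length * total) if total > 0 else 0.0
            rows.append((contig, sample, raw, length, rpkm))
    return pd.DataFrame(rows, columns=["contig", "sample", "raw_count",
                                       "length_bp", "rpkm"])


def quantify(samples: Mapping[str, str | Path],
             reference: Mapping[str, str]) -> pd.DataFrame:
    """Count unique reads per sample SAM and compute RPKM in one step."""
    counts = {role: count_unique_reads(path)
              for role, path in samples.items()}
    lengths = {cid: len(seq) for cid, seq in reference.items()}
    return compute_rpkm(counts, lengths)


def write_quant_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
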