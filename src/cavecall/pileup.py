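"""Per-position, per-sample base counts from SAM alignments.

The pileup is the substrate of the SNP screen: for every contig position it
tallies, per sample, how many aligned reads carry each of A/C/G/T. Reads are
counted through their M/=/X CIGAR operations only; insertions have no
reference column and deletions add no base; N bases are ignored. Reverse-
strand reads contribute reference-orientation bases (SAM stores SEQ that way
already). Coordinates are 0-based half-open throughout; the VCF writer is
the only place the 1-based convention appears.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pysam

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
# byte -> base index lookup (-1 for N/ambiguity codes)
_BASE_CODES = np.full(256, -1, dtype=np.int64)
for _b, _i in _BASE_INDEX.items():
    _BASE_CODES[ord(_b)] = _i

#: sample roles the SNP/ASE stages require
REQUIRED_ROLES = ("surface", "cave", "hybrid")


class PileupInputError(ValueError):
    """SAM/reference inconsistency (unknown contig, length mismatch)."""


@dataclass
class PileupColumn:
    """Base counts at one reference position, keyed by sample then base."""

    contig_id: str
    pos: int  # 0-based
    counts: dict[str, dict[str, int]]

    def depth(self, sample_id: str) -> int:
        return column_depth(self, sample_id)


class Pileup:
    """Dense per-contig count arrays: sample -> (contig_length, 4) int array.

    Dense storage is the right trade-off here: contigs are short (hundreds of
    bp) and every position is interrogated by the SNP screen.
    """

    def __init__(self, reference: Mapping[str, str], samples: list[str]):
        self.reference = dict(reference)
        self.samples = list(samples)
        self._counts: dict[str, dict[str, np.ndarray]] = {
            cid: {s: np.zeros((len(seq), 4), dtype=np.int32)
                  for s in self.samples}
            for cid, seq in self.reference.items()
        }

    def counts(self, contig_id: str, sample_id: str) -> np.ndarray:
        if sample_id not in self.samples:
            raise KeyError(f"unknown sample {sample_id!r}")
        return self._counts[contig_id][sample_id]

    def column(self, contig_id: str, pos: int) -> PileupColumn:
        if not 0 <= pos < len(self.reference[contig_id]):
            raise IndexError(f"position {pos} outside {contig_id}")
        counts = {
            s: {b: int(self._counts[contig_id][s][pos, i])
                for i, b in enumerate(BASES)}
            for s in self.samples
        }
        return PileupColumn(contig_id, pos, counts)

    def columns(self, min_depth: int = 1) -> Iterator[PileupColumn]:
        """Yield columns where any sample has depth >= min_depth."""
        for cid in self.reference:
            per_sample = self._counts[cid]
            covered = np.zeros(len(self.reference[cid]), dtype=bool)
            for s in self.samples:
                covered |= per_sample[s].sum(axis=1) >= min_depth
            for pos in np.flatnonzero(covered):
                yield self.column(cid, int(pos))

    def total_bases(self, sample_id: str) -> int:
        return int(sum(self._counts[cid][sample_id].sum()
                       for cid in self.reference))


def column_depth(col: PileupColumn, sample_id: str) -> int:
    """Total read depth of one sample at this column (0 if uncovered)."""
    if sample_id not in col.counts:
        raise KeyError(f"unknown sample {sample_id!r}")
    return sum(col.counts[sample_id].values())


def _check_header(sam: pysam.AlignmentFile, reference: Mapping[str, str],
                  path: str) -> None:
    for sq in sam.header.get("SQ", []):
        name, length = sq["SN"], sq["LN"]
        if name not in reference:
            raise PileupInputError(
                f"{path}: SAM contig {name!r} absent from reference")
        if length != len(reference[name]):
            raise PileupInputError(
                f"{path}: contig {name!r} length {length} != reference "
                f"{len(reference[name])}")


def _add_sam(pile: Pileup, sample_id: str, sam_path: str | Path,
             min_mapq: int = 0) -> int:
    """Accumulate one sample's alignments; returns reads counted."""
    n_used = 0
    with pysam.AlignmentFile(str(sam_path), "r",
                             check_sq=False) as sam:
        _check_header(sam, pile.reference, str(sam_path))
        for read in sam:
            if (read.is_unmapped or read.is_secondary
                    or read.is_supplementary):
                continue
            if read.mapping_quality < min_mapq:
                continue
            seq = read.query_sequence
            if seq is None:
                logger.warning("read %s has no sequence; skipped",
                               read.query_name)
                continue
            arr = pile._counts[read.reference_name][sample_id]
            cig = read.cigartuples
            if cig is None:
                logger.warning("read %s has no CIGAR; skipped",
                               read.query_name)
                continue
            if len(cig) == 1 and cig[0][0] in (0, 7, 8):
                # all-match CIGAR: vectorised accumulation
                base_idx = _BASE_CODES[np.frombuffer(seq.encode(),
                                                     dtype=np.uint8)]
                valid = base_idx >= 0
                rpos = read.reference_start + np.flatnonzero(valid)
                np.add.at(arr, (rpos, base_idx[valid]), 1)
            else:
                try:
                    pairs = read.get_aligned_pairs(matches_only=True)
                except (ValueError, SystemError) as exc:
                    logger.warning("read %s: malformed CIGAR (%s); skipped",
                                   read.query_name, exc)
                    continue
                for qpos, rpos in pairs:
                    idx = _BASE_INDEX.get(seq[qpos])
                    if idx is not None:  # N and ambiguity codes ignored
                        arr[rpos, idx] += 1
            n_used += 1
    return n_used


def build_pileup(samples: Mapping[str, str | Path],
                 reference: Mapping[str, str],
                 min_mapq: int = 0) -> Pileup:
    """Build the multi-sample pileup from per-role SAM paths.

    ``samples`` maps role (surface/cave/hybrid/embryo/...) to a SAM path.
    Secondary, supplementary and unmapped records are excluded; reads below
    ``min_mapq`` are dropped (default 0 = keep all mapped reads).
    """
    pile = Pileup(reference, list(samples))
    for role, path in samples.items():
        n = _add_sam(pile, role, path, min_mapq=min_mapq)
        logger.info("pileup: %s -> %d reads from %s", role, n, path)
    return pile


def write_pileup_tsv(pile: Pileup, path: str | Path,
                     min_depth: int = 1) -> None:
    """Columnar dump (contig, pos0, sample, A, C, G, T) of covered columns."""
    with open(path, "w") as fh:
        fh.write("contig\tpos0\tsample\tA\tC\tG\tT\n")
        for col in pile.columns(min_depth=min_depth):
            for s, counts in col.counts.items():
                if sum(counts.values()) >= min_depth:
                    fh.write(f"{col.contig_id}\t{col.pos}\t{s}\t"
                             + "\t".join(str(counts[b]) for b in BASES)
                             + "\n")


def read_reference_fasta(path: str | Path) -> dict[str, str]:
    """Load reference contigs as a plain id -> sequence dict."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}
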