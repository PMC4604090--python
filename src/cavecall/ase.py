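"""Allele-specific expression calling in the F1 hybrid.

An F1 hybrid carries one cave and one surface allele of every gene, so with
equal expression each diagnostic SNP should show ~50% of hybrid reads per
parental allele. A contig is called cis-biased only under a strict unanimity
rule: it must (i) be unique in the transcriptome (no redundant near-copy),
(ii) carry at least ``min_snps_per_contig_ase`` diagnostic SNPs, (iii) have
hybrid depth >= ``min_hybrid_depth_ase`` at every SNP used, and (iv) show
the same direction of bias at *every* SNP — cave-biased when every
cave-allele fraction is >= bias_high (default 0.70), surface-biased when
every fraction is <= bias_low (default 0.30). Anything else is unbiased
(mixed directions are annotated as discordant).

A pooled two-sided binomial test against the 50:50 null is attached to each
eligible call as a diagnostic; it is never used as a filter, because the
screen is a deterministic rule, not a hypothesis test.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .sim import revcomp
from .snp import DiagnosticSNP, PipelineThresholds

logger = logging.getLogger(__name__)

VERDICTS = ("cave_biased", "surface_biased", "unbiased", "ineligible")


@dataclass
class ContigAseCall:
    contig_id: str
    n_diag_snps: int
    per_snp: list[tuple[int, int, float | None]]  # (pos, hybrid_depth, cave_frac)
    verdict: str
    ineligibility_reasons: list[str] = field(default_factory=list)
    pooled_cave: int = 0
    pooled_surface: int = 0
    binomial_p: float | None = None
    discordant: bool = False


# ---------------------------------------------------------------------------
# transcriptome uniqueness (redundancy screen)
# ---------------------------------------------------------------------------

def _kmer_index(seqs: dict[str, str], k: int) -> dict[str, list[tuple[str, int]]]:
    index: dict[str, list[tuple[str, int]]] = defaultdict(list)
    for cid, seq in seqs.items():
        for i in range(len(seq) - k + 1):
            index[seq[i:i + k]].append((cid, i))
    return index


def _diagonal_has_match(a: str, b: str, diag: int, minlen: int,
                        identity: float) -> bool:
    """True if some ungapped window of exactly ``minlen`` bp on this
    diagonal (offset diag = pos_a - pos_b) reaches ``identity``."""
    lo_a = max(0, diag)
    hi_a = min(len(a), len(b) + diag)
    span = hi_a - lo_a
    if span < minlen:
        return False
    seg_a = np.frombuffer(a[lo_a:hi_a].encode(), dtype="S1")
    seg_b = np.frombuffer(b[lo_a - diag:hi_a - diag].encode(), dtype="S1")
    match = (seg_a == seg_b).astype(np.int32)
    window = np.convolve(match, np.ones(minlen, dtype=np.int32), "valid")
    return bool(window.max() >= int(np.ceil(identity * minlen)))


def pair_has_redundant_match(a: str, b: str, minlen: int = 100,
                             identity: float = 0.90, k: int = 11) -> bool:
    """Strand-aware redundancy test between two contigs.

    Two contigs are redundant when they share an ungapped window of exactly
    ``minlen`` bp at >= ``identity`` match fraction, on either strand.
    Candidate diagonals are seeded by shared k-mers and then scanned
    exhaustively with a sliding window. The default seed (k=11) can in
    principle miss a window whose mismatches recur more often than every k
    bp; at the 90%/100 bp operating point that requires a near-periodic
    mismatch pattern that does not arise from the divergence processes the
    screen targets (duplicates, near-duplicates, reverse-complement copies).
    """
    if min(len(a), len(b)) < minlen:
        return False
    for bb in (b, revcomp(b)):
        diags: set[int] = set()
        index = _kmer_index({"b": bb}, k)
        for i in range(len(a) - k + 1):
            for _, j in index.get(a[i:i + k], ()):
                diags.add(i - j)
        for diag in sorted(diags):
            if _diagonal_has_match(a, bb, diag, minlen, identity):
                return True
    return False


def uniqueness_filter(contigs: Mapping[str, str],
                      thresholds: PipelineThresholds | None = None,
                      ) -> set[str]:
    """Return the ids of contigs unique in the transcriptome.

    A contig is non-unique if any other contig shares an ungapped local
    match of >= ``uniqueness_minlen`` bp at >= ``uniqueness_identity``
    identity on either strand; both members of such a pair are excluded.
    """
    th = thresholds or PipelineThresholds()
    k = 11
    ids = list(contigs)
    order = {cid: i for i, cid in enumerate(ids)}
    # one global k-mer index over forward and reverse-complement sequences
    # yields candidate (pair, strand, diagonal) triples; each seeded
    # diagonal is then scanned exhaustively with the fixed-length window
    fwd_index = _kmer_index(dict(contigs), k)
    rc = {cid: revcomp(seq) for cid, seq in contigs.items()}
    candidate_diags: dict[tuple[str, str, str], set[int]] = defaultdict(set)
    for cid, seq in contigs.items():
        for i in range(len(seq) - k + 1):
            kmer = seq[i:i + k]
            for other, j in fwd_index.get(kmer, ()):
                if order[other] > order[cid]:
                    candidate_diags[(cid, other, "+")].add(i - j)
                # reverse-strand hits: a shared k-mer between cid and
                # revcomp(other) appears as a hit of revcomp(kmer) in other
            for other, j in fwd_index.get(revcomp(kmer), ()):
                if order[other] > order[cid]:
                    # position of the k-mer within revcomp(other)
                    j_rc = len(contigs[other]) - k - j
                    candidate_diags[(cid, other, "-")].add(i - j_rc)
    redundant: set[str] = set()
    for (a, b, strand), diags in candidate_diags.items():
        if a in redundant and b in redundant:
            continue
        sb = contigs[b] if strand == "+" else rc[b]
        for diag in sorted(diags):
            if _diagonal_has_match(contigs[a], sb, diag,
                                   th.uniqueness_minlen,
                                   th.uniqueness_identity):
                redundant.update((a, b))
                break
    unique = set(ids) - redundant
    logger.info("uniqueness: %d/%d contigs unique", len(unique), len(ids))
    return unique


# ---------------------------------------------------------------------------
# ASE verdicts
# ---------------------------------------------------------------------------

def call_ase(snps: Iterable[DiagnosticSNP], unique_ids: set[str],
             thresholds: PipelineThresholds | None = None,
             ) -> list[ContigAseCall]:
    """Per-contig ASE verdicts from diagnostic SNPs with hybrid counts.

    Operates on the stage-1 diagnostic set: a fully one-sided hybrid site
    (cave fraction 0 or 1) is the strongest possible bias signal and must
    stay in the denominator here even though the marker-oriented stage-2
    filter would discard it.
    """
    th = thresholds or PipelineThresholds()
    by_contig: dict[str, list[DiagnosticSNP]] = defaultdict(list)
    for s in snps:
        by_contig[s.contig_id].append(s)

    calls: list[ContigAseCall] = []
    for cid in sorted(by_contig):
        group = sorted(by_contig[cid], key=lambda s: s.pos)
        per_snp = [(s.pos, s.hybrid_parental_depth, s.hybrid_cave_fraction)
                   for s in group]
        call = ContigAseCall(cid, len(group), per_snp, "ineligible")
        reasons = []
        if cid not in unique_ids:
            reasons.append("non_unique_contig")
        if len(group) < th.min_snps_per_contig_ase:
            reasons.append("too_few_snps")
        if any(s.hybrid_parental_depth < th.min_hybrid_depth_ase
               for s in group):
            reasons.append("low_hybrid_depth")
        if reasons:
            call.ineligibility_reasons = reasons
            calls.append(call)
            continue

        fracs = [s.hybrid_cave_fraction for s in group]
        call.pooled_cave = sum(s.hybrid_cave_count for s in group)
        call.pooled_surface = sum(s.hybrid_surface_count for s in group)
        n = call.pooled_cave + call.pooled_surface
        call.binomial_p = float(stats.binomtest(call.pooled_cave, n,
                                                0.5).pvalue)
        if all(f >= th.bias_high for f in fracs):
            call.verdict = "cave_biased"
        elif all(f <= th.bias_low for f in fracs):
            call.verdict = "surface_biased"
        else:
            call.verdict = "unbiased"
            cave_leaning = any(f >= th.bias_high for f in fracs)
            surf_leaning = any(f <= th.bias_low for f in fracs)
            if cave_leaning and surf_leaning:
                call.discordant = True
                call.ineligibility_reasons = ["discordant_snps"]
        calls.append(call)
    n_biased = sum(c.verdict.endswith("_biased") for c in calls)
    logger.info("ase: %d contigs called, %d biased", len(calls), n_biased)
    return calls


def ase_report(calls: Iterable[ContigAseCall]) -> pd.DataFrame:
    """Tabular report, biased contigs first, then unbiased, then ineligible."""
    order = {"cave_biased": 0, "surface_biased": 0, "unbiased": 1,
             "ineligible": 2}
    rows = []
    for c in sorted(calls, key=lambda c: (order[c.verdict], c.contig_id)):
        fracs = ";".join("NA" if f is None else f"{f:.4g}"
                         for _, _, f in c.per_snp)
        depths = ";".join(str(d) for _, d, _ in c.per_snp)
        rows.append({
            "contig": c.contig_id,
            "verdict": c.verdict,
            "n_diag_snps": c.n_diag_snps,
            "per_snp_cave_fractions": fracs,
            "per_snp_hybrid_depths": depths,
            "pooled_cave": c.pooled_cave,
            "pooled_surface": c.pooled_surface,
            "binomial_p": "" if c.binomial_p is None else f"{c.binomial_p:.6g}",
            "reasons": ";".join(c.ineligibility_reasons),
        })
    return pd.DataFrame(rows, columns=["contig", "verdict", "n_diag_snps",
                                       "per_snp_cave_fractions",
                                       "per_snp_hybrid_depths",
                                       "pooled_cave", "pooled_surface",
                                       "binomial_p", "reasons"])


def write_ase_tsv(calls: Iterable[ContigAseCall], path: str | Path) -> None:
    ase_report(calls).to_csv(path, sep="\t", index=False)


def read_ase_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False)
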