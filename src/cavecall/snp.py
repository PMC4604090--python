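"""Morph-diagnostic SNP discovery.

Two-stage deterministic screen over the multi-sample pileup:

Stage 1 — a position is a diagnostic SNP when both morph samples have
adequate depth (>= ``min_morph_depth`` reads each, default 4, assessed per
site) and each morph's reads are unanimous for its own allele, the two
alleles differing (reciprocal fixation). With a single sequenced individual
per morph this is the strongest available evidence that the site
differentiates the populations.

Stage 2 — retain only hybrid-informative SNPs: the F1 hybrid (one allele
from each morph) must show at least one read of *each* parental allele,
i.e. neither 0% nor 100% of one allele. Sites where the hybrid is uncovered
are dropped. Hybrid reads carrying a third allele (sequencing error) are
excluded from the parental-allele denominator rather than disqualifying the
site.

This is a filter, not a statistical test: no likelihoods, no multiple-
testing machinery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

from .pileup import BASES, Pileup

logger = logging.getLogger(__name__)


@dataclass
class PipelineThresholds:
    """All numeric filter settings of the SNP/ASE pipeline.

    Defaults are the screen's published operating point: per-site morph
    depth >= 4, hybrid depth >= 6 per SNP used in an ASE call, >= 3
    diagnostic SNPs per contig, bias bands 0-30% / 70-100%, and the
    redundancy rule (>= 100 bp ungapped match at >= 90% identity) for the
    transcriptome-uniqueness screen.
    """

    min_morph_depth: int = 4
    min_hybrid_depth_ase: int = 6
    min_snps_per_contig_ase: int = 3
    bias_low: float = 0.30
    bias_high: float = 0.70
    uniqueness_identity: float = 0.90
    uniqueness_minlen: int = 100

    def __post_init__(self) -> None:
        if not 0 <= self.bias_low < 0.5 < self.bias_high <= 1:
            raise ValueError(
                f"bias bands must satisfy 0 <= bias_low < 0.5 < bias_high "
                f"<= 1, got {self.bias_low}/{self.bias_high}")
        if self.min_morph_depth < 1 or self.min_hybrid_depth_ase < 1:
            raise ValueError("depth thresholds must be >= 1")


@dataclass
class DiagnosticSNP:
    """A reciprocally fixed cave/surface difference at one position."""

    contig_id: str
    pos: int  # 0-based
    surface_allele: str
    cave_allele: str
    depth_surface: int
    depth_cave: int
    depth_hybrid: int = 0
    hybrid_surface_count: int = 0
    hybrid_cave_count: int = 0
    hybrid_informative: bool = False

    @property
    def hybrid_parental_depth(self) -> int:
        """Hybrid reads carrying either parental allele (third alleles
        excluded)."""
        return self.hybrid_surface_count + self.hybrid_cave_count

    @property
    def hybrid_cave_fraction(self) -> float | None:
        """Cave-allele fraction among hybrid parental-allele reads;
        None when the hybrid has no parental-allele coverage."""
        d = self.hybrid_parental_depth
        return self.hybrid_cave_count / d if d else None


def discover_diagnostic_snps(pile: Pileup,
                             thresholds: PipelineThresholds | None = None,
                             ) -> list[DiagnosticSNP]:
    """Stage-1 screen: reciprocally fixed sites at adequate morph depth.

    Emits a :class:`DiagnosticSNP` for every column where surface and cave
    each have >= ``min_morph_depth`` reads, each is unanimous for one base,
    and the two bases differ. Hybrid counts at the two parental alleles are
    recorded when a hybrid sample is present. A zero-SNP result is valid.
    """
    import numpy as np

    th = thresholds or PipelineThresholds()
    for role in ("surface", "cave"):
        if role not in pile.samples:
            raise ValueError(f"pileup lacks required sample {role!r}")
    has_hybrid = "hybrid" in pile.samples
    out: list[DiagnosticSNP] = []
    for cid in sorted(pile.reference):
        S = pile.counts(cid, "surface")
        C = pile.counts(cid, "cave")
        ds, dc = S.sum(axis=1), C.sum(axis=1)
        # reciprocal fixation: exactly one base observed per morph, and the
        # two unanimous bases differ
        s_allele_idx = S.argmax(axis=1)
        c_allele_idx = C.argmax(axis=1)
        ok = ((ds >= th.min_morph_depth) & (dc >= th.min_morph_depth)
              & ((S > 0).sum(axis=1) == 1) & ((C > 0).sum(axis=1) == 1)
              & (s_allele_idx != c_allele_idx))
        H = pile.counts(cid, "hybrid") if has_hybrid else None
        for pos in np.flatnonzero(ok):
            s_allele = BASES[s_allele_idx[pos]]
            c_allele = BASES[c_allele_idx[pos]]
            snp = DiagnosticSNP(cid, int(pos), s_allele, c_allele,
                                int(ds[pos]), int(dc[pos]))
            if H is not None:
                snp.depth_hybrid = int(H[pos].sum())
                snp.hybrid_surface_count = int(H[pos, s_allele_idx[pos]])
                snp.hybrid_cave_count = int(H[pos, c_allele_idx[pos]])
            out.append(snp)
    logger.info("stage 1: %d diagnostic SNPs in %d contigs", len(out),
                len({s.contig_id for s in out}))
    return out


def filter_hybrid_informative(snps: Iterable[DiagnosticSNP],
                              thresholds: PipelineThresholds | None = None,
                              ) -> list[DiagnosticSNP]:
    """Stage-2 screen: keep SNPs heterozygously expressed in the hybrid.

    A SNP survives iff the hybrid shows >= 1 read of each parental allele
    (not 0% and not 100% of either). Uncovered sites are dropped. Survivors
    are returned as new records with ``hybrid_informative`` set.
    """
    out = [replace(s, hybrid_informative=True) for s in snps
           if s.hybrid_surface_count >= 1 and s.hybrid_cave_count >= 1]
    logger.info("stage 2: %d hybrid-informative SNPs in %d contigs",
                len(out), len({s.contig_id for s in out}))
    return out


@dataclass
class SnpSummary:
    n_snps: int
    n_contigs: int
    mean_snps_per_contig: float
    note: str = ""


def summarize_snps(snps: Iterable[DiagnosticSNP]) -> SnpSummary:
    """Headline counts: SNPs, contigs carrying them, mean SNPs per contig."""
    snps = list(snps)
    contigs = {s.contig_id for s in snps}
    if not contigs:
        return SnpSummary(0, 0, 0.0, note="no SNPs; mean undefined")
    return SnpSummary(len(snps), len(contigs), len(snps) / len(contigs))


# ---------------------------------------------------------------------------
# VCF output
# ---------------------------------------------------------------------------

_VCF_INFO = (
    '##INFO=<ID=SA,Number=1,Type=String,Description="Surface allele">\n'
    '##INFO=<ID=CA,Number=1,Type=String,Description="Cave allele">\n'
    '##INFO=<ID=DPS,Number=1,Type=Integer,Description="Surface depth">\n'
    '##INFO=<ID=DPC,Number=1,Type=Integer,Description="Cave depth">\n'
    '##INFO=<ID=DPH,Number=1,Type=Integer,Description="Hybrid depth">\n'
    '##INFO=<ID=HSC,Number=1,Type=Integer,Description='
    '"Hybrid surface-allele count">\n'
    '##INFO=<ID=HCC,Number=1,Type=Integer,Description='
    '"Hybrid cave-allele count">\n'
    '##INFO=<ID=HCF,Number=1,Type=Float,Description='
    '"Hybrid cave-allele fraction (parental denominator)">\n'
    '##INFO=<ID=HINF,Number=0,Type=Flag,Description='
    '"Hybrid-informative (stage-2 survivor)">\n'
)


def write_vcf(snps: Iterable[DiagnosticSNP], reference: Mapping[str, str],
              path: str | Path) -> None:
    """Write diagnostic SNPs as VCFv4.2 (positions converted to 1-based).

    REF is the reference base; ALT lists whichever parental alleles differ
    from it (both, comma-separated, when neither matches the reference —
    logged, since it means the assembly consensus sided with neither morph).
    """
    snps = sorted(snps, key=lambda s: (s.contig_id, s.pos))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=cavecall\n")
        for cid, seq in reference.items():
            fh.write(f"##contig=<ID={cid},length={len(seq)}>\n")
        fh.write(_VCF_INFO)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in snps:
            ref_base = reference[s.contig_id][s.pos]
            alts = [a for a in (s.surface_allele, s.cave_allele)
                    if a != ref_base]
            if len(alts) == 2:
                logger.info("SNP %s:%d: both parental alleles differ from "
                            "reference base %s", s.contig_id, s.pos, ref_base)
            info = [f"SA={s.surface_allele}", f"CA={s.cave_allele}",
                    f"DPS={s.depth_surface}", f"DPC={s.depth_cave}",
                    f"DPH={s.depth_hybrid}",
                    f"HSC={s.hybrid_surface_count}",
                    f"HCC={s.hybrid_cave_count}"]
            frac = s.hybrid_cave_fraction
            if frac is not None:
                info.append(f"HCF={frac:.6g}")
            if s.hybrid_informative:
                info.append("HINF")
            fh.write(f"{s.contig_id}\t{s.pos + 1}\t.\t{ref_base}\t"
                     f"{','.join(alts) or '.'}\t.\tPASS\t{';'.join(info)}\n")


def read_vcf(path: str | Path) -> list[DiagnosticSNP]:
    """Parse a cavecall VCF back into DiagnosticSNP records (round-trip)."""
    import pysam

    out: list[DiagnosticSNP] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = rec.info
            snp = DiagnosticSNP(
                contig_id=rec.chrom,
                pos=rec.pos - 1,
                surface_allele=info["SA"],
                cave_allele=info["CA"],
                depth_surface=info["DPS"],
                depth_cave=info["DPC"],
                depth_hybrid=info["DPH"],
                hybrid_surface_count=info["HSC"],
                hybrid_cave_count=info["HCC"],
                hybrid_informative=bool(info.get("HINF", False)),
            )
            out.append(snp)
    return out


def write_summary_tsv(stage1: SnpSummary, stage2: SnpSummary,
                      path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("stage\tn_snps\tn_contigs\tmean_snps_per_contig\n")
        fh.write(f"diagnostic\t{stage1.n_snps}\t{stage1.n_contigs}\t"
                 f"{stage1.mean_snps_per_contig:.4g}\n")
        fh.write(f"hybrid_informative\t{stage2.n_snps}\t{stage2.n_contigs}\t"
                 f"{stage2.mean_snps_per_contig:.4g}\n")
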