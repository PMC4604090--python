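"""Synthetic cave/surface transcriptome simulator.

Generates a reference contig set, per-morph haplotypes carrying known fixed
differences, an F1 hybrid with per-contig cis-regulatory expression bias, and
454-style single-end reads with substitution errors — together with complete
machine-readable truth tables, so every downstream stage (pileup, SNP
discovery, ASE calling, quantification) can be verified against known ground
truth at desk scale.

Design choices (documented in docs/methods.md):

* substitution-only error model — no homopolymer indels — because the
  downstream analysis is substitution (SNP) based;
* reads are emitted with their *true* alignments (SAM, all-match CIGAR);
  read mapping is not the object of study;
* per-morph polymorphic sites model a heterozygous individual: reads of
  that morph draw the alternative allele with probability 0.5;
* the F1 hybrid carries exactly one surface and one cave haplotype per
  contig, with per-read parental origin Bernoulli(cave expression fraction).

Default calibration: contig lengths 21–3490 bp with mean ~500 bp, mean read
depth ~7x — the descriptive statistics of the assembly the pipeline targets.
"""

from __future__ import annotations

import dataclasses
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pysam
import yaml

SAMPLES = ("surface", "cave", "hybrid", "embryo")
_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# stable per-stage RNG stream offsets so each stage is independently
# reproducible under a single user seed
_STAGE_SALT = {"reference": 11, "haplotypes": 23, "reads": 37}
_SAMPLE_SALT = {s: i + 1 for i, s in enumerate(SAMPLES)}


class SimConfigError(ValueError):
    """Raised when a simulation parameter is out of its valid range."""


@dataclass
class SimConfig:
    """Parameters of the synthetic transcriptome experiment.

    Rates are per-bp probabilities; lengths in bp; ``depth_mean`` is the mean
    per-sample read depth per contig; ``bias_ratio`` is the expected
    cave-allele expression fraction in the hybrid for cis-biased contigs.
    """

    n_contigs: int = 200
    length_mean_bp: float = 500.0
    length_min_bp: int = 21
    length_max_bp: int = 3490
    fixed_snp_rate: float = 0.005
    shared_poly_rate: float = 0.001
    depth_mean: float = 7.0
    read_length_mean_bp: float = 350.0
    error_rate: float = 0.0
    biased_fraction: float = 0.1
    bias_ratio: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        for name in ("fixed_snp_rate", "shared_poly_rate", "error_rate",
                     "biased_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimConfigError(f"{name} must be in [0, 1], got {v}")
        if self.n_contigs < 1:
            raise SimConfigError(f"n_contigs must be >= 1, got {self.n_contigs}")
        if not (0 < self.length_min_bp <= self.length_mean_bp
                <= self.length_max_bp):
            raise SimConfigError(
                "lengths must satisfy 0 < length_min_bp <= length_mean_bp <= "
                f"length_max_bp, got {self.length_min_bp}/"
                f"{self.length_mean_bp}/{self.length_max_bp}")
        if self.depth_mean <= 0:
            raise SimConfigError(f"depth_mean must be > 0, got {self.depth_mean}")
        if self.read_length_mean_bp <= 0:
            raise SimConfigError("read_length_mean_bp must be > 0, got "
                                 f"{self.read_length_mean_bp}")
        if self.biased_fraction > 0 and not 0.5 < self.bias_ratio <= 1.0:
            raise SimConfigError(
                f"bias_ratio must be in (0.5, 1] for biased contigs, got "
                f"{self.bias_ratio}")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class ReadRecord:
    """Provenance of one simulated read (appended to the truth tables)."""

    read_id: str
    sample: str
    contig: str
    start: int
    length: int
    reverse: bool
    haplotype: str  # 'surface' | 'cave'
    n_errors: int


@dataclass
class SimTruth:
    """Complete ground truth of one simulated experiment."""

    config: SimConfig
    reference: dict[str, str]
    surface_hap: dict[str, str]
    cave_hap: dict[str, str]
    # contig -> list of (pos0, surface_allele, cave_allele)
    fixed_snps: dict[str, list[tuple[int, str, str]]]
    # contig -> list of (pos0, morph, alt_allele): morph individual is het
    poly_sites: dict[str, list[tuple[int, str, str]]]
    # contig -> expected cave-allele expression fraction in the hybrid
    cave_fraction: dict[str, float]
    reads: list[ReadRecord] = field(default_factory=list)

    def biased_contigs(self) -> set[str]:
        return {c for c, f in self.cave_fraction.items() if f != 0.5}


def _rng(seed: int, *salts: int) -> np.random.Generator:
    return np.random.default_rng([seed, *salts])


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# reference + haplotypes
# ---------------------------------------------------------------------------

def _draw_lengths(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Contig lengths: lognormal with the configured mean, clipped to range.

    Degenerate case length_min == length_max pins every contig to that length.
    """
    if cfg.length_min_bp == cfg.length_max_bp:
        return np.full(cfg.n_contigs, cfg.length_min_bp, dtype=int)
    sigma = 0.7  # skew comparable to a short-read transcriptome assembly
    mu = math.log(cfg.length_mean_bp) - sigma ** 2 / 2
    lengths = rng.lognormal(mu, sigma, size=cfg.n_contigs)
    return np.clip(np.round(lengths), cfg.length_min_bp,
                   cfg.length_max_bp).astype(int)


def simulate_reference(cfg: SimConfig) -> dict[str, str]:
    """Generate ``cfg.n_contigs`` random contigs over {A,C,G,T}.

    Deterministic given ``cfg.seed``; contig ids are ``contig_00000``...
    """
    cfg.validate()
    rng = _rng(cfg.seed, _STAGE_SALT["reference"])
    lengths = _draw_lengths(cfg, rng)
    width = max(5, len(str(cfg.n_contigs)))
    contigs: dict[str, str] = {}
    for i, L in enumerate(lengths):
        seq = rng.choice(_BASES, size=int(L)).tobytes().decode()
        contigs[f"contig_{i:0{width}d}"] = seq
    return contigs


def simulate_haplotypes(contigs: dict[str, str], cfg: SimConfig) -> SimTruth:
    """Place fixed cave/surface differences and within-morph polymorphisms.

    Fixed differences are Bernoulli(``fixed_snp_rate``) per position with the
    cave allele drawn uniformly from the three non-reference bases (surface
    keeps the reference base). Within-morph polymorphic sites are
    Bernoulli(``shared_poly_rate``) per position, each assigned to one morph
    which is heterozygous reference/alt there. cis-biased contigs are the
    first ``ceil(biased_fraction * n)`` under a seeded shuffle of contig ids.
    """
    cfg.validate()
    if not contigs:
        raise SimConfigError("contigs must be nonempty")
    rng = _rng(cfg.seed, _STAGE_SALT["haplotypes"])

    truth = SimTruth(config=cfg, reference=dict(contigs), surface_hap={},
                     cave_hap={}, fixed_snps={}, poly_sites={},
                     cave_fraction={})
    for cid, seq in contigs.items():
        L = len(seq)
        arr = np.frombuffer(seq.encode(), dtype="S1")
        fixed_pos = np.flatnonzero(rng.random(L) < cfg.fixed_snp_rate)
        cave = arr.copy()
        snps: list[tuple[int, str, str]] = []
        for p in fixed_pos:
            ref = arr[p].decode()
            alts = [b for b in "ACGT" if b != ref]
            alt = alts[rng.integers(3)]
            cave[p] = alt.encode()
            snps.append((int(p), ref, alt))
        poly_mask = rng.random(L) < cfg.shared_poly_rate
        poly_mask[fixed_pos] = False  # diagnostic sites stay diagnostic
        polys: list[tuple[int, str, str]] = []
        for p in np.flatnonzero(poly_mask):
            morph = "surface" if rng.random() < 0.5 else "cave"
            base = (arr if morph == "surface" else cave)[p].decode()
            alts = [b for b in "ACGT" if b != base]
            polys.append((int(p), morph, alts[rng.integers(3)]))
        truth.surface_hap[cid] = seq
        truth.cave_hap[cid] = cave.tobytes().decode()
        truth.fixed_snps[cid] = snps
        truth.poly_sites[cid] = polys
        truth.cave_fraction[cid] = 0.5

    ids = list(contigs)
    rng.shuffle(ids)
    n_biased = math.ceil(cfg.biased_fraction * len(ids))
    for cid in ids[:n_biased]:
        truth.cave_fraction[cid] = cfg.bias_ratio
    return truth


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def simulate_reads(truth: SimTruth, sample_id: str,
                   cfg: SimConfig | None = None,
                   depth_mean: float | None = None,
                   ) -> list[ReadRecord]:
    """Simulate 454-style reads for one sample and append them to the truth.

    Per contig the read count is Poisson(depth_mean * L / read_length_mean).
    Surface/embryo reads come from the surface haplotype, cave reads from the
    cave haplotype; hybrid reads pick the cave haplotype with the contig's
    true cave expression fraction. Each read may be reverse-complemented with
    probability 0.5 and carries iid substitution errors at ``error_rate``.

    Returns the records for this sample; sequences are materialised by
    :func:`read_sequence` and written by :func:`write_reads_fasta` /
    :func:`write_sam`.
    """
    if sample_id not in SAMPLES:
        raise ValueError(f"unknown sample_id {sample_id!r}; expected one of "
                         f"{SAMPLES}")
    cfg = cfg or truth.config
    depth = depth_mean if depth_mean is not None else cfg.depth_mean
    rng = _rng(cfg.seed, _STAGE_SALT["reads"], _SAMPLE_SALT[sample_id])
    records: list[ReadRecord] = []
    for cid, ref in truth.reference.items():
        L = len(ref)
        # reads on contigs shorter than the read length are truncated to the
        # contig, so the coverage target uses the effective read length
        eff_len = min(cfg.read_length_mean_bp, L)
        n_reads = int(rng.poisson(depth * L / eff_len))
        cave_frac = truth.cave_fraction[cid]
        for j in range(n_reads):
            rl = int(np.clip(round(rng.normal(cfg.read_length_mean_bp,
                                              0.15 * cfg.read_length_mean_bp)),
                             30, L))
            start = int(rng.integers(0, L - rl + 1))
            if sample_id == "hybrid":
                hap = "cave" if rng.random() < cave_frac else "surface"
            elif sample_id == "cave":
                hap = "cave"
            else:  # surface, embryo (surface pool)
                hap = "surface"
            reverse = bool(rng.random() < 0.5)
            # errors decided here so provenance is complete; positions drawn
            # lazily in read_sequence from a read-specific stream
            n_errors = int(rng.binomial(rl, cfg.error_rate))
            rid = f"{sample_id}_{cid}_{len(records):06d}"
            records.append(ReadRecord(rid, sample_id, cid, start, rl,
                                      reverse, hap, n_errors))
    truth.reads.extend(records)
    return records


def _haplotype_read(truth: SimTruth, rec: ReadRecord,
                    rng: np.random.Generator) -> str:
    """Forward-orientation read bases drawn from the source haplotype,
    resolving heterozygous (polymorphic) sites of the source morph."""
    hap = (truth.cave_hap if rec.haplotype == "cave"
           else truth.surface_hap)[rec.contig]
    seq = list(hap[rec.start:rec.start + rec.length])
    for pos, morph, alt in truth.poly_sites[rec.contig]:
        if morph == rec.haplotype and rec.start <= pos < rec.start + rec.length:
            if rng.random() < 0.5:
                seq[pos - rec.start] = alt
    return "".join(seq)


def read_sequence(truth: SimTruth, rec: ReadRecord) -> str:
    """Materialise the read's base string (reference-forward orientation),
    applying its substitution errors. Deterministic per read id."""
    rng = _rng(truth.config.seed, _STAGE_SALT["reads"],
               zlib.crc32(rec.read_id.encode()))
    seq = list(_haplotype_read(truth, rec, rng))
    if rec.n_errors:
        for p in rng.choice(rec.length, size=rec.n_errors, replace=False):
            alts = [b for b in "ACGT" if b != seq[p]]
            seq[p] = alts[rng.integers(3)]
    return "".join(seq)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_reference_fasta(contigs: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for cid, seq in contigs.items():
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def write_reads_fasta(truth: SimTruth, records: Iterable[ReadRecord],
                      path: str | Path) -> None:
    """Reads in sequencing orientation (reverse reads reverse-complemented)."""
    with open(path, "w") as fh:
        for rec in records:
            seq = read_sequence(truth, rec)
            if rec.reverse:
                seq = revcomp(seq)
            fh.write(f">{rec.read_id}\n{seq}\n")


def write_sam(truth: SimTruth, records: Iterable[ReadRecord],
              path: str | Path) -> None:
    """True alignments as plain-text SAM with all-match CIGARs.

    SEQ is stored reference-forward (per the format), with flag 16 marking
    reads sequenced from the reverse strand.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": cid, "LN": len(seq)}
               for cid, seq in truth.reference.items()],
    }
    tid = {cid: i for i, cid in enumerate(truth.reference)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec.read_id
            a.flag = 16 if rec.reverse else 0
            a.reference_id = tid[rec.contig]
            a.reference_start = rec.start
            a.mapping_quality = 60
            a.cigarstring = f"{rec.length}M"
            a.query_sequence = read_sequence(truth, rec)
            out.write(a)


def write_truth_tables(truth: SimTruth, outdir: str | Path) -> dict[str, Path]:
    """Write truth_snps.tsv, truth_bias.tsv and truth_reads.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    p = outdir / "truth_snps.tsv"
    with open(p, "w") as fh:
        fh.write("contig\tpos0\tsurface_allele\tcave_allele\n")
        for cid, snps in truth.fixed_snps.items():
            for pos, s, c in snps:
                fh.write(f"{cid}\t{pos}\t{s}\t{c}\n")
    paths["snps"] = p
    p = outdir / "truth_bias.tsv"
    with open(p, "w") as fh:
        fh.write("contig\tcave_fraction\tbiased\n")
        for cid, f in truth.cave_fraction.items():
            fh.write(f"{cid}\t{f}\t{int(f != 0.5)}\n")
    paths["bias"] = p
    p = outdir / "truth_reads.tsv"
    with open(p, "w") as fh:
        fh.write("read_id\tsample\tcontig\tstart\tlength\treverse\t"
                 "haplotype\tn_errors\n")
        for r in truth.reads:
            fh.write(f"{r.read_id}\t{r.sample}\t{r.contig}\t{r.start}\t"
                     f"{r.length}\t{int(r.reverse)}\t{r.haplotype}\t"
                     f"{r.n_errors}\n")
    paths["reads"] = p
    return paths


def simulate_experiment(cfg: SimConfig, outdir: str | Path,
                        samples: Iterable[str] = ("surface", "cave", "hybrid",
                                                  "embryo"),
                        ) -> tuple[SimTruth, dict[str, Path]]:
    """Full generator run: reference, haplotypes, reads and all files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    contigs = simulate_reference(cfg)
    truth = simulate_haplotypes(contigs, cfg)
    paths: dict[str, Path] = {"reference": outdir / "reference.fasta"}
    write_reference_fasta(contigs, paths["reference"])
    for s in samples:
        recs = simulate_reads(truth, s, cfg)
        paths[f"{s}_sam"] = outdir / f"{s}.sam"
        write_sam(truth, recs, paths[f"{s}_sam"])
        paths[f"{s}_fasta"] = outdir / f"{s}.reads.fasta"
        write_reads_fasta(truth, recs, paths[f"{s}_fasta"])
    paths.update(write_truth_tables(truth, outdir))
    cfg.to_yaml(outdir / "sim_config.yaml")
    paths["config"] = outdir / "sim_config.yaml"
    return truth, paths
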