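"""Shared fixtures and independent brute-force oracles.

The oracles here re-derive each rule from first principles (naive scans over
raw base calls, all-offsets window searches, threshold enumeration) and are
deliberately kept independent of the package's implementation paths.
"""

from __future__ import annotations

import numpy as np
import pytest

from cavecall.pileup import BASES, Pileup
from cavecall.sim import SimConfig, revcomp, simulate_experiment


# ---------------------------------------------------------------------------
# pileup construction helpers
# ---------------------------------------------------------------------------

def make_pileup(columns, contig_lengths=None,
                samples=("surface", "cave", "hybrid")):
    """Build a Pileup directly from {(contig, pos): {sample: {base: n}}}.

    Bypasses SAM parsing so filter rules can be unit-tested on exact counts.
    """
    if contig_lengths is None:
        contig_lengths = {}
        for (cid, pos) in columns:
            contig_lengths[cid] = max(contig_lengths.get(cid, 0), pos + 1)
    reference = {cid: "A" * L for cid, L in contig_lengths.items()}
    pile = Pileup(reference, list(samples))
    for (cid, pos), per_sample in columns.items():
        for sample, base_counts in per_sample.items():
            for base, n in base_counts.items():
                pile.counts(cid, sample)[pos, BASES.index(base)] += n
    return pile


def write_sam(path, reference, records):
    """Write a minimal SAM: records are (name, flag, contig, pos0, cigar,
    seq) tuples, seq in reference-forward orientation."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for cid, seq in reference.items():
            fh.write(f"@SQ\tSN:{cid}\tLN:{len(seq)}\n")
        for name, flag, contig, pos0, cigar, seq in records:
            fh.write(f"{name}\t{flag}\t{contig}\t{pos0 + 1}\t60\t{cigar}"
                     f"\t*\t0\t0\t{seq}\t*\n")
    return path


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def oracle_diagnostic_sites(base_calls, min_depth=4):
    """Naive SNP screen over raw per-read base calls.

    ``base_calls`` maps (contig, pos) -> {sample: list of bases}. Returns
    the set of (contig, pos, surface_allele, cave_allele) satisfying the
    reciprocal-fixation rule at >= min_depth reads per morph.
    """
    out = set()
    for (cid, pos), per_sample in base_calls.items():
        surf = [b for b in per_sample.get("surface", []) if b in BASES]
        cave = [b for b in per_sample.get("cave", []) if b in BASES]
        if len(surf) < min_depth or len(cave) < min_depth:
            continue
        if len(set(surf)) == 1 and len(set(cave)) == 1 \
                and surf[0] != cave[0]:
            out.add((cid, pos, surf[0], cave[0]))
    return out


def oracle_ase_verdict(fracs, depths, n_min=3, d_min=6, lo=0.30, hi=0.70,
                       unique=True):
    """Naive per-contig ASE rule: eligibility then unanimity of direction."""
    if not unique:
        return "ineligible"
    if len(fracs) < n_min or any(d < d_min for d in depths):
        return "ineligible"
    if all(f >= hi for f in fracs):
        return "cave_biased"
    if all(f <= lo for f in fracs):
        return "surface_biased"
    return "unbiased"


def oracle_redundant_pair(a, b, minlen=100, identity=0.90):
    """All-offsets, all-windows ungapped scan (both strands)."""
    need = int(np.ceil(identity * minlen))
    for bb in (b, revcomp(b)):
        for diag in range(-(len(bb) - minlen), len(a) - minlen + 1):
            lo_a = max(0, diag)
            hi_a = min(len(a), len(bb) + diag)
            if hi_a - lo_a < minlen:
                continue
            matches = [a[i] == bb[i - diag] for i in range(lo_a, hi_a)]
            for start in range(len(matches) - minlen + 1):
                if sum(matches[start:start + minlen]) >= need:
                    return True
    return False


def oracle_n50(lengths):
    """Largest L with sum(lengths >= L) >= total/2, by direct enumeration."""
    total = sum(lengths)
    return max(L for L in lengths
               if sum(x for x in lengths if x >= L) >= total / 2)


# ---------------------------------------------------------------------------
# simulated experiments (session-scoped: deterministic, reused across tests)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def clean_sim(tmp_path_factory):
    """Error-free, polymorphism-free simulation: 120 contigs at 10x."""
    cfg = SimConfig(n_contigs=120, fixed_snp_rate=0.005, shared_poly_rate=0.0,
                    depth_mean=10.0, error_rate=0.0, biased_fraction=0.1,
                    bias_ratio=0.8, seed=11)
    outdir = tmp_path_factory.mktemp("clean_sim")
    truth, paths = simulate_experiment(
        cfg, outdir, samples=("surface", "cave", "hybrid"))
    return cfg, truth, paths
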