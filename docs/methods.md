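# Methods

This note documents the models, rules and numerical choices behind
`cavecall`, the assumptions of the synthetic-data generator, and the known
limits of what the benchmarks demonstrate.

## Study design being modelled

Four non-normalised cDNA samples sequenced on a 454-style platform: a
surface-morph head, a cave-morph head, an F1 hybrid head (surface × cave)
and a pooled surface embryo/hatchling sample. Reads are aligned to a
reference transcriptome of de-novo contigs; all inference happens on the
resulting per-position base counts. One individual per morph means
"fixation" is fixation *in the sampled reads*, and the package accordingly
treats stage-1 SNPs as candidate markers, not population-validated ones.

## The filters

**Stage 1 — reciprocal fixation.** A column is a diagnostic SNP iff both
morph samples have ≥ `min_morph_depth` (default 4) reads *at that site*,
each morph's reads are unanimous for one base, and the bases differ. The
depth rule is applied per site, not per contig: fixation is a per-site
statement, and a contig-level reading would let 1× columns be called fixed.
The screen is a deterministic filter; no genotype likelihoods and no
multiple-testing machinery are involved.

**Stage 2 — hybrid informativeness.** An F1 hybrid must carry one allele
of each parent, so a usable marker should show both parental alleles in
the hybrid's reads (neither 0% nor 100%). SNPs with no hybrid coverage are
dropped. Hybrid reads carrying a third allele are treated as sequencing
error and excluded from the parental denominator rather than disqualifying
the site. The minimum evidence adopted is one read per parental allele.

**ASE verdicts.** Per contig, eligibility requires: uniqueness in the
transcriptome, ≥ `min_snps_per_contig_ase` (3) diagnostic SNPs, and hybrid
parental depth ≥ `min_hybrid_depth_ase` (6) at *every* SNP used (per-SNP,
the stricter reading: a 0.70 fraction at depth < 6 cannot exclude a
single-read artifact). The verdict is unanimous-direction: cave-biased iff
every per-SNP cave fraction ≥ `bias_high` (0.70), surface-biased iff every
fraction ≤ `bias_low` (0.30), otherwise unbiased; mixed-direction contigs
are annotated `discordant_snps`. Where more than 3 SNPs are present, all
of them must agree (interpretation of the "all SNPs present" rule). The
ASE caller consumes the *stage-1* SNP set: a hybrid fraction of 0 or 1 is
the strongest possible bias signal and belongs in the ASE denominator even
though the marker-oriented stage-2 filter discards it. A pooled two-sided
binomial test against 0.5 is attached as a diagnostic only — the published
screen used fixed bands, not a test, so no p-value thresholding is done.

**Uniqueness.** "Unique in the transcriptome" is operationalised as: no
other contig shares an ungapped window of exactly `uniqueness_minlen`
(100) bp at ≥ `uniqueness_identity` (0.90) match fraction, on either
strand; both members of a redundant pair are excluded. Implementation:
one global 11-mer index seeds candidate (pair, strand, diagonal) triples;
each seeded diagonal is scanned exhaustively with a fixed-length sliding
window. An 11-mer seed can in principle miss a window whose mismatches
recur more often than every 11 bp; such near-periodic divergence does not
arise from the duplication processes the screen targets, and the
test-suite checks agreement with an all-offsets brute-force scan.

**Quantification.** A read counts toward a contig iff its query name has
exactly one non-secondary, non-supplementary alignment in the sample's
SAM; any secondary record or repeated name disqualifies it (the strictest
defensible reading of "uniquely aligned"). RPKM = count · 10⁹ /
(length_bp · total mapped in sample); a sample with zero mapped reads gets
RPKM 0 with a warning. The identity Σ RPKM·length = 10⁹ holds by
construction when the total equals the sum of counts, and is asserted in
the tests. No cross-sample differential expression is attempted — single
individuals per morph cannot support it.

**Linkage placement.** Backcross genotypes take two codes, A
(homozygous-like) and H (heterozygous). Concordance between a candidate
and each mapped marker is counted over individuals non-missing in both;
because raw SNP alleles carry no canonical phase against the map's allele
coding, both orientations (as-is and A↔H swapped) are evaluated and the
orientation with fewer mismatches is reported. Zero-mismatch markers place
the candidate; failing that, markers with ≤ `max_mismatch` (1) recombinant
are used; if the selected markers span several linkage groups the
candidate is left unplaced with an ambiguity flag (ties across groups are
surfaced, never silently resolved). Map cM positions are carried for
reporting only; map construction is out of scope.

## The synthetic-data generator

The generator emulates the study conditions so that every stage can be
verified against machine-readable truth:

* **Contigs:** lognormal lengths (σ = 0.7) clipped to [21, 3490] bp with
  mean ≈ 500 bp, matching the target assembly's descriptive statistics;
  default mean depth 7×.
* **Haplotypes:** fixed cave/surface differences Bernoulli per bp
  (`fixed_snp_rate`, benchmark value 0.005 so that desk-scale contig sets
  carry a few SNPs per contig); the cave allele is drawn uniformly from
  the three non-reference bases. Within-morph polymorphic sites
  (`shared_poly_rate`, default 0.001 — a free parameter, the study does
  not report per-morph polymorphism) model a heterozygous individual:
  reads of that morph draw the alternative allele with probability 0.5.
  Polymorphic sites are never placed on fixed-difference positions.
* **Reads:** 454-like single-end reads, length ~ Normal(350, 0.15·350)
  truncated to [30 bp, contig length], uniform placement, strand flipped
  with probability 0.5, iid substitution errors at `error_rate`. Indel and
  homopolymer errors are *not* simulated: the downstream analysis is
  substitution-only, and a substitution error model keeps the pileup logic
  aligned with it. Reads are emitted with their true alignments
  (all-match CIGAR SAM); read mapping is out of scope and not the object
  of study. Reads on contigs shorter than the read length are truncated,
  and the per-contig read count uses the effective read length so mean
  column depth matches the configured depth.
* **Hybrid:** carries exactly one surface and one cave haplotype per
  contig; each hybrid read picks the cave haplotype with the contig's true
  cave expression fraction (0.5, or `bias_ratio` = 0.8 for the first
  ⌈`biased_fraction`·n⌉ contigs under a seeded shuffle).
* **Determinism:** every stage draws from `default_rng([seed, salt])`
  streams; per-read error positions come from a CRC32-keyed per-read
  stream, so FASTA/SAM/truth outputs are byte-identical across runs.

What the generator does **not** model: quality scores, paired ends, PCR
duplicates, homopolymer indels, reference/assembly error, mapping
ambiguity from real paralogy (redundant contigs must be planted
explicitly), and trans-acting or imprinting effects that could also skew
hybrid allele ratios. Benchmarks passing on this generator therefore
demonstrate correctness of the *filters and estimators*, not robustness
to alignment artifacts or biological confounders of ASE.

## Benchmark design and statistical notes

Problem sizes are chosen so the full suite runs in minutes on a laptop
while keeping the statistical checks well-powered.

* **Exact SNP recovery** (100 contigs, 10×, error-free, 20 seeds): the
  emitted stage-1 set must equal the truth fixed differences restricted to
  columns with both morph depths ≥ 4. Columns carrying a within-morph
  polymorphism are excluded from the comparison: a heterozygous site whose
  reads happen to sample only one allele is *by construction*
  indistinguishable from a fixed difference at the read level — this is a
  real limitation of single-individual screens, not an implementation
  artifact.
* **Hybrid-filter calibration:** at hybrid parental depth d the 0/100%
  rule removes a truth SNP with probability 2·(1/2)^d (all d reads one
  allele). Measured at d = 6 by conditioning on observed depth (the
  conditional removal probability is depth-exact, so no exact-coverage
  read placement is needed). One depth-6 SNP is taken per contig: SNPs on
  a contig share the hybrid reads covering them, so within-contig removals
  are correlated and only across-contig events are independent Bernoulli
  draws for the 3-SD binomial band.
* **ASE operating point:** the 0.70/0.30 bands with unanimity define, at
  per-SNP depth 30 with fully shared reads, a recovery of
  1 − P(Bin(30, 0.8) ≤ 20) ≈ 0.94 for truly 80:20 contigs and a
  false-bias rate of ≈ 0.04 for 50:50 contigs. The recovery benchmark
  therefore uses transcript-spanning hybrid reads (every SNP of a contig
  read by the same ~30 reads), which realises that model exactly through
  the full read → SAM → pileup → call path; measured: ~93% recovery, ~4%
  false bias, no direction reversals. **Limitation:** with sub-transcript
  fragment reads (e.g. 350 bp reads on contigs up to 3.5 kb), SNPs near
  contig ends see fewer, partially independent reads, and the all-SNP
  unanimity rule's sensitivity drops to ~84% under otherwise identical
  conditions — the rule trades sensitivity for direction reliability, and
  long multi-SNP contigs pay most of that cost.
* **Backcross simulator:** gametes recombine between adjacent loci with
  Haldane probability r = (1 − e^(−2d/100))/2 for d cM; genotypes are H
  where the hybrid parent transmitted the non-recurrent allele. A
  candidate inserted at a marker's exact position is recovered to the
  correct linkage group in ≥ 95/100 replicates (50 individuals, 8 groups ×
  10 markers at 10 cM).

## Numerical and I/O conventions

Coordinates are 0-based half-open everywhere except VCF output (1-based,
VCFv4.2); REF is the assembly base and ALT lists whichever parental
alleles differ from it (both, when the consensus sided with neither
morph — logged). Pileups exclude secondary/supplementary/unmapped records;
the mapping-quality floor defaults to 0 (the upstream screen's filters are
not documented, so defaults are package decisions, recorded here).
Insertions contribute no reference column and deletions no base; N bases
are ignored. Degenerate inputs are defined rather than fatal: empty SNP
sets are valid results, mean SNPs/contig over zero contigs reports 0 with
a note, zero-total RPKM is 0 with a warning, and an empty zero-mismatch
*and* one-recombinant marker set leaves a candidate unplaced. Assembly
N50 is the largest length L such that contigs ≥ L sum to at least half the
assembly (descending cumulative sum; brute-force checked).

The workflow embeds the effective configuration, input checksums and seed
in `manifest.json`; identical configuration and seed reproduce identical
stage outputs byte-for-byte (timestamps excluded).
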