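"""Candidate-gene placement on an existing linkage map by genotype
concordance.

In a backcross pedigree every individual falls into one of two genotype
classes per marker — homozygous-like ('A') or heterozygous ('H'). A new
candidate marker is genotyped on a subset of the pedigree and compared,
individual by individual, against every mapped marker. Markers in full
agreement (zero mismatches) place the candidate; if there are none, markers
with exactly one recombinant individual are used as a fallback. The
candidate is assigned the linkage group of the selected markers when they
agree on a single group, and flagged ambiguous otherwise.

Because raw SNP alleles carry no canonical phase against the map's allele
coding, each comparison is evaluated in both orientations (as-is and with
A/H swapped) and the orientation with fewer mismatches is reported.

A seeded backcross simulator (Haldane mapping function, r = (1 - e^(-2d/100))/2
for d in cM) provides the ground truth for testing placement recovery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = "-"
CODES = ("A", "H")
_SWAP = {"A": "H", "H": "A"}


class LinkmapInputError(ValueError):
    pass


@dataclass
class MarkerMap:
    """Marker metadata: linkage group and (optional, report-only) cM."""

    table: pd.DataFrame  # columns: marker, group, cM

    def __post_init__(self) -> None:
        required = {"marker", "group"}
        if not required <= set(self.table.columns):
            raise LinkmapInputError(
                f"marker map needs columns {sorted(required)}")
        if self.table["marker"].duplicated().any():
            raise LinkmapInputError("marker map has duplicate markers")

    def group_of(self, marker: str) -> str:
        row = self.table.loc[self.table["marker"] == marker]
        if row.empty:
            raise KeyError(f"marker {marker!r} not on map")
        return str(row["group"].iloc[0])


@dataclass
class GenotypeMatrix:
    """Individuals x markers genotype codes in {A, H, missing}."""

    genotypes: pd.DataFrame  # index: individuals, columns: markers
    marker_map: MarkerMap

    def __post_init__(self) -> None:
        bad = set(np.unique(self.genotypes.fillna(MISSING).values)) \
            - {*CODES, MISSING}
        if bad:
            raise LinkmapInputError(
                f"genotype codes outside {{A, H, {MISSING!r}}}: {sorted(bad)}")
        unmapped = set(self.genotypes.columns) \
            - set(self.marker_map.table["marker"])
        if unmapped:
            raise LinkmapInputError(
                f"genotyped markers missing from map: {sorted(unmapped)}")


@dataclass
class MarkerScore:
    marker: str
    shared: int  # individuals non-missing in both
    mismatches: int  # min over the two phase orientations
    flipped: bool  # True if the flipped orientation was the better one


@dataclass
class PlacementResult:
    candidate_id: str
    n_genotyped: int
    scores: list[MarkerScore]
    best_markers: list[str]  # zero mismatches
    one_recombinant_markers: list[str]
    assigned_linkage_group: str | None
    ambiguous: bool = False
    used_fallback: bool = False


def score_concordance(candidate: pd.Series,
                      matrix: GenotypeMatrix) -> list[MarkerScore]:
    """Per-marker shared-individual and mismatch counts for a candidate.

    ``candidate`` is a Series of {A, H, missing} indexed by individual id.
    Markers with no shared informative individuals are reported with
    shared=0 (non-comparable). Raises if the candidate shares no genotyped
    individual with the matrix at all.
    """
    cand = candidate.replace({None: MISSING}).fillna(MISSING)
    common_ind = [i for i in matrix.genotypes.index
                  if i in cand.index and cand[i] in CODES]
    if not common_ind:
        raise LinkmapInputError(
            "candidate shares no genotyped individual with the matrix")
    scores: list[MarkerScore] = []
    for marker in matrix.genotypes.columns:
        col = matrix.genotypes[marker]
        shared_ids = [i for i in common_ind
                      if str(col[i]) in CODES]
        shared = len(shared_ids)
        if shared == 0:
            scores.append(MarkerScore(marker, 0, 0, False))
            continue
        raw = sum(cand[i] != col[i] for i in shared_ids)
        flipped = shared - raw  # mismatches after swapping A<->H
        if flipped < raw:
            scores.append(MarkerScore(marker, shared, flipped, True))
        else:
            scores.append(MarkerScore(marker, shared, raw, False))
    return scores


def place_candidate(candidate_id: str, scores: Sequence[MarkerScore],
                    marker_map: MarkerMap, max_mismatch: int = 1,
                    n_genotyped: int | None = None) -> PlacementResult:
    """Assign a linkage group from concordance scores.

    Zero-mismatch markers place the candidate; when none exist, markers
    with <= ``max_mismatch`` mismatches (default 1 recombinant) are the
    fallback. If the selected markers span multiple linkage groups the
    candidate is left unplaced with the ambiguity flag set.
    """
    if not scores:
        raise LinkmapInputError("scores must be nonempty")
    comparable = [s for s in scores if s.shared > 0]
    best = [s.marker for s in comparable if s.mismatches == 0]
    one_rec = [s.marker for s in comparable if s.mismatches == 1]
    if n_genotyped is None:
        n_genotyped = max((s.shared for s in comparable), default=0)

    if best:
        selected, fallback = best, False
    else:
        selected = [s.marker for s in comparable
                    if 0 < s.mismatches <= max_mismatch]
        fallback = True

    result = PlacementResult(candidate_id, n_genotyped, list(scores),
                             best, one_rec, None,
                             used_fallback=fallback and bool(selected))
    if not selected:
        return result
    groups = {marker_map.group_of(m) for m in selected}
    if len(groups) == 1:
        result.assigned_linkage_group = groups.pop()
    else:
        result.ambiguous = True
        logger.info("candidate %s: selected markers span groups %s; "
                    "left unplaced", candidate_id, sorted(groups))
    return result


def placement_table(results: Sequence[PlacementResult]) -> pd.DataFrame:
    """Report mirroring the candidate-placement table: individuals
    genotyped, markers in agreement, markers with one recombinant, group."""
    rows = []
    for r in results:
        rows.append({
            "candidate": r.candidate_id,
            "n_genotyped": r.n_genotyped,
            "markers_in_agreement": ", ".join(r.best_markers),
            "markers_one_recombinant": ", ".join(r.one_recombinant_markers),
            "linkage_group": (r.assigned_linkage_group if
                              r.assigned_linkage_group is not None
                              else ("ambiguous" if r.ambiguous
                                    else "unplaced")),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# backcross simulator (test harness for placement)
# ---------------------------------------------------------------------------

def haldane_r(d_cM: float) -> float:
    """Recombination fraction for a map distance d in centimorgan."""
    return (1.0 - np.exp(-2.0 * d_cM / 100.0)) / 2.0


def simulate_backcross(n_individuals: int, map_spec: Mapping[str, Sequence[tuple[str, float]]],
                       candidate: tuple[str, float] | None = None,
                       candidate_id: str = "candidate",
                       seed: int = 0,
                       ) -> tuple[GenotypeMatrix, pd.Series | None]:
    """Simulate backcross genotypes along a marker map.

    ``map_spec`` maps linkage-group id to an ordered list of
    (marker, position_cM). The hybrid parent transmits, per linkage group,
    a gamete built with inter-marker recombination probability given by the
    Haldane mapping function; the recurrent parent contributes a constant
    allele, so genotypes are 'H' where the hybrid transmitted the
    non-recurrent allele and 'A' otherwise. ``candidate`` = (group, cM)
    inserts an extra locus at that position whose genotypes are returned
    separately (it is not part of the map).
    """
    for g, markers in map_spec.items():
        if not markers:
            raise LinkmapInputError(f"linkage group {g!r} has no markers")
        pos = [p for _, p in markers]
        if any(b < a for a, b in zip(pos, pos[1:])):
            raise LinkmapInputError(
                f"linkage group {g!r} positions must be non-decreasing")
    if candidate is not None and candidate[0] not in map_spec:
        raise LinkmapInputError(
            f"candidate group {candidate[0]!r} not in map_spec")
    rng = np.random.default_rng(seed)
    individuals = [f"ind_{i:03d}" for i in range(n_individuals)]
    columns: dict[str, list[str]] = {}
    cand_column: list[str] | None = [] if candidate is not None else None
    map_rows = []

    for g, markers in map_spec.items():
        loci: list[tuple[str, float, bool]] = [
            (m, p, False) for m, p in markers]
        if candidate is not None and candidate[0] == g:
            loci.append((candidate_id, candidate[1], True))
        loci.sort(key=lambda t: (t[1], t[2]))  # candidate after ties
        for m, p, is_cand in loci:
            if not is_cand:
                map_rows.append({"marker": m, "group": g, "cM": p})
                columns[m] = []
        for _ in individuals:
            state = int(rng.random() < 0.5)  # which hybrid chromatid
            prev_pos = loci[0][1]
            for m, p, is_cand in loci:
                r = haldane_r(p - prev_pos)
                if rng.random() < r:
                    state = 1 - state
                prev_pos = p
                code = "H" if state else "A"
                if is_cand:
                    cand_column.append(code)
                else:
                    columns[m].append(code)

    geno = pd.DataFrame(columns, index=individuals)
    mmap = MarkerMap(pd.DataFrame(map_rows))
    matrix = GenotypeMatrix(geno, mmap)
    cand_series = (pd.Series(cand_column, index=individuals,
                             name=candidate_id)
                   if candidate is not None else None)
    return matrix, cand_series


# ---------------------------------------------------------------------------
# TSV interfaces
# ---------------------------------------------------------------------------

def read_marker_map(path: str | Path) -> MarkerMap:
    return MarkerMap(pd.read_csv(path, sep="\t", dtype={"group": str}))


def read_genotype_matrix(path: str | Path, marker_map: MarkerMap,
                         ) -> GenotypeMatrix:
    """Genotype TSV: first column individual id, one column per marker."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return GenotypeMatrix(df.fillna(MISSING), marker_map)


def read_candidate_genotypes(path: str | Path) -> dict[str, pd.Series]:
    """Candidate TSV: first column individual id, one column per candidate."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str).fillna(MISSING)
    return {c: df[c] for c in df.columns}


def write_placement_tsv(results: Sequence[PlacementResult],
                        path: str | Path) -> None:
    placement_table(results).to_csv(path, sep="\t", index=False)
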