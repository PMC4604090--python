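"""Linkage-map placement: concordance scoring, decision rule, backcross sim."""

import numpy as np
import pandas as pd
import pytest

from cavecall.linkmap import (GenotypeMatrix, LinkmapInputError, MarkerMap,
                              haldane_r, place_candidate, placement_table,
                              read_candidate_genotypes, read_genotype_matrix,
                              read_marker_map, score_concordance,
                              simulate_backcross, write_placement_tsv)


def make_matrix(columns, groups, individuals=None):
    """GenotypeMatrix from {marker: genotype-string}, {marker: group}."""
    n = len(next(iter(columns.values())))
    individuals = individuals or [f"i{j}" for j in range(n)]
    geno = pd.DataFrame({m: list(s) for m, s in columns.items()},
                        index=individuals)
    mmap = MarkerMap(pd.DataFrame(
        [{"marker": m, "group": g, "cM": i * 10.0}
         for i, (m, g) in enumerate(groups.items())]))
    return GenotypeMatrix(geno, mmap)


class TestConcordance:
    def test_full_agreement_pattern(self):
        """8 individuals in complete agreement with two markers on one
        group places the candidate there (the classic zero-recombinant
        pattern)."""
        col = "AHAHHAAH"
        matrix = make_matrix({"aa98": col, "aa58": col, "aa12": "AAAAAAAA"},
                             {"aa98": "6", "aa58": "6", "aa12": "3"})
        cand = pd.Series(list(col), index=matrix.genotypes.index)
        scores = score_concordance(cand, matrix)
        by = {s.marker: s for s in scores}
        assert (by["aa98"].shared, by["aa98"].mismatches) == (8, 0)
        assert (by["aa58"].shared, by["aa58"].mismatches) == (8, 0)
        result = place_candidate("ruby_like", scores, matrix.marker_map)
        assert set(result.best_markers) == {"aa98", "aa58"}
        assert result.assigned_linkage_group == "6"
        assert not result.used_fallback

    def test_one_recombinant_fallback(self):
        """15 individuals with exactly one mismatch against two linked
        markers: the zero-mismatch set is empty and the one-recombinant
        fallback assigns the group."""
        col = "AHAHHAAHAHHAAHA"
        flipped = "H" + col[1:]  # one recombinant individual
        matrix = make_matrix({"aa56": col, "aa74": col,
                              "far": "A" * 7 + "H" * 8},
                             {"aa56": "2", "aa74": "2", "far": "5"})
        cand = pd.Series(list(flipped), index=matrix.genotypes.index)
        scores = score_concordance(cand, matrix)
        by = {s.marker: s for s in scores}
        assert (by["aa56"].shared, by["aa56"].mismatches) == (15, 1)
        result = place_candidate("kfase_like", scores, matrix.marker_map)
        assert result.best_markers == []
        assert set(result.one_recombinant_markers) == {"aa56", "aa74"}
        assert result.assigned_linkage_group == "2"
        assert result.used_fallback

    def test_ambiguous_groups_left_unplaced(self):
        col = "AHAHHAAH"
        matrix = make_matrix({"m1": col, "m2": col},
                             {"m1": "1", "m2": "2"})
        cand = pd.Series(list(col), index=matrix.genotypes.index)
        result = place_candidate("c", score_concordance(cand, matrix),
                                 matrix.marker_map)
        assert result.assigned_linkage_group is None
        assert result.ambiguous

    def test_phase_flip_detected(self):
        """A candidate coded in opposite phase still scores zero
        mismatches, via the A<->H orientation flip."""
        col = "AHAHHAAH"
        swapped = col.translate(str.maketrans("AH", "HA"))
        matrix = make_matrix({"m": col}, {"m": "1"})
        cand = pd.Series(list(swapped), index=matrix.genotypes.index)
        (score,) = score_concordance(cand, matrix)
        assert (score.mismatches, score.flipped) == (0, True)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        a = "".join(rng.choice(["A", "H"], 12))
        b = "".join(rng.choice(["A", "H"], 12))
        m1 = make_matrix({"m": b}, {"m": "1"})
        m2 = make_matrix({"m": a}, {"m": "1"})
        idx = m1.genotypes.index
        s_ab = score_concordance(pd.Series(list(a), index=idx), m1)[0]
        s_ba = score_concordance(pd.Series(list(b), index=idx), m2)[0]
        assert (s_ab.shared, s_ab.mismatches) == (s_ba.shared,
                                                  s_ba.mismatches)

    def test_missing_codes_excluded_from_shared(self):
        matrix = make_matrix({"m": "AH-A"}, {"m": "1"})
        cand = pd.Series(list("A-HA"), index=matrix.genotypes.index)
        (score,) = score_concordance(cand, matrix)
        assert score.shared == 2  # individuals 0 and 3

    def test_all_missing_overlap_non_comparable(self):
        matrix = make_matrix({"m": "--AA", "ok": "AHAH"},
                             {"m": "1", "ok": "1"})
        cand = pd.Series(list("AH--"), index=matrix.genotypes.index)
        by = {s.marker: s for s in score_concordance(cand, matrix)}
        assert by["m"].shared == 0

    def test_no_overlap_at_all_is_error(self):
        matrix = make_matrix({"m": "AHAH"}, {"m": "1"})
        cand = pd.Series(list("AHAH"), index=["x1", "x2", "x3", "x4"])
        with pytest.raises(LinkmapInputError, match="no genotyped"):
            score_concordance(cand, matrix)

    def test_bad_genotype_codes_rejected(self):
        with pytest.raises(LinkmapInputError, match="codes"):
            make_matrix({"m": "ABAH"}, {"m": "1"})


class TestBackcrossSim:
    MAP = {"1": [("m0", 0.0), ("m1", 10.0), ("m2", 20.0)]}

    def test_haldane_limits(self):
        assert haldane_r(0) == 0.0
        assert haldane_r(1e9) == pytest.approx(0.5)
        assert haldane_r(10) == pytest.approx((1 - np.exp(-0.2)) / 2)

    def test_zero_distance_identical_columns(self):
        spec = {"1": [("a", 5.0), ("b", 5.0)]}
        matrix, _ = simulate_backcross(40, spec, seed=1)
        assert (matrix.genotypes["a"] == matrix.genotypes["b"]).all()

    def test_unlinked_markers_uncorrelated(self):
        spec = {"1": [("a", 0.0), ("b", 100000.0)]}
        matrix, _ = simulate_backcross(400, spec, seed=2)
        a = (matrix.genotypes["a"] == "H").astype(int)
        b = (matrix.genotypes["b"] == "H").astype(int)
        assert abs(np.corrcoef(a, b)[0, 1]) < 0.15

    def test_recombinant_fraction_matches_haldane(self):
        """Observed recombinants between markers 10 cM apart sit within 3
        binomial SDs of the Haldane fraction."""
        n = 500
        matrix, _ = simulate_backcross(n, self.MAP, seed=3)
        r = haldane_r(10.0)
        rec = (matrix.genotypes["m0"] != matrix.genotypes["m1"]).mean()
        assert abs(rec - r) < 3 * np.sqrt(r * (1 - r) / n)

    def test_candidate_at_marker_recovered(self):
        spec = {g: [(f"g{g}m{i}", i * 10.0) for i in range(5)]
                for g in "1234"}
        hits = 0
        for seed in range(20):
            matrix, cand = simulate_backcross(
                50, spec, candidate=("3", 20.0), seed=seed)
            scores = score_concordance(cand, matrix)
            result = place_candidate("cand", scores, matrix.marker_map)
            hits += result.assigned_linkage_group == "3"
        assert hits >= 18

    def test_determinism(self):
        m1, c1 = simulate_backcross(20, self.MAP, candidate=("1", 5.0),
                                    seed=7)
        m2, c2 = simulate_backcross(20, self.MAP, candidate=("1", 5.0),
                                    seed=7)
        assert m1.genotypes.equals(m2.genotypes)
        assert c1.equals(c2)

    def test_invalid_map_spec(self):
        with pytest.raises(LinkmapInputError, match="no markers"):
            simulate_backcross(5, {"1": []})
        with pytest.raises(LinkmapInputError, match="non-decreasing"):
            simulate_backcross(5, {"1": [("a", 10.0), ("b", 5.0)]})
        with pytest.raises(LinkmapInputError, match="candidate group"):
            simulate_backcross(5, self.MAP, candidate=("9", 0.0))


class TestTsvInterfaces:
    def test_round_trip_through_files(self, tmp_path):
        matrix, cand = simulate_backcross(
            12, {"2": [("aa56", 0.0), ("aa74", 8.0)]},
            candidate=("2", 4.0), seed=5)
        map_path = tmp_path / "map.tsv"
        matrix.marker_map.table.to_csv(map_path, sep="\t", index=False)
        geno_path = tmp_path / "geno.tsv"
        matrix.genotypes.rename_axis("individual").to_csv(
            geno_path, sep="\t")
        cand_path = tmp_path / "cand.tsv"
        cand.rename_axis("individual").to_frame().to_csv(
            cand_path, sep="\t")

        mmap = read_marker_map(map_path)
        back = read_genotype_matrix(geno_path, mmap)
        cands = read_candidate_genotypes(cand_path)
        assert back.genotypes.equals(matrix.genotypes)
        (name, series), = cands.items()
        scores = score_concordance(series, back)
        result = place_candidate(name, scores, mmap)
        assert result.assigned_linkage_group == "2"

        out = tmp_path / "placement.tsv"
        write_placement_tsv([result], out)
        table = pd.read_csv(out, sep="\t", dtype=str)
        assert table.loc[0, "linkage_group"] == "2"

    def test_placement_table_columns(self):
        matrix, cand = simulate_backcross(
            10, {"1": [("a", 0.0), ("b", 10.0)]}, candidate=("1", 0.0),
            seed=9)
        result = place_candidate(
            "x", score_concordance(cand, matrix), matrix.marker_map)
        table = placement_table([result])
        assert list(table.columns) == ["candidate", "n_genotyped",
                                       "markers_in_agreement",
                                       "markers_one_recombinant",
                                       "linkage_group"]
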