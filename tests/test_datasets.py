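"""Filtering rules carry exact boundary semantics (strictly 'fewer than'
10% / 70%) and a hand-computable mean + 3*IQR hypervariability cutoff;
dataset construction, SNP reduction and bootstrap are checked against
brute-force recomputation on constructed fixtures."""

import numpy as np
import pandas as pd
import pytest

from gbsfoil.datasets import (FilterThresholds, bootstrap_loci, build_dataset,
                              filter_hypervariable, filter_missingness,
                              locus_variability, select_best_unit,
                              to_sequence_dataset, to_snp_dataset)
from gbsfoil.grouping import expand_individuals, load_study_grouping
from gbsfoil.matrix import LocusMatrix
from gbsfoil.simulate import SimulationConfig, simulate_matrix


def make_matrix(cells: dict, length: int = 10) -> LocusMatrix:
    loci = {l for l, _ in cells}
    inds = sorted({i for _, i in cells})
    return LocusMatrix(lengths={l: length for l in loci}, individuals=inds,
                       cells={k: tuple(v) for k, v in cells.items()})


def seq_with_variability(n_var: int, length: int = 100) -> tuple[str, str]:
    a = "A" * length
    b = "C" * n_var + "A" * (length - n_var)
    return a, b


class TestVariability:
    def test_identical_sequences_zero(self):
        assert locus_variability(["ACGT" * 5] * 4) == 0.0

    def test_one_variable_column_of_ten(self):
        assert locus_variability(["AAAAAAAAAA", "CAAAAAAAAA"]) == pytest.approx(0.1)

    def test_missing_states_ignored(self):
        # N never creates a variable column
        assert locus_variability(["AAAA", "NAAA"]) == 0.0

    def test_matches_bruteforce_on_random_alignments(self, rng):
        for _ in range(25):
            arr = rng.integers(0, 5, size=(4, 30))
            seqs = ["".join("ACGTN"[b] for b in row) for row in arr]
            brute = sum(
                1 for c in range(30)
                if len({s[c] for s in seqs if s[c] != "N"}) >= 2) / 30
            assert locus_variability(seqs) == pytest.approx(brute)

    def test_zero_length_errors(self):
        with pytest.raises(ValueError):
            locus_variability([])


class TestHypervariableFilter:
    def test_equal_variability_none_removed(self):
        cells = {(f"L{i}", "a"): (seq_with_variability(2)[0],)
                 for i in range(5)}
        cells.update({(f"L{i}", "b"): (seq_with_variability(2)[1],)
                      for i in range(5)})
        m = make_matrix(cells, length=100)
        assert len(filter_hypervariable(m, 3.0).lengths) == 5

    def test_hand_computed_outlier_removed(self):
        # v = 0.02 x10, 0.04 x10, 0.90 x1
        # mean = 1.5/21 ~= 0.0714; IQR (linear quartiles) = 0.04-0.02 = 0.02
        # cutoff = 0.0714 + 3*0.02 = 0.1314 -> only the 0.90 locus falls
        cells = {}
        for i in range(10):
            a, b = seq_with_variability(2)
            cells[(f"A{i}", "u")] = (a,)
            cells[(f"A{i}", "v")] = (b,)
        for i in range(10):
            a, b = seq_with_variability(4)
            cells[(f"B{i}", "u")] = (a,)
            cells[(f"B{i}", "v")] = (b,)
        a, b = seq_with_variability(90)
        cells[("X", "u")] = (a,)
        cells[("X", "v")] = (b,)
        m = make_matrix(cells, length=100)
        out = filter_hypervariable(m, 3.0)
        assert "X" not in out.lengths
        assert len(out.lengths) == 20

    def test_simulated_paralogs_removed_with_high_sensitivity(self):
        config = SimulationConfig(n_loci=300, seed=31, paralog_rate=0.1,
                                  dropout=0.1)
        matrix, truth = simulate_matrix(config)
        labels = truth.labels()
        paralogs = {l for l in matrix.loci if labels[l] == "paralog"}
        assert paralogs
        kept = set(filter_hypervariable(matrix, 3.0).lengths)
        sensitivity = len(paralogs - kept) / len(paralogs)
        assert sensitivity >= 0.9


class TestMissingnessFilter:
    def _matrix(self, presence: dict[str, list[str]], n_loci: int):
        # presence: individual -> loci held
        cells = {(l, i): ("A" * 10,)
                 for i, loci in presence.items() for l in loci}
        loci = {f"L{k}" for k in range(n_loci)}
        inds = sorted(presence)
        return LocusMatrix(lengths={l: 10 for l in loci}, individuals=inds,
                           cells=cells)

    def test_individual_boundaries_strict(self):
        loci = [f"L{k}" for k in range(20)]
        full = {f"i{j}": loci for j in range(9)}
        full["at_10pct"] = loci[:2]    # exactly 10%: kept
        full["below"] = loci[:1]       # 5%: dropped
        m = self._matrix(full, 20)
        out = filter_missingness(m, 0.10, 0.0)
        assert "at_10pct" in out.individuals
        assert "below" not in out.individuals

    def test_locus_boundaries_strict(self):
        loci = [f"L{k}" for k in range(2)]
        presence = {}
        for j in range(10):
            held = ["L0"]
            if j < 7:
                held.append("L1")   # L1 in exactly 70%: kept
            presence[f"i{j}"] = held
        m = self._matrix(presence, 2)
        out = filter_missingness(m, 0.0, 0.70)
        assert set(out.lengths) == {"L0", "L1"}
        # at 6/10 = 60% the locus falls
        presence["i6"] = ["L0"]
        m2 = self._matrix(presence, 2)
        out2 = filter_missingness(m2, 0.0, 0.70)
        assert set(out2.lengths) == {"L0"}

    def test_individuals_dropped_before_locus_pass(self):
        # the locus filter is evaluated against post-step-1 individuals:
        # after dropping the sparse individual, L1 is present in 100%
        loci = ["L0", "L1"]
        presence = {"good1": loci, "good2": loci, "sparse": []}
        cells = {(l, i): ("A" * 10,) for i, ls in presence.items() for l in ls}
        m = LocusMatrix(lengths={l: 10 for l in loci},
                        individuals=sorted(presence), cells=cells)
        out = filter_missingness(m, 0.10, 0.9)
        assert "sparse" not in out.individuals
        assert set(out.lengths) == {"L0", "L1"}

    def test_complete_matrix_unchanged(self):
        presence = {f"i{j}": ["L0", "L1"] for j in range(4)}
        m = self._matrix(presence, 2)
        out = filter_missingness(m, 0.10, 0.70)
        assert set(out.lengths) == {"L0", "L1"}
        assert out.individuals == m.individuals

    def test_everything_filtered_errors(self):
        empty = LocusMatrix(lengths={"L0": 10}, individuals=["i0"], cells={})
        with pytest.raises(ValueError, match="removed everything"):
            filter_missingness(empty, 0.10, 0.70)

    def test_theta_loc_monotonicity(self, rng):
        config = SimulationConfig(n_loci=60, seed=32)
        matrix, _ = simulate_matrix(config)
        counts = [len(filter_missingness(matrix, 0.1, t).lengths)
                  for t in (0.3, 0.5, 0.7, 0.8)]
        assert counts == sorted(counts, reverse=True)


class TestBestUnit:
    def _matrix(self):
        cells = {(f"L{k}", "A"): ("AAAAAAAAAA",) for k in range(9)}
        cells.update({(f"L{k}", "B"): ("AAAAAAAAAA",) for k in range(8)})
        cells.update({(f"L{k}", "C"): ("AAAAAAAAAA",) for k in range(9)})
        return make_matrix(cells)

    def test_single_member(self):
        assert select_best_unit(self._matrix(), ["B"]) == "B"

    def test_most_loci_wins(self):
        assert select_best_unit(self._matrix(), ["A", "B"]) == "A"

    def test_read_count_tiebreak_then_lexicographic(self):
        m = self._matrix()
        assert select_best_unit(m, ["A", "C"],
                                read_counts={"A": 10**6, "C": 10**5}) == "A"
        assert select_best_unit(m, ["C", "A"],
                                read_counts={"A": 10**5, "C": 10**6}) == "C"
        assert select_best_unit(m, ["C", "A"]) == "A"


class TestBuildDataset:
    def test_taxon_level_study_grouping_has_13_units(self):
        # the packaged population table, Albanian capillacea separate
        grouping = expand_individuals()
        inds = list(grouping["individual"])
        cells = {(f"L{k}", i): ("ACGTACGTAC",) for k in range(5) for i in inds}
        m = LocusMatrix(lengths={f"L{k}": 10 for k in range(5)},
                        individuals=inds, cells=cells)
        ds = build_dataset(m, "taxon", grouping)
        assert len(ds.units) == 13
        assert sorted(ds.units) == sorted(load_study_grouping()["taxon"].unique())

    def test_population_level_single_population(self):
        grouping = pd.DataFrame({
            "individual": ["a", "b"], "population": ["p", "p"],
            "taxon": ["t", "t"]})
        cells = {("L0", "a"): ("AAAAAAAAAA",), ("L1", "a"): ("AAAAAAAAAA",),
                 ("L0", "b"): ("AAAAAAAAAA",)}
        m = make_matrix(cells)
        ds = build_dataset(m, "population", grouping,
                           FilterThresholds(theta_loc=0.0))
        assert ds.units == ["a"]

    def test_taxon_composite_fill_in(self):
        # best individual lacks L1; its population mate has it
        grouping = pd.DataFrame({
            "individual": ["a", "b"], "population": ["p", "p"],
            "taxon": ["t", "t"]})
        cells = {("L0", "a"): ("AAAAAAAAAA",), ("L2", "a"): ("AAAAAAAAAA",),
                 ("L0", "b"): ("CCCCCCCCCC",), ("L1", "b"): ("GGGGGGGGGG",)}
        m = make_matrix(cells)
        ds = build_dataset(m, "taxon", grouping,
                           FilterThresholds(theta_loc=0.0))
        assert ds.units == ["t"]
        assert ds.alleles("L0", "t") == ("AAAAAAAAAA",)   # best individual
        assert ds.alleles("L1", "t") == ("GGGGGGGGGG",)   # filled from mate
        assert ds.alleles("L2", "t") == ("AAAAAAAAAA",)

    def test_postfilter_presence_guarantee(self):
        config = SimulationConfig(n_loci=80, seed=33)
        matrix, truth = simulate_matrix(config)
        ds = build_dataset(matrix, "individual", truth.grouping)
        for locus in set(ds.loci):
            frac = np.mean([1 if ds.alleles(locus, u) else 0
                            for u in ds.units])
            assert frac >= ds.thresholds.theta_loc

    def test_unknown_individual_errors(self):
        grouping = pd.DataFrame({"individual": ["a"], "population": ["p"],
                                 "taxon": ["t"]})
        m = make_matrix({("L0", "a"): ("AAAAAAAAAA",),
                         ("L0", "zzz"): ("AAAAAAAAAA",)})
        with pytest.raises(KeyError):
            build_dataset(m, "individual", grouping)


def _toy_dataset(het=False):
    grouping = pd.DataFrame({
        "individual": ["a", "b", "c"], "population": ["pa", "pb", "pc"],
        "taxon": ["ta", "tb", "tc"]})
    al = ("AAAAAAAAAA", "AAAAAAAAAC") if het else ("AAAAAAAAAA",)
    cells = {("L0", "a"): al, ("L0", "b"): ("AAAAAAAAAA",),
             ("L0", "c"): ("AAAAAAAAAA",),
             ("L1", "a"): ("CCCCCCCCCC",), ("L1", "b"): ("CCCCCCCCCC",),
             ("L1", "c"): ("CCCCCCCCCC",)}
    m = make_matrix(cells)
    return build_dataset(m, "individual", grouping)


class TestReformat:
    def test_homozygous_supermatrix_seed_independent(self):
        ds = _toy_dataset(het=False)
        s1 = to_sequence_dataset(ds, np.random.default_rng(1))
        s2 = to_sequence_dataset(ds, np.random.default_rng(99))
        assert s1.sequences == s2.sequences

    def test_total_length_equals_partition_sum(self):
        ds = _toy_dataset()
        seq = to_sequence_dataset(ds, np.random.default_rng(2))
        total = sum(end - start + 1 for _, start, end in seq.partition)
        assert seq.total_length == total == ds.total_length

    def test_supermatrix_deterministic_under_seed(self):
        ds = _toy_dataset(het=True)
        s1 = to_sequence_dataset(ds, np.random.default_rng(3))
        s2 = to_sequence_dataset(ds, np.random.default_rng(3))
        assert s1.sequences == s2.sequences

    def test_missing_locus_filled_with_N(self):
        grouping = pd.DataFrame({
            "individual": ["a", "b"], "population": ["pa", "pb"],
            "taxon": ["ta", "tb"]})
        cells = {("L0", "a"): ("ACGTACGTAC",), ("L0", "b"): ("ACGTACGTAC",),
                 ("L1", "a"): ("GGGGGGGGGG",)}
        m = make_matrix(cells)
        ds = build_dataset(m, "individual", grouping,
                           FilterThresholds(theta_loc=0.5))
        seq = to_sequence_dataset(ds, np.random.default_rng(4))
        assert seq.sequences["b"].endswith("N" * 10) or \
            seq.sequences["b"].startswith("N" * 10)

    def test_snp_biallelic_site_unchanged(self):
        grouping = pd.DataFrame({
            "individual": list("abcd"), "population": list("abcd"),
            "taxon": list("abcd")})
        cells = {("L0", i): (s,) for i, s in
                 zip("abcd", ["AAAAAAAAAA", "AAAAAAAAAA",
                              "CAAAAAAAAA", "CAAAAAAAAA"])}
        ds = build_dataset(make_matrix(cells), "individual", grouping)
        snp = to_snp_dataset(ds, np.random.default_rng(5))
        assert snp.n_sites == 1
        col = snp.data[:, 0]
        assert not np.isnan(col).any()
        assert set(col) == {0.0, 1.0}

    def test_snp_triallelic_reduced_to_two_states(self):
        grouping = pd.DataFrame({
            "individual": list("abc"), "population": list("abc"),
            "taxon": list("abc")})
        cells = {("L0", i): (s,) for i, s in
                 zip("abc", ["AAAAAAAAAA", "CAAAAAAAAA", "GAAAAAAAAA"])}
        ds = build_dataset(make_matrix(cells), "individual", grouping)
        snp = to_snp_dataset(ds, np.random.default_rng(6))
        col = snp.data[:, 0]
        assert np.isnan(col).sum() == 1
        assert sorted(col[~np.isnan(col)]) == [0.0, 1.0]

    def test_snp_deterministic_under_seed(self):
        grouping = pd.DataFrame({
            "individual": list("abc"), "population": list("abc"),
            "taxon": list("abc")})
        cells = {("L0", i): (s,) for i, s in
                 zip("abc", ["AAAAAAAAAA", "CAAAAAAAAA", "GAAAAAAAAA"])}
        ds = build_dataset(make_matrix(cells), "individual", grouping)
        a = to_snp_dataset(ds, np.random.default_rng(7)).data
        b = to_snp_dataset(ds, np.random.default_rng(7)).data
        assert np.array_equal(a, b, equal_nan=True)


class TestBootstrap:
    def test_zero_replicates(self):
        ds = _toy_dataset()
        assert bootstrap_loci(ds, 0, np.random.default_rng(8)) == []

    def test_replicates_keep_locus_count(self):
        ds = _toy_dataset()
        for rep in bootstrap_loci(ds, 5, np.random.default_rng(9)):
            assert len(rep.loci) == len(ds.loci)
            assert rep.total_length == ds.total_length

    def test_single_locus_dataset_identical_replicates(self):
        grouping = pd.DataFrame({"individual": ["a"], "population": ["p"],
                                 "taxon": ["t"]})
        cells = {("L0", "a"): ("ACGTACGTAC",)}
        ds = build_dataset(make_matrix(cells), "individual", grouping)
        for rep in bootstrap_loci(ds, 3, np.random.default_rng(10)):
            assert rep.loci == ds.loci
            assert rep.partition == ds.partition
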