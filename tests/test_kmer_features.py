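import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tcrpred.repertoire_io import Repertoire, AMINO_ACIDS
from tcrpred.kmer_features import (
    FeatureError,
    build_feature_matrix,
    extract_kmers,
    prevalence_filter,
    quantile_scale,
    sis_dimension,
    sis_screen,
)

seqs = st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=15)


class TestExtractKmers:
    def test_sliding_windows(self):
        rep = Repertoire("A", [("CASSHGRAEAFF", 1)])
        counts = extract_kmers(rep, 3, weight_by_abundance=False)
        expected = ["CAS", "ASS", "SSH", "SHG", "HGR", "GRA", "RAE", "AEA", "EAF", "AFF"]
        assert counts == {k: 1 for k in expected}

    def test_short_sequence_empty(self):
        assert extract_kmers(Repertoire("A", [("CA", 5)]), 3) == {}

    def test_abundance_weighting(self):
        rep = Repertoire("A", [("CASF", 2), ("ASFA", 3)])
        counts = extract_kmers(rep, 2, weight_by_abundance=True)
        assert counts == {"CA": 2, "AS": 5, "SF": 5, "FA": 3}

    @given(st.lists(st.tuples(seqs, st.integers(1, 9)), min_size=1, max_size=8, unique_by=lambda c: c[0]))
    @settings(max_examples=40, deadline=None)
    def test_total_mass(self, clones):
        rep = Repertoire("A", clones)
        k = 3
        counts = extract_kmers(rep, k, weight_by_abundance=False)
        assert sum(counts.values()) == sum(max(0, len(s) - k + 1) for s, _ in clones)


class TestBuildFeatureMatrix:
    def test_matches_bruteforce_recount(self, small_pool):
        reps = small_pool[:5]
        fm = build_feature_matrix(reps, 3)
        # independent sliding-window recount
        for i, rep in enumerate(reps):
            tally = {}
            for seq, w in rep.clones:
                for s in range(len(seq) - 2):
                    km = seq[s : s + 3]
                    tally[km] = tally.get(km, 0.0) + w
            for j, name in enumerate(fm.feature_names):
                assert fm.values[i, j] == tally.get(name, 0.0)

    def test_columns_sorted_and_complete(self, small_pool):
        fm = build_feature_matrix(small_pool[:4], 3)
        assert fm.feature_names == sorted(fm.feature_names)
        assert (fm.values >= 0).all()
        assert fm.p <= 20**3

    def test_disjoint_repertoires_block_structure(self):
        r1 = Repertoire("A", [("CCCC", 2)])
        r2 = Repertoire("B", [("WWWW", 2)])
        fm = build_feature_matrix([r1, r2], 3)
        assert fm.feature_names == ["CCC", "WWW"]
        # 2 sliding windows x abundance 2 in each block
        assert fm.values.tolist() == [[4.0, 0.0], [0.0, 4.0]]

    def test_row_permutation_equivariance(self, small_pool):
        reps = small_pool[:6]
        fm = build_feature_matrix(reps, 3)
        fm_rev = build_feature_matrix(reps[::-1], 3)
        assert fm.feature_names == fm_rev.feature_names
        assert np.array_equal(fm.values[::-1], fm_rev.values)

    def test_all_short_errors(self):
        with pytest.raises(FeatureError):
            build_feature_matrix([Repertoire("A", [("CA", 2)])], 3)


def _fm(cols, names=None):
    vals = np.array(cols, dtype=float).T
    names = names or [f"K{j}" for j in range(vals.shape[1])]
    from tcrpred.kmer_features import FeatureMatrix

    return FeatureMatrix(vals, names, [f"I{i}" for i in range(vals.shape[0])], 3)


class TestQuantileScale:
    def test_linear_interpolation_quantile(self):
        out = quantile_scale(_fm([[0, 0, 4, 8]]), 0.75)
        # type-7 quantile of [0,0,4,8] at 0.75 is 5
        assert out.scale_factors[0] == pytest.approx(5.0)
        assert out.values[:, 0] == pytest.approx([0, 0, 0.8, 1.6])

    def test_nonzero_mode(self):
        out = quantile_scale(_fm([[0, 0, 4, 8]]), 0.75, nonzero_only=True)
        assert out.scale_factors[0] == pytest.approx(7.0)

    def test_zero_column_unchanged(self):
        out = quantile_scale(_fm([[0, 0, 0, 0]]), 0.75)
        assert out.scale_factors[0] == 1.0
        assert (out.values == 0).all()

    def test_constant_column_becomes_ones(self):
        out = quantile_scale(_fm([[3, 3, 3, 3]]), 0.75)
        assert out.values[:, 0] == pytest.approx([1, 1, 1, 1])

    def test_scaling_round_trip(self, small_pool):
        fm = build_feature_matrix(small_pool[:6], 3)
        scaled = quantile_scale(fm, 0.75)
        restored = scaled.values * scaled.scale_factors
        assert np.allclose(restored, fm.values, atol=1e-12)


class TestPrevalenceFilter:
    def test_boundary_at_five_percent(self):
        cols = []
        col4 = [0.0] * 100
        col5 = [0.0] * 100
        for i in range(4):
            col4[i] = 1.0
        for i in range(5):
            col5[i] = 1.0
        fm = _fm([col4, col5], ["four", "five"])
        out = prevalence_filter(fm, 0.05)
        assert out.feature_names == ["five"]

    def test_zero_threshold_is_identity(self, small_pool):
        fm = build_feature_matrix(small_pool[:5], 3)
        out = prevalence_filter(fm, 0.0)
        assert out.feature_names == fm.feature_names

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(3)
        vals = rng.binomial(1, 0.1, size=(50, 200)) * rng.uniform(1, 5, size=(50, 200))
        from tcrpred.kmer_features import FeatureMatrix

        fm = FeatureMatrix(vals, [f"c{j}" for j in range(200)], [f"i{i}" for i in range(50)], 3)
        out = prevalence_filter(fm, 0.05)
        expected = [f"c{j}" for j in range(200) if (vals[:, j] != 0).mean() >= 0.05]
        assert out.feature_names == expected

    def test_all_removed_errors(self):
        fm = _fm([[0.0] * 10])
        with pytest.raises(FeatureError, match="lower"):
            prevalence_filter(fm, 0.5)


class TestSISScreen:
    def test_default_dimension_formula(self):
        assert sis_dimension(500) == 40

    def test_outcome_equal_to_column_ranked_first(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(30, 8))
        from tcrpred.kmer_features import FeatureMatrix

        fm = FeatureMatrix(vals, [f"c{j}" for j in range(8)], [f"i{i}" for i in range(30)], 3)
        out = sis_screen(fm, vals[:, 5], d=1)
        assert out.feature_names == ["c5"]

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(size=(40, 30))
        y = rng.normal(size=40)
        from tcrpred.kmer_features import FeatureMatrix

        fm = FeatureMatrix(vals, [f"c{j:02d}" for j in range(30)], [f"i{i}" for i in range(40)], 3)
        out = sis_screen(fm, y, d=5)
        cors = [abs(np.corrcoef(vals[:, j], y)[0, 1]) for j in range(30)]
        expected = sorted(sorted(range(30), key=lambda j: (-cors[j], f"c{j:02d}"))[:5])
        assert out.feature_names == [f"c{j:02d}" for j in expected]

    def test_zero_variance_column_ranked_last(self):
        vals = np.column_stack([np.ones(20), np.arange(20.0)])
        from tcrpred.kmer_features import FeatureMatrix

        fm = FeatureMatrix(vals, ["const", "lin"], [f"i{i}" for i in range(20)], 3)
        out = sis_screen(fm, np.arange(20.0), d=1)
        assert out.feature_names == ["lin"]

    def test_column_order_invariance(self):
        rng = np.random.default_rng(11)
        vals = rng.normal(size=(25, 12))
        y = rng.normal(size=25)
        from tcrpred.kmer_features import FeatureMatrix

        names = [f"c{j}" for j in range(12)]
        fm = FeatureMatrix(vals, names, [f"i{i}" for i in range(25)], 3)
        perm = rng.permutation(12)
        fm2 = FeatureMatrix(vals[:, perm], [names[j] for j in perm], fm.individual_ids, 3)
        assert set(sis_screen(fm, y, 4).feature_names) == set(
            sis_screen(fm2, y, 4).feature_names
        )
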