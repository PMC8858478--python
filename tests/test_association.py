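"""Correlation, entropy, mutual information and the variance-artifact demo."""

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

from triage_eval import (
    CUBES,
    ISS,
    SUM,
    UndefinedStatisticError,
    cardinality_gap_report,
    conditional_entropy,
    entropy,
    joint_entropy,
    make_profile,
    mutual_information,
    normalized_mi,
    pearson,
    permutation_pvalue,
    sample_variance,
    score,
)
from triage_eval.association import DiscreteDistribution, OutcomeTable, empirical_distribution

# H of the mortality column (counts 3,1,3,1,3,1 over 12 rows):
# 3 values at p=1/4 and 3 at p=1/12 -> 1.5 + 0.25*log2(12)
H_MORTALITY = 2.396240625180289


class TestPearson:
    def test_self_correlation(self):
        assert pearson([1.0, 2.0, 5.0], [1.0, 2.0, 5.0]) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "spec, expected", [(SUM, 0.77), (ISS, 0.92), (CUBES, 0.92)]
    )
    def test_mortality_correlations(self, table4, mortality, spec, expected):
        xs = [float(v) for v in table4.score_column(spec)]
        assert round(pearson(xs, mortality), 2) == expected

    def test_against_scipy(self, table4, mortality):
        xs = [float(v) for v in table4.score_column(ISS)]
        assert pearson(xs, mortality) == pytest.approx(
            scipy.stats.pearsonr(xs, mortality).statistic, abs=1e-12
        )

    def test_zero_variance_raises(self):
        with pytest.raises(UndefinedStatisticError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_weights_equal_row_duplication(self):
        x, y = [1.0, 2.0, 4.0], [0.0, 1.0, 5.0]
        weighted = pearson(x, y, weights=[2, 1, 1])
        assert weighted == pytest.approx(pearson([1.0] + x, [0.0] + y))

    @settings(derandomize=True, max_examples=50)
    @given(
        xs=st.lists(st.floats(-50, 50), min_size=3, max_size=12, unique=True),
        slope=st.floats(0.1, 10),
        shift=st.floats(-5, 5),
    )
    def test_affine_invariance_and_sign_flip(self, xs, slope, shift):
        ys = [v**2 + 1 for v in xs]
        if len(set(ys)) < 2:
            return
        r = pearson(xs, ys)
        assert pearson([slope * v + shift for v in xs], ys) == pytest.approx(r, abs=1e-8)
        assert pearson([-slope * v + shift for v in xs], ys) == pytest.approx(-r, abs=1e-8)


class TestEntropy:
    def test_uniform_and_degenerate(self):
        assert entropy(DiscreteDistribution(("a", "b"), (0.5, 0.5))) == pytest.approx(1.0)
        assert entropy(DiscreteDistribution(("a",), (1.0,))) == 0.0
        assert entropy(DiscreteDistribution(("a", "b"), (1.0, 0.0))) == 0.0

    def test_mortality_entropy_pinned(self, mortality):
        assert entropy(mortality) == pytest.approx(H_MORTALITY, abs=1e-12)

    def test_invalid_distribution(self):
        with pytest.raises(Exception):
            DiscreteDistribution(("a", "b"), (0.6, 0.6))

    def test_empirical_distribution_counts(self, mortality):
        d = empirical_distribution(mortality)
        assert sorted(d.support) == [18, 43, 59, 62, 86, 92]
        assert sum(d.probabilities) == pytest.approx(1.0)


class TestMutualInformation:
    def test_independent_product_design_is_zero(self):
        x = [0, 0, 1, 1] * 3
        y = [0, 1, 0, 1] * 3
        assert mutual_information(x, y) == pytest.approx(0.0, abs=1e-12)
        assert normalized_mi(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_injective_relabeling_gives_marginal_entropy(self):
        x = [1, 1, 2, 3, 3, 3]
        y = ["a", "a", "b", "c", "c", "c"]
        assert mutual_information(x, y) == pytest.approx(entropy(x), abs=1e-12)
        assert normalized_mi(x, y) == pytest.approx(1.0)

    def test_distinct_scores_capture_full_outcome_entropy(self, table4, mortality):
        # the cubic score takes 12 distinct values on the 12 rows, so the
        # plug-in MI with mortality saturates at H(mortality)
        xs = table4.score_column(CUBES)
        assert len(set(xs)) == len(xs)
        assert mutual_information(xs, mortality) == pytest.approx(H_MORTALITY, abs=1e-12)

    def test_symmetry(self, table4, mortality):
        xs = table4.score_column(ISS)
        assert mutual_information(xs, mortality) == pytest.approx(
            mutual_information(mortality, xs), abs=1e-12
        )

    def test_two_formulas_agree(self, table4, mortality):
        # H(X) - H(X|Y) against H(X) + H(Y) - H(X,Y), two code paths
        xs = table4.score_column(ISS)
        via_conditional = mutual_information(xs, mortality)
        via_joint = entropy(xs) + entropy(mortality) - joint_entropy(xs, mortality)
        assert via_conditional == pytest.approx(via_joint, abs=1e-12)
        assert conditional_entropy(xs, xs) == pytest.approx(0.0, abs=1e-12)

    def test_mortality_nmi_ordering(self, table4, mortality):
        nmis = {
            spec.name: normalized_mi(table4.score_column(spec), mortality)
            for spec in (SUM, ISS, CUBES)
        }
        assert nmis["cubes"] > nmis["iss"] > nmis["sum"]
        assert nmis["cubes"] == pytest.approx(0.801257, abs=1e-6)
        assert nmis["iss"] == pytest.approx(0.766897, abs=1e-6)
        assert nmis["sum"] == pytest.approx(0.523306, abs=1e-6)

    def test_nmi_undefined_for_two_constants(self):
        with pytest.raises(UndefinedStatisticError):
            normalized_mi([1, 1, 1], [2, 2, 2])

    @settings(derandomize=True, max_examples=100)
    @given(
        pairs=st.lists(
            st.tuples(st.integers(0, 3), st.integers(0, 3)), min_size=2, max_size=30
        )
    )
    def test_nmi_bounds_and_mi_nonnegative(self, pairs):
        x, y = zip(*pairs)
        assert mutual_information(x, y) >= 0.0
        if entropy(x) + entropy(y) > 0:
            assert 0.0 <= normalized_mi(x, y) <= 1.0 + 1e-12


class TestPermutationTest:
    def test_identity_pearson_attains_minimum_p(self):
        x = list(np.arange(20.0))
        assert permutation_pvalue(x, x, statistic="pearson", n_perm=999, seed=3) == pytest.approx(1 / 1000)

    def test_identity_nmi_with_ties_attains_minimum_p(self):
        x = [v for v in range(10) for _ in range(2)]
        assert permutation_pvalue(x, x, statistic="nmi", n_perm=999, seed=3) == pytest.approx(1 / 1000)

    def test_distinct_valued_column_degenerates_for_mi(self, table4, mortality):
        # every permutation of the outcome column is still an injective
        # relabelling of a 12-distinct-value score, so plug-in MI never moves
        xs = table4.score_column(CUBES)
        assert permutation_pvalue(xs, mortality, statistic="mi", n_perm=200, seed=0) == 1.0

    def test_pearson_on_mortality_is_significant(self, table4, mortality):
        xs = table4.score_column(CUBES)
        p = permutation_pvalue(xs, mortality, statistic="pearson", n_perm=999, seed=0)
        assert p < 0.01

    def test_null_behavior_independent_columns(self):
        rng = np.random.default_rng(42)
        x = list(rng.integers(0, 3, size=60))
        y = list(rng.integers(0, 3, size=60))
        assert permutation_pvalue(x, y, statistic="nmi", n_perm=499, seed=1) > 0.05

    def test_reproducible_for_fixed_seed(self, table4, mortality):
        xs = table4.score_column(ISS)
        args = dict(statistic="nmi", n_perm=99, seed=7)
        assert permutation_pvalue(xs, mortality, **args) == permutation_pvalue(xs, mortality, **args)


class TestVarianceArtifact:
    @pytest.mark.parametrize(
        "pair, expected",
        [
            ((((5, 2, 2), (5, 3, 0))), 0.5),
            ((((5, 3, 2), (5, 4, 0))), 4.5),
            ((((5, 3, 3), (5, 4, 1))), 0.5),
        ],
    )
    def test_consecutive_rank_samples(self, pair, expected):
        scores = [score(make_profile(g), ISS) for g in pair]
        assert sample_variance(scores) == expected

    def test_constant_sample(self):
        assert sample_variance([7.0, 7.0, 7.0]) == 0.0

    def test_too_few_values(self):
        with pytest.raises(Exception):
            sample_variance([1.0])


class TestGapReport:
    def test_iss_gaps_are_uneven(self):
        rep = cardinality_gap_report(ISS)
        rows = {rank: (score_, gap) for rank, score_, gap in rep.rows}
        assert rows[32] == (38, 3)   # 38 -> 41
        assert rows[34] == (42, 1)   # 42 -> 43
        assert rep.gaps_monotone is False

    def test_sum_gaps_all_one(self):
        rep = cardinality_gap_report(SUM)
        assert all(gap == 1 for _, _, gap in rep.rows[:-1])
        assert rep.rows[-1][2] is None
        assert rep.gaps_monotone is True


class TestOutcomeTable:
    def test_bundled_table_shape(self, table4):
        assert len(table4) == 12
        assert sorted(set(table4.outcomes)) == [18, 43, 59, 62, 86, 92]

    def test_csv_round_trip(self, table4, tmp_path):
        path = tmp_path / "t.csv"
        table4.to_csv(path)
        back = OutcomeTable.from_csv(path)
        assert back.profiles == table4.profiles
        assert back.outcomes == table4.outcomes

    def test_rejects_single_row(self):
        with pytest.raises(Exception):
            OutcomeTable((make_profile((1, 0, 0)),), (1.0,))
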