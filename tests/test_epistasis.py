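"""Split enumeration, additive expectations, epsilon and the interaction taxonomy."""

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epideconv import (
    Thresholds,
    additive_expectation,
    analyze_all,
    classify_epistasis,
    enumerate_splits,
    epistasis_epsilon,
    summarize_types,
)
from epideconv.epistasis import LABELS, CombinationSplit

from conftest import make_dataset, random_dataset


class TestEnumerateSplits:
    def test_three_sites_seven_table_rows(self):
        splits = enumerate_splits(3, mode="paper")
        assert len(splits) == 7
        kinds = [s.kind for s in splits]
        assert kinds.count("B") == 6 and kinds.count("T") == 1

    def test_two_sites_single_split(self):
        splits = enumerate_splits(2, mode="paper")
        assert len(splits) == 1
        assert splits[0].parts == (frozenset({0}), frozenset({1}))

    def test_four_sites_against_bruteforce(self):
        # oracle: count unordered disjoint nonempty pairs by direct enumeration
        pairs = set()
        universe = range(4)
        subsets = [
            frozenset(c)
            for k in range(1, 5)
            for c in combinations(universe, k)
        ]
        for a in subsets:
            for b in subsets:
                if a and b and not (a & b):
                    pairs.add(frozenset((a, b)))
        assert len(pairs) == 25
        assert len(enumerate_splits(4, mode="paper")) == 26  # + all-singles split
        assert len(enumerate_splits(4, mode="binary_only")) == 25

    def test_deterministic_order_no_duplicates(self):
        splits = enumerate_splits(4, mode="all_kway")
        assert splits == enumerate_splits(4, mode="all_kway")
        assert len(splits) == len(set(splits))

    def test_too_few_sites(self):
        with pytest.raises(ValueError):
            enumerate_splits(1)


class TestAdditiveExpectation:
    def test_single_part_is_identity(self, bm3):
        expected, sem = additive_expectation(bm3, [{1, 2}], "ddg")
        assert expected == pytest.approx(bm3.value("-II", "ddg"))
        assert sem == pytest.approx(bm3.sem("-II", "ddg"))

    def test_two_part_expectation_sums_effects(self, bm3):
        expected, _ = additive_expectation(bm3, [{2}, {0, 1}], "ddg")
        parent = bm3.value("---", "ddg")
        w = bm3.value("--I", "ddg") - parent
        w2 = bm3.value("II-", "ddg") - parent
        assert expected == pytest.approx(parent + w + w2)

    def test_zero_noise_additive_data_exact(self, additive_zero_noise):
        ds = additive_zero_noise
        for split in enumerate_splits(3, mode="paper"):
            expected, _ = additive_expectation(ds, split.parts, "f")
            observed = ds.value(split.union_genotype(ds), "f")
            assert expected == pytest.approx(observed, abs=1e-9)

    def test_singles_sum_to_published_expectation(self, bm3):
        expected, sem = additive_expectation(bm3, [{0}, {1}, {2}], "ddg")
        assert expected == pytest.approx(-3.45, abs=1e-9)
        assert sem == pytest.approx(0.25, abs=1e-6)


class TestEpistasisEpsilon:
    def test_selectivity_tertiary_worked_example(self, bm3):
        split = CombinationSplit((frozenset({0}), frozenset({1}), frozenset({2})))
        r = epistasis_epsilon(bm3, split, "ddg")
        assert r.observed == pytest.approx(5.6)
        assert r.expected == pytest.approx(-3.45)
        assert r.epsilon == pytest.approx(9.05)

    def test_ttf_binary_from_published_series(self):
        ds = make_dataset({"---": 11, "-I-": 11, "--I": 21, "-II": 72}, trait="ttf")
        split = CombinationSplit((frozenset({1}), frozenset({2})))
        r = epistasis_epsilon(ds, split, "ttf")
        assert r.epsilon == pytest.approx(72 - 11 - 21 + 11)  # = 51

    def test_zero_noise_additive_epsilon_zero(self, additive_zero_noise):
        table = analyze_all(additive_zero_noise, mode="all_kway")
        assert table.results
        for r in table.results:
            assert r.epsilon == pytest.approx(0.0, abs=1e-9)
            assert r.label == "ADD"

    def test_epsilon_symmetric_under_part_permutation(self, rng):
        ds = random_dataset(rng, 3)
        a = epistasis_epsilon(ds, CombinationSplit((frozenset({0}), frozenset({1, 2}))), "f")
        b = epistasis_epsilon(ds, CombinationSplit((frozenset({1, 2}), frozenset({0}))), "f")
        assert a.epsilon == b.epsilon and a.sem_epsilon == b.sem_epsilon

    def test_sem_propagation_quadrature(self, rng):
        ds = random_dataset(rng, 3, sems=True)
        split = CombinationSplit((frozenset({0}), frozenset({1}), frozenset({2})))
        r = epistasis_epsilon(ds, split, "f")
        sems = {g.label: ds.sem(g, "f") for g in ds.genotypes()}
        expected_var = (
            sems["III"] ** 2
            + sems["I--"] ** 2 + sems["-I-"] ** 2 + sems["--I"] ** 2
            + 4 * sems["---"] ** 2
        )
        assert r.sem_epsilon == pytest.approx(math.sqrt(expected_var))


class TestClassification:
    @pytest.mark.parametrize(
        "w_parts, w_combined, expected_label",
        [
            # both beneficial
            ((2, 3), 9, "+ME"),
            ((2, 3), 3, "-ME"),
            ((2, 3), -4, "-RSE"),
            # both deleterious
            ((-2, -3), -9, "-ME"),
            ((-2, -3), -3, "+ME"),
            ((-2, -3), 4, "+RSE"),
            # mixed signs
            ((-2, 5), 7, "+SE"),
            ((-2, 5), -1, "-SE"),
            ((2, -5), -7, "-SE"),
            # three parts, taxonomy generalized by shared sign
            ((2, 3, 4), 20, "+ME"),
            ((-2, -3, -4), 5, "+RSE"),
            ((-2, 3, 4), 9, "+SE"),
        ],
    )
    def test_taxonomy_truth_table(self, w_parts, w_combined, expected_label):
        epsilon = w_combined - sum(w_parts)
        label, marginal = classify_epistasis(w_parts, w_combined, epsilon, 0.0)
        assert label == expected_label and marginal == ()

    def test_exact_additivity(self):
        label, _ = classify_epistasis((1, 1), 2, 0.0, 0.0)
        assert label == "ADD"

    def test_sub_threshold_epsilon_is_additive(self):
        label, _ = classify_epistasis((1, 1), 2.3, 0.3, sem_epsilon=0.5)
        assert label == "ADD"

    def test_orientation_flips_beneficial(self):
        # lower-is-better: two decreases are beneficial; ME keeps epsilon's oriented sign
        label, _ = classify_epistasis((-2, -3), -9, -4, 0.0, higher_is_better=False)
        assert label == "+ME"

    def test_marginal_part_grouped_with_majority(self):
        # one effect within 1 SEM of zero: grouped with the other's sign -> ME, flagged
        label, marginal = classify_epistasis(
            (0.05, 3.0), 5.0, 1.95, 0.1, sem_w_parts=(0.2, 0.2)
        )
        assert label == "+ME" and marginal == (0,)

    @settings(derandomize=True, max_examples=500)
    @given(
        w=st.lists(st.floats(-10, 10), min_size=2, max_size=4),
        wc=st.floats(-30, 30),
        higher=st.booleans(),
    )
    def test_total_on_every_input(self, w, wc, higher):
        epsilon = wc - sum(w)
        label, _ = classify_epistasis(
            tuple(w), wc, epsilon, 0.0, higher_is_better=higher
        )
        assert label in LABELS


class TestAnalyzeAndSummaries:
    def test_fixture_selectivity_counts(self, bm3):
        table = analyze_all(bm3, traits=["ddg"])
        summary = summarize_types(table.for_trait("ddg"))
        assert summary["counts"] == {"+ME": 1, "+SE": 6}
        assert summary["percent"] == {"+ME": 14, "+SE": 86}
        # the single ME is the (R47I, T49I) pair
        me = [r for r in table.results if r.label == "+ME"]
        assert len(me) == 1 and me[0].resulting_genotype == "II-"

    def test_incomplete_split_skipped_with_reason(self, bm3, rng):
        ds = make_dataset({"---": 0, "I--": 1, "-I-": 2, "II-": 5})
        table = analyze_all(ds, mode="binary_only")
        done = {r.resulting_genotype for r in table.results}
        assert done == {"II-"}
        assert all("unmeasured" in reason for _, _, reason in table.skipped)

    def test_sign_percentages(self):
        from epideconv.epistasis import EpistasisResult

        def fake(label):
            split = CombinationSplit((frozenset({0}), frozenset({1})))
            return EpistasisResult(
                split, "f", "a + b -> ab", "ab", (1, 1), (0, 0), 2, 0,
                2, 0, 2, 0, 0, 0, label=label,
            )

        results = [fake("+SE")] * 5 + [fake("-SE")] + [fake("+RSE")]
        summary = summarize_types(results)
        assert summary["sign_percent"] == {"positive": 86, "negative": 14}

    def test_summarize_requires_results(self):
        with pytest.raises(ValueError):
            summarize_types([])


class TestSemEpsilonMonteCarlo:
    def test_propagated_sem_matches_resampling(self, rng):
        """Propagated sem_epsilon vs 1e5 normal perturbations of the means."""
        ds = random_dataset(rng, 3, sems=True)
        split = CombinationSplit((frozenset({0}), frozenset({1, 2})))
        r = epistasis_epsilon(ds, split, "f")
        labels = ["---", "I--", "-II", "III"]
        coeff = {"III": 1.0, "I--": -1.0, "-II": -1.0, "---": 1.0}
        draws = np.zeros(100_000)
        for lab in labels:
            draws += coeff[lab] * rng.normal(
                ds.value(lab, "f"), ds.sem(lab, "f"), draws.shape
            )
        assert r.sem_epsilon == pytest.approx(np.std(draws), rel=0.10)
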