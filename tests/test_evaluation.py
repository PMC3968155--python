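import numpy as np
import pytest

from memtype import (
    MembraneType,
    breakdown_by_type_count,
    evalue_sweep,
    loo_evaluate,
    multilabel_accuracy,
    precision_recall,
)
from memtype.evaluation import PredictionRecord, record_accuracy
from memtype.homology import BuiltinAligner
from memtype.synth import SynthConfig, generate_dataset

T = MembraneType


def rec(actual, predicted, stage="m"):
    return PredictionRecord(
        id="x", actual=frozenset(T(i) for i in actual),
        predicted=None if predicted is None else frozenset(T(i) for i in predicted),
        stage=stage)


class TestPrecisionRecall:
    def test_half_overlap(self):
        precision, recall = precision_recall([rec({1, 2}, {2, 3})])
        assert precision == pytest.approx(0.5)
        assert recall == pytest.approx(0.5)

    def test_superset_prediction_has_recall_one(self):
        # predicting every type trivially covers the truth
        _, recall = precision_recall([rec({1, 2}, {1, 2, 3, 4, 5, 6})])
        assert recall == 1.0

    def test_nonempty_subset_prediction_has_precision_one(self):
        precision, _ = precision_recall([rec({1, 2, 3}, {2})])
        assert precision == 1.0

    def test_empty_record_list_rejected(self):
        with pytest.raises(ValueError):
            precision_recall([])


class TestMultilabelAccuracy:
    def test_exact_match_scores_one_under_both_variants(self):
        records = [rec({1, 2}, {1, 2}), rec({3}, {3})]
        assert multilabel_accuracy(records) == 1.0
        assert multilabel_accuracy(records, "jaccard") == 1.0

    def test_extra_type_penalized(self):
        r = rec({1}, {1, 2})
        assert record_accuracy(r) == pytest.approx(0.5)  # 1 - 1/2
        assert record_accuracy(r, "jaccard") == pytest.approx(0.5)

    def test_disjoint_prediction_extremes(self):
        r = rec({1}, {2})
        assert record_accuracy(r) == pytest.approx(-1.0)
        assert record_accuracy(r, "jaccard") == pytest.approx(0.0)

    def test_variant_bounds_and_exactness_iff_equal(self, rng):
        types = list(range(1, 7))
        for _ in range(50):
            actual = set(rng.choice(types, size=int(rng.integers(1, 4)), replace=False))
            predicted = set(rng.choice(types, size=int(rng.integers(1, 4)), replace=False))
            r = rec(actual, predicted)
            default = record_accuracy(r)
            jaccard = record_accuracy(r, "jaccard")
            assert -1.0 <= default <= 1.0
            assert 0.0 <= jaccard <= 1.0
            assert (default == 1.0) == (actual == predicted)
            assert (jaccard == 1.0) == (actual == predicted)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            multilabel_accuracy([rec({1}, {1})], variant="f1")


class TestBreakdownByTypeCount:
    def test_cpe_classification(self):
        records = [
            rec({1, 2}, {1, 2}),  # c
            rec({1, 2}, {1}),     # p
            rec({1, 2}, {1, 3}),  # p
            rec({1}, {3}),        # e
            rec({1}, {1}),        # c
        ]
        out = breakdown_by_type_count(records)
        assert (out[2].c, out[2].p, out[2].e) == (1, 2, 0)
        assert (out[1].c, out[1].p, out[1].e) == (1, 0, 1)

    def test_partition_per_multiplicity_group(self, rng):
        types = list(range(1, 7))
        records = []
        for _ in range(60):
            actual = set(rng.choice(types, size=int(rng.integers(1, 4)), replace=False))
            predicted = set(rng.choice(types, size=int(rng.integers(1, 4)), replace=False))
            records.append(rec(actual, predicted))
        out = breakdown_by_type_count(records)
        by_mult = {}
        for r in records:
            by_mult[len(r.actual)] = by_mult.get(len(r.actual), 0) + 1
        for mult, cpe in out.items():
            assert cpe.total == by_mult[mult]


@pytest.fixture(scope="module")
def duplicated_families():
    # every protein has an exact duplicate family member
    return generate_dataset(SynthConfig(
        n_proteins=24, n_families=12, mutation_rate=0.0, seed=3))


@pytest.fixture(scope="module")
def decoy_world():
    config = SynthConfig(n_proteins=45, n_families=30, mutation_rate=0.0,
                         decoy_fraction=0.5, seed=11)
    dataset, _, _ = generate_dataset(config)
    return dataset


class TestLooEvaluate:
    def test_one_record_per_protein(self, duplicated_families):
        dataset, interactions, _ = duplicated_families
        report = loo_evaluate(dataset, interactions, method="integrated")
        assert len(report.records) == len(dataset)
        assert report.nu == 0

    def test_planted_duplicates_make_homology_perfect(self, duplicated_families):
        dataset, interactions, _ = duplicated_families
        report = loo_evaluate(dataset, interactions, method="homology")
        assert report.nu == 0
        assert report.accuracy == 1.0
        assert report.precision == report.recall == 1.0

    def test_stage_na_counts_partition_the_dataset(self, duplicated_families):
        dataset, interactions, _ = duplicated_families
        report = loo_evaluate(dataset, interactions, method="integrated")
        assert sum(st.na for st in report.per_stage.values()) + report.nu == len(dataset)

    def test_single_method_abstentions_counted_as_nu(self, duplicated_families):
        dataset, _, _ = duplicated_families
        # no interactions at all: network-only leaves every protein unannotated
        report = loo_evaluate(dataset, method="network")
        assert report.nu == len(dataset)
        assert report.accuracy is None

    def test_reports_are_reproducible(self, duplicated_families):
        dataset, interactions, _ = duplicated_families
        r1 = loo_evaluate(dataset, interactions, method="integrated")
        r2 = loo_evaluate(dataset, interactions, method="integrated")
        assert r1.records == r2.records
        assert r1.accuracy == r2.accuracy

    def test_unknown_method_rejected(self, duplicated_families):
        dataset, interactions, _ = duplicated_families
        with pytest.raises(ValueError):
            loo_evaluate(dataset, interactions, method="oracle")


class TestEvalueSweep:
    def test_nu_monotone_non_increasing_in_cutoff(self, decoy_world):
        table = evalue_sweep(decoy_world, cutoffs=(1e-10, 0.01, 10.0))
        nu = table["NU"].tolist()
        assert nu == sorted(nu, reverse=True)

    def test_cutoff_below_every_hit_annotates_nothing(self, decoy_world):
        table = evalue_sweep(decoy_world, cutoffs=(1e-300, 10.0))
        assert table.loc[0, "NU"] == len(decoy_world)
        assert np.isnan(table.loc[0, "Acc"])

    def test_loose_gate_admits_false_homologs_and_lowers_accuracy(self, decoy_world):
        provider = BuiltinAligner()
        table = evalue_sweep(decoy_world, provider=provider, cutoffs=(0.01, 10.0))
        acc_strict = table.loc[0, "Acc"]
        acc_loose = table.loc[1, "Acc"]
        assert table.loc[1, "NA"] > table.loc[0, "NA"]
        assert acc_loose < acc_strict

    def test_fewer_than_two_cutoffs_rejected(self, decoy_world):
        with pytest.raises(ValueError):
            evalue_sweep(decoy_world, cutoffs=(0.01,))
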