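import math

import numpy as np
import pytest
from sklearn.metrics import (
    f1_score,
    matthews_corrcoef,
    mean_absolute_error,
    precision_score,
    r2_score,
    recall_score,
)

from borysite import (
    ConfusionCounts,
    CurationConfig,
    curate,
    major_product_accuracy,
    make_splits,
    mcc,
    molecule_accuracy,
    regression_metrics,
    site_metrics,
)


class TestMcc:
    def test_perfect(self):
        assert mcc(ConfusionCounts(TP=5, TN=5, FP=0, FN=0)) == 1.0

    def test_degenerate_denominator_is_zero(self):
        assert mcc(ConfusionCounts(TP=0, FP=0, TN=4, FN=2)) == 0.0

    def test_hand_value(self):
        # numerator 3*5 - 1*1 = 14; denominator 4*4*6*6 = 576
        value = mcc(ConfusionCounts(TP=3, TN=5, FP=1, FN=1))
        assert value == pytest.approx(14 / math.sqrt(576), abs=1e-15)
        assert value == pytest.approx(matthews_corrcoef([1]*4 + [0]*6,
                                                        [1, 1, 1, 0, 1, 0, 0, 0, 0, 0]),
                                      abs=1e-12)

    def test_agrees_with_sklearn_on_random_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            y = rng.integers(0, 2, size=30)
            p = rng.integers(0, 2, size=30)
            ours = mcc(ConfusionCounts.from_labels(y.tolist(), p.tolist()))
            assert ours == pytest.approx(matthews_corrcoef(y, p), abs=1e-12)


class TestSiteMetrics:
    def test_hand_example(self):
        rep = site_metrics([1, 0, 0, 1], [1, 1, 0, 0])
        assert rep.site_accuracy == 0.5
        assert rep.ppv == 0.5
        assert rep.recall == 0.5
        assert rep.f1 == 0.5
        assert rep.mcc == 0.0

    def test_all_correct(self):
        rep = site_metrics([1, 0, 1], [1, 0, 1])
        assert (rep.site_accuracy, rep.f1, rep.mcc) == (1.0, 1.0, 1.0)

    def test_matches_sklearn_suite(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            y = rng.integers(0, 2, size=40)
            p = rng.integers(0, 2, size=40)
            rep = site_metrics(y.tolist(), p.tolist())
            assert rep.ppv == pytest.approx(
                precision_score(y, p, zero_division=0), abs=1e-12
            )
            assert rep.recall == pytest.approx(
                recall_score(y, p, zero_division=0), abs=1e-12
            )
            assert rep.f1 == pytest.approx(
                f1_score(y, p, zero_division=0), abs=1e-12
            )

    def test_joint_permutation_invariance(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, size=50)
        p = rng.integers(0, 2, size=50)
        order = rng.permutation(50)
        a = site_metrics(y.tolist(), p.tolist())
        b = site_metrics(y[order].tolist(), p[order].tolist())
        assert a.as_dict() == b.as_dict()

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            site_metrics([1, 0], [1])


class TestMoleculeAccuracy:
    def test_half_correct(self):
        grouped = {"a": [(1, 1), (0, 0)], "b": [(1, 0), (0, 0)]}
        assert molecule_accuracy(grouped) == 0.5

    def test_one_iff_site_accuracy_one(self):
        grouped = {"a": [(1, 1)], "b": [(0, 0), (1, 1)]}
        assert molecule_accuracy(grouped) == 1.0

    def test_bounded_by_macro_site_accuracy(self):
        rng = np.random.default_rng(9)
        grouped = {
            str(i): [
                (int(rng.integers(0, 2)), int(rng.integers(0, 2)))
                for _ in range(rng.integers(1, 6))
            ]
            for i in range(30)
        }
        macro = np.mean(
            [np.mean([y == p for y, p in v]) for v in grouped.values()]
        )
        assert molecule_accuracy(grouped) <= macro + 1e-12

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            molecule_accuracy({})


class TestMajorProductAccuracy:
    def test_perfect_regressor(self):
        grouped = {
            "a": [(0, 80.0, 75.0), (1, 3.0, None)],
            "b": [(2, 60.0, 50.0), (3, 10.0, 20.0)],
        }
        # b: experimental major is site 3 (20 > ... wait 50 > 20 -> site 2)
        acc, excluded = major_product_accuracy(grouped)
        assert acc == 1.0
        assert excluded == 0

    def test_tied_experimental_majors_both_count(self):
        grouped = {"a": [(0, 9.0, 50.0), (1, 8.0, 50.0)]}
        acc, _ = major_product_accuracy(grouped)
        assert acc == 1.0

    def test_unlabeled_substrate_excluded(self):
        grouped = {
            "a": [(0, 5.0, 60.0)],
            "b": [(0, 5.0, None)],
        }
        acc, excluded = major_product_accuracy(grouped)
        assert acc == 1.0
        assert excluded == 1


class TestRegressionMetrics:
    def test_perfect_fit(self):
        block = regression_metrics([0, 10, 50], [0, 10, 50])
        assert block["r2"] == 1.0
        assert block["mae"] == 0.0
        assert block["rmse"] == 0.0
        assert block["outcome_mcc"] == 1.0

    def test_anticorrelated_outcomes(self):
        block = regression_metrics([0, 10], [10, 0], success_threshold=5)
        assert block["outcome_mcc"] == -1.0

    def test_hand_example(self):
        block = regression_metrics([0, 0, 50, 100], [0, 0, 60, 90])
        assert block["mae"] == pytest.approx(5.0)
        assert block["rmse"] == pytest.approx(math.sqrt(50))

    def test_matches_sklearn(self):
        rng = np.random.default_rng(2)
        y = rng.uniform(0, 100, 100)
        yhat = rng.uniform(0, 100, 100)
        block = regression_metrics(y, yhat)
        assert block["r2"] == pytest.approx(r2_score(y, yhat), abs=1e-12)
        assert block["mae"] == pytest.approx(mean_absolute_error(y, yhat), abs=1e-12)

    def test_constant_truth_warns_nan_r2(self):
        with pytest.warns(UserWarning):
            block = regression_metrics([5, 5, 5], [4, 5, 6])
        assert math.isnan(block["r2"])


@pytest.fixture(scope="module")
def curated(tiny_synthetic):
    retained, _ = curate(
        tiny_synthetic, CurationConfig(require_yield=True, require_ir=True)
    )
    return retained


class TestSplits:
    def test_random_split_is_disjoint_and_covers(self, curated):
        spec = make_splits(curated, "random", seed=7)
        substrates = {r.substrate.smiles for r in curated}
        assert spec.train | spec.test == substrates
        assert spec.train & spec.test == set()
        assert spec.test

    def test_random_split_seed_determinism(self, curated):
        a = make_splits(curated, "random", seed=3)
        b = make_splits(curated, "random", seed=3)
        assert a.test == b.test

    def test_ring_type_partitions(self, curated):
        het, carb, ambiguous = make_splits(curated, "ring_type")
        substrates = {r.substrate.smiles for r in curated}
        assert het.test | carb.test == substrates
        assert het.test & carb.test == set()

    def test_ring_count_partitions(self, curated):
        one, mult = make_splits(curated, "ring_count")
        substrates = {r.substrate.smiles for r in curated}
        assert one.test | mult.test == substrates
        assert one.test & mult.test == set()

    def test_named_memberships(self):
        from borysite import parse_reaction

        indole_bpin = "CC1(C)OB(OC1(C)C)c1cc2ccccc2[nH]1"
        biphenyl_bpin = "CC1(C)OB(OC1(C)C)c1ccc(-c2ccccc2)cc1"
        phbpin = "CC1(C)OB(OC1(C)C)c1ccccc1"
        records, _ = curate(
            [
                parse_reaction(f"c1ccc2[nH]ccc2c1>[Ir]>{indole_bpin}"),
                parse_reaction(f"c1ccccc1>[Ir]>{phbpin}"),
                parse_reaction(f"c1ccc(-c2ccccc2)cc1>[Ir]>{biphenyl_bpin}"),
            ]
        )
        assert len(records) == 3
        het, carb, _ = make_splits(records, "ring_type")
        one, mult = make_splits(records, "ring_count")
        indole = "c1ccc2[nH]ccc2c1"
        benzene = "c1ccccc1"
        biphenyl = "c1ccc(-c2ccccc2)cc1"
        assert indole in het.test
        assert benzene in carb.test and benzene in one.test
        assert biphenyl in mult.test

    def test_ring_type_requires_site_labels(self, benzene, phbpin):
        from borysite import ReactionRecord

        rec = ReactionRecord(reactants=[benzene], agents=[], products=[phbpin])
        with pytest.raises(ValueError):
            make_splits([rec], "ring_type")
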