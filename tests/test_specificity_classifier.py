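import itertools

import numpy as np
import pandas as pd
import pytest

from tissuespec import (
    SpecificityParams,
    category_census,
    classify_all,
    classify_gene,
    find_enriched_group,
    specificity_score,
)
from tissuespec.specificity_classifier import ELEVATED

from conftest import random_fpkm_row

PARAMS = SpecificityParams(target_tissue="T0")


def row_over(values, target_first=True, prefix="T"):
    labels = [f"{prefix}{i}" for i in range(len(values))]
    return pd.Series(list(values), index=labels, name="g", dtype=float)


def exhaustive_group(row: pd.Series, params: SpecificityParams):
    """Independent oracle: enumerate every subset of allowed size that
    contains the target and test the fold condition; return the minimal
    qualifying size, or None."""
    labels = list(row.index)
    values = row.to_numpy(dtype=float)
    t_idx = labels.index(params.target_tissue)
    n = len(labels)
    for k in range(params.group_min, min(params.group_max, n) + 1):
        for combo in itertools.combinations(range(n), k):
            if t_idx not in combo:
                continue
            outside = [values[i] for i in range(n) if i not in combo]
            max_out = max(outside) if outside else 0.0
            if min(values[i] for i in combo) >= params.fold * max_out:
                return k
    return None


class TestSpecificityScore:
    def test_fold_over_runner_up(self):
        assert specificity_score(row_over([10.0, 2.0, 1.0]), "T0") == 5.0

    def test_exclusive_expression_is_infinite(self):
        assert specificity_score(row_over([3.0, 0.0, 0.0]), "T0") == np.inf

    def test_silent_target_scores_zero(self):
        assert specificity_score(row_over([0.0, 4.0, 1.0]), "T0") == 0.0

    def test_all_zero_is_undefined(self):
        assert np.isnan(specificity_score(row_over([0.0, 0.0, 0.0]), "T0"))

    def test_missing_target_raises(self):
        with pytest.raises(KeyError):
            specificity_score(row_over([1.0, 2.0]), "nope")


class TestFindEnrichedGroup:
    def test_pair_dominating_the_panel(self):
        row = row_over([8.0, 7.0] + [1.0] * 25)
        assert find_enriched_group(row, PARAMS) == ("T0", "T1")

    def test_runner_up_below_fold_blocks_any_group(self):
        row = row_over([8.0, 3.0] + [1.0] * 25)
        assert exhaustive_group(row, PARAMS) is None  # oracle agrees
        assert find_enriched_group(row, PARAMS) is None

    @pytest.mark.parametrize("seed", range(10))
    def test_prefix_scan_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        tissues = [f"T{i}" for i in range(10)]
        params = SpecificityParams(target_tissue="T0")
        for _ in range(20):
            row = random_fpkm_row(rng, tissues)
            expected = exhaustive_group(row, params)
            found = find_enriched_group(row, params)
            if expected is None:
                assert found is None
            else:
                assert found is not None and len(found) == expected
                members = row[list(found)].to_numpy()
                outside = row.drop(list(found)).to_numpy()
                max_out = outside.max() if outside.size else 0.0
                assert members.min() >= params.fold * max_out
                assert "T0" in found

    def test_returned_group_contains_target_and_respects_size(self):
        row = row_over([50.0, 45.0, 40.0, 35.0] + [1.0] * 23)
        group = find_enriched_group(row, PARAMS)
        assert group is not None
        assert "T0" in group
        assert PARAMS.group_min <= len(group) <= PARAMS.group_max


class TestClassifyGene:
    def test_enriched_with_score(self):
        cls = classify_gene(row_over([10.0, 2.0, 1.0, 0.4]), PARAMS)
        assert cls.category == "tissue_enriched"
        assert cls.score == 5.0

    def test_below_cutoff_not_detected(self):
        cls = classify_gene(row_over([0.5, 0.0, 0.0]), PARAMS)
        assert cls.category == "not_detected"

    def test_enhanced_beats_mean_but_not_runner_up(self):
        # 27 tissues: mean 39/27 ~ 1.444, 10 >= 5 x 1.444 but 10 < 5 x 4,
        # and no 2-7 group exists since 4 < 5 x 1
        row = row_over([10.0, 4.0] + [1.0] * 25)
        assert exhaustive_group(row, PARAMS) is None
        cls = classify_gene(row, PARAMS)
        assert cls.category == "tissue_enhanced"

    def test_flat_panel_expressed_in_all(self):
        cls = classify_gene(row_over([2.0] * 27), PARAMS)
        assert cls.category == "expressed_in_all"
        assert cls.n_detected == 27

    def test_partial_detection_is_mixed(self):
        row = row_over([2.0] * 10 + [0.0] * 17)
        assert classify_gene(row, PARAMS).category == "mixed"


class TestClassifyAll:
    @pytest.fixture()
    def toy_profile(self):
        return pd.DataFrame(
            [[10.0, 2.0, 1.0, 0.4] + [0.0] * 23,
             [0.5] + [0.0] * 26,
             [10.0, 4.0] + [1.0] * 25,
             [2.0] * 27],
            index=["enriched", "nd", "enhanced", "ubiquitous"],
            columns=[f"T{i}" for i in range(27)],
        )

    def test_toy_census(self, toy_profile):
        census = category_census(classify_all(toy_profile, PARAMS))
        assert census["tissue_enriched"] == 1
        assert census["not_detected"] == 1
        assert census["tissue_enhanced"] == 1
        assert census["expressed_in_all"] == 1
        assert census["elevated"] == 2

    def test_census_partitions_genes(self, toy_profile):
        census = category_census(classify_all(toy_profile, PARAMS))
        total = sum(v for k, v in census.items() if k != "elevated")
        assert total == len(toy_profile)

    def test_matches_per_gene_classification(self):
        rng = np.random.default_rng(42)
        tissues = [f"T{i}" for i in range(12)]
        params = SpecificityParams(target_tissue="T0")
        profile = pd.DataFrame(
            [random_fpkm_row(rng, tissues).to_numpy() for _ in range(100)],
            index=[f"g{i}" for i in range(100)], columns=tissues)
        table = classify_all(profile, params)
        for gene in profile.index:
            single = classify_gene(profile.loc[gene], params)
            assert table.loc[gene, "category"] == single.category
            assert table.loc[gene, "group"] == single.group
            np.testing.assert_equal(table.loc[gene, "score"], single.score)

    def test_target_boost_never_demotes_elevated(self):
        rng = np.random.default_rng(3)
        tissues = [f"T{i}" for i in range(12)]
        params = SpecificityParams(target_tissue="T0")
        profile = pd.DataFrame(
            [random_fpkm_row(rng, tissues).to_numpy() for _ in range(100)],
            index=[f"g{i}" for i in range(100)], columns=tissues)
        before = classify_all(profile, params)
        boosted = profile.copy()
        boosted["T0"] = boosted["T0"] * 3.0
        after = classify_all(boosted, params)
        was_elev = before["category"].isin(ELEVATED)
        assert after.loc[was_elev.to_numpy(), "category"].isin(ELEVATED).all()

    def test_global_rescaling_preserves_categories(self):
        rng = np.random.default_rng(4)
        tissues = [f"T{i}" for i in range(12)]
        params = SpecificityParams(target_tissue="T0")
        profile = pd.DataFrame(
            rng.uniform(2, 100, (50, 12)),  # everything detected, both scales
            index=[f"g{i}" for i in range(50)], columns=tissues)
        before = classify_all(profile, params)["category"]
        after = classify_all(profile * 7.5, params)["category"]
        assert (before == after).all()

    def test_score_at_least_fold_iff_enriched_rule(self):
        rng = np.random.default_rng(5)
        tissues = [f"T{i}" for i in range(12)]
        params = SpecificityParams(target_tissue="T0")
        profile = pd.DataFrame(
            [random_fpkm_row(rng, tissues).to_numpy() for _ in range(200)],
            index=[f"g{i}" for i in range(200)], columns=tissues)
        table = classify_all(profile, params)
        detected = profile["T0"] >= params.detection_cutoff
        rule = (table["score"] >= params.fold) & detected
        assert (rule == (table["category"] == "tissue_enriched")).all()

    def test_missing_target_tissue_raises(self, toy_profile):
        with pytest.raises(KeyError):
            classify_all(toy_profile, SpecificityParams(target_tissue="XX"))


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        SpecificityParams(target_tissue="t", detection_cutoff=0.0)
    with pytest.raises(ValueError):
        SpecificityParams(target_tissue="t", fold=1.0)
    with pytest.raises(ValueError):
        SpecificityParams(target_tissue="t", group_min=8, group_max=7)
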