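"""Filtering/imputation/normalization chain and identification statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phosphopipe.site_processing import (
    ProcessingParams,
    filter_class_one,
    filter_valid_values,
    impute_group_mean,
    log2_transform,
    median_normalize,
    residue_fraction_percentages,
    run_processing,
    summarize,
    total_peptides,
)
from phosphopipe.tables import DataError, SiteTable, StudyDesign

from conftest import make_site_table, random_table


def table_with_scores(scores):
    """One site per (locprob, delta) pair, two observed samples."""
    rows = []
    for i, (lp, ds) in enumerate(scores):
        rows.append({
            "protein_id": f"P{i:03d}", "gene_name": f"G{i:03d}",
            "position": 10 + i, "residue": "S",
            "localization_prob": lp, "delta_score": ds, "multiplicity": "1",
            "A1": 2.0, "A2": 4.0,
        })
    return SiteTable(pd.DataFrame(rows), ["A1", "A2"])


class TestClassOneFilter:
    def test_boundaries_inclusive(self):
        t = table_with_scores([(0.75, 8.0), (0.749, 100.0), (1.0, 7.999)])
        out = filter_class_one(t)
        assert len(out) == 1
        assert out.data.iloc[0]["localization_prob"] == 0.75

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(7)
        scores = list(zip(rng.uniform(0, 1, 100), rng.uniform(0, 30, 100)))
        t = table_with_scores(scores)
        out = filter_class_one(t)
        expected = [i for i, (lp, ds) in enumerate(scores) if lp >= 0.75 and ds >= 8]
        assert list(out.data["position"] - 10) == expected

    def test_idempotent_and_monotone(self):
        rng = np.random.default_rng(8)
        scores = list(zip(rng.uniform(0, 1, 50), rng.uniform(0, 30, 50)))
        t = table_with_scores(scores)
        once = filter_class_one(t)
        twice = filter_class_one(once)
        pd.testing.assert_frame_equal(once.data, twice.data)
        assert set(once.data["position"]) <= set(t.data["position"])


class TestValidValueFilter:
    samples = ["A1", "A2", "A3", "B1", "B2", "B3"]

    def _design(self):
        return StudyDesign(groups={"A": self.samples[:3], "B": self.samples[3:]})

    def test_two_of_three_in_one_group_kept(self):
        nan = math.nan
        t = make_site_table([[1, 2, nan, nan, nan, nan]], self.samples)
        out = filter_valid_values(t, self._design())
        assert len(out) == 1

    def test_one_of_three_everywhere_dropped(self):
        nan = math.nan
        t = make_site_table([[1, nan, nan, 2, nan, nan]], self.samples)
        out = filter_valid_values(t, self._design())
        assert len(out) == 0

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_matches_bruteforce_fractions(self, seed):
        rng = np.random.default_rng(seed)
        t = random_table(rng, 40, self.samples, missing_rate=0.5)
        d = self._design()
        out = filter_valid_values(t, d)
        expected = []
        for _, row in t.data.iterrows():
            ok = False
            for g, cols in d.groups.items():
                n_obs = sum(not math.isnan(row[c]) for c in cols)
                if n_obs / len(cols) >= 0.5:
                    ok = True
            if ok:
                expected.append(row["position"])
        assert list(out.data["position"]) == expected


class TestImputation:
    samples = ["A1", "A2", "A3", "B1", "B2", "B3"]

    def _design(self):
        return StudyDesign(groups={"A": self.samples[:3], "B": self.samples[3:]})

    def test_group_mean_fill(self):
        nan = math.nan
        t = make_site_table([[2, 4, nan, 1, 1, 1]], self.samples)
        out = impute_group_mean(t, self._design())
        assert out.data.loc[0, "A3"] == pytest.approx(3.0)

    def test_below_threshold_left_missing(self):
        nan = math.nan
        t = make_site_table([[nan, nan, 5, 1, 1, 1]], self.samples)
        out = impute_group_mean(t, self._design())
        assert math.isnan(out.data.loc[0, "A1"])
        assert math.isnan(out.data.loc[0, "A2"])
        assert out.data.loc[0, "A3"] == 5

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_observed_unchanged_imputed_equal_oracle(self, seed):
        rng = np.random.default_rng(seed)
        t = random_table(rng, 30, self.samples, missing_rate=0.4)
        d = self._design()
        out = impute_group_mean(t, d)
        for idx, row in t.data.iterrows():
            for g, cols in d.groups.items():
                observed = [row[c] for c in cols if not math.isnan(row[c])]
                eligible = len(observed) / len(cols) >= 0.5
                for c in cols:
                    if not math.isnan(row[c]):
                        assert out.data.loc[idx, c] == row[c]
                    elif eligible:
                        assert out.data.loc[idx, c] == pytest.approx(
                            sum(observed) / len(observed))
                    else:
                        assert math.isnan(out.data.loc[idx, c])


class TestTransforms:
    def test_log2_values(self):
        t = make_site_table([[8.0, 1.0]], ["A1", "A2"])
        out = log2_transform(t)
        assert out.data.loc[0, "A1"] == 3.0
        assert out.data.loc[0, "A2"] == 0.0
        assert out.scale == "log2"

    def test_log2_random_matches_numpy(self):
        rng = np.random.default_rng(5)
        t = random_table(rng, 20, ["A1", "A2"])
        out = log2_transform(t)
        np.testing.assert_allclose(out.intensities.to_numpy(),
                                   np.log2(t.intensities.to_numpy()))

    def test_median_shift_to_common_median(self):
        t = make_site_table([[9, 11], [10, 12], [11, 13]], ["A1", "A2"],
                            scale="log2")
        out = median_normalize(t)
        assert out.data["A1"].median() == pytest.approx(11.0)
        assert out.data["A2"].median() == pytest.approx(11.0)
        # location preserved: common median is the median of (10, 12)
        np.testing.assert_allclose(out.data["A1"], [10, 11, 12])

    def test_already_equal_is_identity(self):
        t = make_site_table([[1, 1], [2, 2], [3, 3]], ["A1", "A2"], scale="log2")
        out = median_normalize(t)
        np.testing.assert_allclose(out.intensities.to_numpy(),
                                   t.intensities.to_numpy(), atol=1e-12)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_idempotence_property(self, seed):
        rng = np.random.default_rng(seed)
        t = random_table(rng, 25, ["A1", "A2", "A3"], missing_rate=0.2,
                         scale="log2")
        once = median_normalize(t)
        medians = [once.data[s].median() for s in once.sample_ids]
        assert max(medians) - min(medians) < 1e-9
        twice = median_normalize(once)
        np.testing.assert_allclose(twice.intensities.to_numpy(),
                                   once.intensities.to_numpy(), atol=1e-9)

    def test_empty_sample_errors(self):
        t = make_site_table([[math.nan, 2.0]], ["A1", "A2"], scale="log2")
        with pytest.raises(DataError, match="A1"):
            median_normalize(t)


class TestSummaryAndChain:
    def test_residue_fraction_arithmetic(self):
        fracs = residue_fraction_percentages({"S": 17577, "T": 3424, "Y": 238})
        assert fracs == {"S": 82.76, "T": 16.12, "Y": 1.12}

    def test_total_peptides_arithmetic(self):
        assert total_peptides((17003, 2824, 571, 95)) == 20493

    def test_summary_conserves_generator_counts(self, small_study):
        stats = summarize(small_study.site_table)
        assert stats.n_sites == len(small_study.site_table)
        assert sum(stats.multiplicity_counts.values()) == stats.n_records
        assert abs(sum(stats.residue_fractions.values()) - 1.0) < 1e-12
        assert sum(stats.residue_counts.values()) == stats.n_sites

    def test_chain_preserves_metadata(self, small_study):
        result = run_processing(small_study.site_table, small_study.design)
        out = result.table
        key = ["protein_id", "position", "multiplicity"]
        merged = out.data[key].merge(small_study.site_table.data[key],
                                     on=key, how="left", indicator=True)
        assert (merged["_merge"] == "both").all()
        assert out.scale == "log2"
        assert len(out.provenance) > len(small_study.site_table.provenance)

    def test_paper_literal_stage_order_supported(self, small_study):
        params = ProcessingParams(stage_order=(
            "valid_values", "impute", "class_one", "log2", "median_normalize"))
        result = run_processing(small_study.site_table, small_study.design, params)
        assert result.table.scale == "log2"
        meds = [result.table.data[s].median() for s in result.table.sample_ids]
        assert max(meds) - min(meds) < 1e-9

    def test_imputation_after_normalization_keeps_medians(self, small_study):
        """Imputing ≤ half the cells per sample leaves sample medians fixed."""
        params = ProcessingParams()
        result = run_processing(small_study.site_table, small_study.design, params)
        meds = [result.table.data[s].median() for s in result.table.sample_ids]
        assert max(meds) - min(meds) < 0.2
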