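import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from picong.preprocess import (
    CommunityMatrix,
    RarefactionSpec,
    aggregate_to_rank,
    build_ng_matrix,
    filter_rare_otus,
    rarefy,
    remove_organelles,
)

from conftest import make_otu_table


class TestRemoveOrganelles:
    def test_chloroplast_order_dropped(self):
        table = make_otu_table(
            {"OTU1": [5, 5], "OTU2": [3, 3]},
            ["S1", "S2"],
            taxonomy={"OTU1": {"Order": "Chloroplast"}},
        )
        out = remove_organelles(table)
        assert list(out.otu_ids) == ["OTU2"]
        assert (out.counts.loc["OTU2"] == table.counts.loc["OTU2"]).all()

    def test_mixed_case_mitochondria_dropped(self):
        table = make_otu_table(
            {"OTU1": [5, 5]}, ["S1", "S2"], taxonomy={"OTU1": {"Family": "MITOCHONDRIA"}}
        )
        assert len(remove_organelles(table).otu_ids) == 0

    def test_clean_table_unchanged(self, toy_table):
        out = remove_organelles(toy_table)
        pd.testing.assert_frame_equal(out.counts, toy_table.counts)


class TestFilterRareOtus:
    @pytest.mark.parametrize(
        "counts, kept",
        [
            ([10, 10, 10, 0], True),   # reaches 10 in exactly 3 samples
            ([9, 9, 9, 9], False),     # never reaches 10
            ([30, 0, 0, 0], False),    # reaches 10 in only 1 sample
        ],
    )
    def test_prevalence_abundance_rule(self, counts, kept):
        table = make_otu_table({"OTU1": counts}, [f"S{i}" for i in range(4)])
        out = filter_rare_otus(table)
        assert ("OTU1" in out.otu_ids) is kept

    def test_idempotent_and_commutes_with_organelle_removal(self, toy_table):
        once = filter_rare_otus(toy_table, 10, 2)
        twice = filter_rare_otus(once, 10, 2)
        pd.testing.assert_frame_equal(once.counts, twice.counts)
        a = filter_rare_otus(remove_organelles(toy_table), 10, 2)
        b = remove_organelles(filter_rare_otus(toy_table, 10, 2))
        pd.testing.assert_frame_equal(a.counts, b.counts)

    @settings(derandomize=True, deadline=None, max_examples=25)
    @given(
        data=st.lists(
            st.lists(st.integers(0, 40), min_size=4, max_size=4), min_size=1, max_size=8
        ),
        min_count=st.integers(1, 15),
        min_samples=st.integers(1, 4),
    )
    def test_matches_counting_oracle(self, data, min_count, min_samples):
        table = make_otu_table(
            {f"OTU{i}": row for i, row in enumerate(data)}, [f"S{j}" for j in range(4)]
        )
        out = filter_rare_otus(table, min_count, min_samples)
        expected = {
            f"OTU{i}"
            for i, row in enumerate(data)
            if sum(c >= min_count for c in row) >= min_samples
        }
        assert set(out.otu_ids) == expected


class TestRarefy:
    def test_output_columns_sum_exactly_to_depth(self):
        rng = np.random.default_rng(7)
        table = make_otu_table(
            {f"OTU{i}": rng.integers(0, 200, size=5).tolist() for i in range(40)},
            [f"S{j}" for j in range(5)],
        )
        depth = int(table.sample_totals.min())
        out = rarefy(table, RarefactionSpec(depth=depth, seed=1))
        assert (out.sample_totals == depth).all()
        assert (out.counts.to_numpy() <= table.counts.loc[out.otu_ids].to_numpy()).all()
        assert np.issubdtype(out.counts.to_numpy().dtype, np.integer)

    def test_sample_at_exact_depth_unchanged(self):
        table = make_otu_table({"OTU1": [6, 50], "OTU2": [4, 50]}, ["S1", "S2"])
        out = rarefy(table, RarefactionSpec(depth=10, seed=0))
        assert out.counts["S1"].tolist() == [6, 4]

    def test_shallow_samples_dropped_with_warning(self, caplog):
        table = make_otu_table({"OTU1": [6, 3], "OTU2": [4, 2]}, ["S1", "S2"])
        with caplog.at_level("WARNING"):
            out = rarefy(table, RarefactionSpec(depth=10, seed=0))
        assert list(out.sample_ids) == ["S1"]
        assert "S2" in caplog.text

    def test_depth_beyond_all_samples_rejected(self):
        table = make_otu_table({"OTU1": [6, 3]}, ["S1", "S2"])
        with pytest.raises(ValueError, match="depth"):
            rarefy(table, RarefactionSpec(depth=100, seed=0))

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        table = make_otu_table(
            {f"OTU{i}": rng.integers(0, 100, size=3).tolist() for i in range(20)},
            ["S1", "S2", "S3"],
        )
        a = rarefy(table, RarefactionSpec(depth=50, seed=42))
        b = rarefy(table, RarefactionSpec(depth=50, seed=42))
        pd.testing.assert_frame_equal(a.counts, b.counts)
        c = rarefy(table, RarefactionSpec(depth=50, seed=43))
        assert not a.counts.equals(c.counts)

    def test_subsampling_is_hypergeometric_in_expectation(self):
        # taxon with proportion p: mean rarefied count over seeds ~ depth * p
        total, depth, n_rep = 2000, 400, 1000
        taxon = 300  # p = 0.15
        table = make_otu_table({"OTU1": [taxon], "OTU2": [total - taxon]}, ["S1"])
        draws = np.array(
            [
                rarefy(table, RarefactionSpec(depth=depth, seed=s)).counts.loc["OTU1", "S1"]
                for s in range(n_rep)
            ],
            dtype=float,
        )
        p = taxon / total
        expected = depth * p
        # hypergeometric variance with finite-population correction
        var = depth * p * (1 - p) * (total - depth) / (total - 1)
        se = np.sqrt(var / n_rep)
        assert abs(draws.mean() - expected) < 3 * se


class TestAggregateToRank:
    def test_relative_abundance_arithmetic(self):
        table = make_otu_table(
            {"OTU1": [30], "OTU2": [10], "OTU3": [60]},
            ["S1"],
            taxonomy={
                "OTU1": {"Phylum": "Bacteroidota"},
                "OTU2": {"Phylum": "Bacteroidota"},
                "OTU3": {"Phylum": "Proteobacteria"},
            },
        )
        cm = aggregate_to_rank(table, "Phylum")
        assert cm.values.loc["S1", "Bacteroidota"] == pytest.approx(0.40)

    def test_single_otu_gives_unit_feature(self):
        table = make_otu_table({"OTU1": [17, 3]}, ["S1", "S2"])
        cm = aggregate_to_rank(table, "Phylum")
        assert cm.values.shape == (2, 1)
        assert (cm.values == 1.0).all().all()

    def test_unlabeled_otus_pool_into_unclassified(self):
        table = make_otu_table(
            {"OTU1": [5], "OTU2": [5]}, ["S1"], taxonomy={"OTU2": {"Phylum": ""}}
        )
        cm = aggregate_to_rank(table, "Phylum")
        assert "unclassified_phylum" in cm.values.columns

    def test_zero_total_sample_rejected(self):
        table = make_otu_table({"OTU1": [5, 0]}, ["S1", "S2"])
        with pytest.raises(ValueError, match="zero"):
            aggregate_to_rank(table, "Phylum")

    @settings(derandomize=True, deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_group_by_oracle_and_conserves_mass(self, seed):
        rng = np.random.default_rng(seed)
        n_otu, n_samp = 12, 4
        counts = rng.integers(0, 50, size=(n_otu, n_samp))
        counts[:, counts.sum(axis=0) == 0] += 1  # avoid zero-total samples
        phyla = rng.choice(["A", "B", "C"], size=n_otu)
        table = make_otu_table(
            {f"OTU{i}": counts[i].tolist() for i in range(n_otu)},
            [f"S{j}" for j in range(n_samp)],
            taxonomy={f"OTU{i}": {"Phylum": phyla[i]} for i in range(n_otu)},
        )
        cm = aggregate_to_rank(table, "Phylum")
        assert np.allclose(cm.values.sum(axis=1), 1.0, atol=1e-9)
        for j in range(n_samp):
            total = counts[:, j].sum()
            for p in set(phyla):
                brute = counts[phyla == p, j].sum() / total
                assert cm.values.loc[f"S{j}", p] == pytest.approx(brute)


class TestBuildNgMatrix:
    def _matrix(self, arr, cols):
        frame = pd.DataFrame(arr, index=[f"S{i}" for i in range(len(arr))], columns=cols)
        return CommunityMatrix(frame, "cardfish_proportions")

    def test_identity_without_standardization(self):
        cm = self._matrix([[1.0, 2.0], [3.0, 4.0]], ["a", "b"])
        out = build_ng_matrix(cm)
        pd.testing.assert_frame_equal(out.values, cm.values)

    def test_standardize_centers_and_scales(self):
        rng = np.random.default_rng(0)
        cm = self._matrix(rng.uniform(0, 50, size=(20, 3)), ["a", "b", "c"])
        out = build_ng_matrix(cm, standardize=True)
        assert np.allclose(out.values.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(out.values.std(axis=0, ddof=0), 1.0, atol=1e-9)

    def test_constant_column_maps_to_zeros(self, caplog):
        cm = self._matrix([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]], ["const", "x"])
        with caplog.at_level("WARNING"):
            out = build_ng_matrix(cm, standardize=True)
        assert (out.values["const"] == 0).all()
        assert "const" in caplog.text

    def test_missing_values_rejected_with_sample_names(self):
        frame = pd.DataFrame(
            [[1.0, np.nan], [2.0, 3.0]], index=["S1", "S2"], columns=["a", "b"]
        )
        cm = CommunityMatrix(frame, "cardfish_proportions")
        with pytest.raises(ValueError, match="S1"):
            build_ng_matrix(cm)
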