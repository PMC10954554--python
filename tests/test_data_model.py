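import numpy as np
import pytest

from odontolife.data_model import (
    AgeDataset,
    CorporaDataset,
    SchemaError,
    SpeciesTraits,
    ValidationError,
    apply_inclusion_filters,
    read_age_datasets,
    read_corpora_datasets,
    read_traits,
    read_trees,
    write_age_datasets,
    write_corpora_datasets,
    write_traits,
)


def _ds(dataset_id="d1", species="sp", records=None, **kw):
    return AgeDataset(dataset_id=dataset_id, species=species, sex="female",
                      population_id="p1", records=records or [(5.0, 3), (12.0, 7)], **kw)


class TestAgeDatasetIO:
    def test_round_trip_is_lossless(self, tmp_path):
        ds = _ds(growth_prior=(0.1, 0.02), bias_window=(3.0, 10.0),
                 age_bias_offset=2.0, source_type="by-catch")
        path = tmp_path / "ages.csv"
        write_age_datasets([ds], path)
        (back,) = read_age_datasets(path)
        assert back.records == ds.records
        assert back.growth_prior == ds.growth_prior
        assert back.bias_window == ds.bias_window
        assert back.age_bias_offset == ds.age_bias_offset
        assert back.max_observed_age == 12.0

    def test_negative_count_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("dataset_id,species,sex,population_id,age,count\nd1,sp,female,p1,5,-1\n")
        with pytest.raises(ValidationError, match="row"):
            read_age_datasets(path)

    def test_missing_column_names_it(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("dataset_id,species,sex,age,count\nd1,sp,female,5,1\n")
        with pytest.raises(SchemaError, match="population_id"):
            read_age_datasets(path)

    def test_two_dataset_ids_give_two_datasets(self, tmp_path):
        path = tmp_path / "ages.csv"
        write_age_datasets([_ds("d1"), _ds("d2")], path)
        assert len(read_age_datasets(path)) == 2

    def test_missing_sidecar_gives_default_metadata(self, tmp_path):
        path = tmp_path / "ages.csv"
        path.write_text("dataset_id,species,sex,population_id,age,count\nd1,sp,female,p1,5,1\n")
        (ds,) = read_age_datasets(path)
        assert ds.growth_prior == (0.0, 0.05)
        assert ds.bias_window is None
        assert ds.age_bias_offset == 0.0


class TestValidation:
    def test_counts_must_sum_positive(self):
        with pytest.raises(ValidationError):
            _ds(records=[(5.0, 0)])

    def test_bias_window_must_lie_inside_observed_range(self):
        with pytest.raises(ValidationError):
            _ds(bias_window=(5.0, 30.0))

    def test_traits_sd_nonnegative(self):
        with pytest.raises(ValidationError):
            SpeciesTraits("sp", "female", 300.0, -1.0, 10.0, 1.0, 0)


class TestOtherReaders:
    def test_corpora_round_trip(self, tmp_path):
        ds = CorporaDataset("c1", "sp", [(12.0, 3), (20.0, 8)], age_at_maturity=10.0,
                            max_lifespan_age=40.0)
        path = tmp_path / "corpora.csv"
        write_corpora_datasets([ds], path)
        (back,) = read_corpora_datasets(path)
        assert back.records == ds.records
        assert back.sampling_rate == pytest.approx(2 / 40.0)

    def test_traits_missing_sd_defaults_to_zero_with_warning(self, tmp_path):
        path = tmp_path / "traits.csv"
        path.write_text("species,sex,length_mean,maturity_mean,menopause\nsp,female,300,10,1\n")
        with pytest.warns(UserWarning, match="length_sd"):
            (t,) = read_traits(path)
        assert t.length_sd == 0.0 and t.maturity_sd == 0.0

    def test_traits_round_trip(self, tmp_path):
        t = SpeciesTraits("sp", "female", 312.5, 20.0, 9.5, 1.0, 1, 120)
        path = tmp_path / "traits.csv"
        write_traits([t], path)
        assert read_traits(path)[0] == t


class TestTrees:
    def test_patristic_distances_from_hand_path_sums(self, tmp_path):
        path = tmp_path / "trees.nwk"
        path.write_text("((A:1,B:1):1,C:2);\n")
        (chrono,) = read_trees(path)
        i = {t: k for k, t in enumerate(chrono.taxa)}
        D = chrono.distances
        assert D[i["A"], i["B"]] == pytest.approx(2.0)
        assert D[i["A"], i["C"]] == pytest.approx(4.0)
        assert chrono.ultrametric

    def test_empty_tree_file_errors(self, tmp_path):
        path = tmp_path / "empty.nwk"
        path.write_text("")
        with pytest.raises(ValidationError):
            read_trees(path)

    def test_missing_taxon_listed(self, tmp_path):
        path = tmp_path / "trees.nwk"
        path.write_text("((A:1,B:1):1,C:2);\n")
        with pytest.raises(ValidationError, match="D"):
            read_trees(path, required_taxa=["A", "D"])

    def test_non_ultrametric_flagged_not_rejected(self, tmp_path):
        path = tmp_path / "trees.nwk"
        path.write_text("((A:1,B:3):1,C:2);\n")
        with pytest.warns(UserWarning, match="ultrametric"):
            (chrono,) = read_trees(path)
        assert not chrono.ultrametric

    def test_multi_tree_file(self, tmp_path):
        path = tmp_path / "trees.nwk"
        path.write_text("((A:1,B:1):1,C:2);\n((A:2,B:2):2,C:4);\n")
        trees = read_trees(path)
        assert [t.tree_index for t in trees] == [0, 1]
        assert np.allclose(trees[1].distances, 2 * trees[0].distances)


class TestInclusionFilters:
    def _lifespan_ds(self, n_adult, max_age, maturity=10.0):
        recs = [(maturity + 1.0, n_adult), (float(max_age), 1)]
        return _ds(records=recs)

    def test_lifespan_rate_examples(self):
        # 11 adults over 20 years -> rate 0.55, in; 12 adults over 30 -> 0.40, out
        ds_in = self._lifespan_ds(10, 20)    # 10 + the max-age one = 11 adults
        ds_out = self._lifespan_ds(11, 30)
        inc, exc = apply_inclusion_filters([ds_in, ds_out], "lifespan", 10.0)
        assert inc == [ds_in]
        assert exc[0].dataset_id == ds_out.dataset_id
        assert exc[0].rule == "sampling_rate"
        assert exc[0].value == pytest.approx(0.40)

    def test_corpora_sample_size_rule(self):
        small = CorporaDataset("c1", "sp", [(11.0 + i, i) for i in range(19)], 10.0, 30.0)
        big = CorporaDataset("c2", "sp", [(11.0 + i, i) for i in range(20)], 10.0, 30.0)
        inc, exc = apply_inclusion_filters([small, big], "corpora")
        assert [d.dataset_id for d in inc] == ["c2"]
        assert exc[0].rule == "sample_size" and exc[0].value == 19

    def test_juvenile_rule(self):
        juv = _ds(records=[(2.0, 101), (15.0, 5)])
        few = _ds("d2", records=[(2.0, 100), (15.0, 5)])
        inc, exc = apply_inclusion_filters([juv, few], "juvenile", 10.0)
        assert inc == [juv] and exc[0].dataset_id == "d2"

    def test_unknown_kind_errors(self):
        with pytest.raises(ValueError, match="unknown"):
            apply_inclusion_filters([], "adult")

    def test_partition_exhaustive_and_idempotent(self):
        rng = np.random.default_rng(0)
        datasets = []
        for k in range(12):
            n_adult = int(rng.integers(1, 40))
            max_age = float(rng.integers(15, 60))
            datasets.append(_ds(f"d{k}", records=[(11.0, n_adult), (max_age, 1)]))
        inc, exc = apply_inclusion_filters(datasets, "lifespan", 10.0)
        assert len(inc) + len(exc) == len(datasets)
        ids = {d.dataset_id for d in inc} | {e.dataset_id for e in exc}
        assert ids == {d.dataset_id for d in datasets}
        inc2, exc2 = apply_inclusion_filters(inc, "lifespan", 10.0)
        assert inc2 == inc and exc2 == []
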