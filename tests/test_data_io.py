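import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microlvm import data_io
from microlvm.data_io import (
    CommunityTable,
    InputError,
    derive_covariates,
    filter_prevalence,
    read_community,
    standardize,
    unstandardize,
)


def write_counts(tmp_path, rows, sites=("s1", "s2")):
    path = tmp_path / "counts.tsv"
    lines = ["taxonomy\t" + "\t".join(sites)]
    for lineage, counts in rows:
        lines.append(lineage + "\t" + "\t".join(map(str, counts)))
    path.write_text("\n".join(lines) + "\n")
    return path


class TestReadCommunity:
    def test_same_order_rows_are_summed(self, tmp_path):
        path = write_counts(tmp_path, [
            ("k__Bacteria;p__P1;c__C1;o__O1", [3, 4]),
            ("k__Bacteria;p__P1;c__C1;o__O1", [1, 0]),
        ])
        table = read_community(path)
        assert table.n_taxa == 1
        assert table.counts[:, 0].tolist() == [4, 4]

    def test_class_level_taxon_gets_double_star(self, tmp_path):
        path = write_counts(tmp_path, [
            ("k__Bacteria;p__P1;c__C1;o__", [1, 2]),
        ])
        table = read_community(path)
        assert table.taxa[0].display_name == "C1**"
        assert table.taxa[0].resolution_flag == "class"

    def test_phylum_level_taxon_gets_star(self, tmp_path):
        path = write_counts(tmp_path, [("k__Bacteria;p__P9", [1, 2])])
        table = read_community(path)
        assert table.taxa[0].display_name == "P9*"
        assert table.taxa[0].resolution_flag == "phylum"

    def test_empty_file_is_an_error(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with pytest.raises(InputError):
            read_community(path)

    def test_duplicate_site_columns_rejected(self, tmp_path):
        path = write_counts(tmp_path, [("k__B;p__P;c__C;o__O", [1, 2])],
                            sites=("s1", "s1"))
        with pytest.raises(InputError, match="duplicate site"):
            read_community(path)

    def test_negative_counts_rejected(self, tmp_path):
        path = write_counts(tmp_path, [("k__B;p__P;c__C;o__O", [1, -2])])
        with pytest.raises(InputError):
            read_community(path)

    def test_non_integer_counts_rejected(self, tmp_path):
        path = write_counts(tmp_path, [("k__B;p__P;c__C;o__O", [1.5, 2])])
        with pytest.raises(InputError):
            read_community(path)

    def test_aggregation_conserves_total_count(self, tmp_path):
        rng = np.random.default_rng(0)
        rows = []
        total = 0
        for i in range(12):
            counts = rng.integers(0, 50, size=2)
            total += counts.sum()
            order = f"o__O{i % 4}" if i % 3 else "o__"
            rows.append((f"k__B;p__P{i % 2};c__C{i % 3};{order}", counts.tolist()))
        table = read_community(write_counts(tmp_path, rows))
        assert table.counts.sum() == total

    def test_distinct_phyla_do_not_merge_when_unclassified_at_order(self, tmp_path):
        path = write_counts(tmp_path, [
            ("k__B;p__PA", [1, 0]),
            ("k__B;p__PB", [0, 2]),
        ])
        assert read_community(path).n_taxa == 2

    def test_rank_aggregation_to_phylum(self, tmp_path):
        path = write_counts(tmp_path, [
            ("k__B;p__P1;c__C1;o__O1", [3, 4]),
            ("k__B;p__P1;c__C2;o__O2", [1, 1]),
        ])
        table = read_community(path, rank="phylum")
        assert table.n_taxa == 1
        assert table.counts[:, 0].tolist() == [4, 5]


class TestFilterPrevalence:
    def _table(self, prevalences, n_sites=43):
        taxa = []
        cols = []
        from tests.conftest import make_taxa
        taxa = make_taxa(len(prevalences))
        for p in prevalences:
            col = np.zeros(n_sites, dtype=np.int64)
            col[:p] = 1
            cols.append(col)
        return CommunityTable(counts=np.stack(cols, axis=1),
                              site_ids=[f"s{i}" for i in range(n_sites)], taxa=taxa)

    def test_four_of_43_sites_removed(self):
        table = self._table([4, 10])
        out = filter_prevalence(table, 5)
        assert out.n_taxa == 1

    def test_exactly_five_sites_retained(self):
        table = self._table([5, 10])
        assert filter_prevalence(table, 5).n_taxa == 2

    def test_min_sites_one_is_identity_without_zero_taxa(self):
        table = self._table([3, 7, 1])
        out = filter_prevalence(table, 1)
        assert out.n_taxa == 3
        np.testing.assert_array_equal(out.counts, table.counts)

    def test_idempotent(self):
        table = self._table([2, 5, 9, 43])
        once = filter_prevalence(table, 5)
        twice = filter_prevalence(once, 5)
        np.testing.assert_array_equal(once.counts, twice.counts)
        assert once.taxon_names == twice.taxon_names

    def test_all_removed_advises_threshold(self):
        table = self._table([1, 2])
        with pytest.raises(InputError, match="threshold"):
            filter_prevalence(table, 5)

    def test_site_set_unchanged(self):
        table = self._table([4, 10])
        assert filter_prevalence(table, 5).site_ids == table.site_ids


class TestDeriveCovariates:
    def frame(self, **overrides):
        base = {"TC": [10.0], "TN": [5.0], "DOC": [2.0],
                "A250": [2.0], "A254": [1.0], "A365": [0.5]}
        base.update(overrides)
        return pd.DataFrame(base, index=["siteA"])

    def test_e2e3_ratio(self):
        out = derive_covariates(self.frame())
        assert out["E2/E3"].iloc[0] == pytest.approx(4.0)

    def test_cn_ratio(self):
        out = derive_covariates(self.frame())
        assert out["C:N"].iloc[0] == pytest.approx(2.0)

    def test_suva254(self):
        out = derive_covariates(self.frame())
        assert out["SUVA254"].iloc[0] == pytest.approx(0.5)

    def test_zero_doc_names_site_and_covariate(self):
        with pytest.raises(InputError, match="DOC.*siteA"):
            derive_covariates(self.frame(DOC=[0.0]))

    def test_missing_column(self):
        raw = self.frame().drop(columns=["A365"])
        with pytest.raises(InputError, match="A365"):
            derive_covariates(raw)


class TestStandardize:
    def test_simple_column(self):
        env = pd.DataFrame({"pH": [2.0, 4.0, 6.0]})
        out = standardize(env, ["pH"])
        np.testing.assert_allclose(out.values[:, 0], [-1, 0, 1])

    def test_columns_have_zero_mean_unit_sample_sd(self, rng):
        env = pd.DataFrame(rng.normal(3, 7, size=(20, 2)), columns=["TC", "TN"])
        out = standardize(env, ["TC", "TN"])
        assert np.all(np.abs(out.values.mean(axis=0)) < 1e-10)
        assert np.all(np.abs(out.values.std(axis=0, ddof=1) - 1) < 1e-10)

    def test_idempotence(self, rng):
        env = pd.DataFrame(rng.normal(size=(15, 1)), columns=["DOC"])
        once = standardize(env, ["DOC"])
        again = standardize(once.to_frame(), ["DOC"])
        np.testing.assert_allclose(again.values, once.values, atol=1e-10)

    def test_constant_column_is_an_error(self):
        env = pd.DataFrame({"pH": [1.0, 1.0, 1.0]})
        with pytest.raises(InputError, match="zero-variance"):
            standardize(env, ["pH"])

    def test_roundtrip_identity(self, rng):
        env = pd.DataFrame(rng.normal(5, 2, size=(12, 3)),
                           columns=["TC", "TN", "DOC"])
        back = unstandardize(standardize(env, ["TC", "TN", "DOC"]))
        np.testing.assert_allclose(back.to_numpy(), env.to_numpy(), atol=1e-10)

    def test_missing_values_hard_error_by_default(self):
        env = pd.DataFrame({"TC": [1.0, np.nan, 3.0]})
        with pytest.raises(InputError, match="impute"):
            standardize(env, ["TC"])

    def test_every_covariate_in_exactly_one_group(self):
        env = pd.DataFrame({"TC": [1.0, 2.0, 4.0], "latitude": [1.0, 3.0, 2.0]})
        out = standardize(env, ["TC", "latitude"])
        assert out.groups["TC"] == "C&N"
        assert out.groups["latitude"] == "geographic distance"

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(-1e4, 1e4), min_size=3, max_size=30))
    def test_standardize_properties(self, values):
        arr = np.asarray(values)
        if np.std(arr, ddof=1) < 1e-6 or not np.all(np.isfinite(arr)):
            return
        env = pd.DataFrame({"TP": arr})
        out = standardize(env, ["TP"])
        assert abs(out.values.mean()) < 1e-8
        assert abs(out.values.std(ddof=1) - 1) < 1e-8


def test_write_read_roundtrip(tmp_path, toy_counts):
    path = tmp_path / "counts.tsv"
    toy_counts.write(path)
    back = read_community(path)
    np.testing.assert_array_equal(back.counts, toy_counts.counts)
    assert back.site_ids == toy_counts.site_ids


def test_read_metadata_canonicalises_names(tmp_path):
    path = tmp_path / "meta.csv"
    path.write_text("site,ph,tc,ELEVATION\ns1,7.1,10,2800\ns2,6.8,12,3100\n")
    meta = data_io.read_metadata(path)
    assert set(meta.columns) == {"pH", "TC", "elevation"}
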