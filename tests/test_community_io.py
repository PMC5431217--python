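import numpy as np
import pandas as pd
import pytest

from temporal_beta import (
    CommunityMatrix,
    EnvironmentTable,
    StudyDataset,
    ValidationError,
    read_community_long,
    read_environment,
    write_results,
)
from temporal_beta.community_io import (
    attach_gamma,
    read_community_wide,
    write_community_long,
    write_environment,
)

LONG_COLS = "site\tyear\ttaxon\tcount\n"


def write_long(tmp_path, rows, name="comm.tsv"):
    p = tmp_path / name
    p.write_text(LONG_COLS + "".join(f"{s}\t{y}\t{t}\t{c}\n" for s, y, t, c in rows))
    return p


class TestReadCommunityLong:
    def test_pivot_fills_absent_combinations_with_zero(self, tmp_path):
        p = write_long(tmp_path, [("A", 2000, "t1", 2), ("A", 2000, "t2", 1), ("A", 2001, "t1", 4)])
        (m,) = read_community_long(p)
        assert m.site_id == "A"
        assert m.years.tolist() == [2000, 2001]
        assert m.taxa == ["t1", "t2"]
        assert m.counts.tolist() == [[2, 1], [4, 0]]

    def test_row_order_does_not_matter(self, tmp_path):
        rows = [("A", 2001, "t2", 5), ("A", 2000, "t1", 2), ("A", 2001, "t1", 4), ("A", 2000, "t3", 7)]
        p1 = write_long(tmp_path, rows, "a.tsv")
        p2 = write_long(tmp_path, rows[::-1], "b.tsv")
        (m1,), (m2,) = read_community_long(p1), read_community_long(p2)
        assert m1.taxa == m2.taxa
        assert np.array_equal(m1.counts, m2.counts)

    def test_14_year_site_has_13_consecutive_pairs_downstream(self, tmp_path):
        rows = [("A", 2000 + y, f"t{j}", 1 + (y + j) % 4) for y in range(14) for j in range(6)]
        p = write_long(tmp_path, rows)
        (m,) = read_community_long(p)
        assert m.n_years == 14
        from temporal_beta import consecutive_dissimilarities

        assert len(consecutive_dissimilarities(m).values) == 13

    def test_negative_count_rejected(self, tmp_path):
        p = write_long(tmp_path, [("A", 2000, "t1", 2), ("A", 2001, "t1", -1)])
        with pytest.raises(ValidationError, match="non-negative"):
            read_community_long(p)

    def test_duplicate_site_year_taxon_rejected(self, tmp_path):
        p = write_long(tmp_path, [("A", 2000, "t1", 2), ("A", 2000, "t1", 3), ("A", 2001, "t1", 1)])
        with pytest.raises(ValidationError, match="duplicate"):
            read_community_long(p)

    def test_year_gap_rejected(self, tmp_path):
        p = write_long(tmp_path, [("A", 2000, "t1", 2), ("A", 2002, "t1", 3)])
        with pytest.raises(ValidationError, match="consecutive"):
            read_community_long(p)

    def test_taxon_exclusion_list(self, tmp_path):
        p = write_long(
            tmp_path,
            [("A", 2000, "t1", 2), ("A", 2000, "chiro", 9), ("A", 2001, "t1", 1), ("A", 2001, "chiro", 5)],
        )
        (m,) = read_community_long(p, exclude_taxa=["chiro"])
        assert m.taxa == ["t1"]


class TestCommunityMatrix:
    def test_alpha_and_gamma(self, small_matrix):
        assert small_matrix.alpha().tolist() == [3, 4, 4, 4]
        assert small_matrix.gamma == 5

    def test_all_zero_column_dropped_with_warning(self, caplog):
        counts = np.array([[1, 0, 2], [2, 0, 1]])
        with caplog.at_level("WARNING", logger="temporal_beta.community_io"):
            m = CommunityMatrix("A", np.array([2000, 2001]), ["a", "b", "c"], counts)
        assert m.taxa == ["a", "c"]
        assert "all-zero" in caplog.text

    def test_single_year_rejected(self):
        with pytest.raises(ValidationError, match="2 years"):
            CommunityMatrix("A", np.array([2000]), ["a"], np.array([[1]]))

    def test_duplicate_taxa_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            CommunityMatrix("A", np.array([2000, 2001]), ["a", "a"], np.ones((2, 2), int))


class TestRoundTrip:
    def test_long_write_read_is_identity(self, tmp_path, default_dataset):
        mats = default_dataset.matrices[:3]
        p = tmp_path / "rt.tsv"
        write_community_long(mats, p)
        back = read_community_long(p)
        assert [m.site_id for m in back] == [m.site_id for m in mats]
        for a, b in zip(mats, back):
            assert a.taxa == b.taxa
            assert np.array_equal(a.counts, b.counts)

    def test_environment_round_trip_to_12_digits(self, tmp_path, default_dataset):
        env = default_dataset.environment
        p = tmp_path / "env.tsv"
        write_environment(env, p)
        back = read_environment(p)
        pd.testing.assert_frame_equal(back.data, env.data, rtol=1e-12)

    def test_wide_reader_matches_long(self, tmp_path, small_matrix):
        wide = pd.DataFrame(small_matrix.counts, columns=small_matrix.taxa)
        wide.insert(0, "year", small_matrix.years)
        p = tmp_path / "wide.tsv"
        wide.to_csv(p, sep="\t", index=False)
        m = read_community_wide(p, site_id="A")
        assert m.taxa == small_matrix.taxa
        assert np.array_equal(m.counts, small_matrix.counts)


class TestEnvironmentTable:
    def make_df(self, n=4):
        return pd.DataFrame(
            {
                "site": [f"S{i}" for i in range(n)],
                "bmi": np.linspace(5, 30, n),
                "bryophytes": np.linspace(10, 70, n),
                "simpson": np.linspace(2, 5, n),
                "temperature": np.linspace(7, 11, n),
                "connectivity": np.linspace(200, 1500, n),
                "gamma": np.arange(50, 50 + n),
            }
        )

    def test_valid_table_accepted(self):
        env = EnvironmentTable(self.make_df())
        assert env.sites == ["S0", "S1", "S2", "S3"]

    def test_duplicate_site_rejected(self):
        df = self.make_df()
        df.loc[1, "site"] = "S0"
        with pytest.raises(ValidationError, match="duplicated"):
            EnvironmentTable(df)

    def test_missing_value_names_cell(self):
        df = self.make_df()
        df.loc[2, "simpson"] = np.nan
        with pytest.raises(ValidationError, match=r"\(S2, simpson\)"):
            EnvironmentTable(df)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "env.tsv"
        p.write_text("")
        with pytest.raises(ValidationError, match="empty"):
            read_environment(p)

    def test_gamma_attached_from_matrices(self, default_dataset):
        df = default_dataset.environment.data.reset_index().drop(columns="gamma")
        env = attach_gamma(df, default_dataset.matrices)
        for m in default_dataset.matrices:
            assert env.data.loc[m.site_id, "gamma"] == m.gamma

    def test_dataset_gamma_mismatch_rejected(self, default_dataset):
        df = default_dataset.environment.data.copy()
        df.iloc[0, df.columns.get_loc("gamma")] += 1
        with pytest.raises(ValidationError, match="gamma"):
            StudyDataset(matrices=default_dataset.matrices, environment=EnvironmentTable(df.reset_index()))


class TestWriteResults:
    def test_tables_written(self, tmp_path):
        tables = {"beta_by_site": pd.DataFrame({"site": ["A"], "beta_obs": [0.3]})}
        written = write_results(tables, tmp_path / "out", manifest={"seed": 1})
        names = {p.name for p in written}
        assert names == {"beta_by_site.tsv", "manifest.json"}

    def test_empty_result_set_rejected(self, tmp_path):
        with pytest.raises(ValidationError):
            write_results({}, tmp_path)
        with pytest.raises(ValidationError):
            write_results({"t": pd.DataFrame()}, tmp_path)
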