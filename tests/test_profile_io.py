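import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from microbiomegsm.errors import InputError
from microbiomegsm.profile_io import (AbundanceMatrix, attach_labels_and_clean,
                                      deepest_prefix, filter_samples_by_reads,
                                      normalize_abundances, parse_merged_table,
                                      select_species_rows)

MIXED_TABLE = """\
# merged abundance profile
clade_name\tSampleA\tSampleB
k__Bacteria|p__P|c__C|o__O|f__F|g__G|s__G_sp1\t40\t10
k__Bacteria|p__P|c__C|o__O|f__F|g__G\t60\t90
k__Bacteria|p__P|c__C|o__O|f__F|g__G|s__G_sp2\t20\t80
"""


def table(text: str) -> pd.DataFrame:
    return parse_merged_table(io.StringIO(text))


class TestParseMergedTable:
    def test_rows_and_sample_columns(self):
        df = table(MIXED_TABLE)
        assert df.shape == (3, 2)
        assert list(df.columns) == ["SampleA", "SampleB"]
        assert df.iloc[0].tolist() == [40.0, 10.0]

    def test_percent_values_returned_unscaled(self):
        df = table(MIXED_TABLE)
        assert df.to_numpy().max() > 1  # rescaling is normalize's job, not parsing's

    def test_empty_file_is_an_error(self):
        with pytest.raises(InputError, match="no data rows"):
            table("")
        with pytest.raises(InputError, match="no data rows"):
            table("# only a comment\n")

    def test_non_numeric_cell_names_row_and_column(self):
        bad = "clade\tS1\nk__A|s__B\toops\n"
        with pytest.raises(InputError, match="oops.*k__A\\|s__B.*S1"):
            table(bad)

    def test_duplicate_clade_is_an_error(self):
        dup = "clade\tS1\nk__A|s__B\t1\nk__A|s__B\t2\n"
        with pytest.raises(InputError, match="duplicate clade"):
            table(dup)


class TestSelectSpeciesRows:
    def test_keeps_only_deepest_species_rows(self):
        df = table(MIXED_TABLE)
        out = select_species_rows(df)
        assert list(out.index) == [df.index[0], df.index[2]]

    def test_strain_rows_excluded(self):
        text = ("clade\tS1\n"
                "k__A|s__sp\t1\n"
                "k__A|s__sp|t__strain\t2\n")
        out = select_species_rows(table(text))
        assert list(out.index) == ["k__A|s__sp"]

    def test_all_species_is_identity(self):
        text = "clade\tS1\nk__A|s__x\t1\nk__A|s__y\t2\n"
        df = table(text)
        assert select_species_rows(df).equals(df)

    def test_no_species_rows_is_an_error(self):
        with pytest.raises(InputError, match="no species"):
            select_species_rows(table("clade\tS1\nk__A|g__B\t1\n"))


def _matrix(values, labels=None):
    values = np.asarray(values, dtype=float)
    return AbundanceMatrix(
        sample_ids=[f"S{i}" for i in range(values.shape[0])],
        species_ids=[f"k__A|s__sp{j}" for j in range(values.shape[1])],
        values=values,
        labels=labels,
    )


class TestNormalize:
    def test_closure(self):
        out = normalize_abundances(_matrix([[20, 30, 50]]))
        assert np.allclose(out.values, [[0.2, 0.3, 0.5]])

    def test_already_normalized_is_identity(self):
        out = normalize_abundances(_matrix([[0.2, 0.3, 0.5]]))
        assert np.allclose(out.values, [[0.2, 0.3, 0.5]])

    def test_all_zero_sample_is_an_error(self):
        with pytest.raises(InputError, match="all-zero.*S1"):
            normalize_abundances(_matrix([[1, 2, 3], [0, 0, 0]]))

    @given(st.lists(st.lists(st.floats(0.01, 1e6), min_size=3, max_size=3),
                    min_size=1, max_size=6),
           st.floats(1e-3, 1e3))
    def test_idempotent_and_scale_invariant(self, rows, c):
        m = _matrix(rows)
        once = normalize_abundances(m)
        assert np.allclose(once.values.sum(axis=1), 1.0, atol=1e-6)
        twice = normalize_abundances(once)
        assert np.allclose(once.values, twice.values, atol=1e-12)
        scaled = normalize_abundances(_matrix(np.asarray(rows) * c))
        assert np.allclose(once.values, scaled.values, atol=1e-9)


class TestReadFilter:
    def counts(self, values):
        return {f"S{i}": v for i, v in enumerate(values)}

    def test_threshold_removes_shallow_samples(self):
        m = _matrix(np.ones((5, 3)), labels=[1, 1, 0, 0, 1])
        out = filter_samples_by_reads(m, self.counts([2e6, 9e5, 2e6, 9e5, 2e6]))
        assert out.sample_ids == ["S0", "S2", "S4"]
        assert out.labels.tolist() == [1, 0, 1]

    def test_all_deep_is_identity(self):
        m = _matrix(np.ones((3, 2)))
        out = filter_samples_by_reads(m, self.counts([2e6] * 3))
        assert out.sample_ids == m.sample_ids

    def test_missing_counts_is_logged_noop(self, caplog):
        m = _matrix(np.ones((2, 2)))
        with caplog.at_level("WARNING", logger="microbiomegsm"):
            out = filter_samples_by_reads(m, None)
        assert out is m
        assert "filter skipped" in caplog.text

    def test_sample_missing_from_counts_strict_vs_lenient(self):
        m = _matrix(np.ones((2, 2)))
        with pytest.raises(InputError, match="S1"):
            filter_samples_by_reads(m, {"S0": 2_000_000})
        out = filter_samples_by_reads(m, {"S0": 2_000_000}, strict=False)
        assert out.sample_ids == ["S0", "S1"]


class TestAttachLabels:
    def test_drops_unlabeled_and_incomplete_samples(self):
        values = pd.DataFrame(np.ones((10, 3)) / 3,
                              index=[f"S{i}" for i in range(10)],
                              columns=["k__A|s__a", "k__A|s__b", "k__A|s__c"])
        values.iloc[3, 1] = np.nan
        labels = {f"S{i}": i % 2 for i in range(9)}  # S9 unlabeled
        out = attach_labels_and_clean(values, labels)
        assert out.n_samples == 8
        assert "S3" not in out.sample_ids and "S9" not in out.sample_ids

    def test_text_labels_mapped_via_positive_class(self):
        values = pd.DataFrame(np.ones((4, 2)) / 2, index=list("abcd"),
                              columns=["k__A|s__x", "k__A|s__y"])
        out = attach_labels_and_clean(values, {"a": "yes", "b": "no", "c": "yes", "d": "no"},
                                      positive_label="yes")
        assert out.labels.tolist() == [1, 0, 1, 0]

    def test_single_class_after_cleaning_is_an_error(self):
        values = pd.DataFrame(np.ones((3, 2)), index=list("abc"),
                              columns=["k__A|s__x", "k__A|s__y"])
        with pytest.raises(InputError, match="one class"):
            attach_labels_and_clean(values, {"a": 1, "b": 1, "c": 1})


_name = st.text(alphabet="abcdefgh", min_size=1, max_size=4)


@st.composite
def clade_strings(draw):
    depth = draw(st.integers(1, 7))
    prefixes = "kpcofgs"[:depth]
    kept = [p for p in prefixes if p in ("k", prefixes[-1]) or draw(st.booleans())]
    return "|".join(f"{p}__{draw(_name)}" for p in kept)


@given(st.lists(clade_strings(), min_size=1, max_size=8, unique=True))
def test_species_selection_only_returns_species_rows(clades):
    """Fuzzed: parsing then species selection never yields a non-s__ row."""
    text = "clade\tS1\n" + "".join(f"{c}\t1\n" for c in clades)
    df = table(text)
    try:
        out = select_species_rows(df)
    except InputError:
        assert all(deepest_prefix(c) != "s" for c in clades)
        return
    assert all(deepest_prefix(c) == "s" for c in out.index)


def test_prebuilt_sample_matrix_csv_loads(tmp_path):
    from microbiomegsm.profile_io import read_sample_matrix_csv

    path = tmp_path / "matrix.csv"
    path.write_text(
        "sample_id,k__A|s__x,k__A|s__y,label\n"
        "S1,0.4,0.6,1\nS2,0.7,0.3,0\n"
    )
    values, labels = read_sample_matrix_csv(path)
    out = attach_labels_and_clean(values, labels)
    assert out.species_ids == ["k__A|s__x", "k__A|s__y"]
    assert out.labels.tolist() == [1, 0]
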