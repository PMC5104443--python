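import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from foodnet.panel import BipartitePanel
from foodnet.tables import (
    build_panel,
    filter_countries,
    read_matrix,
    read_records,
    write_matrix,
)
from tests.conftest import make_population


class TestReadRecords:
    def test_direct_parse(self, tmp_path):
        path = tmp_path / "p.csv"
        path.write_text("country,product,year,tonnes\nA,wheat,2011,100\n")
        table = read_records(path, "production")
        assert len(table) == 1
        row = table.iloc[0]
        assert (row["country"], row["product"], row["year"], row["tonnes"]) == (
            "A", "wheat", 2011, 100.0,
        )

    def test_header_only_gives_empty_table(self, tmp_path):
        path = tmp_path / "p.csv"
        path.write_text("country,product,year,tonnes\n")
        assert read_records(path, "production").empty

    def test_negative_tonnes_names_line(self, tmp_path):
        path = tmp_path / "p.csv"
        path.write_text("country,product,year,tonnes\nA,wheat,2011,-5\n")
        with pytest.raises(ValueError, match="line 2"):
            read_records(path, "production")

    def test_missing_column_is_hard_error(self, tmp_path):
        path = tmp_path / "p.csv"
        path.write_text("country,product,year\nA,wheat,2011\n")
        with pytest.raises(ValueError, match="tonnes"):
            read_records(path, "production")

    def test_malformed_numeric_names_line(self, tmp_path):
        path = tmp_path / "p.csv"
        path.write_text("country,product,year,tonnes\nA,wheat,2011,10\nB,rice,2011,oops\n")
        with pytest.raises(ValueError, match="line 3"):
            read_records(path, "production")

    def test_custom_column_names(self, tmp_path):
        path = tmp_path / "p.csv"
        path.write_text("Area,Item,Year,Value\nA,wheat,2011,7\n")
        table = read_records(
            path, "production",
            columns={"country": "Area", "product": "Item", "year": "Year", "tonnes": "Value"},
        )
        assert table.iloc[0]["tonnes"] == 7.0

    def test_population_dialect_rejects_nonpositive(self, tmp_path):
        path = tmp_path / "pop.csv"
        path.write_text("country,year,persons\nA,2011,0\n")
        with pytest.raises(ValueError, match="persons"):
            read_records(path, "population")

    def test_labels_are_whitespace_trimmed(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text("country\tproduct\tyear\ttonnes\n A \twheat\t2011\t1\n")
        assert read_records(path, "production").iloc[0]["country"] == "A"


class TestFilterCountries:
    def _records(self, countries):
        return pd.DataFrame(
            {"country": countries, "product": "wheat", "year": 2011, "tonnes": 1.0}
        )

    def test_half_million_excluded_at_default(self):
        records = self._records(["A"])
        population = make_population(["A"], persons=400_000)
        assert filter_countries(records, population, 2011).empty

    def test_strict_boundary_retained(self):
        records = self._records(["A", "B"])
        population = pd.DataFrame(
            {"country": ["A", "B"], "year": 2011, "persons": [500_001.0, 500_000.0]}
        )
        kept = filter_countries(records, population, 2011)
        assert sorted(kept["country"].unique()) == ["A"]

    def test_all_below_threshold_warns(self, caplog):
        records = self._records(["A", "B"])
        population = make_population(["A", "B"], persons=1000)
        with caplog.at_level("WARNING"):
            out = filter_countries(records, population, 2011)
        assert out.empty
        assert "threshold" in caplog.text

    def test_unknown_country_dropped_with_warning(self, caplog):
        records = self._records(["A", "Z"])
        population = make_population(["A"])
        with caplog.at_level("WARNING"):
            kept = filter_countries(records, population, 2011)
        assert sorted(kept["country"].unique()) == ["A"]
        assert "Z" in caplog.text

    def test_idempotent(self):
        records = self._records(["A", "B", "Z"])
        population = pd.DataFrame(
            {"country": ["A", "B"], "year": 2011, "persons": [2e6, 1e5]}
        )
        once = filter_countries(records, population, 2011)
        twice = filter_countries(once, population, 2011)
        pd.testing.assert_frame_equal(once, twice)


class TestBuildPanel:
    def test_per_capita_division(self):
        records = pd.DataFrame(
            {"country": ["A"], "product": ["wheat"], "year": [2011], "tonnes": [100.0]}
        )
        panel = build_panel(records, make_population(["A"], persons=50), 2011)
        assert panel.W[0, 0] == 2.0
        assert panel.M[0, 0] == 1

    def test_zero_tonnes_is_non_production(self):
        records = pd.DataFrame(
            {"country": ["A", "A"], "product": ["wheat", "maize"],
             "year": 2011, "tonnes": [5.0, 0.0]}
        )
        panel = build_panel(records, make_population(["A"]), 2011)
        j = panel.products.index("maize")
        assert panel.M[0, j] == 0 and panel.W[0, j] == 0.0
        assert "maize" in panel.meta["zero_products"]

    def test_duplicate_rows_summed_then_divided(self):
        # oracle: (60 + 40) / 100 = 1.0
        records = pd.DataFrame(
            {"country": ["A", "A"], "product": ["wheat", "wheat"],
             "year": 2011, "tonnes": [60.0, 40.0]}
        )
        panel = build_panel(records, make_population(["A"], persons=100), 2011)
        assert panel.W[0, 0] == 1.0

    def test_missing_population_is_hard_error(self):
        records = pd.DataFrame(
            {"country": ["A"], "product": ["wheat"], "year": [2011], "tonnes": [1.0]}
        )
        with pytest.raises(ValueError, match="population"):
            build_panel(records, make_population(["B"]), 2011)

    def test_other_years_ignored(self):
        records = pd.DataFrame(
            {"country": ["A", "A"], "product": ["wheat", "rice"],
             "year": [2011, 2010], "tonnes": [1.0, 1.0]}
        )
        panel = build_panel(records, make_population(["A"]), 2011)
        assert panel.products == ["wheat"]

    def test_end_to_end_from_files(self, production_csv, population_csv):
        records = read_records(production_csv, "production")
        population = read_records(population_csv, "population")
        kept = filter_countries(records, population, 2011)
        # A (pop 100) is filtered out; C produced only a zero tonnage
        panel = build_panel(kept, population, 2011)
        assert panel.countries == ["B", "C"]
        assert panel.meta["zero_countries"] == ["C"]


class TestMatrixRoundTrip:
    def test_round_trip_weighted_bit_exact(self, small_panel, tmp_path):
        path = tmp_path / "panel.tsv"
        write_matrix(small_panel, path, form="weighted")
        back = read_matrix(path)
        assert back.countries == small_panel.countries
        assert back.products == small_panel.products
        assert back.year == small_panel.year
        assert np.array_equal(back.W, small_panel.W)
        assert np.array_equal(back.M, small_panel.M)

    def test_binary_form_keeps_support(self, small_panel, tmp_path):
        path = tmp_path / "panel.tsv"
        write_matrix(small_panel, path, form="binary")
        back = read_matrix(path)
        assert np.array_equal(back.M, small_panel.M)

    def test_empty_panel_header_only(self, tmp_path):
        panel = BipartitePanel(2011, [], ["p1", "p2"], np.empty((0, 2)), np.empty((0, 2)))
        path = tmp_path / "panel.tsv"
        write_matrix(panel, path, form="weighted")
        body = [ln for ln in path.read_text().splitlines() if not ln.startswith("#")]
        assert body == ["country\tp1\tp2"]
        assert read_matrix(path).shape == (0, 2)

    def test_sparse_companion_files(self, small_panel, tmp_path):
        path = tmp_path / "panel.tsv"
        write_matrix(small_panel, path, form="weighted", sparse=True)
        assert (tmp_path / "panel.mtx").read_text().startswith("%%MatrixMarket")
        assert "A" in (tmp_path / "panel.tsv.labels.tsv").read_text()

    def test_header_metadata_round_trips(self, small_panel, tmp_path):
        path = tmp_path / "panel.tsv"
        write_matrix(small_panel, path, header={"seed": 7})
        assert read_matrix(path).meta["seed"] == "7"

    @settings(max_examples=25, deadline=None)
    @given(
        W=hnp.arrays(
            float,
            hnp.array_shapes(min_dims=2, max_dims=2, min_side=1, max_side=6),
            elements=st.floats(0, 1e9, allow_nan=False, width=64),
        )
    )
    def test_round_trip_property(self, W, tmp_path_factory):
        n_c, n_p = W.shape
        panel = BipartitePanel.from_weighted(
            2000, [f"c{i}" for i in range(n_c)], [f"p{j}" for j in range(n_p)], W
        )
        path = tmp_path_factory.mktemp("rt") / "m.tsv"
        write_matrix(panel, path, form="weighted")
        back = read_matrix(path)
        assert np.array_equal(back.W, panel.W)
        # support consistency invariant
        assert np.array_equal(back.W > 0, back.M == 1)
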