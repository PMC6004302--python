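import numpy as np
import pandas as pd
import pytest

import paleozone as pz
from paleozone.core_io import (
    AssemblageCounts,
    to_ppm,
    _parse_cell,
    write_assemblage_table,
    write_loi_table,
    read_loi_table,
    write_age_table,
    write_geochem_table,
    default_registry,
)


class TestAssemblageValidation:
    def test_counts_single_row(self):
        c = AssemblageCounts(
            ["s1"], ["a", "b", "c"], [0.0], [1.0], [[10, 20, 70]], mode="counts"
        )
        assert c.totals.tolist() == [100.0]

    def test_relative_row_sum_rejected_with_sample_name(self):
        with pytest.raises(ValueError, match="bad_sample"):
            AssemblageCounts(
                ["ok", "bad_sample"],
                ["a", "b"],
                [0, 1],
                [1, 2],
                [[0.5, 0.5], [0.4, 0.4]],
                mode="relative",
                row_sum_tolerance=0.05,
            )

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            AssemblageCounts(["s1"], ["a"], [0], [1], [[-1.0]], mode="counts")

    def test_depth_ordering_enforced(self):
        with pytest.raises(ValueError, match="increasing"):
            AssemblageCounts(
                ["s1", "s2"], ["a"], [0, 0], [2, 1], [[1.0], [1.0]], mode="counts"
            )

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            AssemblageCounts(["s1"], ["a"], [0], [1], [[1.5]], mode="counts")


class TestUnitsAndCensoring:
    @pytest.mark.parametrize(
        "value,unit,expected",
        [(2.5, "%", 25_000.0), (7.0, "ppm", 7.0), (1500.0, "ppb", 1.5)],
    )
    def test_to_ppm(self, value, unit, expected):
        assert to_ppm(value, unit) == pytest.approx(expected)

    def test_unknown_unit(self):
        with pytest.raises(ValueError, match="unit"):
            to_ppm(1.0, "mol/L")

    @pytest.mark.parametrize(
        "cell,value,flag",
        [
            ("<0.5", 0.5, "below_DL"),
            (">100", 100.0, "above_DL"),
            ("", None, "missing"),
            ("3.2", 3.2, "none"),
        ],
    )
    def test_cell_dialect(self, cell, value, flag):
        v, f = _parse_cell(cell)
        assert f == flag
        if value is None:
            assert np.isnan(v)
        else:
            assert v == pytest.approx(value)

    def test_non_numeric_cell_is_an_error(self):
        with pytest.raises(ValueError, match="non-numeric"):
            _parse_cell("lots")


class TestRoundTrips:
    def test_assemblage_round_trip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(0)
        vals = rng.integers(0, 50, size=(5, 4)).astype(float)
        c = AssemblageCounts(
            [f"s{i}" for i in range(5)],
            ["t1", "t2", "t3", "t4"],
            np.arange(5.0),
            np.arange(1.0, 6.0),
            vals,
            mode="counts",
        )
        p = tmp_path / "a.csv"
        write_assemblage_table(c, p)
        back = pz.read_assemblage_table(p, mode="counts")
        assert back.values.tolist() == c.values.tolist()
        assert back.sample_ids == c.sample_ids

    def test_loi_round_trip(self, tmp_path):
        loi = pz.LOISeries(
            [1.0, 2.0], [0.1, 0.2], [0.3, 0.35], [0.02, 0.02], [0.68, 0.63]
        )
        p = tmp_path / "loi.csv"
        write_loi_table(loi, p)
        back = read_loi_table(p)
        assert back.organics.tolist() == loi.organics.tolist()

    def test_geochem_round_trip_preserves_censoring(self, tmp_path):
        prof = pz.GeochemProfile(
            [1.0, 2.0, 3.0],
            {"As": np.array([10.0, 0.5, 20.0])},
            {"As": np.array(["none", "below_DL", "none"])},
        )
        p = tmp_path / "g.csv"
        write_geochem_table(prof, p)
        back = pz.read_geochem_table(p)
        assert back.flags["As"].tolist() == ["none", "below_DL", "none"]
        assert back.concentrations["As"].tolist() == [10.0, 0.5, 20.0]

    def test_age_round_trip_keeps_hiatus(self, tmp_path):
        table = pz.frame_lake_age_table()
        p = tmp_path / "ages.csv"
        write_age_table(table, p)
        back = pz.read_age_table(p)
        assert back.n_tie_points == table.n_tie_points
        assert back.hiatuses[0].depth == 17.0
        assert back.hiatuses[0].age_below_label == ">7,000 BP"


class TestRegistry:
    def test_default_registry_group_counts(self):
        reg = default_registry()
        groups = [e.functional_group for e in reg.entries.values()]
        assert groups.count("centropyxid") == 6
        assert groups.count("other") == 1
        assert groups.count("difflugiid") == 25

    def test_cucurbitella_excluded_from_ratio(self):
        reg = default_registry()
        entry = reg.lookup("Cucurbitella tricuspis")
        assert entry.functional_group == "difflugiid"
        assert entry.in_dc_ratio is False

    def test_spelling_synonym_resolves(self):
        reg = default_registry()
        assert reg.lookup("Medilous corona").taxon_id == "Mediolus corona"
        assert reg.group_of('centropyxis ACULEATA aculeata') == "centropyxid"

    def test_missing_taxon_named_in_error(self):
        reg = default_registry()
        with pytest.raises(KeyError, match="Nebela collaris"):
            reg.lookup("Nebela collaris")

    def test_duplicate_taxon_rejected(self):
        from paleozone.core_io import TaxonRegistry, TaxonEntry

        reg = TaxonRegistry()
        reg.add(TaxonEntry("Difflugia urens", "Difflugia urens", "difflugiid", True))
        with pytest.raises(ValueError, match="duplicate"):
            reg.add(TaxonEntry("difflugia urens", "x", "difflugiid", True))


class TestPackagedFixtures:
    def test_lake_table_shape_and_tolerance(self, lake_counts):
        assert lake_counts.n_samples == 30
        assert lake_counts.n_taxa == 32
        sums = lake_counts.values.sum(axis=1)
        assert np.all(np.abs(sums - 1) <= 0.05)

    def test_lake_table_resolves_against_registry(self, lake_counts, registry):
        assert all(registry.knows(t) for t in lake_counts.taxa)

    def test_age_fixture_has_21_tie_points_with_known_knots(self):
        table = pz.frame_lake_age_table()
        assert table.n_tie_points == 21
        lookup = dict(zip(table.depths, table.years))
        assert lookup[17.0] == 1962.69
        assert lookup[6.0] == 2000.47
        assert np.all(table.ash_rates == 0.34)

    def test_loi_fixture_closure(self):
        loi = pz.frame_lake_loi()
        closure = loi.organics + loi.carbonates + loi.minerogenics
        assert np.all(np.abs(closure - 1) <= 0.02)
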