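import math

import pytest

from nemadelim.errors import MorphometricsError
from nemadelim.morphometrics import (
    KeySpec,
    MorphometricRecord,
    compare_to_ranges,
    compute_indices,
    load_reference_tables,
    run_key,
    summary_statistics,
)
from nemadelim.synthetic_data import simulate_morphometrics

# Raw holotype measurements (micrometers) of the two type males, as printed in
# the original descriptions; the derived indices they should reproduce are in
# the acceptance suite.
RUANDICA_MALE = {
    "L": 760, "BD": 37.5, "lip": 6.5, "stoma": 9.5, "BL": 18.5, "PL": 95.2,
    "NR": 68, "EP": 84.3, "NL": 98, "ABD": 26.1, "T": 29, "SL": 49, "GL": 20.2,
}
ZACATECANA_MALE = {
    "L": 808.1, "BD": 42.5, "lip": 6.2, "stoma": 10, "BL": 20.2, "PL": 95.2,
    "NR": 65.4, "EP": 96.2, "NL": 99.3, "ABD": 19.6, "T": 28, "SL": 54.1, "GL": 18.7,
}


def male(characters, specimen="m1"):
    return compute_indices(
        MorphometricRecord(specimen_id=specimen, stage="male", characters=dict(characters))
    )


class TestComputeIndices:
    def test_ratio_identity(self):
        rec = compute_indices(
            MorphometricRecord("x", "IJ", {"T": 55.0, "ABD": 55.0})
        )
        assert rec.derived["c_prime"] == 1.0

    def test_holotype_spot_values(self):
        rec = male(RUANDICA_MALE)
        assert round(rec.derived["a"], 1) == 20.3
        assert round(rec.derived["GS_pct"], 1) == 41.2
        rec2 = male(ZACATECANA_MALE)
        assert round(rec2.derived["GS_pct"], 2) == 34.57  # prints as 34.56 (truncated)
        assert abs(rec2.derived["GS_pct"] - 34.56) < 0.01

    def test_missing_operands_skipped(self):
        rec = compute_indices(MorphometricRecord("x", "male", {"L": 700.0}))
        assert "a" not in rec.derived  # BD missing
        assert rec.errors == {}

    def test_negative_characters_rejected(self):
        with pytest.raises(MorphometricsError):
            MorphometricRecord("y", "male", {"SL": 40.0, "GL": -1.0})

    def test_zero_denominator_isolated_per_index(self):
        # a zero operand must not poison the other indices: the failing
        # index is reported, the rest computed
        rec = MorphometricRecord("x", "male", {"L": 700.0, "BD": 35.0, "NL": 0.0})
        done = compute_indices(rec)
        assert done.derived["a"] == 20.0
        assert "b" not in done.derived
        assert "b" in done.errors


class TestRangeTables:
    def test_all_four_stages_load(self, range_table):
        assert set(range_table.stages()) == {"male", "hermaphrodite", "female", "IJ"}

    def test_printed_row_counts(self, range_table):
        # each comparative stage table prints 40 species-description rows
        for stage in range_table.stages():
            assert range_table.n_rows(stage) == 40

    def test_ruandica_ij_row(self, range_table):
        assert range_table.interval("H. ruandica", "IJ", "L") == (496.0, 591.0)
        assert range_table.interval("H. ruandica", "IJ", "EP") == (70.0, 89.0)
        assert range_table.interval("H. ruandica", "IJ", "T") == (49.0, 64.0)

    def test_zacatecana_male_row(self, range_table):
        assert range_table.interval("H. zacatecana", "male", "SL") == (38.0, 55.0)
        assert range_table.interval("H. zacatecana", "male", "GL") == (15.0, 25.0)

    def test_degenerate_and_inverted_cells_normalized(self, range_table):
        # single printed value -> degenerate interval
        assert range_table.interval("H. bacteriophora", "male", "SW_pct") == (174.0, 174.0)
        # typeset inversion is swapped at load time
        frame = range_table.frame
        assert (frame["min"] <= frame["max"]).all()


class TestCompareToRanges:
    def test_worked_example_ij(self, range_table):
        rec = MorphometricRecord("ij1", "IJ", {"EP": 75.0, "T": 55.0, "L": 540.0})
        report = compare_to_ranges(rec, range_table)
        status = report.species_status()
        assert status["H. ruandica"] == "consistent"
        assert status["H. bacteriophora"] == "excluded"

    def test_boundary_value_is_inside(self, range_table):
        rec = MorphometricRecord("ij2", "IJ", {"L": 496.0})  # exactly at ruandica minimum
        report = compare_to_ranges(rec, range_table)
        assert report.species_status()["H. ruandica"] == "consistent"

    def test_monotone_in_range_width(self, range_table):
        rec = MorphometricRecord("ij3", "IJ", {"EP": 75.0, "T": 55.0, "L": 540.0})
        report = compare_to_ranges(rec, range_table)
        import pandas as pd

        widened = range_table.frame.copy()
        widened["min"] = 0.0
        widened["max"] = widened["max"] * 10
        from nemadelim.morphometrics import RangeTable

        wide_report = compare_to_ranges(rec, RangeTable(widened, range_table.inventory))
        before = report.species_status()
        after = wide_report.species_status()
        for species, status in before.items():
            if status == "consistent":
                assert after[species] == "consistent"

    def test_unknown_stage_raises(self, range_table):
        from nemadelim.morphometrics import RangeTable

        ij_only = RangeTable(
            range_table.frame[range_table.frame["stage"] == "IJ"],
            range_table.inventory[range_table.inventory["stage"] == "IJ"],
        )
        rec = MorphometricRecord("m", "male", {"L": 800.0})
        with pytest.raises(MorphometricsError):
            compare_to_ranges(rec, ij_only)


class TestKeys:
    def test_one_node_key(self):
        key = KeySpec({"character": "L", "op": "lt", "threshold": 400,
                       "if_true": {"species": "P"}, "if_false": {"species": "Q"}})
        rec = MorphometricRecord("x", "IJ", {"L": 350.0})
        result = run_key(rec, key)
        assert result.species == "P"
        assert result.path == [("L", "L < 400", True)]

    def test_two_level_key_hand_trace(self):
        key = KeySpec({
            "character": "T", "op": "ge", "threshold": 83,
            "if_true": {"species": "big-tail"},
            "if_false": {"character": "EP", "op": "ge", "threshold": 100,
                         "if_true": {"species": "far-pore"},
                         "if_false": {"species": "near-pore"}},
        })
        rec = MorphometricRecord("x", "IJ", {"T": 60.0, "EP": 80.0})
        result = run_key(rec, key)
        assert result.species == "near-pore"
        assert [step[2] for step in result.path] == [False, False]

    def test_missing_root_character_is_indeterminate(self):
        key = KeySpec({"character": "L", "op": "lt", "threshold": 400,
                       "if_true": {"species": "P"}, "if_false": {"species": "Q"}})
        result = run_key(MorphometricRecord("x", "IJ", {"T": 60.0}), key)
        assert result.indeterminate
        assert result.missing_character == "L"

    def test_boundary_side_declared(self):
        with pytest.raises(MorphometricsError):
            KeySpec({"character": "L", "op": "around", "threshold": 1,
                     "if_true": {"species": "P"}, "if_false": {"species": "Q"}})

    def test_packaged_key_separates_type_species(self, range_table):
        key = KeySpec.packaged()
        ruandica = MorphometricRecord("r", "IJ", {"T": 56.0, "EP": 78.0, "NR": 55.0})
        zacatecana = MorphometricRecord("z", "IJ", {"T": 58.0, "EP": 89.0, "NR": 70.0})
        bacteriophora = MorphometricRecord("b", "IJ", {"T": 95.0, "EP": 98.0, "NR": 80.0})
        assert run_key(ruandica, key).species == "H. ruandica"
        assert run_key(zacatecana, key).species == "H. zacatecana"
        assert run_key(bacteriophora, key).species == "H. bacteriophora"


class TestSimulatedMorphometrics:
    def test_records_consistent_with_own_species(self, range_table):
        records, labels = simulate_morphometrics(range_table, n_per_species=3, seed=6,
                                                 species=["H. ruandica", "H. megidis"])
        for rec in records:
            status = compare_to_ranges(rec, range_table).species_status()
            assert status[labels[rec.specimen_id]] == "consistent"

    def test_disjoint_ranges_exclude_wrong_species(self, range_table):
        import pandas as pd

        from nemadelim.morphometrics import RangeTable

        frame = pd.DataFrame(
            [
                {"species": "X", "listed_as": "X", "stage": "IJ", "character": "L",
                 "min": 100.0, "max": 200.0, "note": "", "country": "", "reference": "synthetic"},
                {"species": "Y", "listed_as": "Y", "stage": "IJ", "character": "L",
                 "min": 300.0, "max": 400.0, "note": "", "country": "", "reference": "synthetic"},
            ]
        )
        table = RangeTable(frame)
        records, labels = simulate_morphometrics(table, n_per_species=4, seed=2)
        for rec in records:
            status = compare_to_ranges(rec, table).species_status()
            own = labels[rec.specimen_id]
            other = "Y" if own == "X" else "X"
            assert status[own] == "consistent"
            assert status[other] == "excluded"

    def test_fixed_seed_reproducible(self, range_table):
        a, _ = simulate_morphometrics(range_table, 2, seed=3, species=["H. ruandica"])
        b, _ = simulate_morphometrics(range_table, 2, seed=3, species=["H. ruandica"])
        assert [r.characters for r in a] == [r.characters for r in b]

    def test_summary_statistics_shape(self, range_table):
        records, _ = simulate_morphometrics(range_table, 5, seed=4, species=["H. ruandica"])
        stats = summary_statistics(records)
        assert (stats["n"] == 5).all()
        assert (stats["min"] <= stats["mean"]).all() and (stats["mean"] <= stats["max"]).all()
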