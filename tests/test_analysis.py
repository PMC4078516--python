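"""conformer_analysis: parsing, classification, binning, populations, bands."""

import math

import numpy as np
import pandas as pd
import pytest

from acvconf.analysis import (ConformerRecord, ConformerTable,
                              PopulationConfig, SchemaError, TorsionBin,
                              UnclassifiableError, bin_torsions,
                              boltzmann_populations, classify_conformer,
                              energy_band_stats, read_conformer_table)
from acvconf.synthetic import load_table1, load_table2


def _pop(table, name, temperature=298.15, energy_column="dE"):
    frame = boltzmann_populations(
        table, PopulationConfig(temperature=temperature,
                                energy_column=energy_column))
    return float(frame.loc[frame["name"] == name, "population_pct"].iloc[0])


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def test_table2_fixture_has_78_records(table2):
    assert len(table2) == 78


def test_table1_fixture_has_5_tautomers(table1):
    assert sorted(table1.frame["name"]) == ["N1", "N3", "N7", "OHC", "OHT"]


def test_level_filter_skips_other_rows(caplog):
    full = load_table2(level=None)
    assert len(full) == 78 + 18  # extra rows at two other levels


def test_empty_file_schema_error(tmp_path):
    path = tmp_path / "empty.tsv"
    path.write_text("")
    with pytest.raises(SchemaError):
        read_conformer_table(path)


def test_missing_column_schema_error(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("name\tdE\nA1\t0\n")
    with pytest.raises(SchemaError, match="missing mandatory"):
        read_conformer_table(path)


def test_unicode_minus_normalized(tmp_path):
    path = tmp_path / "uni.tsv"
    header = "name\tR\tbeta\tPhi\tphi1\tphi2\tphi3\tphi4\tphi5\tmu\tdE\tdG\n"
    path.write_text(header + "X1\t3.9\t72\t53\t−74.1\t144\t-93\t71\t-73"
                    "\t5.4\t0\t0\n", encoding="utf-8")
    table = read_conformer_table(path)
    assert table.frame["phi1"].iloc[0] == pytest.approx(-74.1)


def test_unparseable_numeric_names_line(tmp_path):
    path = tmp_path / "bad.tsv"
    header = "name\tR\tbeta\tPhi\tphi1\tphi2\tphi3\tphi4\tphi5\tmu\tdE\tdG\n"
    path.write_text(header + "X1\t3.9\t72\t53\tnot_a_number\t144\t-93\t71"
                    "\t-73\t5.4\t0\t0\n")
    with pytest.raises(SchemaError, match="line 2"):
        read_conformer_table(path)


def test_comma_separated_accepted(tmp_path):
    path = tmp_path / "t.csv"
    path.write_text("name,R,beta,Phi,phi1,phi2,phi3,phi4,phi5,mu,dE,dG\n"
                    "X1,3.9,72,53,-74.1,144,-93,71,-73,5.4,0,0\n")
    assert len(read_conformer_table(path)) == 1


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def test_classify_a1_anti():
    record = ConformerRecord(name="A1", phi1=-74.1, phi2=0, phi3=0,
                             phi4=0, phi5=0)
    assert classify_conformer(record) == ("A", "anti")


def test_classify_b1_syn():
    assert classify_conformer(73.5) == ("B", "syn")


def test_classify_zero_errors():
    with pytest.raises(UnclassifiableError):
        classify_conformer(0.0)


def test_classification_partitions_table(table2):
    classes = [classify_conformer(r)[0] for r in table2.records]
    assert classes.count("A") + classes.count("B") == len(table2)
    assert classes.count("A") == 47
    assert classes.count("B") == 31


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

def test_phi2_bimodal_counts(table2):
    report = bin_torsions(table2, "phi2", [(65, 180), (-180, -66)])
    assert report.totals() == [49, 29]
    assert report.counts[0]["A"] == 34 and report.counts[0]["B"] == 15
    assert report.counts[1]["A"] == 13 and report.counts[1]["B"] == 16
    assert report.unbinned["total"] == 0


def test_phi3_bimodal_counts(table2):
    report = bin_torsions(table2, "phi3", [(58, 180), (-180, -58)])
    assert report.totals() == [32, 46]
    assert report.counts[0]["A"] == 22 and report.counts[1]["A"] == 25


def test_phi4_trimodal_counts_circular(table2):
    report = bin_torsions(table2, "phi4",
                          [(175, -173), (41, 118), (-75, -45)])
    assert report.totals() == [28, 28, 22]
    assert [c["A"] for c in report.counts] == [16, 17, 14]
    assert [c["B"] for c in report.counts] == [12, 11, 8]


def test_phi5_trimodal_known_edge_case(table2):
    # one record (phi5 = -39.3) sits outside the printed modal ranges; it
    # lands in the explicit unbinned bucket rather than being guessed
    report = bin_torsions(table2, "phi5",
                          [(165, -166), (39, 123), (-120, -46)])
    assert report.totals() == [29, 29, 19]
    assert report.unbinned["total"] == 1
    assert report.unbinned["names"] == ["A2"]


def test_bins_plus_unbinned_partition_any_binset(table2, rng):
    for _ in range(10):
        lo, hi = sorted(rng.uniform(-180, 180, size=2))
        report = bin_torsions(table2, "phi1", [(lo, hi)])
        assert report.totals()[0] + report.unbinned["total"] == len(table2)


def test_empty_table_zero_counts():
    empty = ConformerTable.from_records([])
    report = bin_torsions(empty, "phi2", [(65, 180), (-180, -66)])
    assert report.totals() == [0, 0]
    assert report.unbinned["total"] == 0


def test_overlapping_bins_rejected(table2):
    with pytest.raises(ValueError, match="overlap"):
        bin_torsions(table2, "phi2", [(0, 100), (50, 150)])


def test_circular_bin_membership():
    wrap = TorsionBin(175, -173)
    assert wrap.contains(180.0)
    assert wrap.contains(-180.0)
    assert wrap.contains(-175.0)
    assert not wrap.contains(0.0)


# ---------------------------------------------------------------------------
# Boltzmann populations
# ---------------------------------------------------------------------------

def test_tautomer_populations_298(table1):
    assert _pop(table1, "N1") == pytest.approx(48.1, abs=0.15)
    assert _pop(table1, "OHC") == pytest.approx(37.7, abs=0.15)
    assert _pop(table1, "OHT") == pytest.approx(14.3, abs=0.15)
    assert _pop(table1, "N3") < 0.05
    assert _pop(table1, "N7") < 0.05


def test_tautomer_populations_273(table1):
    assert _pop(table1, "N1", temperature=273.15) == pytest.approx(49.2,
                                                                   abs=0.1)
    assert _pop(table1, "OHT", temperature=273.15) == pytest.approx(13.1,
                                                                    abs=0.1)


def test_equal_energies_split_evenly():
    records = [ConformerRecord(name=f"X{i}", phi1=-10.0, phi2=0, phi3=0,
                               phi4=0, phi5=0, dE=1.7) for i in range(2)]
    table = ConformerTable.from_records(records)
    frame = boltzmann_populations(table)
    np.testing.assert_allclose(frame["population_pct"], [50.0, 50.0])


def test_populations_sum_to_100(table2):
    frame = boltzmann_populations(table2)
    assert math.isclose(frame["population_pct"].sum(), 100.0, abs_tol=1e-9)


def test_reference_shift_invariance(table2):
    shifted = ConformerTable(table2.frame.assign(dE=table2.frame["dE"] + 7.3))
    np.testing.assert_allclose(
        boltzmann_populations(shifted)["population_pct"],
        boltzmann_populations(table2)["population_pct"], atol=1e-9)


def test_temperature_limits(table2):
    cold = boltzmann_populations(
        table2, PopulationConfig(temperature=1e-3))
    winner = cold.loc[cold["population_pct"].idxmax()]
    assert winner["name"] == "A1"
    assert winner["population_pct"] == pytest.approx(100.0, abs=1e-6)

    hot = boltzmann_populations(
        table2, PopulationConfig(temperature=1e9))
    np.testing.assert_allclose(hot["population_pct"],
                               100.0 / len(table2), atol=1e-4)


def test_negative_temperature_rejected():
    with pytest.raises(ValueError):
        PopulationConfig(temperature=-1.0)


def test_missing_energy_named():
    records = [ConformerRecord(name="X1", phi1=-1, phi2=0, phi3=0, phi4=0,
                               phi5=0, dE=0.0),
               ConformerRecord(name="X2", phi1=1, phi2=0, phi3=0, phi4=0,
                               phi5=0, dE=math.nan)]
    with pytest.raises(ValueError, match="X2"):
        boltzmann_populations(ConformerTable.from_records(records))


def test_dG_column_selectable(table1):
    frame = boltzmann_populations(
        table1, PopulationConfig(energy_column="dG"))
    assert math.isclose(frame["population_pct"].sum(), 100.0, abs_tol=1e-9)


# ---------------------------------------------------------------------------
# energy bands
# ---------------------------------------------------------------------------

def test_band_0_1_has_four_conformers(table2):
    assert energy_band_stats(table2, (0.0, 1.0)).count == 4


def test_band_1_3_has_seven_conformers(table2):
    stats = energy_band_stats(table2, (1.0, 3.0))
    assert stats.count == 7
    assert stats.count_A == 3 and stats.count_B == 4  # three anti, four syn


def test_low_band_ratio(table2):
    assert energy_band_stats(table2, (0.0, 3.0)).ratio_rounded == 0.8


def test_high_band_ratio(table2):
    stats = energy_band_stats(table2, (3.0, 8.5), include_upper=True)
    assert stats.ratio_rounded == 1.7


def test_bands_partition_table(table2):
    total = (energy_band_stats(table2, (0.0, 1.0)).count
             + energy_band_stats(table2, (1.0, 3.0)).count
             + energy_band_stats(table2, (3.0, 8.5), include_upper=True).count)
    assert total == len(table2)


def test_empty_band_ratio_undefined(table2):
    stats = energy_band_stats(table2, (100.0, 200.0))
    assert stats.count == 0
    assert stats.ratio is None
    assert stats.ratio_rounded is None


def test_invalid_band_rejected(table2):
    with pytest.raises(ValueError):
        energy_band_stats(table2, (3.0, 1.0))
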