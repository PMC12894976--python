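"""Tabular artifact I/O: quant tables, channel maps, properties, results."""

import numpy as np
import pandas as pd
import pytest

from crowdtpp.quant_io import (
    QuantFormatError,
    ValidationError,
    ProteomeQuant,
    DEFAULT_TEMPERATURES,
    default_channel_map,
    read_channel_map,
    write_channel_map,
    read_quant_table,
    write_quant_table,
    read_crowder_properties,
    read_fasta,
    read_annotations,
    write_results,
    read_table,
)

GRADIENT = list(DEFAULT_TEMPERATURES)


def toy_table(tmp_path, rows, columns=None, name="quant.tsv"):
    columns = columns or (["protein_id"] + [f"ch{i}" for i in range(10)])
    path = tmp_path / name
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)
    return path


@pytest.fixture
def channel_map():
    return {f"ch{i}": t for i, t in enumerate(GRADIENT)}


class TestReadQuantTable:
    def test_paper_gradient_round_trip(self, tmp_path, channel_map):
        rows = [
            ["P2"] + list(np.linspace(100, 10, 10)),
            ["P1"] + list(np.linspace(200, 20, 10)),
        ]
        quant = read_quant_table(toy_table(tmp_path, rows), channel_map, "control")
        assert list(quant.temperatures) == GRADIENT
        assert quant.protein_ids == ["P1", "P2"]  # sorted by accession
        assert quant.intensities[0, 0] == 200.0

    def test_channels_reordered_by_temperature(self, tmp_path):
        # map channels to temperatures out of column order
        cmap = {"chB": 70.0, "chA": 30.0}
        path = toy_table(
            tmp_path, [["P1", 5.0, 100.0]], columns=["protein_id", "chB", "chA"]
        )
        quant = read_quant_table(path, cmap, "control")
        assert list(quant.temperatures) == [30.0, 70.0]
        assert list(quant.intensities[0]) == [100.0, 5.0]

    def test_unmapped_reporter_column_ignored_with_warning(self, tmp_path, caplog):
        cmap = {"Reporter intensity corrected 1": 30.0,
                "Reporter intensity corrected 2": 70.0}
        cols = ["protein_id"] + list(cmap) + ["Reporter intensity corrected 3"]
        path = toy_table(tmp_path, [["P1", 10.0, 5.0, 999.0]], columns=cols)
        with caplog.at_level("WARNING"):
            quant = read_quant_table(path, cmap, "control")
        assert quant.intensities.shape == (1, 2)
        assert "Reporter intensity corrected 3" in caplog.text

    def test_flagged_reverse_row_dropped_and_counted(self, tmp_path, channel_map):
        cols = ["protein_id"] + list(channel_map) + ["Reverse"]
        rows = [
            ["P1"] + [1.0] * 10 + [""],
            ["REV_P9"] + [1.0] * 10 + ["+"],
        ]
        quant = read_quant_table(toy_table(tmp_path, rows, columns=cols), channel_map, "c")
        assert quant.protein_ids == ["P1"]
        assert quant.n_flagged_dropped == 1

    def test_missing_channel_column_named_in_error(self, tmp_path, channel_map):
        path = toy_table(
            tmp_path, [["P1"] + [1.0] * 9],
            columns=["protein_id"] + [f"ch{i}" for i in range(9)],
        )
        with pytest.raises(QuantFormatError, match="ch9"):
            read_quant_table(path, channel_map, "control")

    def test_duplicate_accession_rejected(self, tmp_path, channel_map):
        rows = [["P1"] + [1.0] * 10, ["P1"] + [2.0] * 10]
        with pytest.raises(QuantFormatError, match="duplicate"):
            read_quant_table(toy_table(tmp_path, rows), channel_map, "control")

    def test_row_order_independent_of_file_order(self, tmp_path, channel_map):
        rows = [["P3"] + [1.0] * 10, ["P1"] + [2.0] * 10, ["P2"] + [3.0] * 10]
        q1 = read_quant_table(toy_table(tmp_path, rows, name="a.tsv"), channel_map, "c")
        q2 = read_quant_table(
            toy_table(tmp_path, rows[::-1], name="b.tsv"), channel_map, "c"
        )
        assert q1.protein_ids == q2.protein_ids
        np.testing.assert_array_equal(q1.intensities, q2.intensities)

    def test_negative_intensity_rejected(self, tmp_path, channel_map):
        rows = [["P1"] + [-1.0] + [1.0] * 9]
        with pytest.raises(ValidationError):
            read_quant_table(toy_table(tmp_path, rows), channel_map, "control")

    def test_write_read_round_trip(self, tmp_path):
        quant = ProteomeQuant(
            protein_ids=["A1", "B2"],
            intensities=np.array([[3.0, 2.0, 1.0], [30.0, 20.0, np.nan]]),
            temperatures=np.array([30.0, 50.0, 70.0]),
            condition="control",
            abundance=np.array([1e8, 2e7]),
        )
        path = tmp_path / "q.tsv"
        cmap = write_quant_table(quant, path)
        back = read_quant_table(path, cmap, "control", abundance_column="LFQ intensity")
        np.testing.assert_allclose(back.intensities, quant.intensities, rtol=1e-9)
        np.testing.assert_allclose(back.abundance, quant.abundance, rtol=1e-9)


class TestChannelMap:
    def test_default_map_covers_gradient(self):
        cmap = default_channel_map()
        assert list(cmap.values()) == GRADIENT
        assert "Reporter intensity corrected 1" in cmap

    def test_yaml_and_tsv_round_trip(self, tmp_path):
        cmap = {"ch1": 30.0, "ch2": 70.0}
        tsv = tmp_path / "map.tsv"
        write_channel_map(cmap, tsv)
        assert read_channel_map(tsv) == cmap
        yml = tmp_path / "map.yaml"
        yml.write_text("ch1: 30\nch2: 70\n")
        assert read_channel_map(yml) == cmap


class TestCrowderProperties:
    def write(self, tmp_path, df):
        path = tmp_path / "props.tsv"
        df.to_csv(path, sep="\t", index=False)
        return path

    def toy(self):
        return pd.DataFrame(
            {
                "reagent": ["ficoll70", "ficoll400", "dextran40", "dextran86", "peg1", "peg8"],
                "molecular_weight": [70, 400, 40, 86, 1, 8],
                "intrinsic_viscosity": [14, 20, 18, 25, 5, 12],
                "polar_atom_fraction": [0.55, 0.55, 0.58, 0.58, 0.33, 0.33],
                "hydrophobicity_index": [0.2, 0.2, 0.1, 0.1, 0.6, 0.6],
                "topology": ["branched", "branched", "linear", "linear", "linear", "linear"],
            }
        )

    def test_six_reagent_round_trip(self, tmp_path):
        props = read_crowder_properties(self.write(tmp_path, self.toy()))
        assert len(props) == 6 and props.index.is_unique

    def test_extra_columns_preserved(self, tmp_path):
        df = self.toy().assign(mass_concentration=150.0)
        props = read_crowder_properties(self.write(tmp_path, df))
        assert "mass_concentration" in props.columns

    def test_polar_fraction_out_of_bounds(self, tmp_path):
        df = self.toy()
        df.loc[0, "polar_atom_fraction"] = 1.3
        with pytest.raises(ValidationError, match="polar_atom_fraction"):
            read_crowder_properties(self.write(tmp_path, df))

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with pytest.raises(QuantFormatError):
            read_crowder_properties(path)

    def test_missing_descriptor_rejected(self, tmp_path):
        df = self.toy().drop(columns=["intrinsic_viscosity"])
        with pytest.raises(QuantFormatError, match="intrinsic_viscosity"):
            read_crowder_properties(self.write(tmp_path, df))


class TestResults:
    def fits(self):
        return pd.DataFrame(
            {
                "protein": ["P1", "P2", "P3"],
                "condition": ["control"] * 3,
                "a": [2000.123456789, 2100.0, 2200.0],
                "b": [40.0, 41.0, 42.0],
                "plateau": [0.1, 0.15, 0.2],
                "tm": [50.123456789, 51.98765432, 52.5],
                "slope": [-0.11, -0.12, -0.13],
                "r2": [0.99, 0.98, 0.97],
                "converged": [True, True, True],
                "qc_pass": [True, True, False],
                "qc_reasons": ["", "", "r2"],
            }
        )

    def calls(self):
        return pd.DataFrame(
            {
                "protein": ["P1", "P2"],
                "crowder": ["ficoll70", "ficoll70"],
                "delta_tm": [3.0, -2.0],
                "z": [2.5, -2.1],
                "call": ["stabilized", "destabilized"],
            }
        )

    def test_round_trip_to_six_significant_digits(self, tmp_path):
        paths = write_results(self.fits(), self.calls(), tmp_path)
        back = read_table(paths["fits"])
        np.testing.assert_allclose(back["tm"], self.fits()["tm"], rtol=1e-7)
        np.testing.assert_allclose(back["a"], self.fits()["a"], rtol=1e-7)

    def test_empty_collections_yield_header_only_files(self, tmp_path):
        paths = write_results(pd.DataFrame(), pd.DataFrame(), tmp_path)
        fits = read_table(paths["fits"])
        calls = read_table(paths["calls"])
        assert len(fits) == 0 and "tm" in fits.columns
        assert len(calls) == 0 and "call" in calls.columns

    def test_unknown_call_class_rejected(self, tmp_path):
        calls = self.calls()
        calls.loc[0, "call"] = "wobbly"
        with pytest.raises(ValidationError, match="wobbly"):
            write_results(self.fits(), calls, tmp_path)

    def test_summary_counts_per_condition(self, tmp_path):
        paths = write_results(self.fits(), self.calls(), tmp_path)
        summary = read_table(paths["summary"])
        row = summary[summary["condition"] == "control"].iloc[0]
        assert row["n_proteins"] == 3 and row["n_qc_pass"] == 2


class TestSequencesAndAnnotations:
    def test_fasta_uniprot_header_unwrapped(self, tmp_path):
        path = tmp_path / "seqs.fasta"
        path.write_text(">sp|P12345|NAME_TEST desc\nMKV\n>Q0K5Z3\nAAA\n")
        seqs = read_fasta(path)
        assert seqs == {"P12345": "MKV", "Q0K5Z3": "AAA"}

    def test_annotations_long_format(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text("protein\tkeyword\nP1\tcofactor\nP1\tsubunit\nP2\tcofactor\n")
        ann = read_annotations(path)
        assert ann == {"P1": {"cofactor", "subunit"}, "P2": {"cofactor"}}

    def test_empty_keyword_rejected(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text("protein\tkeyword\nP1\t \n")
        with pytest.raises(ValidationError):
            read_annotations(path)
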