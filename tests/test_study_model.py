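import numpy as np
import pytest

from fermgenomics.errors import FormatError, ParseError, ValidationError
from fermgenomics.study_model import (
    FermentationRecord,
    StudyTable,
    distinct_conditions,
    load_fermentation_table,
    phenotype_range,
    validate_design,
    write_fermentation_table,
)


def make_record(ferm_id="F1", **kwargs):
    base = dict(
        ferm_id=ferm_id,
        nacl_mM=0.0,
        aa_factor=1.1,
        temperature_C=28.0,
        pH=5.8,
        aeration="N2",
        od_max=6.0,
        mu_max=0.5,
    )
    base.update(kwargs)
    return FermentationRecord(**base)


class TestLoading:
    def test_packaged_table_has_30_fermentors_in_order(self, table1):
        assert len(table1) == 30
        assert table1.ids()[0] == "F1"
        assert table1.ids()[-1] == "F30"
        f16 = table1.get("F16")
        assert (f16.nacl_mM, f16.pH, f16.aeration) == (300.0, 6.4, "N2")
        assert not table1.get("F30").transcriptome
        assert len(table1.transcriptome_records()) == 29

    def test_header_only_file_is_an_empty_table(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text(
            "ferm_id\tnacl_mM\taa_factor\ttemperature_C\tpH\taeration\tod_max\tmu_max\n"
        )
        with pytest.raises(ValidationError, match="no data rows"):
            load_fermentation_table(path)

    def test_duplicate_fermentor_id_is_rejected_by_name(self, table1, tmp_path):
        frame = table1.to_frame()
        frame.loc[len(frame)] = frame.iloc[0]
        path = tmp_path / "dup.tsv"
        frame.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValidationError, match="F1"):
            load_fermentation_table(path)

    def test_missing_required_column(self, table1, tmp_path):
        frame = table1.to_frame().drop(columns=["pH"])
        path = tmp_path / "nocol.tsv"
        frame.to_csv(path, sep="\t", index=False)
        with pytest.raises(FormatError, match="pH"):
            load_fermentation_table(path)

    def test_non_numeric_phenotype_names_the_row(self, table1, tmp_path):
        frame = table1.to_frame().astype({"mu_max": object})
        frame.loc[2, "mu_max"] = "fast"
        path = tmp_path / "bad.tsv"
        frame.to_csv(path, sep="\t", index=False)
        with pytest.raises(ParseError, match="F3"):
            load_fermentation_table(path)

    def test_off_design_levels_need_strict_false(self, table1, tmp_path):
        frame = table1.to_frame()
        frame.loc[0, "temperature_C"] = 30.0
        path = tmp_path / "odd.tsv"
        frame.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValidationError, match="temperature_C"):
            load_fermentation_table(path)
        assert load_fermentation_table(path, strict=False).get("F1").temperature_C == 30.0

    def test_round_trip_reproduces_records(self, table1, tmp_path):
        path = tmp_path / "copy.tsv"
        write_fermentation_table(table1, path)
        again = load_fermentation_table(path)
        assert again.records == table1.records


class TestDistinctConditions:
    def test_design_has_24_distinct_conditions(self, table1):
        count, groups = distinct_conditions(table1)
        assert count == 24
        assert groups[(0.0, 2.0, 37.0, 5.8, "N2")] == ["F18", "F20", "F30"]

    def test_identical_rows_collapse_to_one(self):
        table = StudyTable([make_record(f"F{i}") for i in range(1, 6)])
        count, groups = distinct_conditions(table)
        assert count == 1
        assert len(next(iter(groups.values()))) == 5

    def test_partial_sharing(self):
        table = StudyTable(
            [
                make_record("A", temperature_C=28.0),
                make_record("B", temperature_C=37.0),
                make_record("C", temperature_C=28.0),
            ]
        )
        count, groups = distinct_conditions(table)
        assert count == 2
        assert sorted(len(g) for g in groups.values()) == [1, 2]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_groups_partition_the_table(self, seed):
        rng = np.random.default_rng(seed)
        records = [
            make_record(
                f"F{i}",
                temperature_C=float(rng.choice([28.0, 37.0])),
                pH=float(rng.choice([5.2, 5.8, 6.4])),
                aeration=str(rng.choice(["N2", "O2"])),
            )
            for i in range(20)
        ]
        table = StudyTable(records)
        _, groups = distinct_conditions(table)
        all_ids = [fid for members in groups.values() for fid in members]
        assert sorted(all_ids) == sorted(table.ids())


class TestPhenotypeRange:
    def test_growth_rate_extremes(self, table1):
        r = phenotype_range(table1, "mu_max")
        assert (r.min, r.max) == (0.23, 0.80)
        assert r.argmax == "F1"
        # F16 and F28 tie at 0.23; the first record in table order wins
        assert r.argmin == "F16"

    def test_biomass_yield_extremes(self, table1):
        r = phenotype_range(table1, "od_max")
        assert r.min == 4.16
        assert r.max == 7.74  # F17, the largest OD printed in the design table
        assert (r.argmin, r.argmax) == ("F16", "F17")

    def test_single_record(self):
        table = StudyTable([make_record("A", mu_max=0.4)])
        r = phenotype_range(table, "mu_max")
        assert r.min == r.max == 0.4

    def test_unknown_phenotype(self, table1):
        with pytest.raises(KeyError):
            phenotype_range(table1, "glucose")

    def test_extremes_bound_all_values(self, table1):
        r = phenotype_range(table1, "od_max")
        values = [rec.od_max for rec in table1]
        assert all(r.min <= v <= r.max for v in values)


class TestValidateDesign:
    def test_nacl_balanced_over_design_points(self, table1):
        report = validate_design(table1)
        assert report.n_design_points == 24
        assert report.level_counts["nacl_mM"] == {0.0: 12, 300.0: 12}

    def test_full_factorial_is_warning_free(self):
        records = [
            make_record(f"F{i}", nacl_mM=nacl, temperature_C=temp)
            for i, (nacl, temp) in enumerate(
                [(0.0, 28.0), (0.0, 37.0), (300.0, 28.0), (300.0, 37.0)]
            )
        ]
        report = validate_design(StudyTable(records))
        assert report.warnings == []
        assert report.level_counts["nacl_mM"] == {0.0: 2, 300.0: 2}

    def test_missing_combination_is_flagged(self):
        records = [
            make_record("A", pH=5.2, aeration="N2"),
            make_record("B", pH=5.2, aeration="O2"),
            make_record("C", pH=6.4, aeration="N2"),
        ]
        report = validate_design(StudyTable(records))
        assert any("pH=6.4" in w and "aeration=O2" in w for w in report.warnings)

    def test_report_serializes_to_json(self, table1, tmp_path):
        import json

        report = validate_design(table1)
        text = report.to_json(tmp_path / "balance.json")
        payload = json.loads(text)
        assert payload["n_design_points"] == 24
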