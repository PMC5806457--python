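import json

import numpy as np
import pandas as pd
import pytest

import leafagree as la
from leafagree import fileio
from leafagree.errors import ConfigurationError, ParseError


class TestDesignTruthRoundTrip:
    def test_design_round_trip(self, design130, tmp_path):
        path = tmp_path / "design.csv"
        fileio.write_design_csv(design130, path)
        back = fileio.read_design_csv(path)
        pd.testing.assert_frame_equal(back, design130)

    def test_truth_round_trip(self, truth130, tmp_path):
        fileio.write_truth_csv(truth130, tmp_path / "truth.csv")
        fileio.write_emergence_json(truth130, tmp_path / "emergence.json")
        back = fileio.read_ground_truth(
            tmp_path / "truth.csv", tmp_path / "emergence.json"
        )
        pd.testing.assert_frame_equal(back.counts, truth130.counts)
        assert back.young_age_days == truth130.young_age_days
        for k, v in truth130.emergence_times.items():
            np.testing.assert_allclose(back.emergence_times[k], v)


class TestAnnotationCsv:
    def test_round_trip(self, expert_annotations, tmp_path):
        path = tmp_path / "ann.csv"
        fileio.write_annotation_csv(expert_annotations, path)
        back = fileio.read_annotation_csv(path)
        expected = expert_annotations[fileio.ANNOTATION_COLUMNS].reset_index(drop=True)
        pd.testing.assert_frame_equal(back, expected)

    def test_negative_count_parse_error_names_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "observer_id,experience,image_id,dataset_label,mode,reading_index,count\n"
            "o1,ExP,img1,A,tool,1,4\n"
            "o1,ExP,img2,A,tool,1,-1\n"
        )
        with pytest.raises(ParseError) as err:
            fileio.read_annotation_csv(path)
        assert err.value.row == 2
        assert err.value.column == "count"

    def test_non_integer_count_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "observer_id,experience,image_id,dataset_label,mode,reading_index,count\n"
            "o1,ExP,img1,A,tool,1,many\n"
        )
        with pytest.raises(ParseError):
            fileio.read_annotation_csv(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("observer_id,count\no1,3\n")
        with pytest.raises(ParseError):
            fileio.read_annotation_csv(path)

    def test_header_only_yields_empty_set(self, tmp_path, caplog):
        path = tmp_path / "empty.csv"
        path.write_text(
            "observer_id,experience,image_id,dataset_label,mode,reading_index,count\n"
        )
        with caplog.at_level("WARNING", logger="leafagree"):
            frame = fileio.read_annotation_csv(path)
        assert len(frame) == 0
        assert any("no rows" in rec.message for rec in caplog.records)


class TestCitizenExport:
    def test_round_trip(self, citizen_study, design130, tmp_path):
        path = tmp_path / "citizen.csv"
        fileio.write_citizen_export(citizen_study, design130, path, seed=0)
        back = fileio.read_citizen_export(path)
        pd.testing.assert_frame_equal(back, citizen_study)

    def test_dot_payload_length_is_count(self, citizen_study, design130, tmp_path):
        path = tmp_path / "citizen.csv"
        fileio.write_citizen_export(citizen_study, design130, path, seed=0)
        raw = pd.read_csv(path)
        lengths = raw["annotation_json"].map(lambda s: len(json.loads(s)))
        merged = raw.assign(n_dots=lengths)
        study = citizen_study.reset_index(drop=True)
        assert (merged["n_dots"].to_numpy() == study["count"].to_numpy()).all()

    def test_worded_confidence_mapped(self, tmp_path):
        path = tmp_path / "citizen.csv"
        path.write_text(
            "classification_id,user_id,logged_in,image_id,annotation_json,confidence\n"
            '1,u1,True,img1,"[{""x"": 1, ""y"": 2}, {""x"": 3, ""y"": 4}]",Yes\n'
            '2,u2,False,img1,"[]",Not sure\n'
            '3,u3,True,img1,"[{""x"": 0, ""y"": 0}]",missed leaves\n'
        )
        study = fileio.read_citizen_export(path)
        assert study["confidence"].tolist() == [3, 2, 1]
        assert study["count"].tolist() == [2, 0, 1]
        assert study["logged_in"].tolist() == [True, False, True]

    def test_malformed_json_rejected_with_row(self, tmp_path):
        path = tmp_path / "citizen.csv"
        path.write_text(
            "classification_id,user_id,logged_in,image_id,annotation_json,confidence\n"
            "1,u1,True,img1,not-json,3\n"
        )
        with pytest.raises(ParseError) as err:
            fileio.read_citizen_export(path)
        assert err.value.row == 1

    def test_unknown_confidence_rejected(self, tmp_path):
        path = tmp_path / "citizen.csv"
        path.write_text(
            "classification_id,user_id,logged_in,image_id,annotation_json,confidence\n"
            '1,u1,True,img1,"[]",maybe\n'
        )
        with pytest.raises(ParseError):
            fileio.read_citizen_export(path)


class TestAnalysisOutputs:
    def test_ratings_matrix_round_trip(self, pool_annotations, tmp_path):
        mat = la.ratings_matrix(pool_annotations)
        path = tmp_path / "ratings.csv"
        fileio.write_ratings_csv(mat, path)
        back = fileio.read_ratings_csv(path)
        pd.testing.assert_frame_equal(back, mat.astype(float), check_names=False)

    def test_consensus_round_trip(self, citizen_study, tmp_path):
        cc = la.consensus_counts(citizen_study, "average")
        path = tmp_path / "consensus.csv"
        fileio.write_consensus_csv(cc, path)
        back = fileio.read_consensus_csv(path)
        assert back.method == "average"
        pd.testing.assert_frame_equal(
            back.frame, cc.frame, check_dtype=False
        )

    def test_agreement_report_json(self, paired_small, tmp_path):
        report = la.agreement_report(paired_small)
        path = tmp_path / "report.json"
        fileio.write_agreement_report(report, path)
        payload = json.loads(path.read_text())
        assert payload["mse"] == pytest.approx(5 / 3)

    def test_anova_csv_mirrors_terms(self, tmp_path, expert_annotations, design130):
        table = la.build_count_table(expert_annotations, design130, "single")
        result = la.fit_interaction_anova(table)
        path = tmp_path / "anova.csv"
        fileio.write_anova_csv(result, path)
        back = pd.read_csv(path)
        assert back.columns.tolist() == ["term", "sum_sq", "F", "p"]
        assert back["term"].tolist() == ["time", "cultivar", "time:cultivar"]


class TestConfig:
    def test_defaults_and_overrides(self, tmp_path):
        path = tmp_path / "config.toml"
        path.write_text(
            "seed = 99\n[design]\nn_replicates = 3\n[analysis]\nn_trials = 10\n"
        )
        cfg = fileio.load_config(path)
        assert cfg.seed == 99
        assert cfg.n_replicates == 3
        assert cfg.n_trials == 10
        assert cfg.n_timepoints == 13  # untouched default

    def test_missing_seed_rejected(self, tmp_path):
        path = tmp_path / "config.toml"
        path.write_text("[design]\nn_replicates = 3\n")
        with pytest.raises(ConfigurationError):
            fileio.load_config(path)

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "config.toml"
        path.write_text("seed = 1\n[design]\nn_rows = 7\n")
        with pytest.raises(ConfigurationError):
            fileio.load_config(path)

    def test_config_hash_stable_and_sensitive(self):
        a = fileio.PipelineConfig()
        b = fileio.PipelineConfig()
        c = fileio.PipelineConfig(seed=1)
        assert fileio.config_hash(a) == fileio.config_hash(b)
        assert fileio.config_hash(a) != fileio.config_hash(c)

    def test_manifest_written(self, tmp_path):
        cfg = fileio.PipelineConfig()
        path = fileio.write_manifest(tmp_path, cfg)
        payload = json.loads(path.read_text())
        assert payload["seed"] == cfg.seed
        assert "numpy" in payload["versions"]
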