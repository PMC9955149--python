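import numpy as np
import pandas as pd
import pytest

from diacascade import (
    FeatureTable,
    Schema,
    TrainConfig,
    cascade_predict_table,
    cascade_train,
    load_model,
    load_table,
    pid_schema,
    save_model,
)
from diacascade.errors import InputError, ModelFormatError, SchemaError


def _write_csv(path, rows, header):
    path.write_text(header + "\n" + "\n".join(rows) + "\n")


class TestLoadTable:
    def test_pid_dialect_with_binary_outcome_mapping(self, tmp_path):
        p = tmp_path / "pid.csv"
        header = "pregnancies,glucose,blood_pressure,skin_thickness,insulin,bmi,pedigree,age,outcome"
        _write_csv(
            p,
            [
                "1,85,66,29,0,26.6,0.351,31,0",
                "8,183,64,0,0,23.3,0.672,32,1",
                "2,95,70,30,80,28.0,0.4,25,0",
            ],
            header,
        )
        t = load_table(p, pid_schema())
        assert t.n_rows == 3 and t.n_attributes == 8
        assert list(t.labels) == [1, 2, 1]
        assert t.attribute_names[1] == "glucose"
        assert t.values[1, 1] == 183.0

    def test_column_order_invariance(self, tmp_path):
        schema = Schema(
            column_map={"x": "a", "y": "b"},
            label_column="cls",
            label_encoding={0: 1, 1: 2},
        )
        p1, p2 = tmp_path / "one.csv", tmp_path / "two.csv"
        _write_csv(p1, ["1,2,0", "3,4,1"], "x,y,cls")
        _write_csv(p2, ["2,0,1", "4,1,3"], "y,cls,x")
        t1, t2 = load_table(p1, schema), load_table(p2, schema)
        assert t1.attribute_names == t2.attribute_names
        np.testing.assert_array_equal(t1.values, t2.values)
        np.testing.assert_array_equal(t1.labels, t2.labels)

    def test_missing_column_names_the_column(self, tmp_path):
        p = tmp_path / "bad.csv"
        _write_csv(p, ["1,0"], "x,cls")
        schema = Schema(column_map={"x": "a", "y": "b"}, label_column="cls")
        with pytest.raises(SchemaError, match="'y'"):
            load_table(p, schema)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("x,cls\n")
        schema = Schema(column_map={"x": "a"}, label_column="cls")
        with pytest.raises(InputError):
            load_table(p, schema)

    def test_unknown_label_value_names_the_row(self, tmp_path):
        p = tmp_path / "lab.csv"
        _write_csv(p, ["1,0", "2,7"], "x,cls")
        schema = Schema(column_map={"x": "a"}, label_column="cls", label_encoding={0: 1})
        with pytest.raises(InputError, match="row 1"):
            load_table(p, schema)

    @pytest.mark.parametrize(
        "policy,expected_rows", [("keep", 3), ("drop-row", 2), ("impute-column-median", 3)]
    )
    def test_missing_value_policies(self, tmp_path, policy, expected_rows):
        p = tmp_path / "mv.csv"
        _write_csv(p, ["1,2,0", "oops,3,0", "5,6,1"], "x,y,cls")
        schema = Schema(
            column_map={"x": "a", "y": "b"}, label_column="cls",
            label_encoding={0: 1, 1: 2},
        )
        t = load_table(p, schema, missing=policy)
        assert t.n_rows == expected_rows
        if policy == "keep":
            assert np.isnan(t.values[1, 0])
        elif policy == "impute-column-median":
            assert t.values[1, 0] == 3.0  # median of {1, 5}


class TestFeatureTable:
    def test_invariants_enforced(self):
        with pytest.raises(InputError):
            FeatureTable(["a", "a"], np.ones((2, 2)), np.array([1, 1]))
        with pytest.raises(InputError):
            FeatureTable(["a"], np.ones((2, 1)), np.array([1, 7]))
        with pytest.raises(InputError):
            FeatureTable(["a", "b"], np.ones((2, 1)), np.array([1, 1]))

    def test_csv_round_trip_preserves_values_and_labels(self, tmp_path, tiny_table):
        p = tmp_path / "t.csv"
        tiny_table.to_csv(p)
        back = FeatureTable.from_dataframe(pd.read_csv(p))
        np.testing.assert_array_equal(back.values, tiny_table.values)
        np.testing.assert_array_equal(back.labels, tiny_table.labels)
        assert back.attribute_names == tiny_table.attribute_names


@pytest.fixture(scope="module")
def trained():
    rng = np.random.default_rng(0)
    X = np.abs(
        np.vstack([rng.normal(m, 0.3, (20, 3)) for m in (1.0, 3.0, 5.0, 7.0)])
    )
    t = FeatureTable(["a", "b", "c"], X, np.repeat([1, 2, 3, 4], 20))
    return cascade_train(t, TrainConfig(max_epochs=60, seed=1), hidden=(4,))


class TestModelSerialization:

    def test_round_trip_identical_predictions(self, tmp_path, trained):
        p = tmp_path / "model.json"
        save_model(trained, p)
        back = load_model(p)
        rng = np.random.default_rng(5)
        probe = FeatureTable(
            ["a", "b", "c"], np.abs(rng.normal(2, 1, (20, 3))), np.ones(20, dtype=int)
        )
        elig = np.ones(20, dtype=bool)
        np.testing.assert_array_equal(
            cascade_predict_table(trained, probe, elig),
            cascade_predict_table(back, probe, elig),
        )
        # weights reproduce bit-exactly
        for a, b in zip(trained.nets[0].weights, back.nets[0].weights):
            np.testing.assert_array_equal(a, b)

    def test_round_trip_preserves_trace(self, tmp_path, trained):
        p = tmp_path / "model.json"
        save_model(trained, p)
        back = load_model(p)
        assert back.nets[0].trace == trained.nets[0].trace

    def test_version_mismatch_rejected(self, tmp_path, trained):
        import json

        p = tmp_path / "model.json"
        save_model(trained, p)
        payload = json.loads(p.read_text())
        payload["version"] = 999
        p.write_text(json.dumps(payload))
        with pytest.raises(ModelFormatError, match="version"):
            load_model(p)

    def test_truncated_file_rejected(self, tmp_path, trained):
        p = tmp_path / "model.json"
        save_model(trained, p)
        p.write_text(p.read_text()[:50])
        with pytest.raises(ModelFormatError):
            load_model(p)
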