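"""Path grammar, extraction semantics, joins — checked against naive
re-implementations."""

import numpy as np
import pytest

from medintel.errors import ContractError, PathSyntaxError
from medintel.fhir_core import parse_resource
from medintel.flatten import (
    Frame,
    compile_pathspec,
    evaluate_path,
    extract,
    join_frames,
    load_pathspecs_yaml,
)
from medintel.synth import builders as b

from oracles import naive_join, naive_walk

import pandas as pd


class TestGrammar:
    @pytest.mark.parametrize(
        "expr",
        [
            "code.coding.where(system=http://loinc.org).code | first",
            "valueQuantity.value",
            "code.coding[0].code",
            "code.coding.code | join(;)",
            "code.coding.code | explode",
        ],
    )
    def test_accepts_valid_expressions(self, expr):
        spec = compile_pathspec("c", expr)
        assert spec.steps

    @pytest.mark.parametrize(
        "expr, fragment",
        [
            ("code..coding", "empty path segment"),
            ("", "empty path"),
            ("code.", "empty path segment"),
            ("code.coding[x]", "integer"),
            ("code.where(text=foo)", "system"),
            ("a.b | shuffle", "unknown list mode"),
        ],
    )
    def test_rejects_malformed_with_position(self, expr, fragment):
        with pytest.raises(PathSyntaxError) as exc:
            compile_pathspec("c", expr)
        assert fragment in str(exc.value)
        assert "^" in str(exc.value)  # caret rendering

    def test_error_position_points_at_offence(self):
        with pytest.raises(PathSyntaxError) as exc:
            compile_pathspec("c", "code..coding")
        assert exc.value.position == 5


class TestExtract:
    def _obs(self):
        return parse_resource(
            {
                "resourceType": "Observation",
                "id": "o1",
                "code": {
                    "coding": [
                        {"system": "urn:local", "code": "GLU"},
                        {"system": "http://loinc.org", "code": "2339-0"},
                    ]
                },
                "subject": {"reference": "Patient/p1"},
                "valueQuantity": {"value": 99.0, "unit": "mg/dL"},
            }
        )

    def test_where_filter_selects_by_system(self):
        spec = compile_pathspec("loinc", "code.coding.where(system=http://loinc.org).code | first")
        frame = extract([self._obs()], [spec])
        assert frame.df["loinc"].tolist() == ["2339-0"]

    def test_missing_path_yields_null_row_kept(self):
        spec = compile_pathspec("v", "valueQuantity.value")
        patient = parse_resource({"resourceType": "Patient", "id": "p"})
        frame = extract([self._obs(), patient], [spec])
        assert len(frame) == 2
        assert frame.df["v"].tolist()[0] == 99.0
        assert pd.isna(frame.df["v"].tolist()[1])

    def test_explode_multiplies_rows_and_empty_list_keeps_one(self):
        codes = compile_pathspec("code", "code.coding.code | explode")
        subj = compile_pathspec("subject", "subject.reference")
        patient = parse_resource({"resourceType": "Patient", "id": "p"})
        frame = extract([self._obs(), patient], [codes, subj])
        assert frame.df["code"].tolist()[:2] == ["GLU", "2339-0"]
        assert frame.df["subject"].tolist() == ["Patient/p1", "Patient/p1", None]
        assert len(frame) == 3  # 2 exploded + 1 null row

    def test_two_explodes_rejected(self):
        e1 = compile_pathspec("a", "code.coding.code | explode")
        e2 = compile_pathspec("b", "code.coding.system | explode")
        with pytest.raises(ContractError):
            extract([self._obs()], [e1, e2])

    def test_type_clash_falls_back_to_string(self, caplog):
        spec = compile_pathspec("v", "value")
        trees = [
            {"resourceType": "Basic", "id": "1", "value": 1.5},
            {"resourceType": "Basic", "id": "2", "value": "high"},
        ]
        with caplog.at_level("WARNING"):
            frame = extract([parse_resource(t) for t in trees], [spec])
        assert frame.df["v"].tolist() == ["1.5", "high"]

    def test_deterministic_csv(self, demo_corpus):
        envelopes, _ = demo_corpus
        obs = [e for e in envelopes if e.resource_type == "Observation"][:200]
        specs = [
            compile_pathspec("code", "code.coding.where(system=http://loinc.org).code | first"),
            compile_pathspec("value", "valueQuantity.value"),
            compile_pathspec("subject", "subject.reference"),
        ]
        assert extract(obs, specs).to_csv_text() == extract(obs, specs).to_csv_text()

    def test_matches_naive_walker_on_generated_resources(self, demo_corpus):
        envelopes, _ = demo_corpus
        specs = [
            compile_pathspec("code", "code.coding.where(system=http://loinc.org).code | first"),
            compile_pathspec("any_code", "code.coding.code | first"),
            compile_pathspec("value", "valueQuantity.value"),
            compile_pathspec("unit", "valueQuantity.unit"),
            compile_pathspec("subject", "subject.reference"),
            compile_pathspec("time", "effectiveDateTime"),
        ]
        sample = envelopes[:600]
        frame = extract(sample, specs)
        for col_idx, spec in enumerate(specs):
            got = frame.df[spec.column_name].tolist()
            for row, env in enumerate(sample):
                expected = naive_walk(env.raw, list(spec.steps))
                expected_first = expected[0] if expected else None
                value = got[row]
                if expected_first is None:
                    assert value is None or value != value
                else:
                    assert value == expected_first or float(value) == expected_first


class TestJoin:
    def _frame(self, rows):
        df = pd.DataFrame(rows)
        df.insert(0, "resource_type", "X")
        df.insert(1, "resource_id", [str(i) for i in range(len(df))])
        return Frame(df)

    def test_inner_join_on_shared_ids(self):
        left = self._frame([{"pid": "a", "x": 1}, {"pid": "b", "x": 2}, {"pid": "c", "x": 3}])
        right = self._frame([{"pid": "a", "y": 10}, {"pid": "c", "y": 30}, {"pid": "d", "y": 40}])
        out = join_frames(left, right, on="pid", how="inner")
        assert sorted(out.df["pid"]) == ["a", "c"]

    def test_left_join_keeps_unmatched_with_nulls(self):
        left = self._frame([{"pid": "a", "x": 1}, {"pid": None, "x": 2}])
        right = self._frame([{"pid": "a", "y": 10}])
        out = join_frames(left, right, on="pid", how="left")
        assert len(out) == 2
        null_row = out.df[out.df["pid"].isna()]
        assert null_row["y"].isna().all()  # null keys never match

    def test_random_joins_match_nested_loop(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            keys = list("abcdef")
            left_rows = [
                {"pid": keys[rng.integers(0, 6)] if rng.random() > 0.2 else None,
                 "x": int(rng.integers(0, 100))}
                for _ in range(rng.integers(1, 8))
            ]
            right_rows = [
                {"pid": keys[rng.integers(0, 6)] if rng.random() > 0.2 else None,
                 "y": int(rng.integers(0, 100))}
                for _ in range(rng.integers(1, 8))
            ]
            for how in ("inner", "left"):
                got = join_frames(self._frame(left_rows), self._frame(right_rows), "pid", how)
                expected = naive_join(left_rows, right_rows, "pid", how)
                got_keys = sorted(
                    (r if r == r and r is not None else "<null>", int(x))
                    for r, x in zip(got.df["pid"], got.df["x"])
                )
                exp_keys = sorted(
                    (r.get("pid") if r.get("pid") is not None else "<null>", int(r["x"]))
                    for r in expected
                )
                assert got_keys == exp_keys, how


def test_pathspecs_load_from_yaml(tmp_path):
    doc = tmp_path / "specs.yaml"
    doc.write_text(
        "columns:\n"
        "  - name: code\n"
        "    path: code.coding.where(system=http://loinc.org).code | first\n"
        "  - name: value\n"
        "    path: valueQuantity.value\n"
    )
    specs = load_pathspecs_yaml(doc)
    assert [s.column_name for s in specs] == ["code", "value"]
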