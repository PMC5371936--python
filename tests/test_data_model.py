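"""Domain-type validation and file round trips."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cohortdem import (
    CohortCensus,
    OvipositionTable,
    ProjectionMatrix,
    SchemaError,
    StageSchema,
    ValidationError,
    cbb_schema,
    read_census,
    read_matrix,
    read_oviposition,
    write_census,
    write_matrix,
    write_oviposition,
)

from conftest import make_census_frame


class TestStageSchema:
    def test_cbb_schema_shape(self, schema):
        assert schema.n_stages == 6
        assert schema.stages[0] == "egg"
        assert schema.reproductive_stage == "adult"
        assert schema.projection_interval_days == 6

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(stages=("a", "a"), reproductive_stage="a"),
            dict(stages=("a", "b"), reproductive_stage="a"),
            dict(stages=("a", "b"), reproductive_stage="b",
                 projection_interval_days=0),
        ],
    )
    def test_invalid_schemas_rejected(self, kwargs):
        with pytest.raises(SchemaError):
            StageSchema(**kwargs)

    def test_unknown_stage_label(self, schema):
        with pytest.raises(SchemaError, match="adultt"):
            schema.index("adultt")


class TestCensusValidation:
    def test_round_trip(self, tmp_path, schema):
        df = make_census_frame(
            [
                ("c1", "i1", 0, "egg", "alive"),
                ("c1", "i1", 1, "egg", "alive"),
                ("c1", "i1", 2, "larva", "alive"),
            ]
        )
        census = CohortCensus(records=df, schema=schema).validate()
        path = tmp_path / "census.csv"
        write_census(census, path)
        back = read_census(path, schema)
        assert back.records.equals(census.records)

    def test_typo_stage_rejected(self, tmp_path, schema):
        path = tmp_path / "census.csv"
        path.write_text(
            "cohort_id,individual_id,day,stage,status\nc1,i1,0,adultt,alive\n"
        )
        with pytest.raises(SchemaError, match="adultt"):
            read_census(path, schema)

    def test_alive_after_dead_rejected(self, schema):
        df = make_census_frame(
            [
                ("c1", "i1", 6, "egg", "dead"),
                ("c1", "i1", 7, "egg", "alive"),
            ]
        )
        with pytest.raises(ValidationError, match="i1"):
            CohortCensus(records=df, schema=schema).validate()

    def test_reverse_molt_rejected(self, schema):
        df = make_census_frame(
            [
                ("c1", "i1", 0, "larva", "alive"),
                ("c1", "i1", 1, "egg", "alive"),
            ]
        )
        with pytest.raises(ValidationError, match="reverse molt"):
            CohortCensus(records=df, schema=schema).validate()

    def test_non_increasing_days_rejected(self, schema):
        df = make_census_frame(
            [
                ("c1", "i1", 3, "egg", "alive"),
                ("c1", "i1", 3, "egg", "alive"),
            ]
        )
        with pytest.raises(ValidationError, match="strictly increase"):
            CohortCensus(records=df, schema=schema).validate()

    def test_empty_census_rejected(self, schema):
        df = make_census_frame([])
        with pytest.raises(ValidationError, match="empty"):
            CohortCensus(records=df, schema=schema).validate()


class TestOviposition:
    def test_round_trip(self, tmp_path):
        import pandas as pd

        df = pd.DataFrame(
            {
                "female_id": ["f1", "f1", "f2"],
                "treatment": ["control"] * 3,
                "day": [0, 1, 0],
                "eggs": [2, 0, 5],
            }
        )
        table = OvipositionTable(records=df).validate()
        path = tmp_path / "ovi.csv"
        write_oviposition(table, path)
        assert read_oviposition(path).records.equals(df)

    def test_duplicate_female_day_rejected(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "female_id": ["f1", "f1"],
                "treatment": ["control"] * 2,
                "day": [0, 0],
                "eggs": [1, 2],
            }
        )
        with pytest.raises(ValidationError, match="duplicate"):
            OvipositionTable(records=df).validate()


class TestMatrixSerialization:
    def test_round_trip_identity(self, tmp_path, schema):
        m = ProjectionMatrix(
            schema=schema,
            P=np.array([0.1, 0.2, 0.05, 0.3, 0.15, 0.99]),
            G=np.array([0.8, 0.5, 0.9, 0.6, 0.7]),
            F=20.0,
        ).validate()
        path = tmp_path / "m.json"
        write_matrix(m, path)
        back = read_matrix(path)
        assert np.array_equal(back.P, m.P)
        assert np.array_equal(back.G, m.G)
        assert back.F == m.F
        assert back.schema == m.schema

    def test_named_blocks_match_independent_serializer(self, tmp_path, schema):
        m = ProjectionMatrix(
            schema=schema,
            P=np.array([0.1, 0.1, 0.1, 0.1, 0.1, 0.99]),
            G=np.array([0.8, 0.8, 0.8, 0.8, 0.8]),
            F=20.0,
        )
        path = tmp_path / "m.json"
        write_matrix(m, path)
        raw = json.loads(path.read_text())
        assert raw["P"] == m.P.tolist()
        assert raw["G"] == m.G.tolist()
        assert raw["F"] == 20.0

    def test_mask_violation_rejected(self, tmp_path, schema):
        m = ProjectionMatrix(
            schema=schema,
            P=np.full(6, 0.1),
            G=np.full(5, 0.5),
            F=3.0,
        )
        path = tmp_path / "m.json"
        write_matrix(m, path)
        raw = json.loads(path.read_text())
        raw["matrix"][2][4] = 0.25  # off-structure entry
        path.write_text(json.dumps(raw))
        with pytest.raises(ValidationError, match=r"\(2, 4\)"):
            read_matrix(path)

    @pytest.mark.parametrize(
        "P,G,F",
        [
            (np.array([1.1, 0.5]), np.array([0.2]), 1.0),
            (np.array([0.5, 0.5]), np.array([0.6]), 1.0),  # P1+G1 > 1
            (np.array([0.5, 0.5]), np.array([0.2]), -1.0),
        ],
    )
    def test_invalid_matrices_rejected(self, schema2, P, G, F):
        with pytest.raises(ValidationError):
            ProjectionMatrix(schema=schema2, P=P, G=G, F=F).validate()

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(data=st.data())
    def test_round_trip_property(self, tmp_path_factory, data):
        """read ∘ write is the identity on randomly generated matrices."""
        s = data.draw(st.integers(min_value=2, max_value=8))
        stages = tuple(f"s{i}" for i in range(s))
        schema = StageSchema(stages=stages, reproductive_stage=stages[-1],
                             projection_interval_days=data.draw(
                                 st.integers(min_value=1, max_value=30)))
        unit = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)
        P = np.array(data.draw(st.lists(unit, min_size=s, max_size=s)))
        G = np.array(
            data.draw(st.lists(unit, min_size=s - 1, max_size=s - 1))
        )
        G = np.minimum(G, 1.0 - P[:-1])
        F = data.draw(st.floats(min_value=0.0, max_value=1e6, allow_nan=False))
        m = ProjectionMatrix(schema=schema, P=P, G=G, F=F).validate()
        path = tmp_path_factory.mktemp("rt") / "m.json"
        write_matrix(m, path)
        back = read_matrix(path)
        assert np.array_equal(back.P, m.P)
        assert np.array_equal(back.G, m.G)
        assert back.F == m.F
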