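import pytest

from obskit import (
    KeyBinding,
    KeystrokeSchema,
    SessionRecord,
    default_info,
    demo_schema,
    gen_session_record,
)


@pytest.fixture
def schema() -> KeystrokeSchema:
    return demo_schema()


@pytest.fixture
def schema_no_conditions() -> KeystrokeSchema:
    return KeystrokeSchema(
        name="bare",
        bindings=(
            KeyBinding("a", "hitting", "frequency"),
            KeyBinding("z", "aggression", "duration"),
        ),
    )


@pytest.fixture
def session(schema) -> SessionRecord:
    return gen_session_record(
        schema, {"hitting": 0.2, "kicking": 0.1, "aggression": 0.05},
        duration_s=120.0, seed=7,
    )


@pytest.fixture
def empty_session(schema) -> SessionRecord:
    return SessionRecord(info=default_info(schema, 60.0), schema=schema)
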