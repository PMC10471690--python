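import numpy as np
import pytest

from qsynth import (
    QuestionnaireCascade,
    default_registry_spec,
    generate_cohort,
    load_schema,
)


@pytest.fixture(scope="session")
def schema():
    return load_schema()


@pytest.fixture(scope="session")
def registry_cohort(schema):
    """n=2000 cohort from the planted registry-like structure (block missingness on)."""
    return generate_cohort(default_registry_spec(n_records=2000, seed=0), schema)


@pytest.fixture(scope="session")
def small_full_cohort(schema):
    """n=400 cohort with every block present, for fast cascade training."""
    spec = default_registry_spec(n_records=400, seed=11)
    spec.retention = {q: 1.0 for q in schema.names}
    return generate_cohort(spec, schema)


@pytest.fixture(scope="session")
def fitted_small(small_full_cohort):
    return QuestionnaireCascade(small_full_cohort, backend="linear").fit(seed=0)


@pytest.fixture()
def rng():
    # fresh, deterministic stream per test: results do not depend on test order
    return np.random.default_rng(1234)


TOY_SCHEMA_YAML = """
questionnaires:
  - name: QA
    short: qa
    questions: 2
    answer_min: 0
    answer_max: 1
    has_total: false
    subscales:
      - {name: A total, subject: Physic, items: [1, 2]}
  - name: QB
    short: qb
    questions: 2
    answer_min: 0
    answer_max: 1
    has_total: false
    subscales:
      - {name: B total, subject: Mental, items: [1, 2]}
"""


@pytest.fixture()
def toy_schema(tmp_path):
    p = tmp_path / "toy.yaml"
    p.write_text(TOY_SCHEMA_YAML)
    return load_schema(p)
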