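import textwrap

import pytest

from metastage.config import SourceBinding, parse_config
from metastage.ingest import Dialect, Provenance, SourceTable


MINIMAL_YAML = textwrap.dedent(
    """
    study: {label: DEMO, code: D1}
    sources:
      patients: {path: patients.csv, role: patient-file, key: [pid]}
    entities:
      - name: Demographics
        anchor: patient
        source: patients
        attributes: [{name: sex, column: sex}]
    """
)

FIG4_YAML = textwrap.dedent(
    """
    study: {label: LABSTUDY}
    sources:
      patients: {path: patients.csv, role: patient-file, key: [pid]}
      labs: {path: labs.csv, role: data-file, key: [pid], timestamp: date}
    entities:
      - name: Labs
        anchor: patient
        source: labs
        eav:
          parameters: [Parameter]
          value: Result
          meta: [Unit, Norm range]
    """
)


def make_table(logical_name, columns, rows, row_ids=None):
    """In-memory SourceTable without touching the filesystem."""
    return SourceTable(
        logical_name=logical_name,
        columns=list(columns),
        rows=[list(r) for r in rows],
        provenance=Provenance(path=f"{logical_name}.csv", encoding="utf-8", dialect=Dialect()),
        row_ids=row_ids or list(range(2, 2 + len(rows))),
    )


@pytest.fixture
def minimal_cfg():
    return parse_config(MINIMAL_YAML)


@pytest.fixture
def fig4_cfg():
    return parse_config(FIG4_YAML)


def binding(name="t", role="data-file", key=None, timestamp=None):
    return SourceBinding(
        logical_name=name, path=f"{name}.csv", role=role,
        key_columns=key or (["k"] if role != "data-file" else []),
        timestamp_column=timestamp,
    )
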