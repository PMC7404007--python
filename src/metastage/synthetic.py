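"""Synthetic multi-file clinical studies with ground truth.

The three study shapes the staging engine must absorb — a structured
research study, longitudinal clinical EAV data with repeated measurements
per visit, and highly structured visit-level data — are emulated in
miniature by one generator: a patient file (demographics), a visit file
(time windows), a visit-anchored declared-attribute file (assessments) and
an EAV lab file (Parameter/Result/Unit/Norm range). Messiness is injected
under explicit control (encodings, delimiters, duplicates, missing cells,
partial dates, decimal commas, ragged rows, repeated measurements), and
every injected defect is written to a ledger, so the expected staging
output — the :class:`GroundTruth` — is known exactly by construction.

All randomness flows from a single integer seed; equal seeds give
byte-identical files. Value distributions are simple but plausible: lab
values log-normal, categories uniform over small sets, event dates uniform
within their visit window.
"""

from __future__ import annotations

import csv
import io
import json
from collections import Counter
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from random import Random

from .config import (
    AttributeDef,
    CleansingOptions,
    EavSpec,
    EntityDef,
    KeySpec,
    MetaAttributeDef,
    SourceBinding,
    StagingConfig,
    serialize_config,
)
from .errors import MetastageError

STUDY_LABEL = "SYNTH"
STUDY_CODE = "SY"

_PARAM_NAMES = ["LDL", "HDL", "CRP", "Glucose", "Sodium", "Potassium", "Creatinine", "TSH"]
_UNITS = ["mg/dL", "mg/L", "mmol/L", "U/L", "%"]
_SEXES = ["M", "F"]
_STATUSES = ["final", "draft", "amended"]


@dataclass
class MessinessSpec:
    """Controllable heterogeneity of a generated study."""

    encodings: list[str] = field(default_factory=lambda: ["utf-8"])
    delimiters: list[str] = field(default_factory=lambda: [","])
    duplicate_rate: float = 0.0
    missing_rate: float = 0.0
    partial_date_rate: float = 0.0
    decimal_comma: bool = False
    eav_parameter_count: int = 20
    ragged_row_rate: float = 0.0
    #: fraction of lab slots that get a second, later measurement in the visit
    repeat_rate: float = 0.0
    #: attach Unit / Norm range meta-attributes to the lab entity
    include_meta: bool = True

    def __post_init__(self) -> None:
        for name in ("duplicate_rate", "missing_rate", "partial_date_rate",
                     "ragged_row_rate", "repeat_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    @classmethod
    def clean(cls, **overrides) -> "MessinessSpec":
        return cls(**overrides)


@dataclass
class GroundTruth:
    """Expected staging output, exact by construction."""

    subjects: list[str] = field(default_factory=list)
    visits: list[str] = field(default_factory=list)
    facts: Counter = field(default_factory=Counter)
    ledger: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "subjects": self.subjects,
                "visits": self.visits,
                "facts": [
                    {"fact": list(t[:7]), "modifiers": dict(sorted(t[7])), "count": n}
                    for t, n in sorted(self.facts.items())
                ],
                "ledger": self.ledger,
            },
            indent=2,
        )


@dataclass
class Study:
    files: dict[str, bytes]
    file_params: dict[str, tuple[str, str]]  # filename -> (encoding, delimiter)
    config: StagingConfig
    config_yaml: str
    ground_truth: GroundTruth
    seed: int

    def write(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, data in self.files.items():
            (directory / name).write_bytes(data)
        (directory / "staging.yaml").write_text(self.config_yaml, encoding="utf-8")
        (directory / "ground_truth.json").write_text(
            self.ground_truth.to_json() + "\n", encoding="utf-8"
        )
        return directory


def _render_csv(rows: list[list[str]], delimiter: str) -> str:
    buf = io.StringIO()
    csv.writer(buf, delimiter=delimiter, lineterminator="\n", quoting=csv.QUOTE_MINIMAL).writerows(rows)
    return buf.getvalue()


def _canon_value(token: str, decimal_comma: bool) -> str:
    from ._util import canonical_number

    return canonical_number(token, "," if decimal_comma else ".")


def _path(entity: str, attribute: str) -> str:
    return f"\\{STUDY_LABEL}\\{entity}\\{attribute}\\"


def _partial(token: str, rng: Random, rate: float, ledger: list[dict], file: str, row: int):
    """Maybe degrade a YYYY-MM-DD token to month or year precision."""
    if rate and rng.random() < rate:
        if rng.random() < 0.5:
            out, prec = token[:4], "year"
            rendered = token[:4]
        else:
            out, prec = token[:7], "month"
            rendered = token[:7]
        ledger.append({"event": "partial-date", "file": file, "row": row, "token": out})
        return out, rendered, prec
    return token, token, "day"


def build_config(spec: MessinessSpec) -> StagingConfig:
    """The declarative configuration for a generated study.

    Deliberately independent of the number of EAV parameters: the attribute
    catalog of the lab entity is generated from the data at staging time, so
    the configuration's size is constant in the parameter count.
    """
    meta = (
        [MetaAttributeDef(name="Unit", column="Unit"),
         MetaAttributeDef(name="Norm range", column="Norm range")]
        if spec.include_meta
        else []
    )
    return StagingConfig(
        study_label=STUDY_LABEL,
        study_code=STUDY_CODE,
        sources=[
            SourceBinding(logical_name="patients", path="patients.csv", role="patient-file",
                          key_columns=["patient_id"]),
            SourceBinding(logical_name="visits", path="visits.csv", role="visit-file",
                          key_columns=["patient_id", "visit_id"],
                          timestamp_column="start_date", end_column="end_date"),
            SourceBinding(logical_name="assessments", path="assessments.csv", role="data-file",
                          key_columns=["patient_id", "visit_id"], timestamp_column="assess_date"),
            SourceBinding(logical_name="labs", path="labs.csv", role="data-file",
                          key_columns=["patient_id", "visit_id"], timestamp_column="sample_date"),
        ],
        entities=[
            EntityDef(
                name="Demographics", anchor="patient", source="patients",
                attributes=[
                    AttributeDef(name="sex", column="sex"),
                    AttributeDef(name="birth_year", column="birth_year"),
                    AttributeDef(name="height_cm", column="height_cm"),
                ],
            ),
            EntityDef(
                name="Assessment", anchor="visit", source="assessments",
                attributes=[
                    AttributeDef(name="score", column="score"),
                    AttributeDef(name="status", column="status"),
                ],
            ),
            EntityDef(
                name="Labs", anchor="visit", source="labs",
                eav=EavSpec(parameter_columns=["Parameter"], value_column="Result",
                            meta_columns=meta),
            ),
        ],
        subject_key=KeySpec(columns=["patient_id"]),
        visit_key=KeySpec(columns=["patient_id", "visit_id"]),
        options=CleansingOptions(),
    )


def generate_study(
    n_subjects: int,
    visits_per_subject: int,
    spec: MessinessSpec | None = None,
    seed: int = 0,
    labs_per_visit: int = 5,
    duplicate_count: int | None = None,
) -> Study:
    """Generate a complete synthetic study with its ground truth.

    ``duplicate_count``, when given, overrides ``spec.duplicate_rate`` with
    an exact number of injected duplicate lab rows. Deterministic for a
    fixed seed.
    """
    if n_subjects <= 0 or visits_per_subject <= 0 or labs_per_visit <= 0:
        raise ValueError("n_subjects, visits_per_subject and labs_per_visit must be positive")
    spec = spec or MessinessSpec()
    rng = Random(seed)
    cfg = build_config(spec)
    gt = GroundTruth()
    labs_per_visit = min(labs_per_visit, spec.eav_parameter_count)

    params = list(_PARAM_NAMES[: spec.eav_parameter_count])
    params += [f"LAB{i:04d}" for i in range(len(params), spec.eav_parameter_count)]
    unit_of = {p: _UNITS[i % len(_UNITS)] for i, p in enumerate(params)}
    norm_of = {p: f"{(i % 5) * 10}-{(i % 5) * 10 + 40}" for i, p in enumerate(params)}

    def missing(col: str, file: str, row: int) -> bool:
        if spec.missing_rate and rng.random() < spec.missing_rate:
            gt.ledger.append({"event": "missing", "file": file, "row": row, "column": col})
            return True
        return False

    def num(token_value: float) -> str:
        token = f"{token_value:.1f}"
        return token.replace(".", ",") if spec.decimal_comma else token

    # ---- patients ---------------------------------------------------------
    patient_rows: list[list[str]] = [["patient_id", "sex", "birth_year", "height_cm"]]
    subjects: list[str] = []
    for i in range(n_subjects):
        pid = f"P{i + 1:04d}"
        sid = f"{STUDY_CODE}_{pid}"
        subjects.append(sid)
        row_no = len(patient_rows) + 1
        sex = rng.choice(_SEXES)
        birth_year = str(rng.randint(1940, 2000))
        height = num(rng.uniform(150, 195))
        row = [pid, sex, birth_year, height]
        if missing("sex", "patients.csv", row_no):
            row[1] = "NA"
        else:
            gt.facts[(sid, "", _path("Demographics", "sex"), "", "", "categorical", sex,
                      frozenset())] += 1
        gt.facts[(sid, "", _path("Demographics", "birth_year"), "", "", "numeric", birth_year,
                  frozenset())] += 1
        if missing("height_cm", "patients.csv", row_no):
            row[3] = ""
        else:
            gt.facts[(sid, "", _path("Demographics", "height_cm"), "", "", "numeric",
                      _canon_value(height, spec.decimal_comma), frozenset())] += 1
        patient_rows.append(row)
    gt.subjects = subjects

    # ---- visits -----------------------------------------------------------
    visit_rows: list[list[str]] = [["patient_id", "visit_id", "start_date", "end_date"]]
    windows: dict[tuple[str, str], date] = {}
    for i in range(n_subjects):
        pid = f"P{i + 1:04d}"
        for j in range(visits_per_subject):
            vid = f"V{j + 1}"
            start = date(2019, 1, 1) + timedelta(days=30 * j)
            end = start + timedelta(days=5)
            windows[(pid, vid)] = start
            visit_rows.append([pid, vid, start.isoformat(), end.isoformat()])
            gt.visits.append(f"{STUDY_CODE}_{pid}_{vid}")

    # ---- assessments (declared attributes, visit-anchored) ----------------
    assess_rows: list[list[str]] = [["patient_id", "visit_id", "assess_date", "score", "status"]]
    for (pid, vid), start in windows.items():
        row_no = len(assess_rows) + 1
        vfull = f"{STUDY_CODE}_{pid}_{vid}"
        sid = f"{STUDY_CODE}_{pid}"
        day = (start + timedelta(days=rng.randint(0, 4))).isoformat()
        token, rendered, prec = _partial(
            day, rng, spec.partial_date_rate, gt.ledger, "assessments.csv", row_no
        )
        score = num(rng.uniform(0, 10))
        status = rng.choice(_STATUSES)
        row = [pid, vid, token, score, status]
        if missing("score", "assessments.csv", row_no):
            row[3] = "N/A"
        else:
            gt.facts[(sid, vfull, _path("Assessment", "score"), rendered, prec, "numeric",
                      _canon_value(score, spec.decimal_comma), frozenset())] += 1
        gt.facts[(sid, vfull, _path("Assessment", "status"), rendered, prec, "categorical",
                  status, frozenset())] += 1
        assess_rows.append(row)

    # ---- labs (EAV, visit-anchored) ---------------------------------------
    lab_header = ["patient_id", "visit_id", "sample_date", "Parameter", "Result"]
    if spec.include_meta:
        lab_header += ["Unit", "Norm range"]
    lab_rows: list[list[str]] = [lab_header]
    slot = 0

    def add_lab_row(pid: str, vid: str, param: str, day: date, value: float) -> None:
        row_no = len(lab_rows) + 1
        sid = f"{STUDY_CODE}_{pid}"
        vfull = f"{STUDY_CODE}_{pid}_{vid}"
        token = num(value)
        rendered = day.isoformat()
        row = [pid, vid, rendered, param, token]
        mods: dict[str, str] = {}
        if spec.include_meta:
            unit, norm = unit_of[param], norm_of[param]
            if missing("Unit", "labs.csv", row_no):
                unit = "NULL"
            else:
                mods["Unit"] = unit_of[param]
            row += [unit, norm]
            ragged = spec.ragged_row_rate and rng.random() < spec.ragged_row_rate
            if ragged:
                row = row[:-1]  # short row: trailing Norm range cell lost
                gt.ledger.append(
                    {"event": "ragged", "file": "labs.csv", "row": row_no, "column": "Norm range"}
                )
            else:
                mods["Norm range"] = norm
        if missing("Result", "labs.csv", row_no):
            row[4] = "NA"
        else:
            gt.facts[(sid, vfull, _path("Labs", param), rendered, "day", "numeric",
                      _canon_value(token, spec.decimal_comma), frozenset(mods.items()))] += 1
        lab_rows.append(row)

    for (pid, vid), start in windows.items():
        for _ in range(labs_per_visit):
            param = params[slot % len(params)]
            slot += 1
            day = start + timedelta(days=rng.randint(0, 3))
            value = round(rng.lognormvariate(3.0, 0.5), 1)
            add_lab_row(pid, vid, param, day, value)
            if spec.repeat_rate and rng.random() < spec.repeat_rate:
                gt.ledger.append({"event": "repeat", "file": "labs.csv",
                                  "row": len(lab_rows) + 1, "parameter": param})
                add_lab_row(pid, vid, param, day + timedelta(days=2), round(value + 1.1, 1))

    # ---- duplicate injection (exact copies of complete lab rows) ----------
    k = duplicate_count
    if k is None:
        k = round(spec.duplicate_rate * (len(lab_rows) - 1))
    eligible = [
        r for r in lab_rows[1:]
        if r[4] not in ("NA", "") and len(r) == len(lab_header)
    ]
    k = min(k, len(eligible)) if eligible else 0
    for r in rng.sample(eligible, k) if k else []:
        lab_rows.append(list(r))
        gt.ledger.append({"event": "duplicate", "file": "labs.csv", "copied": r[:4]})

    # ---- serialize --------------------------------------------------------
    tables = {
        "patients.csv": patient_rows,
        "visits.csv": visit_rows,
        "assessments.csv": assess_rows,
        "labs.csv": lab_rows,
    }
    files: dict[str, bytes] = {}
    file_params: dict[str, tuple[str, str]] = {}
    for i, (name, rows) in enumerate(tables.items()):
        encoding = spec.encodings[i % len(spec.encodings)]
        delimiter = spec.delimiters[i % len(spec.delimiters)]
        files[name] = _render_csv(rows, delimiter).encode(encoding)
        file_params[name] = (encoding, delimiter)

    return Study(
        files=files,
        file_params=file_params,
        config=cfg,
        config_yaml=serialize_config(cfg),
        ground_truth=gt,
        seed=seed,
    )


def reserialize(study: Study, encoding: str, delimiter: str) -> Study:
    """Re-encode every data file of a study under a new encoding and delimiter.

    The logical content is unchanged; only the bytes differ. Re-serializing
    back to a file's original parameters reproduces its bytes exactly. An
    unrepresentable character raises an error naming it.
    """
    new_files: dict[str, bytes] = {}
    new_params: dict[str, tuple[str, str]] = {}
    for name, data in study.files.items():
        old_encoding, old_delimiter = study.file_params[name]
        text = data.decode("utf-8-sig" if old_encoding in ("utf-8", "utf-8-sig") else old_encoding)
        rows = list(csv.reader(io.StringIO(text), delimiter=old_delimiter))
        try:
            new_files[name] = _render_csv(rows, delimiter).encode(encoding)
        except UnicodeEncodeError as exc:
            ch = text[exc.start] if exc.object is not text else exc.object[exc.start]
            raise MetastageError(
                f"character {ch!r} in {name} not representable in {encoding}"
            ) from exc
        new_params[name] = (encoding, delimiter)
    return Study(
        files=new_files,
        file_params=new_params,
        config=study.config,
        config_yaml=study.config_yaml,
        ground_truth=study.ground_truth,
        seed=study.seed,
    )
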