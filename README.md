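# metastage

A declarative **meta-loading staging engine** for clinical and translational
data warehouses.

Research groups that run [i2b2](https://www.i2b2.org/) or tranSMART need to
load heterogeneous tabular exports — study questionnaires, longitudinal lab
panels in entity-attribute-value (EAV) form, visit-level billing extracts —
into those platforms, usually through back-end loaders (transmart-batch,
tMDataLoader) that demand clean, rigidly structured staging files and long
imperative configurations. `metastage` inverts that workflow: the user writes
one compact **declarative** YAML document mapping an entity-relationship
model onto the raw files ("entity *Labs* is visit-anchored, EAV-shaped, the
parameter is column *Parameter*, the value is *Result*, qualified by
meta-attributes *Unit* and *Norm range*"), and the engine does the rest —

- **ingest**: automatic character-encoding detection (BOM, then trial
  decoding with fixed priority) and delimiter-dialect sniffing by
  consistency scoring; ragged rows padded/truncated with a logged trail;
- **cleansing**: configurable missing-token normalization, conservative
  column type inference (a single non-numeric cell demotes a column;
  decimal commas accepted only when unambiguous), timestamps parsed with an
  explicit *precision* (`2019-03` is a month, not a fabricated day), row
  filters;
- **EAV denormalization**: the attribute catalog is generated from the
  distinct parameter labels observed in the data — multiple parameter
  columns combine into one label (`Glucose|Serum`) — so the configuration
  size is constant in the number of lab analytes;
- **model building**: subjects, visits and typed facts with key-based or
  timestamp-containment visit linkage, exact-duplicate collapsing and
  keep-first conflict resolution, all counted and reported;
- **ontology derivation**: the prefix-closed i2b2 concept hierarchy
  (folders / concepts / modifier nodes) with stable digest codes;
- **emission**: two staging dialects from the *same* configuration — an
  i2b2-oriented bundle (subjects, separate visits, coded fact files,
  mapping files, ontology, invocation descriptor) and a tranSMART-oriented
  study-directory bundle in which meta-attributes are flattened into
  attribute variants (`LDL (mg/dL)`) and repeated measurements are
  collapsed under an explicit, reported aggregation policy.

The engine emits staging bundles plus an invocation descriptor; executing
the back-end loaders against a live database is deliberately out of scope.

## Worked example

Generate a small synthetic study (5 subjects, 2 visits each, a demographic
file, a visit file, a visit-anchored assessment file and an EAV lab file)
and stage it into both dialects:

```bash
metastage fixtures --out demo --seed 42 --subjects 5 --visits 2
metastage stage --config demo/staging.yaml --out staged
```

which prints

```
INFO metastage: wrote study with 5 subjects / 10 visits to demo
INFO metastage: i2b2 bundle: {'subjects': 5, 'visits': 10, 'facts': 85, 'modifier_rows': 100}
INFO metastage: transmart bundle: {'subjects': 5, 'facts_in': 85, 'facts_emitted': 85, 'collapsed': 0}
staged/report.json
```

85 facts were staged: 3 demographic facts per subject (minus none missing),
2 assessment facts per visit, and 5 lab results per visit carrying `Unit`
and `Norm range` modifier values (the 100 modifier rows). The tranSMART
bundle carries the same 85 facts because this clean fixture has no repeated
measurements to collapse (`collapsed: 0`). The i2b2 bundle looks like:

```
staged/i2b2/
  subjects.tsv  visits.tsv
  facts_Demographics.tsv  facts_Assessment.tsv  facts_Labs.tsv
  ontology.tsv  column_mapping.tsv  word_mapping.tsv
  invocation.txt  manifest.json
```

with coded fact rows such as

```
subject_id  visit_id     concept_cd        instance_num  modifier_cd       value_type  value   timestamp   timestamp_precision
SY_P0001    SY_P0001_V1  b9e5bee37d501075  1             @                 numeric     36.9    2019-01-01  day
SY_P0001    SY_P0001_V1  b9e5bee37d501075  1             6e90474aea7016db  text        mmol/L  2019-01-01  day
```

— the `@` row is the observation itself (a CRP value of 36.9), the second
row attaches the `Unit` modifier through its coded ontology node. The
ontology file ties the codes back to human-readable paths
(`b9e5bee37d501075` → `\SYNTH\Labs\CRP\`) and is prefix-closed by
construction.

The same objects are available as a library:

```python
from metastage import generate_study, run_staging, MessinessSpec

study = generate_study(50, 3, MessinessSpec(decimal_comma=True, missing_rate=0.1), seed=42)
study.write("study_dir")
result = run_staging(study.config, "study_dir")
print(result.counts)          # rows read, facts, duplicates dropped, ...
```

## Limitations

Fixed-width files, spreadsheets, CDISC ODM and direct database extraction
are out of scope, as are terminology mapping, pseudonymization and
incremental loading. The staging dialects are pinned to this package's own
documented tab-separated formats; they are not byte-compatible with any
particular release of the external loaders.
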