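# Methods

This note documents the staging model implemented by `metastage`, the
choices made where the design was genuinely open, and what the synthetic
test studies do and do not demonstrate.

## The staging model

Staging is a compiler pass from `(raw tabular files, declarative ER
configuration)` to back-end loader bundles. It assumes only that input data
are tabular; that every line carries data for one patient, visit or
encounter; that patients and visits are identified by (composite) keys or
timestamps; that exactly one file describes the patients (a visit file is
optional); and that entities relate to patients or visits. Within those
assumptions the pipeline is total: anomalies (ragged rows, unparseable
timestamps, orphan visits, conflicting duplicates) are logged and accounted
for, never silently repaired and — outside strict mode — never fatal.

The canonical model is `Subject` (one per distinct patient-file key tuple),
`Visit` (time window `[start, end]` linked to a subject) and `Fact`
(subject, optional visit, ontology concept path, typed value, optional
timestamp with precision, modifier map). Canonical identifiers are the
sanitized source key values joined by `_` and prefixed with the study code,
so identifiers are stable across runs without any database sequence.

## Ingestion

**Encoding.** A byte-order mark wins outright. Otherwise candidates are
tried in the fixed priority UTF-8 → (NUL-heuristic UTF-16) → ISO-8859-1.
UTF-8 false positives are rare enough that trial decoding is effectively a
statistical test, and the fixed order makes runs reproducible. The
supported and tested families are UTF-8 (±BOM), ISO-8859-1 and UTF-16;
other encodings may decode but carry no guarantee.

**Dialect.** Candidate delimiters `, ; TAB |` are scored on the first 100
lines by the fraction of lines whose parsed cell count equals the modal
count (quote-aware, so `"x,y",2` does not defeat the comma); a candidate
that never splits scores zero, and ties fall back to the fixed candidate
order. The header flag comes from type contrast between line 1 and the
body. 100 lines bounds the cost and stabilizes the decision.

**Ragged rows** are padded (short) or truncated (long), each event logged
with its line number; strict mode turns both into errors. This trades
silent loss against traceable tolerance — the engine's reason for existing
is input that is not yet clean.

## Cleansing and typing

Missing tokens default to `{"", NA, N/A, NULL, -, .}` (configurable),
matched case-insensitively after outer trimming.

A column (or, for EAV entities, the value set of each generated attribute —
a lab table's `Result` column mixes analytes and must be profiled per
parameter) is typed **numeric** only if 100 % of non-missing cells parse
under one decimal convention: one bad cell demotes to categorical, because
silently coercing clinical values is worse than a categorical fallback.
Decimal commas are accepted only when no cell contains a dot and every cell
matches digits-comma-digits, avoiding thousands-separator ambiguity. A
non-numeric column is **date** if ≥ 95 % of cells parse as timestamps,
**categorical** if its distinct count is ≤ max(20, 5 % of rows), else
**text**. Numeric values are canonicalized to `.`-decimal with integral
values rendered without a fractional part.

**Timestamps** carry the precision actually present in the token: `2019`
is year-precision, `2019-03` month, `02.03.2019` day (day-first by default,
matching German-locale clinical exports; configurable, and an impossible
month like `13.05` overrides the convention). The stored instant is the
*start* of the precision window (Jan 1 / first of month / midnight) — a
conventional, monotone representative — and the precision travels with the
fact into the staging files, so downstream consumers can see what was
imputed rather than being handed fabricated exactness.

"Inconsistent timestamps" are handled in two places: a visit whose end
precedes its start is rejected; a key-linked fact whose timestamp falls
outside its visit window is kept with a warning (the key is authoritative,
the timestamp merely suspicious).

## EAV denormalization

Each distinct observed parameter-label combination becomes one generated
attribute; labels are outer-trimmed and internal whitespace collapsed but
compared case-sensitively (merging `ldl` with `LDL` silently could conflate
clinically distinct codes). Multiple parameter columns join with `|`
(configurable) — unambiguous and rarely present in clinical labels.
Generated attributes are sorted by name, making expansion order-independent
and idempotent; a generated name colliding with a declared attribute is a
hard error. A parameter observed at resolve time but missed at expansion
time (multi-file patterns) is admitted on the fly and logged — agility over
strictness.

## Linkage and deduplication

Visit linkage prefers keys; without a visit key, a timestamped fact links
to the unique visit window containing its instant, and with zero or several
candidate windows it stays unlinked with a log entry — the engine never
guesses among candidates. Duplicate identity is the full key *including
modifiers* (two results differing only in unit are distinct facts): exact
duplicates collapse with a count, same-key/different-value conflicts
resolve keep-first with a logged conflict, and
`facts_in == facts_out + dropped + conflicts` holds by construction.

## Ontology and codes

Paths are `\study\entity\attribute\` with modifier nodes one level below
their concept. Segments are sanitized (`\\`, `/`, control characters → `_`,
200-character cap per segment, per i2b2 path-length limits); a
post-sanitization collision is an error, never a silent merge. Sibling
order is fixed lexicographic for determinism. Codes are the first 16 hex
characters of a SHA-256 digest of the full path — injective in practice,
stable across runs and machines, lengthened (and logged) in the
astronomically unlikely collision case. Folders carry value type `none`.

## Back-end dialects

The two bundle formats are pinned to this package's own documented layouts
(tab-separated, UTF-8, LF) with a shipped independent reader defining
bit-exactness for tests; executing live loaders is out of scope, and the
formats are not byte-compatible with any particular external release.

*i2b2 dialect*: subject file, separate visit file, one fact file per entity
with one `@`-row per fact plus one row per modifier value, all annotated
with ontology codes and an instance number so repeated observations of one
concept stay distinguishable; ontology, column-mapping and word-mapping
files; an invocation descriptor recording that ontology loading precedes
fact loading. Everything the model holds is preserved.

*tranSMART dialect*: a study directory containing a wide clinical data file
plus column mapping. Meta-attributes flatten into attribute variants —
label = attribute name + parenthesized meta values in declared meta order,
missing values rendered `n/a`. Multiple values per (subject, visit,
variable) collapse under a policy: **latest** by default (untimestamped
facts sort earliest; ties keep the first by input order), alternatives
`first` and `mean` (numeric only). The platform is known to lose
time-series detail; the policy makes that loss explicit, configurable and
exactly counted, so `i2b2 facts − tranSMART facts == collapsed` reconciles
in the manifests.

Bundles are written atomically (temp dir + rename) with a checksum
manifest; manifests contain no wall-clock times or absolute paths, so
identical inputs give byte-identical outputs, manifest included.

## Synthetic studies

The generator emulates the three data shapes the engine targets: a
structured research file (demographics), longitudinal EAV lab data with
optional repeated measurements per visit, and visit-level structured data
(assessments), plus a visit file with non-overlapping 5-day windows.
Messiness is injected under explicit knobs — encodings, delimiters, exact
or rate-based duplicate rows, missing cells, partial dates, decimal commas,
ragged rows, repeats — and every defect goes into a ledger, so the expected
fact multiset is known exactly by construction. All randomness flows from a
single seed; distributions are simple but plausible (log-normal lab values,
uniform small category sets, dates uniform within windows).

What passing these tests shows: the pipeline's mechanics are exact under
controlled heterogeneity. What it does not show: statistical realism of
clinical distributions, free-text idiosyncrasies, terminology drift, or
scale behavior beyond the test sizes. Default test problem sizes (tens of
subjects, a few visits, up to 1000 EAV parameters for the compactness
property) keep the full suite under a few seconds while still exercising
every code path; the properties asserted are size-independent.

## Known limitations

Subject identification by timestamp alone (nominally allowed by the input
assumptions) is ambiguous and unsupported — only timestamp-based *visit*
linkage is implemented. Parameter labels are not normalized beyond
whitespace (no unit stripping inside labels). No fixed-width files,
spreadsheets, CDISC ODM, SQL extraction, terminology mapping,
pseudonymization, omics data, or incremental loading.
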