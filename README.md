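# edcbridge

A toolkit that bridges two worlds of research data capture: **XLSForm**-based
collection tools (KoBoToolbox/ODK style) and **REDCap**-style data
management. It provides:

- **Core model** (`edcbridge.model`, `edcbridge.logic`) — a canonical
  in-memory instrument representation plus a shared skip-logic /
  branching-logic expression language with parsers and renderers for both
  dialects and a deterministic evaluator.
- **XLSForm I/O** (`edcbridge.xlsform`) — read/write XLSX workbooks
  (survey / choices / settings sheets), including an `hxl` annotation
  column whose hashtags become semantic tags.
- **Form converter** (`edcbridge.dictionary`) — instrument → 18-column
  REDCap data-dictionary rows, with the `checkbox_` naming pre-check for
  multiple-selection fields, per-type mapping, and logic translation
  (`selected(${f},'c')` → `[f(c)] = '1'`, `!=` → `<>`).
- **Embedded store** (`edcbridge.store`) — a SQLite-backed emulation of the
  management-side surfaces: projects, form registry, field metadata,
  records with upsert + append-only change log, record ids, locking,
  data queries, alert recipients/log, and dictionary CSV I/O.
- **ETL processor** (`edcbridge.etl`) — authenticate, clean platform
  metadata out of JSON submission payloads, expand checkbox answers,
  resolve participant ids to record ids, import atomically, and run
  post-save actions (duplicate check, lock, notifications).
- **Data quality** (`edcbridge.quality`) — rule validation (range / format
  / required / regex) with an open→resolved issue lifecycle, visit
  scheduling from a reference date plus day offsets, the participants ×
  visits status panel, and deduplicated alert generation.
- **Reporting** (`edcbridge.reporting`) — CSUQ usability-survey scoring
  (overall + three subscales), respondent breakdowns, project-registry
  summaries, data-management-plan rendering from a bundled template, and
  support/comment logs.
- **Fixtures** (`edcbridge.fixtures`) — seed-deterministic generators for
  instruments, ontologies, submission payloads with planted rule
  violations (ground truth returned alongside), and survey rating matrices
  constructed to hit target item means.
- **Ontology bridge** (`edcbridge.ontology`) — derive instruments from
  datatype-property ontologies and vice versa, serialize/parse a Turtle
  subset, and remap annotated datasets across ontology versions.

## Test

```bash
python -m pytest -q tests/
```

## CLI

All commands are under one entry point:

```bash
edcbridge convert --in form.xlsx --name treatment            # dictionary CSV to stdout
edcbridge convert --in form.xlsx --name treatment --zip out.zip
edcbridge derive-onto --in form.xlsx --base http://example.org/vocab --version v1
edcbridge derive-form --onto onto.ttl --name treatment --out derived.xlsx
edcbridge process --store study.db --project P --form F --in payload.json \
    --user processor --password secret --event visit_0
edcbridge validate --store study.db --project P
edcbridge panel --store study.db --project P --date 2023-02-15 --out panel.csv
edcbridge alerts --store study.db --project P --now 2023-02-15
edcbridge score-csuq --in ratings.csv
edcbridge dmp --meta meta.json --out plan.md
edcbridge fixtures --seed 1 --out fixtures_dir/
```

`convert` exits non-zero when the multiple-selection naming pre-check
fails.

## Conventions worth knowing

- Field names are lower-cased on ingest; labels are verbatim. Dates are
  naive ISO (`YYYY-MM-DD`), datetimes `YYYY-MM-DD HH:MM`.
- A comparison against a missing/empty value evaluates **false** (a field
  whose skip logic depends on an unanswered question stays hidden).
- Multiple-selection fields must be named `checkbox_*`; on records they
  are stored expanded as `name___code` columns with `"1"`/`"0"` values.
- Displayed statistics round half-up at two decimals; raw precision is
  kept internally. The survey scorer expects already-oriented
  (higher-is-better) ratings.
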