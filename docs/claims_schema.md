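# Claims interchange schema

One delimited file per record stream (comma, tab or semicolon; header row
required; quoted fields tolerated; dates ISO-8601 `YYYY-MM-DD`). Codes may
be written with dots/dashes as printed (`I25.10`, `5–361`); they are
normalized on read (uppercase, dots removed, OPS keeps its first hyphen).

## persons.csv

| column | type | notes |
|---|---|---|
| person_id | string | opaque, unique |
| sex | `female` \| `male` | |
| birth_year | int | must precede enrollment start year |
| enrollment_start | date | |
| enrollment_end | date | ≥ enrollment_start |
| death_date | date, optional | when present must equal enrollment_end |

## diagnoses.csv

| column | type | notes |
|---|---|---|
| person_id | string | |
| icd_code | ICD-10-GM | normalized on read |
| setting | `ambulatory` \| `hospital_main` \| `hospital_secondary` | hospital rows dated by admission |
| qualifier | `G` \| `V` \| `A` \| `Z` | required iff setting is ambulatory |
| service_date | date | |

## prescriptions.csv

| column | type | notes |
|---|---|---|
| person_id | string | |
| atc_code | ATC, ≤ 7 chars | |
| dispense_date | date | |
| prescriber_id | string | matched against lab physician_id by criterion 3 |

## procedures.csv

| column | type | notes |
|---|---|---|
| person_id | string | |
| ops_code | OPS (`d-dddd`) | |
| service_date | date | |

## lab_services.csv

| column | type | notes |
|---|---|---|
| person_id | string | |
| ebm_code | string | 32025/32057/32881/32094 are the glucose/HbA1c codes; others are kept but never match |
| service_date | date | |
| physician_id | string | |

`ground_truth.csv` (simulator output only, never read by the analysis):
`person_id, true_t2d, true_cvd, true_onset_year, therapy_class`.
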