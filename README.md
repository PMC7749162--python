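# trialaudit

Metadata-quality auditing for clinical-trial registration records in the
ClinicalTrials.gov public-XML dialect.

Trial registrations are the largest collection of descriptive metadata
about clinical studies, and they are routinely reused far beyond their
regulatory purpose — in systematic reviews, meta-analyses, and patient
matching. That reuse is only as good as the metadata: values must conform
to their declared types, required fields must actually be present, search
fields should carry controlled-vocabulary terms, and semi-structured text
such as eligibility criteria must follow its expected format. `trialaudit`
packages those checks as a reusable pipeline for registry curators,
informaticians studying metadata quality (FAIRness) and anyone who
consumes registration XML programmatically.

## What it checks

Given a corpus of per-record XML files (one registration per file, as in
the public bulk download), the pipeline applies five stages:

1. **Simple-type validation** — Boolean fields must be exactly `Yes`/`No`;
   integer fields sign-free decimals; dates must match the registry's
   grammar `Unknown | MonthName [day,] 4-digit-year` (e.g. `January 3,
   2004`, `March, 2005`), optionally attributed
   `Actual|Anticipated|Estimate`; ages must be `N/A` or
   `positive-integer unit` (e.g. `18 Years`), normalizable to minute
   equivalents so `2 Years` = `24 Months`.
2. **Enumerated-value validation** — sixteen fields have closed permitted
   sets; values outside the set are *rogue* values. Two fields use a
   different syntax in records than in the data dictionary
   (`Parallel Group Assignment` for `Parallel`; masking as
   `Double(Participant, Care Provider)`); these are accepted, annotated,
   and canonicalizable.
3. **Completeness audit** — interventional records are audited for the 28
   publicly checkable required registration fields (of the statutory 41;
   the other 13 are excluded for documented reasons), with
   conditional-requirement logic (e.g. *why study stopped* only for
   suspended/terminated/withdrawn studies), the 2017-01-18 regulatory-era
   split, agency-class stratification, the principal-investigator
   four-way partition, and the contact rule (an overall contact or a
   contact at every site).
4. **Eligibility-criteria classification** — every criteria block maps to
   one of four format classes (correct; correct headers but unbulleted;
   missing/malformed headers; missing), conformant blocks are parsed into
   inclusion/exclusion lists, multi-group criteria are flagged
   heuristically, and sample review results extrapolate to corpus
   estimates with Wilson 95% intervals.
5. **Lexicon coverage** — exact-match coverage of condition and
   intervention values against pluggable term → identifier tables
   (MeSH-like lexicons), per vocabulary and per intervention type.

A seeded synthetic-corpus generator emits registration XML with controlled
defect plans (missing fields, rogue values, criteria classes, contact
degradation, lexicon membership) and a ground-truth file, so every audit
statistic can be tested for exact recovery without the live registry.

## Worked example

Generate a 1,000-record synthetic corpus with the bundled
"paper-profile" defect rates, then audit it:

```sh
$ trialaudit generate -n 1000 --seed 7 --profile paper --out corpus
4762f22ad10bf1af612942dde87b7ceb97e713a49e96e11c813ae24114c28b50
$ trialaudit audit corpus --out report
records=1000 findings=1542
$ head -6 report/criteria_classes.tsv
format_class    count   percent
correct 580     58.0
headers_only    254     25.4
malformed_headers       157     15.7
missing 9       0.9
multi_group_estimate    127     12.7 [9.8, 16.2]
```

The first command prints the corpus checksum (the same seed always
reproduces it byte-for-byte). The audit reports 1,542 findings over 1,000
records and writes paper-shaped tables: here 58.0% of criteria blocks are
correctly formatted, 25.4% have correct headers over unbulleted text,
15.7% have missing or variant headers, 0.9% are absent, and the
multi-group heuristic extrapolates to 127 records (12.7%, Wilson 95% CI
9.8–16.2%) defining criteria for more than one participant group. Other
tables cover missing required fields by era and agency class
(`missing_fields.tsv`, `missing_by_agency.tsv`), rogue enumerated values,
the PI partition, contact accounting, and vocabulary coverage, e.g.:

```sh
$ grep -P "condition\tall" report/coverage.tsv
condition  all  MEDDRA    320  1000  32
condition  all  MESH      615  1000  62
condition  all  RXNORM      0  1000   0
condition  all  SNOMEDCT  303  1000  30
condition  all  ANY       615  1000  62
```

62% of the corpus's condition values exact-match the bundled synthetic
MeSH-like lexicon — the in-lexicon rate this profile plants. The same
library surface is available programmatically
(`trialaudit.run_audit`, `trialaudit.generate`, ...), and auditing a real
bulk download is the same command pointed at its directory or zip.

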