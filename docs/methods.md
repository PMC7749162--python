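# Methods

This note documents the models, rules and conventions behind
`trialaudit`, the design choices made where the design was genuinely
open, and what the synthetic-corpus tests do and do not demonstrate about
real registry data.

## The field registry

The audit is driven by a transcribed machine-readable registry
(`src/trialaudit/data/registry.tsv`) of the 149 ClinicalTrials.gov
data-dictionary elements. Each row carries: the dictionary name, the XML
path in the public dialect, a type category (`boolean`, `integer`,
`date`, `age`, `enumerated`, `ontology_recommended`, `free_text`,
`composite`), the permitted value set for enumerated fields (in
dictionary form and, where the record syntax differs, record form),
multiplicity, whether the XSD types the field, the FDAAA801 and WHO
field-name mappings, requirement status, and era/condition flags.

Of the 41 statutory required fields, 28 are audited; 13 are excluded for
reasons encoded per row: 5 are conditionally required on facts not
public (e.g. whether secondary outcomes exist), 3 are stored internally
and never published, 3 were only added to the registry in late 2017, and
2 are administrative values present in every record by construction.
Composite groups (study design, primary/secondary outcome information,
arm information, facility information, age limits) are represented as a
parent row plus sub-element rows, each auditable independently.

The Study Phase permitted set includes "Phase 2". The dictionary's
printed list omits it between "Phase 1/Phase 2" and "Phase 2/Phase 3",
which we treat as a typographical artifact — the value demonstrably
occurs in records; the registry file records the discrepancy in a
comment. The WHO mapping is carried as metadata only; completeness is
audited against the FDAAA801 set plus the separately reported
principal-investigator rule.

Name lookup works in four namespaces (dictionary, XML, FDAAA801, WHO),
exact after trimming. XML lookup resolves a full slash path first and
falls back to an unambiguous leaf name; leaves shared by several parents
(`description`, `measure`, `last_name`) raise an error listing the
candidate paths rather than guessing.

## Record model

`TrialRecord` is a typed view over one registration: only elements the
audit consumes are promoted to fields, while every leaf-element
occurrence (and attribute) is preserved verbatim in `raw_values`, keyed
by slash path, in document order with duplicates retained. Validation
operates on `raw_values`, so the typed fields can never disagree with
what was actually in the XML. Dates, ages, integers and Booleans are
kept as raw text at parse time: many general-purpose date parsers have
undefined behavior on day-less input such as `March, 2005`, so
interpretation is confined to the validation and era logic. Writing is
deterministic (fixed element order, UTF-8), and `read(write(r))`
reproduces every retained field — the synthetic generator relies on this
to make corpora byte-reproducible.

## Type grammars

The grammars are anchored and case-sensitive:

* Boolean: `Yes|No`.
* Integer: `[0-9]+` (the three integer fields are counts; signs are not
  accepted).
* Date: `Unknown`, or month name + optional day + comma + four-digit
  year (`January 3, 2004`; `March, 2005`), with day 1–31 without leading
  zeros, plus an optional `Actual|Anticipated|Estimate` attribute. Month
  plausibility is deliberately not enforced by the grammar —
  `February 31, 2010` is grammar-valid — because the registry's own
  pattern accepts any day up to 31; a separate strict mode
  (`--strict-dates`) rejects impossible calendar dates.
* Age: `N/A`, or a positive integer without leading zeros, exactly one
  space, and a unit word (`Year(s)`, `Month(s)`, `Week(s)`, `Day(s)`,
  `Hour(s)`, `Minute(s)`). Ages normalize to minute equivalents with the
  fixed conversion Year = 525,600, Month = 43,800, Week = 10,080,
  Day = 1,440, Hour = 60 minutes, so `2 Years` and `24 Months` compare
  equal (1,051,200).

Both grammars are verified against independent brute-force rule checkers
over exhaustive small domains (every month × day 0–32 × several year
shapes; every magnitude/unit shape), in the unit suite and again in the
acceptance script.

## Enumerated validation and canonical forms

Sixteen fields have closed permitted sets; matching is exact and
case-sensitive after trimming. Values outside the set yield
`ROGUE_VALUE` findings (severity *warning*). Two fields are valid only
in a record syntax that differs from the dictionary:

* interventional study model — records append `Assignment`
  (`Parallel Group Assignment` for dictionary `Parallel`);
* masking — records encode `Single|Double|Triple|Quadruple(role, ...)`,
  where the count word must equal the number of distinct roles;
  canonicalization returns the role set and raises on count/role
  mismatch.

Valid record-form values are accepted and annotated with a
`FORMAT_VARIANT` finding of severity *note*. Because every realistic
record with a masking or model value necessarily carries these notes,
"clean" in this package means **zero findings above note severity**:
notes annotate a schema-level divergence between the dictionary and the
record dialect, not a defect of the record. The per-code severity
mapping (TYPE_MISMATCH = error, ROGUE_VALUE = warning, MISSING_REQUIRED
= error, MISSING_CONDITIONAL = warning, FORMAT_VARIANT = note) is this
package's convention; the registry's own entry system documents four
warning levels but no consistent per-rule assignment.

## Completeness audit

Only interventional records are audited (the statute defines required
fields for interventional trials only); other records pass through all
other stages. Presence rules:

* A multiple-occurrence field is missing iff it has zero occurrences.
* Sub-fields of a composite are audited only when the composite has
  occurrences, and a sub-field is missing iff *no* occurrence carries it
  (outcome measure/time frame/description), except the facility
  sub-fields (name, city, country), which are missing if *any* listed
  facility lacks them — matching how per-facility address completeness
  is naturally reported. Both conventions are monotone: filling a value
  can only shrink the missing sets.
* Conditional fields are missing iff absent **and** the condition is
  active: *why study stopped* iff overall status is Suspended,
  Terminated or Withdrawn; *individual site status* iff at least one
  location is listed.
* Era logic: records starting before 2017-01-18 are exempt from the four
  fields that were only recommended before that date (official title,
  why study stopped, study start date, study completion date).
  Day-absent dates compare as day 1; since that makes `January, 2017`
  era-ambiguous, the convention is surfaced per record and an alternate
  `exclude` convention classifies day-absent cutoff-month dates as
  unknown. Records with absent/unparseable start dates get era
  `unknown_start_date` and are *not* exempt — which is also why a
  missing start date is itself always countable.
* The contact rule is satisfied by an overall contact or by a contact at
  every listed site; it is denominated over interventional records,
  while the overall-contact and per-contact phone/email accounting is
  denominated over all records and all provided contacts respectively
  (a contact counts as provided if any of its sub-fields is present).

The principal-investigator partition is four-way: an investigator-typed
responsible party ("Principal Investigator" or "Sponsor-Investigator"),
one or more overall officials, both, or neither.

## Eligibility criteria

The registry never published its classifying expressions, so this
package's grammar is the canonical definition and all class counts are
relative to it. Canonical headers are lines equal (case-insensitively,
whitespace-normalized, optional trailing colon) to `Inclusion Criteria`
or `Exclusion Criteria`. A block is *correct* when both canonical
headers are present and every non-blank body line is a bullet line
(markers `-`, `*`, `•`, or `digits.`/`digits)`); *headers_only* when the
headers are present over at least one unbulleted line; *missing* when
absent or whitespace-only; otherwise *malformed_headers* (a header
missing, misspelled, or a variant such as `Key Inclusion Criteria`).
Classification is total — every block maps to exactly one class — and
correct blocks parse into trimmed inclusion/exclusion lists.

The multi-group heuristic flags blocks with more than two header-like
lines, or any header-like line carrying a qualifier after the
`... Criteria` stem (`Inclusion Criteria - Cohort A`). It is
precision-oriented and advisory: it is validated against synthetic
plants, not against human review.

Sample extrapolation uses the Wilson score interval (via statsmodels)
rather than the Wald interval — better behaved at extreme proportions —
and the point estimate is the rounded product of the sample proportion
and the population size, presented at 3 significant figures where
reports do so. The planning helper returns the smallest n with
z²p(1−p)/n ≤ margin² (385 at 95%/±5 points on worst-case p = 0.5).

The separate-field repair property — reclassifying the split halves of a
header-bearing block in headerless mode carries no header-error codes —
operationalizes, per record, the observation that separate
inclusion/exclusion fields would eliminate the header-error class
entirely.

## Lexicon coverage

"Exact match" is membership of the normalized value (trim, collapse
internal whitespace, case-fold) in a lexicon's normalized preferred-name
key set. Case-folding is the default because registry values capitalize
inconsistently; a strict-case mode is provided. Values are counted as a
bag (once per occurrence), matching how condition/intervention listings
are denominated. Any three-column `(source_id, preferred_name,
identifier)` table plugs in; the bundled file is a small hand-authored
**synthetic** stand-in shaped like exported MeSH/MedDRA/SNOMED-CT/RxNorm
preferred-name spaces, sufficient for testing and demonstration but not
a licensed terminology.

## The synthetic generator

The generator emulates the structural features the audit measures — XML
element structure, type grammars, enumerated sets, era-dependent
requirements, the four criteria format classes (as canonical exemplars
of each), lexicon membership, and the full-name-in-last-name
irregularity of real contact data. It does **not** model realistic text
distributions, inter-field correlations, or the long tail of real-world
formatting noise; exact-recovery tests therefore demonstrate the audit's
bookkeeping correctness, not its behavior on adversarial real text.

Default mixes are the registry-wide composition of the April 2019 public
dump: study types 79.2/19.8/1.0% (interventional/observational/expanded
access), eras 80.6/19.4% (pre/post cutoff), agency classes
2.9/1.3/28.9/66.9% (NIH/U.S. Fed/Industry/Other), and the PI partition
11.7/7.5/53.9/26.9% (none/responsible-party only/official only/both).
All defect plans default to zero: the default corpus is clean. In
`exact_counts` mode (the test default) each plan entry is placed by
sampling without replacement among eligible records, so audit statistics
equal planted counts exactly; `rates` mode draws Bernoulli defects and
is used by the `paper_profile` demonstration preset, whose rates echo
the headline published defect percentages. One PCG64 stream per defect
family is spawned from the master seed, so editing one plan entry does
not reshuffle unrelated placements. Plans are checked for feasibility
(counts versus eligible records), and a few couplings are handled
explicitly: a planted *missing* criteria class is also a missing
required field; planting *why study stopped* forces a Terminated status
and is never co-planted with a missing recruitment status; deleting the
start date moves the record to the unknown era in the ground truth.

Ground truth is the realized per-record assignment of every planted
property plus the aggregate counts those assignments imply — derived
from the plan, never from running the audit, so recovery tests are not
circular.

## Problem sizes and numerics

The acceptance checks run a 500-record clean corpus and a 1,000-record
planted corpus — large enough that every defect family, era, agency
class and intervention-type stratum is populated, and a single pass
(including XML serialization round-trips) completes in seconds on one
CPU. Percent rendering is table-specific (one decimal for criteria
classes, two for the sub-percent missing class, integers elsewhere),
matching how such tables are conventionally printed; empty denominators
render as a flagged zero rather than raising.

## Known limitations

* The registry TSV reflects one fixed dialect (the 2019-era public XML)
  and one pre/post-Final-Rule distinction; it does not track every
  historical dictionary revision.
* The criteria grammar is a declared stand-in for unpublished
  classification rules; counts on real corpora are relative to it.
* The multi-group heuristic has unknown recall on real text.
* The bundled lexicon is synthetic; real coverage analyses require
  exported terminology tables (the `Lexicon` contract accepts any such
  table, including ones built from a terminology service).
* No live-registry access: downloading a bulk dump is a manual step.
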