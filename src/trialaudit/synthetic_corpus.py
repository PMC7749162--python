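"""Seeded synthetic registration corpora with recoverable defect profiles.

The generator emits registration records in the same public-XML dialect the
reader consumes, schema-conformant except where a defect plan plants one:
missing required fields, rogue enumerated values, eligibility-criteria
format classes, out-of-lexicon condition/intervention values, and degraded
contact information. In ``exact_counts`` mode every plan entry is placed by
sampling without replacement among the eligible records, so the audit
statistic it perturbs equals the planted count exactly; ``rates`` mode
draws per-unit Bernoulli defects instead. The realized assignment of every
defect is returned as a :class:`GroundTruth` so tests can compare audit
output against the plan rather than against the audit itself.

Default mixes (study type, era, agency class, PI listing) follow the
registry-wide composition reported for the April 2019 public dump: 79%
interventional records, 81%/19% pre/post Final Rule start dates, lead
sponsors dominated by the Other and Industry classes, and a PI partition in
which 12% of records name no principal investigator. One pseudo-random
stream per defect family is split off the master seed, so editing one plan
entry does not reshuffle unrelated placements.

The full-name-in-last-name irregularity of real records ("Sarah Smith,
M.D." stored whole in the last-name sub-field) is reproduced deliberately.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from .record_io import (
    Arm,
    ContactDetail,
    Intervention,
    Location,
    Official,
    OutcomeMeasure,
    TrialRecord,
    read_record,
    write_record,
)

__all__ = [
    "GeneratorConfig", "GroundTruth", "ConfigError", "generate",
    "write_corpus", "verify_manifest", "paper_profile",
    "CONDITION_TERMS", "INTERVENTION_TERMS", "INTERVENTION_TYPES",
]

STUDY_TYPES = ("Interventional", "Observational", "Expanded Access")
ERAS = ("pre_final_rule", "post_final_rule")
AGENCY_CLASSES = ("NIH", "U.S. Fed", "Industry", "Other")
PI_CATEGORIES = ("no_pi", "rp_investigator_only",
                 "official_with_nonscientific_rp", "both")
CRITERIA_CLASSES = ("correct", "headers_only", "malformed_headers", "missing")

INTERVENTION_TYPES = ("Drug", "Device", "Biologic/Vaccine",
                      "Procedure/Surgery", "Radiation", "Behavioral",
                      "Genetic", "Dietary Supplement", "Combination Product",
                      "Diagnostic Test", "Other")

#: Condition strings whose normalized forms are entries of the bundled
#: fixture lexicon (a test asserts this cross-reference).
CONDITION_TERMS = (
    "Type 2 Diabetes Mellitus", "Hypertension", "Asthma", "Breast Cancer",
    "Chronic Obstructive Pulmonary Disease", "Major Depressive Disorder",
    "Rheumatoid Arthritis", "Atrial Fibrillation", "Alzheimer Disease",
    "Obesity", "Migraine", "Psoriasis", "Chronic Kidney Disease",
    "Heart Failure", "Osteoarthritis", "Epilepsy", "Parkinson Disease",
    "Stroke", "Anemia", "Melanoma",
)

#: Per-type intervention names present in the bundled fixture lexicon.
INTERVENTION_TERMS = {
    "Drug": ("Metformin", "Atorvastatin", "Lisinopril"),
    "Device": ("Insulin Pump", "Cardiac Pacemaker",
               "Continuous Glucose Monitor"),
    "Biologic/Vaccine": ("Influenza Vaccine", "Rituximab", "Adalimumab"),
    "Procedure/Surgery": ("Coronary Artery Bypass Grafting",
                          "Total Knee Arthroplasty",
                          "Laparoscopic Cholecystectomy"),
    "Radiation": ("Stereotactic Body Radiotherapy", "Proton Beam Therapy",
                  "Brachytherapy"),
    "Behavioral": ("Cognitive Behavioral Therapy",
                   "Motivational Interviewing",
                   "Mindfulness-Based Stress Reduction"),
    "Genetic": ("Gene Transfer Therapy", "Antisense Oligonucleotide",
                "CAR T-Cell Therapy"),
    "Dietary Supplement": ("Vitamin D", "Omega-3 Fatty Acids", "Probiotics"),
    "Combination Product": ("Drug-Eluting Stent",
                            "Antibiotic-Loaded Bone Cement",
                            "Naloxone Auto-Injector"),
    "Diagnostic Test": ("Magnetic Resonance Imaging",
                        "Polymerase Chain Reaction Test", "Colonoscopy"),
    "Other": ("Placebo", "Standard of Care", "Exercise Program"),
}

_SPONSORS = ("Meridian Health Network", "Lakeside University",
             "Aurora Therapeutics", "Northgate Medical Center",
             "Crestview Research Institute")
_NAMES = ("Sarah Smith, M.D.", "James Lee, Ph.D.", "Maria Garcia, M.D.",
          "Robert Chen, M.D., Ph.D.", "Emily Johnson, R.N.")
_CITIES = (("Springfield", "United States"), ("Riverton", "United States"),
           ("Oakdale", "Canada"), ("Greenfield", "United States"))
_PHASES = ("Phase 1", "Phase 2", "Phase 3", "Phase 2/Phase 3", "N/A")
_NONSTOP_STATUSES = ("Completed", "Recruiting", "Active, not recruiting")

_MONTH_NAMES = ("January", "February", "March", "April", "May", "June",
                "July", "August", "September", "October", "November",
                "December")


class ConfigError(ValueError):
    """Infeasible or inconsistent generator configuration."""


def _default_study_mix() -> dict[str, float]:
    return {"Interventional": 0.792, "Observational": 0.198,
            "Expanded Access": 0.010}


def _default_era_mix() -> dict[str, float]:
    return {"pre_final_rule": 0.806, "post_final_rule": 0.194}


def _default_agency_mix() -> dict[str, float]:
    return {"NIH": 0.029, "U.S. Fed": 0.013, "Industry": 0.289,
            "Other": 0.669}


def _default_pi_mix() -> dict[str, float]:
    return {"no_pi": 0.117, "rp_investigator_only": 0.075,
            "official_with_nonscientific_rp": 0.539, "both": 0.269}


@dataclass
class GeneratorConfig:
    """Full description of one synthetic corpus.

    All defect plans default to zero/empty: the default corpus is clean and
    passes every audit stage without findings. In ``exact_counts`` mode
    plan values are integers placed exactly; in ``rates`` mode they are
    per-eligible-unit probabilities.
    """

    n_records: int
    seed: int
    mode: str = "exact_counts"
    study_type_mix: dict[str, float] = field(default_factory=_default_study_mix)
    era_mix: dict[str, float] = field(default_factory=_default_era_mix)
    agency_mix: dict[str, float] = field(default_factory=_default_agency_mix)
    pi_mix: dict[str, float] = field(default_factory=_default_pi_mix)
    missing_plan: dict[str, float] = field(default_factory=dict)
    rogue_plan: dict[str, tuple[str, float]] = field(default_factory=dict)
    criteria_class_plan: dict[str, float] | None = None
    multi_group_count: float = 0
    lexicon_membership: dict | None = None
    contact_plan: dict[str, float] = field(default_factory=dict)
    locations_per_record: int = 2

    def validate(self) -> None:
        if self.n_records < 1:
            raise ConfigError("n_records must be >= 1")
        if self.mode not in ("exact_counts", "rates"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        for label, mix, keys in (
                ("study_type_mix", self.study_type_mix, STUDY_TYPES),
                ("era_mix", self.era_mix, ERAS),
                ("agency_mix", self.agency_mix, AGENCY_CLASSES),
                ("pi_mix", self.pi_mix, PI_CATEGORIES)):
            if set(mix) - set(keys):
                raise ConfigError(f"{label}: unknown keys {set(mix) - set(keys)}")
            if abs(sum(mix.values()) - 1.0) > 1e-6:
                raise ConfigError(f"{label} probabilities must sum to 1")
        if self.criteria_class_plan is not None:
            bad = set(self.criteria_class_plan) - set(CRITERIA_CLASSES)
            if bad:
                raise ConfigError(f"criteria_class_plan: unknown classes {bad}")
        if self.locations_per_record < 0:
            raise ConfigError("locations_per_record must be >= 0")


@dataclass
class GroundTruth:
    """Realized per-record assignment of every planted property.

    ``records`` maps record id to its assignment (study type, era, agency
    class, PI category, criteria class, lexicon membership, planted
    defects); ``expected`` holds the aggregate counts those assignments
    imply. Fully determined by the configuration and seed.
    """

    n_records: int
    seed: int
    mode: str
    records: dict[str, dict] = field(default_factory=dict)
    expected: dict = field(default_factory=dict)

    def to_json(self) -> dict:
        return {"n_records": self.n_records, "seed": self.seed,
                "mode": self.mode, "records": self.records,
                "expected": self.expected}

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_json(), indent=1, sort_keys=True),
            encoding="utf-8")


# ---------------------------------------------------------------------------
# assignment helpers


def _apportion(mix: dict[str, float], keys: tuple[str, ...], n: int,
               rng: np.random.Generator, mode: str) -> list[str]:
    """Assign one of ``keys`` to each of n units honoring ``mix``.

    exact_counts: largest-remainder apportionment, then a seeded shuffle;
    rates: i.i.d. draws from the mix.
    """
    probs = [mix.get(k, 0.0) for k in keys]
    if mode == "rates":
        return list(rng.choice(keys, size=n, p=np.array(probs) / sum(probs)))
    quotas = [p * n for p in probs]
    counts = [int(q) for q in quotas]
    shortfall = n - sum(counts)
    remainders = sorted(range(len(keys)), key=lambda i: quotas[i] - counts[i],
                        reverse=True)
    for i in remainders[:shortfall]:
        counts[i] += 1
    labels = [k for k, c in zip(keys, counts) for _ in range(c)]
    rng.shuffle(labels)
    return labels


def _plan_count(value: float, n_eligible: int, mode: str, entry: str,
                rng: np.random.Generator) -> int:
    if mode == "rates":
        if not (0 <= value <= 1):
            raise ConfigError(f"{entry}: rate must be in [0, 1]")
        return int(rng.binomial(n_eligible, value)) if n_eligible else 0
    if value != int(value) or value < 0:
        raise ConfigError(f"{entry}: exact_counts mode needs a nonnegative "
                          f"integer, got {value!r}")
    count = int(value)
    if count > n_eligible:
        raise ConfigError(f"{entry}: planted count {count} exceeds the "
                          f"{n_eligible} eligible records/slots")
    return count


def _sample(eligible: list, count: int, rng: np.random.Generator) -> list:
    if count == 0:
        return []
    idx = rng.choice(len(eligible), size=count, replace=False)
    return [eligible[i] for i in sorted(idx)]


# ---------------------------------------------------------------------------
# criteria exemplars


def _criteria_text(cls: str, condition: str, multi_group: bool) -> str | None:
    if cls == "missing":
        return None
    if multi_group:
        return (
            "Inclusion Criteria - Cohort A:\n"
            f"- Confirmed diagnosis of {condition}\n"
            "- Age 18 to 65 years\n"
            "Exclusion Criteria - Cohort A:\n"
            "- Pregnancy or breastfeeding\n"
            "Inclusion Criteria - Cohort B (healthy volunteers):\n"
            "- No chronic illness\n"
            "Exclusion Criteria - Cohort B (healthy volunteers):\n"
            "- Any current medication\n")
    if cls == "correct":
        return (
            "Inclusion Criteria:\n"
            f"- Confirmed diagnosis of {condition}\n"
            "- Age 18 to 65 years\n"
            "- Able to provide informed consent\n"
            "Exclusion Criteria:\n"
            "- Pregnancy or breastfeeding\n"
            "- Participation in another trial within 30 days\n")
    if cls == "headers_only":
        return (
            "Inclusion Criteria:\n"
            f"Patients are eligible if they are 18 to 65 years of age and "
            f"have a confirmed diagnosis of {condition}.\n"
            "Exclusion Criteria:\n"
            "- Pregnancy or breastfeeding\n")
    # malformed_headers: alternative header wording
    return (
        "Key Inclusion Criteria:\n"
        f"- Confirmed diagnosis of {condition}\n"
        "- Age 18 to 65 years\n"
        "Key Exclusion Criteria:\n"
        "- Pregnancy or breastfeeding\n")


# ---------------------------------------------------------------------------
# record construction


def _make_date(era: str, rng: np.random.Generator) -> str:
    if era == "pre_final_rule":
        year = int(rng.integers(2005, 2017))
        month = _MONTH_NAMES[int(rng.integers(0, 12))]
        day = int(rng.integers(1, 29))
        return f"{month} {day}, {year}"
    year = int(rng.integers(2017, 2020))
    if year == 2017:
        # stay on or after the January 18 cutoff
        month_i = int(rng.integers(0, 12))
        day = int(rng.integers(18, 29)) if month_i == 0 else int(rng.integers(1, 29))
    else:
        month_i = int(rng.integers(0, 12))
        day = int(rng.integers(1, 29))
    return f"{_MONTH_NAMES[month_i]} {day}, {year}"


def _base_record(i: int, study_type: str, era: str, agency: str,
                 pi_category: str, n_locations: int,
                 rng: np.random.Generator) -> TrialRecord:
    rec = TrialRecord(record_id=f"NCT{10000000 + i + 1:08d}")
    rec.study_type = study_type
    rec.org_study_id = f"PROTO-{i + 1:05d}"
    rec.secondary_ids = [f"SEC-{i + 1:05d}"]
    sponsor = _SPONSORS[i % len(_SPONSORS)]
    rec.brief_title = f"Synthetic Study {i + 1:05d}"
    rec.official_title = (f"A {study_type} Study of Candidate Protocol "
                          f"{i + 1:05d}")
    rec.brief_summary = "Synthetic registration generated for audit testing."
    rec.sponsor_name = sponsor
    rec.agency_class = agency
    rec.overall_status_raw = _NONSTOP_STATUSES[i % len(_NONSTOP_STATUSES)]
    rec.start_date_raw = _make_date(era, rng)
    rec.start_date_attr = "Actual"
    rec.completion_date_raw = _make_date(era, rng)
    rec.completion_date_attr = "Anticipated"
    rec.primary_completion_date_raw = rec.completion_date_raw
    rec.primary_completion_date_attr = "Anticipated"
    rec.verification_date_raw = "January, 2019"
    rec.enrollment_raw = str(int(rng.integers(10, 500)))
    rec.enrollment_attr = "Anticipated"
    rec.has_expanded_access_raw = ("Yes" if study_type == "Expanded Access"
                                   else "No")
    rec.gender = "All"
    rec.minimum_age_raw = "18 Years"
    rec.maximum_age_raw = "65 Years"
    rec.healthy_volunteers_raw = "No"
    rec.outcomes = [
        OutcomeMeasure(rank="primary", measure="Change in symptom score",
                       time_frame="Baseline to 12 weeks",
                       description="Primary efficacy endpoint."),
        OutcomeMeasure(rank="secondary", measure="Adverse event rate",
                       time_frame="Through study completion",
                       description="Safety endpoint."),
    ]
    if study_type == "Interventional":
        rec.phase = _PHASES[i % len(_PHASES)]
        d = rec.design
        d.allocation_raw = "Randomized"
        d.interventional_model_raw = "Parallel Group Assignment"
        d.primary_purpose_raw = "Treatment"
        d.masking_raw = "Double(Participant, Investigator)"
        d.number_of_arms_raw = "2"
        d.arms = [
            Arm(label="Active", arm_type_raw="Experimental",
                description="Receives the study intervention."),
            Arm(label="Control", arm_type_raw="Placebo Comparator",
                description="Receives matching placebo."),
        ]
    elif study_type == "Observational":
        rec.phase = "N/A"
        d = rec.design
        d.observational_model_raw = "Cohort"
        d.time_perspective_raw = "Prospective"
        d.sampling_method_raw = "Probability Sample"
    else:
        rec.phase = "N/A"

    p = rec.parties
    official = Official(last_name_raw=_NAMES[i % len(_NAMES)],
                        role_raw="Study Principal Investigator",
                        affiliation=sponsor)
    if pi_category == "both":
        p.responsible_party_type_raw = "Sponsor-Investigator"
        p.overall_officials = [official]
    elif pi_category == "rp_investigator_only":
        p.responsible_party_type_raw = "Principal Investigator"
    elif pi_category == "official_with_nonscientific_rp":
        p.responsible_party_type_raw = "Sponsor"
        p.overall_officials = [official]
    else:
        p.responsible_party_type_raw = "Sponsor"
    if p.responsible_party_type_raw in ("Principal Investigator",
                                        "Sponsor-Investigator"):
        p.rp_investigator_full_name = _NAMES[i % len(_NAMES)]
        p.rp_investigator_affiliation = sponsor
        p.rp_investigator_title = "Professor of Medicine"

    rec.contacts.overall_contact = ContactDetail(
        last_name_raw=_NAMES[(i + 1) % len(_NAMES)],
        phone=f"555-01{i % 100:02d}", email=f"contact{i + 1}@example.org")
    for j in range(n_locations):
        city, country = _CITIES[(i + j) % len(_CITIES)]
        rec.contacts.locations.append(Location(
            facility_name=f"{sponsor} Site {j + 1}",
            city=city, country=country,
            site_status_raw="Recruiting",
            site_contact=ContactDetail(
                last_name_raw=_NAMES[(i + j) % len(_NAMES)],
                phone=f"555-02{(i + j) % 100:02d}",
                email=f"site{j + 1}-{i + 1}@example.org"),
        ))
    return rec


# ---------------------------------------------------------------------------
# defect mutators (missing_plan)

def _del_all_loc(attr: str) -> Callable[[TrialRecord], None]:
    def mut(rec: TrialRecord) -> None:
        for loc in rec.contacts.locations:
            setattr(loc, attr, None)
    return mut


def _del_primary_outcome_field(attr: str) -> Callable[[TrialRecord], None]:
    def mut(rec: TrialRecord) -> None:
        for o in rec.outcomes:
            if o.rank == "primary":
                setattr(o, attr, None)
    return mut


def _set(attr: str, value=None) -> Callable[[TrialRecord], None]:
    def mut(rec: TrialRecord) -> None:
        setattr(rec, attr, value)
    return mut


def _set_design(attr: str) -> Callable[[TrialRecord], None]:
    def mut(rec: TrialRecord) -> None:
        setattr(rec.design, attr, None)
    return mut


def _del_why_stopped(rec: TrialRecord) -> None:
    rec.overall_status_raw = "Terminated"
    rec.why_stopped = None


def _del_interventions_field(attr: str) -> Callable[[TrialRecord], None]:
    def mut(rec: TrialRecord) -> None:
        for iv in rec.interventions:
            setattr(iv, attr, None)
    return mut


_MISSING_MUTATORS: dict[str, Callable[[TrialRecord], None]] = {
    "brief title": _set("brief_title"),
    "brief summary": _set("brief_summary"),
    "study phase": _set("phase"),
    "condition": lambda r: r.conditions.clear(),
    "intervention name": _del_interventions_field("name"),
    "intervention type": _del_interventions_field("intervention_type"),
    "intervention description": _del_interventions_field("description"),
    "eligibility criteria": _set("eligibility_text"),
    "sex": _set("gender"),
    "minimum age": _set("minimum_age_raw"),
    "maximum age": _set("maximum_age_raw"),
    "overall recruitment status": _set("overall_status_raw"),
    "lead sponsor name": _set("sponsor_name"),
    "responsible party type":
        lambda r: setattr(r.parties, "responsible_party_type_raw", None),
    "secondary id": lambda r: r.secondary_ids.clear(),
    "official title": _set("official_title"),
    "primary purpose": _set_design("primary_purpose_raw"),
    "interventional study model": _set_design("interventional_model_raw"),
    "number of arms": _set_design("number_of_arms_raw"),
    "allocation": _set_design("allocation_raw"),
    "masking": _set_design("masking_raw"),
    "arm information": lambda r: r.design.arms.clear(),
    "study start date": _set("start_date_raw"),
    "primary completion date": _set("primary_completion_date_raw"),
    "study completion date": _set("completion_date_raw"),
    "enrollment": _set("enrollment_raw"),
    "primary outcome measure information":
        lambda r: r.outcomes.__setitem__(
            slice(None), [o for o in r.outcomes if o.rank != "primary"]),
    "outcome measure": _del_primary_outcome_field("measure"),
    "outcome time frame": _del_primary_outcome_field("time_frame"),
    "outcome description": _del_primary_outcome_field("description"),
    "accepts healthy volunteers": _set("healthy_volunteers_raw"),
    "why study stopped": _del_why_stopped,
    "individual site status": _del_all_loc("site_status_raw"),
    "availability of expanded access": _set("has_expanded_access_raw"),
    "facility information": lambda r: r.contacts.locations.clear(),
    "facility name": _del_all_loc("facility_name"),
    "facility city": _del_all_loc("city"),
    "facility country": _del_all_loc("country"),
}

#: Fields whose requirement starts at the Final Rule: plant only where the
#: leniency for earlier records does not mask the defect.
_POST_RULE_ONLY = frozenset({"official title", "study completion date",
                             "why study stopped"})

_NEEDS_LOCATIONS = frozenset({"individual site status", "facility name",
                              "facility city", "facility country"})

#: A field cannot be planted missing on a record where one of these other
#: plants would undo or mask it.
_PLANT_CONFLICTS = {
    "why study stopped": frozenset({"overall recruitment status"}),
}


def _missing_eligible(field_name: str, rec: TrialRecord, era: str,
                      already_planted: list[str]) -> bool:
    if rec.study_type != "Interventional":
        return False
    if field_name in already_planted:
        return False
    if _PLANT_CONFLICTS.get(field_name, frozenset()) & set(already_planted):
        return False
    if field_name in _POST_RULE_ONLY and era == "pre_final_rule":
        return False
    if field_name in _NEEDS_LOCATIONS and not rec.contacts.locations:
        return False
    return True


# rogue_plan: eligible iff the field's element currently occurs
_ROGUE_SETTERS: dict[str, tuple[Callable[[TrialRecord], bool],
                                Callable[[TrialRecord, str], None]]] = {
    "study phase": (lambda r: r.phase is not None,
                    lambda r, v: setattr(r, "phase", v)),
    "overall recruitment status":
        (lambda r: r.overall_status_raw is not None,
         lambda r, v: setattr(r, "overall_status_raw", v)),
    "responsible party type":
        (lambda r: r.parties.responsible_party_type_raw is not None,
         lambda r, v: setattr(r.parties, "responsible_party_type_raw", v)),
    "sex": (lambda r: r.gender is not None,
            lambda r, v: setattr(r, "gender", v)),
    "primary purpose":
        (lambda r: r.design.primary_purpose_raw is not None,
         lambda r, v: setattr(r.design, "primary_purpose_raw", v)),
    "interventional study model":
        (lambda r: r.design.interventional_model_raw is not None,
         lambda r, v: setattr(r.design, "interventional_model_raw", v)),
    "allocation": (lambda r: r.design.allocation_raw is not None,
                   lambda r, v: setattr(r.design, "allocation_raw", v)),
    "masking": (lambda r: r.design.masking_raw is not None,
                lambda r, v: setattr(r.design, "masking_raw", v)),
    "arm type": (lambda r: bool(r.design.arms),
                 lambda r, v: setattr(r.design.arms[0], "arm_type_raw", v)),
    "observational study model":
        (lambda r: r.design.observational_model_raw is not None,
         lambda r, v: setattr(r.design, "observational_model_raw", v)),
    "time perspective":
        (lambda r: r.design.time_perspective_raw is not None,
         lambda r, v: setattr(r.design, "time_perspective_raw", v)),
    "sampling method":
        (lambda r: r.design.sampling_method_raw is not None,
         lambda r, v: setattr(r.design, "sampling_method_raw", v)),
    "intervention type":
        (lambda r: bool(r.interventions),
         lambda r, v: setattr(r.interventions[0], "intervention_type", v)),
    "individual site status":
        (lambda r: bool(r.contacts.locations),
         lambda r, v: setattr(r.contacts.locations[0], "site_status_raw", v)),
}


# ---------------------------------------------------------------------------
# generation


def generate(config: GeneratorConfig) -> tuple[list[TrialRecord], GroundTruth]:
    """Generate a corpus and its ground truth.

    A pure function of the configuration (which includes the seed): the
    same configuration yields byte-identical corpora.
    """
    config.validate()
    n = config.n_records
    mode = config.mode
    seeds = np.random.SeedSequence(config.seed).spawn(8)
    (rng_structure, rng_dates, rng_missing, rng_rogue, rng_criteria,
     rng_lexicon, rng_contact, rng_noise) = [
        np.random.Generator(np.random.PCG64(s)) for s in seeds]

    study_types = _apportion(config.study_type_mix, STUDY_TYPES, n,
                             rng_structure, mode)
    eras = _apportion(config.era_mix, ERAS, n, rng_structure, mode)
    agencies = _apportion(config.agency_mix, AGENCY_CLASSES, n,
                          rng_structure, mode)
    pis = _apportion(config.pi_mix, PI_CATEGORIES, n, rng_structure, mode)

    records: list[TrialRecord] = []
    truth = GroundTruth(n_records=n, seed=config.seed, mode=mode)
    assign: list[dict] = []
    for i in range(n):
        rec = _base_record(i, study_types[i], eras[i], agencies[i], pis[i],
                           config.locations_per_record, rng_dates)
        records.append(rec)
        assign.append({
            "study_type": study_types[i],
            "era": eras[i],
            "agency_class": agencies[i],
            "pi_category": pis[i],
            "planted_missing": [],
            "planted_rogue": [],
        })

    # --- lexicon membership (conditions; interventions per type) ----------
    lex = config.lexicon_membership or {}
    cond_plan = lex.get("condition")
    n_in = (n if cond_plan is None
            else _plan_count(cond_plan, n, mode, "lexicon_membership.condition",
                             rng_lexicon))
    in_set = set(range(n)) if cond_plan is None else set(
        int(i) for i in rng_lexicon.choice(n, size=n_in, replace=False))
    for i, rec in enumerate(records):
        if i in in_set:
            term = CONDITION_TERMS[i % len(CONDITION_TERMS)]
            rec.conditions = [term]
            assign[i]["condition_in_lexicon"] = True
        else:
            rec.conditions = [f"Unindexed Condition {i + 1:05d}"]
            assign[i]["condition_in_lexicon"] = False

    interventional_idx = [i for i in range(n)
                          if study_types[i] == "Interventional"]
    for slot, i in enumerate(interventional_idx):
        itype = INTERVENTION_TYPES[slot % len(INTERVENTION_TYPES)]
        records[i].interventions = [Intervention(
            intervention_type=itype,
            name=INTERVENTION_TERMS[itype][slot % 3],
            description=f"Administration of {INTERVENTION_TERMS[itype][slot % 3]}.")]
        assign[i]["intervention_type"] = itype
        assign[i]["intervention_in_lexicon"] = True
    for itype in INTERVENTION_TYPES:
        key = ("intervention", itype)
        plan = lex.get(key, lex.get(f"intervention:{itype}"))
        if plan is None:
            continue
        slots = [i for i in interventional_idx
                 if assign[i].get("intervention_type") == itype]
        n_out = len(slots) - _plan_count(
            plan, len(slots), mode, f"lexicon_membership[{key}]", rng_lexicon)
        for i in _sample(slots, n_out, rng_lexicon):
            records[i].interventions[0].name = (
                f"Unindexed {itype} Product {i + 1:05d}")
            assign[i]["intervention_in_lexicon"] = False

    # --- eligibility criteria classes --------------------------------------
    if config.criteria_class_plan is None:
        classes = ["correct"] * n
    elif mode == "rates":
        probs = [float(config.criteria_class_plan.get(cls, 0.0))
                 for cls in CRITERIA_CLASSES]
        remainder = 1.0 - sum(probs)
        if remainder < -1e-9:
            raise ConfigError("criteria_class_plan: rates sum above 1")
        probs[0] += max(remainder, 0.0)  # unplanned mass -> correct
        classes = [str(c) for c in rng_criteria.choice(
            CRITERIA_CLASSES, size=n, p=np.array(probs) / sum(probs))]
    else:
        counts = {}
        for cls in CRITERIA_CLASSES:
            counts[cls] = _plan_count(
                config.criteria_class_plan.get(cls, 0), n, mode,
                f"criteria_class_plan.{cls}", rng_criteria)
        total = sum(counts.values())
        if total > n:
            raise ConfigError(
                f"criteria_class_plan: class counts sum to {total} > "
                f"n_records {n}")
        counts["correct"] += n - total
        classes = [cls for cls in CRITERIA_CLASSES
                   for _ in range(counts[cls])]
        rng_criteria.shuffle(classes)
    n_multi = _plan_count(config.multi_group_count,
                          classes.count("malformed_headers"), mode,
                          "multi_group_count", rng_criteria)
    malformed_idx = [i for i in range(n)
                     if classes[i] == "malformed_headers"]
    multi_idx = set(_sample(malformed_idx, n_multi, rng_criteria))
    for i, rec in enumerate(records):
        multi = i in multi_idx
        rec.eligibility_text = _criteria_text(
            classes[i], rec.conditions[0], multi)
        assign[i]["criteria_class"] = classes[i]
        assign[i]["multi_group"] = multi
        if classes[i] == "missing" and study_types[i] == "Interventional":
            # a planted missing criteria block is also a missing required
            # field for the completeness audit
            assign[i]["planted_missing"].append("eligibility criteria")

    # --- missing-field plan -------------------------------------------------
    for field_name in sorted(config.missing_plan):
        if field_name not in _MISSING_MUTATORS:
            raise ConfigError(
                f"missing_plan: unknown field {field_name!r}")
        eligible = [i for i in range(n)
                    if _missing_eligible(field_name, records[i],
                                         assign[i]["era"],
                                         assign[i]["planted_missing"])]
        count = _plan_count(config.missing_plan[field_name], len(eligible),
                            mode, f"missing_plan.{field_name}", rng_missing)
        for i in _sample(eligible, count, rng_missing):
            _MISSING_MUTATORS[field_name](records[i])
            assign[i]["planted_missing"].append(field_name)
            if field_name == "study start date":
                assign[i]["era"] = "unknown_start_date"
            if field_name == "eligibility criteria":
                assign[i]["criteria_class"] = "missing"
                assign[i]["multi_group"] = False
            if field_name == "condition":
                assign[i]["condition_in_lexicon"] = None
            if field_name in ("intervention name", "intervention type"):
                assign[i]["intervention_in_lexicon"] = None
            if field_name == "responsible party type":
                assign[i]["pi_category"] = _recompute_pi(records[i])

    # --- rogue-value plan ---------------------------------------------------
    for field_name in sorted(config.rogue_plan):
        if field_name not in _ROGUE_SETTERS:
            raise ConfigError(f"rogue_plan: unknown field {field_name!r}")
        value, amount = config.rogue_plan[field_name]
        pred, setter = _ROGUE_SETTERS[field_name]
        eligible = [i for i in range(n) if pred(records[i])]
        count = _plan_count(amount, len(eligible), mode,
                            f"rogue_plan.{field_name}", rng_rogue)
        for i in _sample(eligible, count, rng_rogue):
            setter(records[i], value)
            assign[i]["planted_rogue"].append(field_name)
            if field_name == "responsible party type":
                assign[i]["pi_category"] = _recompute_pi(records[i])
            if field_name == "intervention type":
                assign[i]["intervention_type"] = value

    # --- contact plan -------------------------------------------------------
    cp = config.contact_plan
    if set(cp) - {"no_overall_contact", "sites_without_contact",
                  "missing_phone", "missing_email"}:
        raise ConfigError(f"contact_plan: unknown keys {set(cp)}")
    if "no_overall_contact" in cp:
        eligible = [i for i in range(n)
                    if records[i].contacts.overall_contact is not None]
        count = _plan_count(cp["no_overall_contact"], len(eligible), mode,
                            "contact_plan.no_overall_contact", rng_contact)
        for i in _sample(eligible, count, rng_contact):
            records[i].contacts.overall_contact = None
    if "sites_without_contact" in cp:
        slots = [(i, j) for i in range(n)
                 for j in range(len(records[i].contacts.locations))]
        count = _plan_count(cp["sites_without_contact"], len(slots), mode,
                            "contact_plan.sites_without_contact", rng_contact)
        for i, j in _sample(slots, count, rng_contact):
            records[i].contacts.locations[j].site_contact = None
    for key, attr in (("missing_phone", "phone"), ("missing_email", "email")):
        if key not in cp:
            continue
        slots = []
        for i in range(n):
            c = records[i].contacts
            if c.overall_contact is not None and c.overall_contact.provided:
                slots.append((i, -1))
            for j, loc in enumerate(c.locations):
                if loc.site_contact is not None and loc.site_contact.provided:
                    slots.append((i, j))
        count = _plan_count(cp[key], len(slots), mode,
                            f"contact_plan.{key}", rng_contact)
        for i, j in _sample(slots, count, rng_contact):
            c = records[i].contacts
            target = c.overall_contact if j == -1 else c.locations[j].site_contact
            setattr(target, attr, None)

    # --- canonical serialization round-trip ---------------------------------
    # Writing and re-reading populates raw_values so the typed fields are
    # true views over the emitted XML.
    records = [read_record(write_record(rec)) for rec in records]

    for i, rec in enumerate(records):
        c = rec.contacts
        overall = c.overall_contact is not None and c.overall_contact.provided
        all_sites = bool(c.locations) and all(
            l.site_contact is not None and l.site_contact.provided
            for l in c.locations)
        assign[i]["overall_contact_present"] = overall
        assign[i]["contact_rule_satisfied"] = overall or all_sites
        truth.records[rec.record_id] = assign[i]

    truth.expected = _aggregate(records, assign)
    return records, truth


def _recompute_pi(rec: TrialRecord) -> str:
    rp = rec.parties.responsible_party_type_raw in (
        "Principal Investigator", "Sponsor-Investigator")
    off = bool(rec.parties.overall_officials)
    return ("both" if rp and off else
            "rp_investigator_only" if rp else
            "official_with_nonscientific_rp" if off else "no_pi")


def _aggregate(records: list[TrialRecord], assign: list[dict]) -> dict:
    missing: dict[str, dict] = {}
    rogue: dict[str, int] = {}
    criteria = {cls: 0 for cls in CRITERIA_CLASSES}
    pi = {cat: 0 for cat in PI_CATEGORIES}
    n_multi = 0
    cond_in = cond_total = 0
    per_type: dict[str, dict[str, int]] = {}
    n_contacts = missing_phone = missing_email = 0
    n_no_overall = n_rule_unsatisfied = 0
    n_interventional = 0
    for rec, a in zip(records, assign):
        if a["study_type"] == "Interventional":
            n_interventional += 1
        for f in a["planted_missing"]:
            entry = missing.setdefault(
                f, {"total": 0, "by_era": {}, "by_agency": {}})
            entry["total"] += 1
            entry["by_era"][a["era"]] = entry["by_era"].get(a["era"], 0) + 1
            entry["by_agency"][a["agency_class"]] = (
                entry["by_agency"].get(a["agency_class"], 0) + 1)
        for f in a["planted_rogue"]:
            rogue[f] = rogue.get(f, 0) + 1
        criteria[a["criteria_class"]] += 1
        n_multi += bool(a["multi_group"])
        pi[a["pi_category"]] += 1
        if a.get("condition_in_lexicon") is not None:
            cond_total += 1
            cond_in += bool(a["condition_in_lexicon"])
        itype = a.get("intervention_type")
        if itype is not None and a.get("intervention_in_lexicon") is not None:
            entry = per_type.setdefault(itype, {"in": 0, "total": 0})
            entry["total"] += 1
            entry["in"] += bool(a["intervention_in_lexicon"])
        c = rec.contacts
        details = [c.overall_contact] + [l.site_contact for l in c.locations]
        for d in details:
            if d is None or not d.provided:
                continue
            n_contacts += 1
            missing_phone += d.phone is None
            missing_email += d.email is None
        n_no_overall += not a["overall_contact_present"]
        # the contact rule is a required-field statistic, denominated over
        # interventional records like the rest of the completeness audit
        n_rule_unsatisfied += (a["study_type"] == "Interventional"
                               and not a["contact_rule_satisfied"])
    return {
        "n_interventional": n_interventional,
        "missing": missing,
        "rogue": rogue,
        "criteria_classes": criteria,
        "multi_group": n_multi,
        "pi_partition": pi,
        "condition_coverage": {"in_lexicon": cond_in, "total": cond_total},
        "intervention_coverage_by_type": per_type,
        "contacts": {
            "n_contacts": n_contacts,
            "missing_phone": missing_phone,
            "missing_email": missing_email,
            "records_without_overall_contact": n_no_overall,
            "records_contact_rule_unsatisfied": n_rule_unsatisfied,
        },
    }


# ---------------------------------------------------------------------------
# corpus writing


def write_corpus(records: list[TrialRecord], truth: GroundTruth,
                 destination: str | Path) -> dict:
    """Write one XML file per record, the ground truth, and a manifest.

    The manifest lists every file with its SHA-256 digest plus a corpus
    checksum (digest of the per-file digests in filename order); it is
    written as ``manifest.json`` and also returned.
    """
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    for rec in records:
        data = write_record(rec)
        name = f"{rec.record_id}.xml"
        (dest / name).write_bytes(data)
        files[name] = hashlib.sha256(data).hexdigest()
    truth_path = dest / "ground_truth.json"
    truth.save(truth_path)
    files["ground_truth.json"] = hashlib.sha256(
        truth_path.read_bytes()).hexdigest()
    corpus_digest = hashlib.sha256(
        "".join(f"{k}:{v}\n" for k, v in sorted(files.items())).encode()
    ).hexdigest()
    manifest = {"n_records": len(records), "files": files,
                "corpus_checksum": corpus_digest}
    (dest / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True), encoding="utf-8")
    return manifest


def verify_manifest(destination: str | Path) -> bool:
    """Re-hash a written corpus and compare against its manifest."""
    dest = Path(destination)
    manifest = json.loads((dest / "manifest.json").read_text(encoding="utf-8"))
    for name, digest in manifest["files"].items():
        path = dest / name
        if not path.exists():
            return False
        if hashlib.sha256(path.read_bytes()).hexdigest() != digest:
            return False
    return True


# ---------------------------------------------------------------------------
# presets


def paper_profile(n_records: int, seed: int) -> GeneratorConfig:
    """Rates-mode preset echoing the headline registry-wide defect rates.

    Intended for demonstration reports: roughly 74% of records without an
    overall contact, 12% without a principal investigator, 10% of
    interventional records without listed arms, a 61/24/15/0.3 criteria
    class split, and 62% of conditions carried by the primary vocabulary.
    """
    return GeneratorConfig(
        n_records=n_records,
        seed=seed,
        mode="rates",
        missing_plan={
            "official title": 0.029,
            "primary purpose": 0.035,
            "interventional study model": 0.029,
            "number of arms": 0.10,
            "arm information": 0.10,
            "allocation": 0.236,
            "masking": 0.023,
            "intervention description": 0.19,
            "study start date": 0.012,
            "primary completion date": 0.063,
            "study completion date": 0.057,
            "enrollment": 0.017,
            "outcome description": 0.37,
        },
        criteria_class_plan={"correct": 0.607, "headers_only": 0.244,
                             "malformed_headers": 0.146, "missing": 0.003},
        multi_group_count=0.33,
        lexicon_membership={"condition": 0.62},
        contact_plan={"no_overall_contact": 0.74,
                      "missing_phone": 0.21, "missing_email": 0.22},
    )
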