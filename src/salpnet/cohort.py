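"""Cohort construction: eligible sterilization encounters from raw claims.

Pipeline order for each era:

1. group claim lines into encounters (outpatient: same enrollee + date;
   inpatient: same enrollee within a run of consecutive inpatient dates),
2. identify tubal-sterilization candidates (a ligation or salpingectomy
   procedure code together with a sterilization-encounter diagnosis and no
   abortion/ectopic diagnosis), assign the care setting (postpartum =
   inpatient childbirth hospitalization; interval = outpatient),
3. apply the exclusion cascade over the previous 12 months and the
   encounter itself, with a telescoping attrition report,
4. classify the opportunistic-salpingectomy (OS) outcome with
   setting-specific code logic,
5. derive the analysis covariates.

Conventions fixed here: dates are ISO-8601, intervals half-open
[start, end); "continuous coverage" tolerates no gap of >= 1 day in the
365 days before the encounter or index date; age is computed from birth
year with a July-1 mid-year convention; diagnosis-based BMI and smoking
default to "<25" and nonsmoker when no code appears in the window (claims
only code the abnormal).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codes import CodeDictionary

__all__ = [
    "AttritionReport",
    "group_encounters",
    "identify_sterilization_encounters",
    "apply_eligibility",
    "classify_outcome",
    "assign_index_dates",
    "derive_covariates",
    "build_cohort",
]

PLAUSIBLE_SURGEON_SPECIALTIES = {"obgyn", "urology"}
LOOKBACK_DAYS = 365


@dataclass
class AttritionReport:
    """Ordered exclusion cascade; counts telescope row to row."""

    rows: list[tuple[str, int, int, int]] = field(default_factory=list)

    def add(self, name: str, n_before: int, n_after: int) -> None:
        if self.rows and self.rows[-1][3] != n_before:
            raise ValueError("attrition counts do not telescope")
        self.rows.append((name, n_before, n_before - n_after, n_after))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows, columns=["filter_name", "n_before", "n_removed", "n_after"]
        )


def _age_at(birth_year: int, date: dt.date) -> float:
    """Age from birth year only, mid-year (July 1) birthday convention."""
    birthday = dt.date(int(birth_year), 7, 1)
    years = date.year - birthday.year
    if (date.month, date.day) < (birthday.month, birthday.day):
        years -= 1
    return years


# ---------------------------------------------------------------------------
# Encounter grouping and candidate identification
# ---------------------------------------------------------------------------


def group_encounters(claims: pd.DataFrame) -> pd.DataFrame:
    """Attach an ``encounter_id`` to every claim line.

    Outpatient lines group by (enrollee, service date); inpatient lines
    group by (enrollee, admission span), where an admission is a maximal
    run of consecutive inpatient service dates.
    """
    df = claims.copy()
    dates = pd.to_datetime(df["service_date"]).dt.date
    df["_date"] = dates
    inpat = df["setting"] == "inpatient"
    df["_adm_start"] = df["_date"]
    if inpat.any():
        sub = df.loc[inpat, ["enrollee_id", "_date"]].drop_duplicates()
        sub = sub.sort_values(["enrollee_id", "_date"])
        ordinals = sub["_date"].map(dt.date.toordinal)
        new_run = (sub["enrollee_id"] != sub["enrollee_id"].shift()) | (
            ordinals.diff() > 1
        )
        run_id = new_run.cumsum()
        start = sub.groupby(run_id)["_date"].transform("min")
        key = pd.Series(
            start.values, index=pd.MultiIndex.from_frame(sub[["enrollee_id", "_date"]])
        )
        df.loc[inpat, "_adm_start"] = pd.MultiIndex.from_arrays(
            [df.loc[inpat, "enrollee_id"], df.loc[inpat, "_date"]]
        ).map(key)
    df["encounter_id"] = (
        df["enrollee_id"].astype(str)
        + "|"
        + df["setting"].astype(str)
        + "|"
        + df["_adm_start"].astype(str)
    )
    return df.drop(columns=["_adm_start"])


def identify_sterilization_encounters(
    claims: pd.DataFrame,
    codes: CodeDictionary,
    era: str,
    era_span: tuple[dt.date, dt.date],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Find candidate sterilization encounters in one era.

    Returns ``(candidates, rejects)``.  A candidate has at least one
    tubal-ligation or salpingectomy procedure code, a sterilization-
    encounter diagnosis, and no abortion or ectopic-pregnancy diagnosis.
    Setting class is postpartum iff the encounter is inpatient with a
    delivery code, interval iff outpatient; inpatient encounters without a
    delivery code go to the rejects stream rather than being silently
    dropped.  The operating surgeon is the physician billing the
    sterilization procedure; ties go to the physician with the most
    interaction-days with the patient, then the lowest id.
    """
    df = group_encounters(claims)
    in_era = (df["_date"] >= era_span[0]) & (df["_date"] < era_span[1])
    df = df.loc[in_era]
    proc = codes.sterilization_procedure_codes
    has_proc = df.groupby("encounter_id")["code"].agg(lambda s: bool(set(s) & proc))
    enc_ids = has_proc[has_proc].index
    sub = df[df["encounter_id"].isin(enc_ids)]

    # interaction-days per (enrollee, physician) over all claims, for ties
    idays = (
        claims.groupby(["enrollee_id", "physician_id"])["service_date"]
        .nunique()
        .to_dict()
    )

    cand_rows, reject_rows = [], []
    for eid, g in sub.groupby("encounter_id"):
        codeset = frozenset(g["code"])
        enrollee = g["enrollee_id"].iloc[0]
        date = g["_date"].min()
        settings = set(g["setting"])
        if not codeset & codes.sterilization_encounter_dx:
            continue
        if codeset & (codes.abortion_dx | codes.ectopic_dx):
            continue
        if len(settings) > 1:
            reject_rows.append((eid, enrollee, date.isoformat(), "conflicting settings"))
            continue
        setting = settings.pop()
        if setting == "inpatient":
            if not codeset & codes.delivery_codes:
                reject_rows.append(
                    (eid, enrollee, date.isoformat(), "inpatient without delivery code")
                )
                continue
            setting_class = "postpartum"
        else:
            setting_class = "interval"
        billers = sorted(set(g.loc[g["code"].isin(proc), "physician_id"]))
        surgeon = min(
            billers, key=lambda p: (-idays.get((enrollee, p), 0), p)
        )
        spec = g.loc[g["physician_id"] == surgeon, "specialty"].iloc[0]
        cand_rows.append(
            {
                "encounter_id": eid,
                "enrollee_id": enrollee,
                "surgeon_id": surgeon,
                "surgeon_specialty": spec,
                "date": date,
                "era": era,
                "setting_class": setting_class,
                "codes": codeset,
            }
        )
    candidates = pd.DataFrame(
        cand_rows,
        columns=[
            "encounter_id",
            "enrollee_id",
            "surgeon_id",
            "surgeon_specialty",
            "date",
            "era",
            "setting_class",
            "codes",
        ],
    )
    rejects = pd.DataFrame(
        reject_rows, columns=["encounter_id", "enrollee_id", "date", "reason"]
    )
    return candidates, rejects


# ---------------------------------------------------------------------------
# Eligibility cascade
# ---------------------------------------------------------------------------


def _covered_365(spans: list[tuple[dt.date, dt.date]], end: dt.date) -> bool:
    """True iff [end-365, end) is fully inside the union of half-open spans."""
    need_start = end - dt.timedelta(days=LOOKBACK_DAYS)
    cursor = need_start
    for s, e in sorted(spans):
        if s > cursor:
            return False
        if e > cursor:
            cursor = e
        if cursor >= end:
            return True
    return cursor >= end


def _codes_in_window(
    claims_by_enrollee: dict, enrollee: str, start: dt.date, end: dt.date
) -> set[str]:
    g = claims_by_enrollee.get(enrollee)
    if g is None:
        return set()
    dates, code_arr = g
    mask = (dates >= start) & (dates < end)
    return set(code_arr[mask])


def apply_eligibility(
    candidates: pd.DataFrame,
    enrollment: pd.DataFrame,
    claims: pd.DataFrame,
    attributes: pd.DataFrame,
    codes: CodeDictionary,
) -> tuple[pd.DataFrame, AttritionReport]:
    """Apply the exclusion cascade; returns eligible encounters + report.

    Criteria, in order: age 18-49 at the encounter; continuous coverage in
    the prior 12 months (missing enrollment counts as non-continuous, in
    its own report row); diagnosis exclusions over the prior 12 months
    *and* the encounter (surgical history, tube/ovary disorders,
    cancer risk); prior salpingectomy/oophorectomy procedure in the 12
    months *before* the encounter date; unknown or implausible surgeon
    specialty.
    """
    report = AttritionReport()
    df = candidates.copy()
    report.add("candidates", len(df), len(df))

    birth = attributes.set_index("enrollee_id")["birth_year"].to_dict()
    ages = np.array(
        [
            _age_at(birth[e], d) if e in birth else np.nan
            for e, d in zip(df["enrollee_id"], df["date"])
        ]
    )
    keep = (ages >= 18) & (ages <= 49)
    n0 = len(df)
    df = df.loc[keep]
    report.add("age_18_49", n0, len(df))

    spans_by_enrollee: dict[str, list] = {}
    for row in enrollment.itertuples(index=False):
        spans_by_enrollee.setdefault(row.enrollee_id, []).append(
            (dt.date.fromisoformat(row.start_date), dt.date.fromisoformat(row.end_date))
        )
    has_enroll = df["enrollee_id"].isin(spans_by_enrollee)
    n0 = len(df)
    df = df.loc[has_enroll]
    report.add("missing_enrollment", n0, len(df))
    covered = [
        _covered_365(spans_by_enrollee[e], d)
        for e, d in zip(df["enrollee_id"], df["date"])
    ]
    n0 = len(df)
    df = df.loc[covered]
    report.add("continuous_coverage_12mo", n0, len(df))

    # per-enrollee date/code arrays once, for the windowed dx lookups
    c = claims[["enrollee_id", "service_date", "code", "code_system"]].copy()
    c["_date"] = pd.to_datetime(c["service_date"]).dt.date
    claims_by_enrollee = {
        e: (g["_date"].to_numpy(), g["code"].to_numpy())
        for e, g in c.groupby("enrollee_id")
    }

    for name, dxset in codes.exclusion_dx.items():
        hits = [
            bool(
                _codes_in_window(
                    claims_by_enrollee,
                    e,
                    d - dt.timedelta(days=LOOKBACK_DAYS),
                    d + dt.timedelta(days=1),  # through the encounter itself
                )
                & dxset
            )
            for e, d in zip(df["enrollee_id"], df["date"])
        ]
        n0 = len(df)
        df = df.loc[[not h for h in hits]]
        report.add(f"exclusion_{name}", n0, len(df))

    removal = codes.salpingectomy_codes | codes.oophorectomy_codes
    prior = [
        bool(
            _codes_in_window(
                claims_by_enrollee, e, d - dt.timedelta(days=LOOKBACK_DAYS), d
            )
            & removal
        )
        for e, d in zip(df["enrollee_id"], df["date"])
    ]
    n0 = len(df)
    df = df.loc[[not h for h in prior]]
    report.add("prior_salpingectomy_oophorectomy", n0, len(df))

    plausible = df["surgeon_specialty"].isin(PLAUSIBLE_SURGEON_SPECIALTIES)
    n0 = len(df)
    df = df.loc[plausible]
    report.add("surgeon_specialty", n0, len(df))

    return df.reset_index(drop=True), report


# ---------------------------------------------------------------------------
# Outcome
# ---------------------------------------------------------------------------


def classify_outcome(
    encounter_codes: frozenset[str], setting_class: str, codes: CodeDictionary
) -> bool:
    """Setting-specific OS flag; pure function of codes + setting.

    Postpartum (inpatient ICD-10-PCS coding): complete salpingectomy and
    no concurrent oophorectomy.  Interval (outpatient CPT coding): any
    salpingectomy and no concurrent oophorectomy.  Unilateral codes count.
    """
    if setting_class not in ("postpartum", "interval"):
        raise AssertionError(f"invalid setting_class {setting_class!r}")
    if encounter_codes & codes.oophorectomy_codes:
        return False
    if setting_class == "postpartum":
        return bool(encounter_codes & codes.complete_salpingectomy_codes)
    return bool(encounter_codes & codes.any_salpingectomy_codes)


# ---------------------------------------------------------------------------
# Index dates (baseline patient-sharing sample)
# ---------------------------------------------------------------------------


def assign_index_dates(
    attributes: pd.DataFrame,
    enrollment: pd.DataFrame,
    t1_candidates: pd.DataFrame,
    t1_span: tuple[dt.date, dt.date],
    seed: int,
) -> pd.DataFrame:
    """Index date per enrollee and patient-sharing-sample membership.

    Sterilized enrollees take their sterilization date; all others a
    seeded uniform random date inside the baseline era.  Membership
    requires age 18-64 at the index date and 12 months of continuous
    coverage before it.
    """
    rng = np.random.default_rng(seed)
    steril_date = (
        t1_candidates.sort_values("date").groupby("enrollee_id")["date"].first().to_dict()
    )
    spans_by_enrollee: dict[str, list] = {}
    for row in enrollment.itertuples(index=False):
        spans_by_enrollee.setdefault(row.enrollee_id, []).append(
            (dt.date.fromisoformat(row.start_date), dt.date.fromisoformat(row.end_date))
        )
    lo, hi = t1_span[0].toordinal(), t1_span[1].toordinal()
    rows = []
    for row in attributes.sort_values("enrollee_id").itertuples(index=False):
        e = row.enrollee_id
        if e in steril_date:
            idx = steril_date[e]
        else:
            idx = dt.date.fromordinal(int(rng.integers(lo, hi)))
        age = _age_at(row.birth_year, idx)
        spans = spans_by_enrollee.get(e, [])
        overlap = any(s < t1_span[1] and e_ > t1_span[0] for s, e_ in spans)
        in_sample = (
            overlap
            and 18 <= age <= 64
            and bool(spans)
            and _covered_365(spans, idx)
        )
        rows.append(
            {
                "enrollee_id": e,
                "index_date": idx.isoformat(),
                "sterilized_t1": e in steril_date,
                "in_sharing_sample": bool(in_sample),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Covariates
# ---------------------------------------------------------------------------

_BMI_ORDER = ["<25", "25-29", "30-39", ">=40"]
_AGE_EDGES = [(18, 29, "18-29"), (30, 34, "30-34"), (35, 39, "35-39"), (40, 49, "40-49")]


def derive_covariates(
    eligible: pd.DataFrame,
    claims: pd.DataFrame,
    attributes: pd.DataFrame,
    codes: CodeDictionary,
) -> pd.DataFrame:
    """Analysis covariates per eligible encounter.

    BMI / smoking / Elixhauser come from diagnosis codes in the 12 months
    before and through the encounter; absence maps to "<25" / nonsmoker /
    zero comorbidities.  Region, SDI class and metro flag come from the
    enrollee attribute table; mode of delivery from the encounter's own
    procedure codes (postpartum only).
    """
    attrs = attributes.set_index("enrollee_id")
    c = claims[["enrollee_id", "service_date", "code"]].copy()
    c["_date"] = pd.to_datetime(c["service_date"]).dt.date
    claims_by_enrollee = {
        e: (g["_date"].to_numpy(), g["code"].to_numpy())
        for e, g in c.groupby("enrollee_id")
    }
    rows = []
    for row in eligible.itertuples(index=False):
        e, d = row.enrollee_id, row.date
        window = _codes_in_window(
            claims_by_enrollee, e, d - dt.timedelta(days=LOOKBACK_DAYS), d + dt.timedelta(days=1)
        )
        bmi_hits = [codes.bmi_dx[k] for k in window & set(codes.bmi_dx)]
        bmi_class = max(bmi_hits, key=_BMI_ORDER.index) if bmi_hits else "<25"
        smoking = bool(window & codes.smoking_dx)
        groups = {codes.elixhauser_groups[k] for k in window & set(codes.elixhauser_groups)}
        elix = "0" if not groups else ("1" if len(groups) == 1 else ">=2")
        age = _age_at(attrs.loc[e, "birth_year"], d)
        band = next(
            (label for lo, hi, label in _AGE_EDGES if lo <= age <= hi), "40-49"
        )
        if row.setting_class == "postpartum":
            mode = (
                "cesarean" if row.codes & codes.cesarean_codes else "vaginal"
            )
        else:
            mode = "n/a"
        rows.append(
            {
                "encounter_id": row.encounter_id,
                "age_band": band,
                "bmi_class": bmi_class,
                "smoking": smoking,
                "elixhauser_class": elix,
                "region": attrs.loc[e, "region"],
                "sdi_class": attrs.loc[e, "sdi_class"],
                "metro": bool(attrs.loc[e, "metro"]),
                "mode_of_delivery": mode,
                "year": d.year,
            }
        )
    return eligible.merge(pd.DataFrame(rows), on="encounter_id")


# ---------------------------------------------------------------------------
# One-call era cohort
# ---------------------------------------------------------------------------


def build_cohort(
    claims: pd.DataFrame,
    enrollment: pd.DataFrame,
    attributes: pd.DataFrame,
    codes: CodeDictionary,
    era: str,
    era_span: tuple[dt.date, dt.date],
) -> tuple[pd.DataFrame, AttritionReport, pd.DataFrame]:
    """Candidates -> eligibility -> outcome -> covariates for one era."""
    candidates, rejects = identify_sterilization_encounters(claims, codes, era, era_span)
    eligible, report = apply_eligibility(candidates, enrollment, claims, attributes, codes)
    eligible = eligible.copy()
    eligible["os_flag"] = [
        classify_outcome(cs, sc, codes)
        for cs, sc in zip(eligible["codes"], eligible["setting_class"])
    ]
    full = derive_covariates(eligible, claims, attributes, codes)
    return full, report, rejects
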