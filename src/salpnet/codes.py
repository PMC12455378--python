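"""Minimal declared code dictionary for sterilization-claims logic.

Claims analyses of tubal sterilization hinge on named sets of procedure and
diagnosis codes: which codes mean tubal ligation, which mean salpingectomy
(complete vs any), which flag the sterilization encounter itself, and which
trigger exclusions.  Real studies ship these as long appendix tables; this
package declares a deliberately small, plausible default inventory that the
synthetic generator emits and the cohort builder consumes, and lets users
override any set from a YAML file when pointing the pipeline at their own
data.

Conventions: postpartum (inpatient) sterilizations are coded in ICD-10-PCS,
where complete salpingectomy is distinguishable; interval (outpatient)
sterilizations are coded in CPT/HCPCS, where only "any salpingectomy" is
observable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import yaml

__all__ = ["CodeDictionary", "default_codes", "load_codes"]


@dataclass
class CodeDictionary:
    """Named code sets driving encounter identification and outcome logic."""

    tubal_ligation_codes: frozenset[str] = frozenset()
    complete_salpingectomy_codes: frozenset[str] = frozenset()  # ICD-10-PCS
    any_salpingectomy_codes: frozenset[str] = frozenset()  # CPT/HCPCS
    oophorectomy_codes: frozenset[str] = frozenset()
    sterilization_encounter_dx: frozenset[str] = frozenset()
    abortion_dx: frozenset[str] = frozenset()
    ectopic_dx: frozenset[str] = frozenset()
    exclusion_surgical_history_dx: frozenset[str] = frozenset()
    exclusion_tube_ovary_disorder_dx: frozenset[str] = frozenset()
    exclusion_cancer_risk_dx: frozenset[str] = frozenset()
    cesarean_codes: frozenset[str] = frozenset()
    vaginal_delivery_codes: frozenset[str] = frozenset()
    bmi_dx: dict[str, str] = field(default_factory=dict)  # code -> bmi class
    smoking_dx: frozenset[str] = frozenset()
    elixhauser_groups: dict[str, str] = field(default_factory=dict)  # code -> group

    def __post_init__(self) -> None:
        overlap = self.salpingectomy_codes & self.oophorectomy_codes
        if overlap:
            raise ValueError(
                f"salpingectomy and oophorectomy sets must be disjoint: {overlap}"
            )

    @property
    def salpingectomy_codes(self) -> frozenset[str]:
        return self.complete_salpingectomy_codes | self.any_salpingectomy_codes

    @property
    def sterilization_procedure_codes(self) -> frozenset[str]:
        return self.tubal_ligation_codes | self.salpingectomy_codes

    @property
    def delivery_codes(self) -> frozenset[str]:
        return self.cesarean_codes | self.vaginal_delivery_codes

    @property
    def exclusion_dx(self) -> dict[str, frozenset[str]]:
        return {
            "surgical_history": self.exclusion_surgical_history_dx,
            "tube_ovary_disorder": self.exclusion_tube_ovary_disorder_dx,
            "cancer_risk": self.exclusion_cancer_risk_dx,
        }


def default_codes() -> CodeDictionary:
    """The shipped minimal code inventory (ICD-10-PCS / CPT / ICD-10-CM)."""
    return CodeDictionary(
        # occlusion / ligation of fallopian tubes (PCS) and CPT equivalents
        tubal_ligation_codes=frozenset(
            {"0UL70ZZ", "0UL74ZZ", "0UL78ZZ", "58600", "58605", "58670", "58671"}
        ),
        # PCS resection of fallopian tube(s): bilateral and unilateral
        complete_salpingectomy_codes=frozenset(
            {"0UT70ZZ", "0UT74ZZ", "0UT78ZZ", "0UT50ZZ", "0UT54ZZ", "0UT60ZZ", "0UT64ZZ"}
        ),
        # CPT salpingectomy, open or laparoscopic (complete or partial)
        any_salpingectomy_codes=frozenset({"58700", "58661"}),
        # ovary resection (PCS) and salpingo-oophorectomy / oophorectomy (CPT)
        oophorectomy_codes=frozenset(
            {"0UT00ZZ", "0UT04ZZ", "0UT10ZZ", "0UT14ZZ", "0UT20ZZ", "0UT24ZZ", "58720", "58940"}
        ),
        sterilization_encounter_dx=frozenset({"Z30.2"}),
        abortion_dx=frozenset({"O03.9", "Z33.2"}),
        ectopic_dx=frozenset({"O00.10", "O00.20", "O00.90"}),
        # (1) hysterectomy / prior ligation / acquired absence of organs
        exclusion_surgical_history_dx=frozenset({"Z90.710", "Z90.721", "Z90.722", "Z98.51"}),
        # (2) ovarian and/or fallopian tube disorders
        exclusion_tube_ovary_disorder_dx=frozenset({"N83.201", "N83.291", "N70.91", "N83.9"}),
        # (3) cancer or elevated cancer risk
        exclusion_cancer_risk_dx=frozenset({"C56.9", "C57.00", "Z15.01", "Z15.02", "Z80.41"}),
        cesarean_codes=frozenset({"10D00Z0", "10D00Z1", "59510", "59514"}),
        vaginal_delivery_codes=frozenset({"10E0XZZ", "59400", "59409"}),
        bmi_dx={
            "Z68.25": "25-29",
            "Z68.27": "25-29",
            "Z68.30": "30-39",
            "Z68.35": "30-39",
            "Z68.41": ">=40",
            "Z68.43": ">=40",
        },
        smoking_dx=frozenset({"F17.210", "Z72.0"}),
        elixhauser_groups={
            "I10": "hypertension",
            "E11.9": "diabetes",
            "J45.909": "pulmonary",
            "D64.9": "anemia",
            "F32.9": "depression",
            "E03.9": "hypothyroid",
        },
    )


_SET_FIELDS = {
    f.name
    for f in fields(CodeDictionary)
    if f.name not in ("bmi_dx", "elixhauser_groups")
}


def load_codes(path) -> CodeDictionary:
    """Load a user code dictionary from YAML, falling back to defaults.

    Any named set present in the file replaces the default set wholesale;
    absent sets keep their defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    base = default_codes()
    kwargs = {}
    for f in fields(CodeDictionary):
        if f.name in raw:
            val = raw[f.name]
            kwargs[f.name] = frozenset(val) if f.name in _SET_FIELDS else dict(val)
        else:
            kwargs[f.name] = getattr(base, f.name)
    return CodeDictionary(**kwargs)
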