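"""Seeded synthetic claims world with planted peer-influence structure.

The generator emulates the *structure* of a commercial-claims sterilization
study, not the marginals of any real extract: physicians of three
specialties sit in planted communities nested in hospital referral regions
(HRRs); patients draw their physicians mostly from their home community (a
stochastic block model on patient-physician visits); tubal-sterilization
encounters occur in two settings (postpartum inpatient, interval
outpatient) across a baseline era T1 and a follow-up era T2; and follow-up
opportunistic-salpingectomy (OS) outcomes for baseline-nonuser surgeons are
drawn from a logistic model with a planted peer-exposure quartile effect
and surgeon- and network-level random intercepts.

Everything is driven by one global seed with named substreams, so adding a
later generation stage never perturbs earlier draws, and identical configs
give bit-identical outputs.

The ground-truth record (community labels, realized random intercepts,
planted coefficients, per-encounter linear predictors) exists so that
downstream parameter-recovery tests can compare estimates against truth.
"""

from __future__ import annotations

import datetime as dt
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .codes import CodeDictionary, default_codes
from .config import SyntheticConfig

__all__ = [
    "GroundTruth",
    "SyntheticData",
    "generate_roster",
    "simulate_sharing_claims",
    "simulate_sterilizations",
    "generate_world",
    "simulate_nested_dataset",
    "write_synthetic",
]

SPECIALTIES = ("obgyn", "urology", "primary_care")
_ROUTINE_VISIT_CPT = "99213"


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, order-independent RNG substream derived from the global seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=(seed, zlib.crc32(name.encode())))
    )


@dataclass
class GroundTruth:
    """What the generator planted; the key for recovery tests."""

    community_of_physician: dict[str, str]
    u_surgeon: dict[str, float]
    v_network: dict[str, float]
    planted_betas: dict
    surgeon_t1_rate: dict[str, float]
    surgeon_quartile: dict[str, str]
    encounters: pd.DataFrame = field(default_factory=pd.DataFrame)
    # encounters columns: enrollee_id, surgeon_id, date, era, setting_class,
    #   os_flag, linear_predictor (NaN outside the planted model's scope)


@dataclass
class SyntheticData:
    roster: pd.DataFrame
    claims: pd.DataFrame
    enrollment: pd.DataFrame
    attributes: pd.DataFrame
    ground_truth: GroundTruth
    config: SyntheticConfig


# ---------------------------------------------------------------------------
# Roster
# ---------------------------------------------------------------------------


def generate_roster(config: SyntheticConfig) -> pd.DataFrame:
    """Physician roster with HRR, planted community, and specialty."""
    config.validate()
    rng = substream(config.seed, "roster")
    rows = []
    pid = 0
    mix = np.array([config.specialty_mix.get(s, 0.0) for s in SPECIALTIES])
    for h in range(config.n_hrrs):
        hrr = f"HRR{h:02d}"
        for c in range(config.communities_per_hrr):
            comm = f"{hrr}-C{c:02d}"
            specs = rng.choice(len(SPECIALTIES), size=config.physicians_per_community, p=mix)
            for k in range(config.physicians_per_community):
                rows.append(
                    {
                        "physician_id": f"P{pid:05d}",
                        "hrr_id": hrr,
                        "community_id": comm,
                        "specialty": SPECIALTIES[specs[k]],
                    }
                )
                pid += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Patient-sharing visit claims (T1)
# ---------------------------------------------------------------------------


def _random_dates(rng, span: tuple[dt.date, dt.date], size: int) -> np.ndarray:
    lo = span[0].toordinal()
    hi = span[1].toordinal()  # half-open
    return rng.integers(lo, hi, size=size)


def simulate_sharing_claims(
    config: SyntheticConfig, roster: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Routine-visit claims for the baseline patient-sharing sample.

    Returns ``(claims, enrollment, attributes)`` for ``n_patients`` women.
    Each patient has a home community; each visit's physician comes from
    the home community with probability ``p_within``, from another
    community of the same HRR with ``p_between``, and uniformly from the
    whole roster otherwise.
    """
    if config.p_within + config.p_between > 1.0 + 1e-12:
        raise ValueError("p_within + p_between must not exceed 1")
    rng = substream(config.seed, "sharing")
    communities = roster["community_id"].unique().tolist()
    by_comm = {c: g["physician_id"].to_numpy() for c, g in roster.groupby("community_id")}
    hrr_of_comm = (
        roster.drop_duplicates("community_id").set_index("community_id")["hrr_id"].to_dict()
    )
    comms_by_hrr: dict[str, list[str]] = {}
    for c in communities:
        comms_by_hrr.setdefault(hrr_of_comm[c], []).append(c)
    all_phys = roster["physician_id"].to_numpy()
    spec_of = roster.set_index("physician_id")["specialty"].to_dict()
    hrr_of = roster.set_index("physician_id")["hrr_id"].to_dict()

    n = config.n_patients
    home = np.array([communities[i % len(communities)] for i in range(n)])
    n_visits = rng.poisson(config.visits_per_patient, size=n)

    claim_rows = []
    for i in range(n):
        eid = f"E{i:06d}"
        comm = home[i]
        hrr = hrr_of_comm[comm]
        others = [c for c in comms_by_hrr[hrr] if c != comm]
        dates = _random_dates(rng, config.t1_span, n_visits[i])
        kinds = rng.random(n_visits[i])
        for v in range(n_visits[i]):
            if kinds[v] < config.p_within or not others:
                pool = by_comm[comm]
            elif kinds[v] < config.p_within + config.p_between:
                pool = by_comm[others[rng.integers(len(others))]]
            else:
                pool = all_phys
            doc = pool[rng.integers(len(pool))]
            claim_rows.append(
                (
                    eid,
                    doc,
                    spec_of[doc],
                    dt.date.fromordinal(dates[v]).isoformat(),
                    "outpatient",
                    "CPT",
                    _ROUTINE_VISIT_CPT,
                    hrr_of[doc],
                )
            )
    claims = pd.DataFrame(
        claim_rows,
        columns=[
            "enrollee_id",
            "physician_id",
            "specialty",
            "service_date",
            "setting",
            "code_system",
            "code",
            "hrr_id",
        ],
    )

    # enrollment: continuous across both eras, with rare planted gaps
    start = (config.t1_span[0] - dt.timedelta(days=365)).isoformat()
    end = config.t2_span[1].isoformat()
    enroll_rows = []
    gap_draw = rng.random(n)
    gap_pos = _random_dates(rng, config.t1_span, n)
    for i in range(n):
        eid = f"E{i:06d}"
        if gap_draw[i] < config.enrollment_dropout_rate:
            g0 = dt.date.fromordinal(gap_pos[i])
            enroll_rows.append((eid, start, g0.isoformat()))
            enroll_rows.append((eid, (g0 + dt.timedelta(days=45)).isoformat(), end))
        else:
            enroll_rows.append((eid, start, end))
    enrollment = pd.DataFrame(enroll_rows, columns=["enrollee_id", "start_date", "end_date"])

    # ages 18-62 at the start of T1 (so 18-64 over the era); regional attrs
    ages = rng.integers(18, 63, size=n)
    attrs = _draw_regional_attributes(rng, config, n)
    attrs.insert(0, "enrollee_id", [f"E{i:06d}" for i in range(n)])
    attrs.insert(1, "birth_year", config.t1_span[0].year - ages)
    attrs["home_community"] = home
    return claims, enrollment, attrs


def _draw_regional_attributes(rng, config: SyntheticConfig, n: int) -> pd.DataFrame:
    out = {}
    for cov in ("region", "sdi_class", "metro"):
        dist = config.covariate_distributions[cov]
        levels = list(dist)
        out[cov] = [levels[j] for j in rng.choice(len(levels), size=n, p=list(dist.values()))]
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Sterilization encounters, both eras
# ---------------------------------------------------------------------------


def _draw_level(rng, dist: dict):
    levels = list(dist)
    return levels[rng.choice(len(levels), p=list(dist.values()))]


def _covariate_effect(config: SyntheticConfig, cov: str, level) -> float:
    return float(config.beta_covariates.get(cov, {}).get(level, 0.0))


_AGE_BAND_RANGE = {"18-29": (18, 29), "30-34": (30, 34), "35-39": (35, 39), "40-49": (40, 49)}
_BMI_CODE = {"25-29": "Z68.27", "30-39": "Z68.35", ">=40": "Z68.41"}


def simulate_sterilizations(
    config: SyntheticConfig,
    roster: pd.DataFrame,
    sharing: tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame],
    codes: CodeDictionary | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Sterilization encounters for T1 and T2, plus the ground truth.

    T1: community OB/GYN "sterilizers" perform eligible sterilizations on
    sharing-sample patients; a configured fraction are strict nonusers
    (T1 OS rate exactly 0), the rest use OS at Beta-distributed rates.
    T2: every sterilizer performs follow-up sterilizations on newly
    enrolled patients; nonuser surgeons' outcomes follow the planted
    logistic model whose quartile term comes from their true-community
    peers' realized T1 OS rates.

    Returns ``(claims, enrollment, attributes)`` additions and the
    populated :class:`GroundTruth`.
    """
    codes = codes or default_codes()
    rng = substream(config.seed, "steril")
    claims_t1, _, attrs = sharing
    comm_of = roster.set_index("physician_id")["community_id"].to_dict()
    hrr_of = roster.set_index("physician_id")["hrr_id"].to_dict()

    # --- choose sterilizing surgeons (community OB/GYNs) -------------------
    obgyn = roster[roster["specialty"] == "obgyn"]
    surgeons: list[str] = []
    for comm, g in obgyn.groupby("community_id"):
        ids = g["physician_id"].tolist()
        take = [pid for pid in ids if rng.random() < 0.7]
        if len(take) < 2 and len(ids) >= 2:
            take = ids[:2]
        surgeons.extend(take)
    surgeons.sort()
    if not surgeons:
        raise RuntimeError("no sterilizing surgeons generated; enlarge the roster")

    is_nonuser = {s: bool(rng.random() < config.nonuser_fraction) for s in surgeons}
    if not any(is_nonuser.values()):
        raise RuntimeError(
            "no baseline-nonuser surgeons generated; the analysis sample would be empty"
        )
    a, b = config.user_rate_beta
    true_rate = {
        s: 0.0 if is_nonuser[s] else float(rng.beta(a, b)) for s in surgeons
    }

    # --- T1 encounters ------------------------------------------------------
    attrs = attrs.set_index("enrollee_id", drop=False)
    candidates_by_comm: dict[str, list[str]] = {}
    age_t1 = config.t1_span[0].year - attrs["birth_year"]
    ok = (age_t1 >= 18) & (age_t1 <= 45)
    for eid, comm in attrs.loc[ok, "home_community"].items():
        candidates_by_comm.setdefault(comm, []).append(eid)

    encounter_rows = []
    claim_rows: list[tuple] = []
    extra_enroll: list[tuple] = []
    extra_attr_rows: list[dict] = []
    used_patients: set[str] = set()
    next_eid = len(attrs)

    excl_kinds = ["surgical_history", "tube_ovary_disorder", "cancer_risk", "prior_salpingectomy"]
    excl_dx_pool = {
        "surgical_history": sorted(codes.exclusion_surgical_history_dx),
        "tube_ovary_disorder": sorted(codes.exclusion_tube_ovary_disorder_dx),
        "cancer_risk": sorted(codes.exclusion_cancer_risk_dx),
        "prior_salpingectomy": None,  # handled as a prior procedure claim
    }

    def emit_encounter(eid, surgeon, date, setting_class, os_flag, covs, era):
        """Append the claim lines realizing one sterilization encounter."""
        iso = date.isoformat()
        hrr = hrr_of[surgeon]
        inpatient = setting_class == "postpartum"
        setting = "inpatient" if inpatient else "outpatient"

        def line(code_system, code):
            claim_rows.append(
                (eid, surgeon, "obgyn", iso, setting, code_system, code, hrr)
            )

        # sterilization procedure
        if inpatient:
            if os_flag:
                line("ICD10PCS", "0UT74ZZ")  # bilateral complete salpingectomy
            else:
                line("ICD10PCS", "0UL74ZZ")  # bilateral tubal occlusion
            line(
                "ICD10PCS",
                "10D00Z1" if covs["mode_of_delivery"] == "cesarean" else "10E0XZZ",
            )
        else:
            if os_flag:
                line("CPT", "58661")  # laparoscopic salpingectomy
            else:
                line("CPT", "58670")  # laparoscopic tubal occlusion
        line("ICD10DX", "Z30.2")  # encounter for sterilization
        # covariate diagnosis codes observable in claims
        if covs["bmi_class"] in _BMI_CODE:
            line("ICD10DX", _BMI_CODE[covs["bmi_class"]])
        if covs["smoking"]:
            line("ICD10DX", "F17.210")
        elix = {"0": 0, "1": 1, ">=2": 2}[covs["elixhauser_class"]]
        for code in sorted(codes.elixhauser_groups)[:elix]:
            line("ICD10DX", code)
        # planted exclusions: a diagnosis inside the look-back window
        for kind in excl_kinds:
            if covs["exclusions"].get(kind):
                prior = date - dt.timedelta(days=int(covs["exclusions"][kind]))
                if kind == "prior_salpingectomy":
                    claim_rows.append(
                        (eid, surgeon, "obgyn", prior.isoformat(), "outpatient", "CPT", "58700", hrr)
                    )
                else:
                    claim_rows.append(
                        (
                            eid,
                            surgeon,
                            "obgyn",
                            prior.isoformat(),
                            "outpatient",
                            "ICD10DX",
                            excl_dx_pool[kind][0],
                            hrr,
                        )
                    )
        encounter_rows.append(
            {
                "enrollee_id": eid,
                "surgeon_id": surgeon,
                "date": iso,
                "era": era,
                "setting_class": setting_class,
                "os_flag": bool(os_flag),
                "excluded_by_design": any(covs["exclusions"].values()),
                "linear_predictor": covs.get("linear_predictor", np.nan),
                "age_band": covs.get("age_band"),
                "bmi_class": covs["bmi_class"],
                "smoking": covs["smoking"],
                "elixhauser_class": covs["elixhauser_class"],
                "mode_of_delivery": covs["mode_of_delivery"],
                "region": covs.get("region"),
                "sdi_class": covs.get("sdi_class"),
                "metro": covs.get("metro"),
                "year": date.year,
            }
        )

    def draw_exclusions():
        out = {}
        for kind in excl_kinds:
            if rng.random() < config.exclusion_rates.get(kind, 0.0):
                out[kind] = int(rng.integers(30, 300))  # days before encounter
        return out

    def draw_covs(setting_class):
        covs = {
            "bmi_class": _draw_level(rng, config.covariate_distributions["bmi_class"]),
            "smoking": _draw_level(rng, config.covariate_distributions["smoking"]),
            "elixhauser_class": _draw_level(
                rng, config.covariate_distributions["elixhauser_class"]
            ),
            "mode_of_delivery": (
                _draw_level(rng, config.covariate_distributions["mode_of_delivery"])
                if setting_class == "postpartum"
                else "n/a"
            ),
            "exclusions": draw_exclusions(),
        }
        return covs

    for surgeon in surgeons:
        comm = comm_of[surgeon]
        pool = [e for e in candidates_by_comm.get(comm, []) if e not in used_patients]
        n_t1 = max(1, int(rng.poisson(config.t1_sterils_per_surgeon)))
        n_t1 = min(n_t1, len(pool))
        chosen = [pool[j] for j in rng.choice(len(pool), size=n_t1, replace=False)] if n_t1 else []
        dates = _random_dates(rng, config.t1_span, n_t1)
        for eid, d in zip(chosen, dates):
            used_patients.add(eid)
            setting_class = (
                "postpartum" if rng.random() < config.postpartum_fraction else "interval"
            )
            covs = draw_covs(setting_class)
            os_flag = rng.random() < true_rate[surgeon]
            emit_encounter(eid, surgeon, dt.date.fromordinal(d), setting_class, os_flag, covs, "T1")

    # realized T1 OS rates among design-eligible encounters
    enc = pd.DataFrame(encounter_rows)
    t1 = enc[(enc["era"] == "T1") & ~enc["excluded_by_design"]]
    t1_counts = t1.groupby("surgeon_id")["os_flag"].agg(["size", "sum"])
    realized_rate = (t1_counts["sum"] / t1_counts["size"]).to_dict()
    realized_n = t1_counts["size"].to_dict()

    # planted peer exposure from true communities
    mean_peer = {}
    for surgeon in surgeons:
        comm = comm_of[surgeon]
        peers = [
            s
            for s in surgeons
            if s != surgeon
            and comm_of[s] == comm
            and realized_n.get(s, 0) >= 5
        ]
        if peers:
            mean_peer[surgeon] = float(np.mean([realized_rate[s] for s in peers]))
    nonusers_with_exposure = [
        s for s in surgeons if is_nonuser[s] and s in mean_peer and s in realized_n
    ]
    quartile_of: dict[str, str] = {}
    if len(nonusers_with_exposure) >= 4:
        vals = np.array([mean_peer[s] for s in nonusers_with_exposure])
        cuts = np.percentile(vals, [25, 50, 75], method="linear")
        for s, v in zip(nonusers_with_exposure, vals):
            quartile_of[s] = "Q" + str(1 + int(np.sum(v > cuts)))
    else:
        for s in nonusers_with_exposure:
            quartile_of[s] = "Q1"

    # random intercepts
    rng_u = substream(config.seed, "u_surgeon")
    rng_v = substream(config.seed, "v_network")
    u = {s: float(rng_u.normal(0.0, np.sqrt(config.sigma2_surgeon))) for s in surgeons}
    communities = sorted(roster["community_id"].unique())
    v = {c: float(rng_v.normal(0.0, np.sqrt(config.sigma2_network))) for c in communities}
    bq = {"Q1": 0.0, "Q2": config.beta_quartile[0], "Q3": config.beta_quartile[1], "Q4": config.beta_quartile[2]}

    # --- T2 encounters ------------------------------------------------------
    year_dist = {2020: 1 / 3, 2021: 1 / 3, 2022: 1 / 3}
    for surgeon in surgeons:
        n_t2 = int(rng.poisson(config.t2_sterils_per_surgeon))
        for _ in range(n_t2):
            eid = f"E{next_eid:06d}"
            next_eid += 1
            setting_class = (
                "postpartum" if rng.random() < config.postpartum_fraction else "interval"
            )
            covs = draw_covs(setting_class)
            covs["age_band"] = _draw_level(rng, config.covariate_distributions["age_band"])
            year = _draw_level(rng, year_dist)
            day = dt.date(year, 1, 1).toordinal() + int(rng.integers(0, 365))
            date = dt.date.fromordinal(day)
            region_attrs = _draw_regional_attributes(rng, config, 1).iloc[0]
            covs["region"] = region_attrs["region"]
            covs["sdi_class"] = region_attrs["sdi_class"]
            covs["metro"] = bool(region_attrs["metro"])
            if is_nonuser[surgeon] and surgeon in quartile_of:
                lp = (
                    config.beta0
                    + bq[quartile_of[surgeon]]
                    + u[surgeon]
                    + v[comm_of[surgeon]]
                    + _covariate_effect(config, "age_band", covs["age_band"])
                    + _covariate_effect(config, "bmi_class", covs["bmi_class"])
                    + _covariate_effect(config, "smoking", covs["smoking"])
                    + _covariate_effect(config, "elixhauser_class", covs["elixhauser_class"])
                    + _covariate_effect(config, "mode_of_delivery", covs["mode_of_delivery"])
                    + _covariate_effect(config, "region", region_attrs["region"])
                    + _covariate_effect(config, "sdi_class", region_attrs["sdi_class"])
                    + _covariate_effect(config, "metro", region_attrs["metro"])
                    + _covariate_effect(config, "year", year)
                )
                p_os = 1.0 / (1.0 + np.exp(-lp))
                covs["linear_predictor"] = lp
                os_flag = rng.random() < p_os
            else:
                os_flag = rng.random() < true_rate[surgeon]
            # age consistent with the drawn band at the encounter date
            lo, hi = _AGE_BAND_RANGE[covs["age_band"]]
            age = int(rng.integers(lo, hi + 1))
            birth_year = date.year - age
            emit_encounter(eid, surgeon, date, setting_class, os_flag, covs, "T2")
            start = (date - dt.timedelta(days=400)).isoformat()
            extra_enroll.append((eid, start, config.t2_span[1].isoformat()))
            extra_attr_rows.append(
                {
                    "enrollee_id": eid,
                    "birth_year": birth_year,
                    "region": region_attrs["region"],
                    "sdi_class": region_attrs["sdi_class"],
                    "metro": region_attrs["metro"],
                    "home_community": comm_of[surgeon],
                }
            )

    claims = pd.DataFrame(
        claim_rows,
        columns=[
            "enrollee_id",
            "physician_id",
            "specialty",
            "service_date",
            "setting",
            "code_system",
            "code",
            "hrr_id",
        ],
    )
    enrollment = pd.DataFrame(
        extra_enroll, columns=["enrollee_id", "start_date", "end_date"]
    )
    attributes = pd.DataFrame(extra_attr_rows)
    truth = GroundTruth(
        community_of_physician=comm_of,
        u_surgeon=u,
        v_network=v,
        planted_betas={
            "beta0": config.beta0,
            "beta_quartile": list(config.beta_quartile),
            "beta_covariates": config.beta_covariates,
            "sigma2_surgeon": config.sigma2_surgeon,
            "sigma2_network": config.sigma2_network,
        },
        surgeon_t1_rate={s: realized_rate.get(s, np.nan) for s in surgeons},
        surgeon_quartile=quartile_of,
        encounters=pd.DataFrame(encounter_rows),
    )
    return claims, enrollment, attributes, truth


def generate_world(config: SyntheticConfig, codes: CodeDictionary | None = None) -> SyntheticData:
    """Run all generator stages and return the combined tables."""
    roster = generate_roster(config)
    share_claims, share_enroll, share_attrs = simulate_sharing_claims(config, roster)
    st_claims, st_enroll, st_attrs, truth = simulate_sterilizations(
        config, roster, (share_claims, share_enroll, share_attrs), codes
    )
    claims = pd.concat([share_claims, st_claims], ignore_index=True)
    enrollment = pd.concat([share_enroll, st_enroll], ignore_index=True)
    attributes = pd.concat(
        [share_attrs.reset_index(drop=True), st_attrs], ignore_index=True
    )
    return SyntheticData(
        roster=roster,
        claims=claims.sort_values(
            ["enrollee_id", "service_date", "physician_id", "code"]
        ).reset_index(drop=True),
        enrollment=enrollment,
        attributes=attributes,
        ground_truth=truth,
        config=config,
    )


# ---------------------------------------------------------------------------
# Direct simulation of the analysis table (no claims plumbing)
# ---------------------------------------------------------------------------


def simulate_nested_dataset(
    n_networks: int = 52,
    surgeons_per_network: int = 12,
    encounters_per_surgeon: int = 8,
    beta0: float = -1.5,
    beta_quartile: tuple[float, float, float] = (0.26236426, 0.53062825, 0.77472717),
    sigma2_surgeon: float = 0.5,
    sigma2_network: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Draw an analysis table directly from the nested logistic model.

    Surgeon-level exposure quartiles are balanced by construction.  Used
    for estimator calibration studies, where the claims plumbing would
    only add noise around the quantity of interest.
    """
    rng = np.random.default_rng(seed)
    S = n_networks * surgeons_per_network
    n = S * encounters_per_surgeon
    surg = np.repeat(np.arange(S), encounters_per_surgeon)
    net = np.repeat(np.arange(n_networks), surgeons_per_network)[surg]
    q = rng.permuted(np.tile(np.arange(4), S // 4 + 1)[:S])
    betas = np.array([0.0, *beta_quartile])
    u = rng.normal(0.0, np.sqrt(sigma2_surgeon), S)
    v = rng.normal(0.0, np.sqrt(sigma2_network), n_networks)
    eta = beta0 + betas[q[surg]] + u[surg] + v[net]
    y = rng.random(n) < 1.0 / (1.0 + np.exp(-eta))
    df = pd.DataFrame(
        {
            "os_flag": y,
            "quartile": np.array(["Q1", "Q2", "Q3", "Q4"])[q[surg]],
            "surgeon_id": surg,
            "network_id": net,
        }
    )
    truth = {
        "beta0": beta0,
        "beta_quartile": tuple(beta_quartile),
        "sigma2_surgeon": sigma2_surgeon,
        "sigma2_network": sigma2_network,
        "u": u,
        "v": v,
        "linear_predictor": eta,
    }
    return df, truth


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------


def write_synthetic(data: SyntheticData, outdir: str | Path) -> dict[str, Path]:
    """Write all generated tables as CSV; returns name -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in [
        ("roster", data.roster),
        ("claims", data.claims),
        ("enrollment", data.enrollment),
        ("attributes", data.attributes),
        ("ground_truth_encounters", data.ground_truth.encounters),
    ]:
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    gt = data.ground_truth
    scalars = pd.DataFrame(
        [
            {"physician_id": s, "community_id": gt.community_of_physician.get(s), "u_surgeon": gt.u_surgeon.get(s), "t1_os_rate": gt.surgeon_t1_rate.get(s), "quartile": gt.surgeon_quartile.get(s)}
            for s in sorted(gt.u_surgeon)
        ]
    )
    p = outdir / "ground_truth_surgeons.csv"
    scalars.to_csv(p, index=False)
    paths["ground_truth_surgeons"] = p
    return paths
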