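"""Configuration objects for the synthetic generator and the pipeline.

Every knob of the synthetic-claims generator is a field of
:class:`SyntheticConfig`, loadable from YAML so that a config file fully
determines a run.  Defaults encode the study conditions the generator is
meant to emulate: two eras (2017-2019 baseline, 2020-2022 follow-up),
physicians of three specialties nested in hospital referral regions (HRRs)
with planted community structure, covariate category frequencies matching a
large US commercial-claims sterilization cohort (e.g. 92.3% cesarean among
postpartum sterilizations), and a logistic outcome model with surgeon- and
network-level random intercepts.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["SyntheticConfig", "PipelineConfig", "load_config"]


def _d(s: str) -> dt.date:
    return dt.date.fromisoformat(s)


# Covariate category frequencies for simulated follow-up-era encounters.
# Keyed by covariate name; values are {level: probability}.
DEFAULT_COVARIATE_DISTRIBUTIONS: dict[str, dict] = {
    "age_band": {"18-29": 0.221, "30-34": 0.367, "35-39": 0.331, "40-49": 0.081},
    "mode_of_delivery": {"vaginal": 0.077, "cesarean": 0.923},
    "bmi_class": {"<25": 0.618, "25-29": 0.052, "30-39": 0.187, ">=40": 0.143},
    "smoking": {False: 0.873, True: 0.127},
    "elixhauser_class": {"0": 0.570, "1": 0.288, ">=2": 0.142},
    "metro": {False: 0.297, True: 0.703},
    "region": {"Midwest": 0.196, "Northeast": 0.093, "South": 0.679, "West": 0.032},
    "sdi_class": {"<25": 0.245, "25-50": 0.263, "50-75": 0.304, ">75": 0.169, "unknown": 0.019},
}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic claims world.

    The planted outcome model for follow-up-era (T2) encounters of
    baseline-nonuser surgeons is

        logit P(OS) = beta0 + beta_quartile[q-1] + covariate terms
                      + u_surgeon + v_network

    with ``u ~ N(0, sigma2_surgeon)`` and ``v ~ N(0, sigma2_network)``.
    """

    # world structure
    n_hrrs: int = 2
    communities_per_hrr: int = 4
    physicians_per_community: int = 30
    specialty_mix: dict[str, float] = field(
        default_factory=lambda: {"obgyn": 0.4, "urology": 0.1, "primary_care": 0.5}
    )
    n_patients: int = 1600
    p_within: float = 0.9
    p_between: float = 0.08
    visits_per_patient: float = 2.5
    t1_span: tuple[dt.date, dt.date] = (_d("2017-01-01"), _d("2020-01-01"))
    t2_span: tuple[dt.date, dt.date] = (_d("2020-01-01"), _d("2023-01-01"))

    # sterilization volume and baseline behaviour
    steril_rate: float = 0.08  # per eligible woman per era (sharing sample)
    postpartum_fraction: float = 0.55
    t1_sterils_per_surgeon: float = 9.0  # Poisson mean, truncated at >=1
    t2_sterils_per_surgeon: float = 8.0
    nonuser_fraction: float = 0.6  # strict baseline nonusers among surgeons
    user_rate_beta: tuple[float, float] = (1.2, 6.0)  # Beta params for user T1 OS rate

    # planted outcome model (follow-up era, nonuser surgeons)
    beta0: float = -2.2
    beta_quartile: tuple[float, float, float] = (0.26236426, 0.53062825, 0.77472717)
    beta_covariates: dict[str, dict] = field(
        default_factory=lambda: {
            "mode_of_delivery": {"cesarean": 0.8},
            "year": {2021: 0.25, 2022: 0.5},
            "region": {"South": -0.4},
            "sdi_class": {">75": -0.3},
        }
    )
    sigma2_surgeon: float = 0.5
    sigma2_network: float = 0.5

    # nuisance structure
    covariate_distributions: dict[str, dict] = field(
        default_factory=lambda: {
            k: dict(v) for k, v in DEFAULT_COVARIATE_DISTRIBUTIONS.items()
        }
    )
    exclusion_rates: dict[str, float] = field(
        default_factory=lambda: {
            "surgical_history": 0.02,
            "tube_ovary_disorder": 0.02,
            "cancer_risk": 0.02,
            "prior_salpingectomy": 0.01,
        }
    )
    enrollment_dropout_rate: float = 0.02
    seed: int = 20170101

    def __post_init__(self) -> None:
        if isinstance(self.t1_span[0], str):
            self.t1_span = (_d(self.t1_span[0]), _d(self.t1_span[1]))
        if isinstance(self.t2_span[0], str):
            self.t2_span = (_d(self.t2_span[0]), _d(self.t2_span[1]))
        self.beta_quartile = tuple(self.beta_quartile)
        self.user_rate_beta = tuple(self.user_rate_beta)
        self.validate()

    def validate(self) -> None:
        if min(self.n_hrrs, self.communities_per_hrr, self.physicians_per_community) < 1:
            raise ValueError("world dimensions must all be >= 1")
        mix_sum = sum(self.specialty_mix.values())
        if abs(mix_sum - 1.0) > 1e-9:
            raise ValueError(f"specialty_mix must sum to 1, got {mix_sum}")
        for name, p in [
            ("p_within", self.p_within),
            ("p_between", self.p_between),
            ("steril_rate", self.steril_rate),
            ("postpartum_fraction", self.postpartum_fraction),
            ("nonuser_fraction", self.nonuser_fraction),
            ("enrollment_dropout_rate", self.enrollment_dropout_rate),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.p_within + self.p_between > 1.0 + 1e-12:
            raise ValueError("p_within + p_between must not exceed 1")
        if self.sigma2_surgeon < 0 or self.sigma2_network < 0:
            raise ValueError("variances must be >= 0")
        if len(self.beta_quartile) != 3:
            raise ValueError("beta_quartile needs exactly 3 contrasts (Q2,Q3,Q4)")
        if not self.t1_span[1] <= self.t2_span[0]:
            raise ValueError("t1_span must precede t2_span without overlap")
        for cov, dist in self.covariate_distributions.items():
            tot = sum(dist.values())
            if abs(tot - 1.0) > 1e-6:
                raise ValueError(f"covariate_distributions[{cov}] sums to {tot}")

    @property
    def n_communities(self) -> int:
        return self.n_hrrs * self.communities_per_hrr

    @property
    def n_physicians(self) -> int:
        return self.n_communities * self.physicians_per_community

    def to_dict(self) -> dict:
        d = asdict(self)
        d["t1_span"] = [s.isoformat() for s in self.t1_span]
        d["t2_span"] = [s.isoformat() for s in self.t2_span]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        for span in ("t1_span", "t2_span"):
            if span in d:
                d[span] = tuple(d[span])
        # YAML maps boolean-keyed dicts fine, but guard str "true"/"false"
        for cov in ("smoking", "metro"):
            dist = d.get("covariate_distributions", {}).get(cov)
            if dist is not None:
                d["covariate_distributions"][cov] = {
                    (k in (True, "true", "True", 1)): v for k, v in dist.items()
                }
        return cls(**d)


@dataclass
class PipelineConfig:
    """End-to-end run parameters; defaults follow the published design."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    input_dir: str | None = None  # if set, read claims tables instead of simulating
    output_dir: str = "salpnet_out"

    cap: int = 8  # per-patient physician cap
    min_patients: int = 4  # node threshold
    min_shared: int = 2  # edge threshold
    min_peer_volume: int = 5  # eligible T1 sterilizations for peer candidacy
    alpha_screen: float = 0.2
    pool_quartiles: bool = True  # pool both setting samples for cutoffs
    weighted_modularity: bool = True
    resolution: float = 1.0
    louvain_seed: int = 1
    index_date_seed: int = 2
    bootstrap_reps: int = 200
    bootstrap_seed: int = 3
    fit_method: str = "agq"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["synthetic"] = self.synthetic.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "synthetic" in d:
            d["synthetic"] = SyntheticConfig.from_dict(d["synthetic"])
        return cls(**d)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(raw)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
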