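"""Seeded generator of SID-like linked inpatient discharge data.

Emulates the structure of state inpatient databases used for readmission
research: one row per admission, a within-state patient linkage key
(``patient_link_id``), hospitals with varying Black-patient shares, race and
income group labels, clinical covariates, planned revisits, in-hospital
deaths, against-medical-advice discharges, and records with broken linkage.

The 30-day unplanned-revisit mechanism is fully controlled: each admission
independently "fires" a revisit with probability
``logistic(base_logit + sum(effects) + group offsets)``, and a fired revisit
is materialized 1-30 days after discharge.  The true per-record event
probability is returned alongside the table so downstream labelling,
scoring and fairness code can be tested against exact ground truth.

Group differences in outcome risk arise from two configurable sources:
shifted covariate distributions for protected groups (the dominant, data-
driven source — protected groups are sicker on the covariates the risk
scores see) and a small residual additive log-odds offset.  Both race-based
sources can be attenuated in hospitals serving a higher share of Black
patients (``composition_attenuation``), which lets simulations reproduce the
empirical pattern of bias shrinking in more diverse hospitals.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConfigurationError",
    "CovariateBaseline",
    "GroupShift",
    "GeneratorConfig",
    "generate_hospitals",
    "generate_discharges",
    "write_discharges",
    "read_discharges",
]

RACE_GROUPS = ("white", "black", "other")
INCOME_GROUPS = ("low", "other")
PAYERS = ("medicare", "medicaid", "private", "other")
COHORTS = ("medicine", "surgery_gyn", "cardiorespiratory", "cardiovascular", "neurology")
DISPOSITIONS = ("home", "facility", "death", "ama")

#: scalar covariates entering the true readmission log-odds
SCALAR_COVARIATES = ("age_decade", "los_days", "charlson", "ed_visits_6mo", "admissions_prior_year")

_MAX_CHAIN_ROUNDS = 40


class ConfigurationError(ValueError):
    """Invalid generator configuration; message names the offending field."""


def _expit(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class CovariateBaseline:
    """Reference-group (White, other-income) covariate distribution parameters."""

    age_mean: float = 61.0
    age_sd: float = 19.5
    los_mean: float = 4.6          # negative-binomial mean, days
    los_dispersion: float = 1.3    # NB shape; smaller = more overdispersed
    charlson_mean: float = 0.5     # Poisson
    ed_mean: float = 0.7           # ED visits in prior 6 months, Poisson
    prior_adm_mean: float = 0.8    # admissions in prior year, Poisson
    oncology_prob: float = 0.08
    procedure_prob: float = 0.55
    condition_prob: float = 0.08   # per condition indicator
    emergent_prob: float = 0.72    # index admissions
    n_diagnoses_mean: float = 11.0
    female_frac: float = 0.58
    facility_prob: float = 0.18    # non-death, non-AMA discharges to facility


@dataclass
class GroupShift:
    """Additive shifts to covariate distribution parameters for one group."""

    age_mean: float = 0.0
    los_mean: float = 0.0
    charlson_mean: float = 0.0
    ed_mean: float = 0.0
    prior_adm_mean: float = 0.0
    condition_prob: float = 0.0


def default_covariate_effects() -> dict:
    # Log-odds per unit; sized so the standard point scores reach moderate
    # discrimination (AUC in the low/mid 0.6s) and overall unplanned 30-day
    # rates sit in the 11-17% band typical of all-payer discharge data.
    return {
        "age_decade": 0.05,
        "los_days": 0.08,
        "charlson": 0.4,
        "ed_visits_6mo": 0.3,
        "admissions_prior_year": 0.3,
    }


def default_condition_effects(n_condition_vars: int) -> np.ndarray:
    """Half the condition indicators carry effects tapering 0.6 -> 0, half are null."""
    eff = np.zeros(n_condition_vars)
    m = (n_condition_vars + 1) // 2
    eff[:m] = np.linspace(0.6, 0.0, m)
    return eff


def default_group_shifts() -> dict:
    # Loosely calibrated to published discharge-level descriptives: Black and
    # low-income inpatients are younger, stay longer, and carry more
    # comorbidity and prior utilization than the reference groups.  These
    # shifts, visible to the risk scores, are what produce the empirical
    # higher-FPR / lower-FNR pattern for the protected groups under a pooled
    # threshold.
    return {
        "black": GroupShift(age_mean=-7.0, los_mean=0.4, charlson_mean=0.08,
                            ed_mean=0.2, prior_adm_mean=0.2, condition_prob=0.03),
        "low_income": GroupShift(age_mean=-2.0, los_mean=0.3, charlson_mean=0.06,
                                 ed_mean=0.15, prior_adm_mean=0.15, condition_prob=0.01),
    }


@dataclass
class GeneratorConfig:
    n_patients: int = 20_000
    n_hospitals: int = 40
    mean_admissions_per_patient: float = 1.6
    study_days: int = 1460
    race_mix: tuple = (0.60, 0.25, 0.15)  # white, black, other
    income_low_frac: float = 0.32
    #: Beta(a, b) over per-hospital Black-patient target share, or a single
    #: float for a degenerate (all-equal) composition.
    hospital_composition: tuple | float = (2.0, 8.0)
    base_logit: float = -3.4
    covariate_effects: dict = field(default_factory=default_covariate_effects)
    condition_effects: np.ndarray | None = None  # defaults per n_condition_vars
    group_offsets: dict = field(default_factory=lambda: {"black": 0.05, "low_income": 0.05})
    group_shifts: dict = field(default_factory=default_group_shifts)
    baseline: CovariateBaseline = field(default_factory=CovariateBaseline)
    n_condition_vars: int = 20
    planned_revisit_prob: float = 0.05
    death_prob: float = 0.02
    ama_prob: float = 0.01
    missing_link_prob: float = 0.02
    under18_prob: float = 0.04
    cohort_mix: tuple = (0.45, 0.20, 0.12, 0.13, 0.10)  # order of COHORTS
    #: 0 = group structure independent of hospital; 1 = race-based offsets and
    #: covariate shifts scale by (1 - black_frac_target), vanishing in
    #: all-Black hospitals.
    composition_attenuation: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.condition_effects is None:
            self.condition_effects = default_condition_effects(self.n_condition_vars)
        self.condition_effects = np.asarray(self.condition_effects, dtype=float)

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        for name in ("n_patients", "n_hospitals", "study_days", "n_condition_vars"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise ConfigurationError(f"{name} must be a positive integer, got {v!r}")
        if self.mean_admissions_per_patient <= 0:
            raise ConfigurationError("mean_admissions_per_patient must be positive")
        for name, length in (("race_mix", 3), ("cohort_mix", len(COHORTS))):
            vec = np.asarray(getattr(self, name), dtype=float)
            if vec.shape != (length,):
                raise ConfigurationError(f"{name} must have length {length}, got {vec.shape}")
            if (vec < 0).any() or abs(vec.sum() - 1.0) > 1e-12:
                raise ConfigurationError(f"{name} must be a probability vector summing to 1")
        for name in ("income_low_frac", "planned_revisit_prob", "death_prob", "ama_prob",
                     "missing_link_prob", "under18_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v!r}")
        hc = self.hospital_composition
        if isinstance(hc, (int, float)) and not isinstance(hc, bool):
            if not 0.0 <= hc <= 1.0:
                raise ConfigurationError("hospital_composition point value must be in [0, 1]")
        else:
            hc = tuple(hc)
            if len(hc) != 2 or hc[0] <= 0 or hc[1] <= 0:
                raise ConfigurationError(
                    "hospital_composition must be two positive shape parameters or a single value")
        if not 0.0 <= self.composition_attenuation <= 1.0:
            raise ConfigurationError("composition_attenuation must be in [0, 1]")
        if self.condition_effects.shape != (self.n_condition_vars,):
            raise ConfigurationError(
                f"condition_effects must have length n_condition_vars={self.n_condition_vars}")
        unknown = set(self.covariate_effects) - set(SCALAR_COVARIATES)
        if unknown:
            raise ConfigurationError(f"covariate_effects has unknown keys: {sorted(unknown)}")
        unknown = set(self.group_offsets) - {"black", "low_income"}
        if unknown:
            raise ConfigurationError(f"group_offsets has unknown keys: {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["condition_effects"] = [float(x) for x in self.condition_effects]
        d["race_mix"] = list(self.race_mix)
        d["cohort_mix"] = list(self.cohort_mix)
        hc = self.hospital_composition
        d["hospital_composition"] = hc if isinstance(hc, (int, float)) else list(hc)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "baseline" in d and isinstance(d["baseline"], dict):
            d["baseline"] = CovariateBaseline(**d["baseline"])
        if "group_shifts" in d:
            d["group_shifts"] = {
                k: GroupShift(**v) if isinstance(v, dict) else v
                for k, v in d["group_shifts"].items()
            }
        if "hospital_composition" in d and isinstance(d["hospital_composition"], list):
            d["hospital_composition"] = tuple(d["hospital_composition"])
        for key in ("race_mix", "cohort_mix"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# hospitals


def generate_hospitals(config: GeneratorConfig) -> pd.DataFrame:
    """Hospital table with target Black-patient share and facility flags."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    n = config.n_hospitals
    hc = config.hospital_composition
    if isinstance(hc, (int, float)) and not isinstance(hc, bool):
        black_frac = np.full(n, float(hc))
    else:
        black_frac = rng.beta(hc[0], hc[1], size=n)
    return pd.DataFrame({
        "hospital_id": [f"H{i:03d}" for i in range(n)],
        "black_frac_target": black_frac,
        "teaching": (rng.random(n) < 0.20).astype(int),
        "large": (rng.random(n) < 0.50).astype(int),
    })


# ---------------------------------------------------------------------------
# discharges


def _patient_frame(config: GeneratorConfig, hospitals: pd.DataFrame,
                   rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_patients
    bl = config.baseline
    race_idx = rng.choice(3, size=n, p=np.asarray(config.race_mix, dtype=float))
    income_low = rng.random(n) < config.income_low_frac
    minor = rng.random(n) < config.under18_prob
    female = rng.random(n) < bl.female_frac

    # hospital choice: Black patients weighted toward high-composition
    # hospitals, others toward the complement, so realized shares track the
    # per-hospital targets.
    f = hospitals["black_frac_target"].to_numpy()
    w_black = f + 1e-9
    w_other = (1.0 - f) + 1e-9
    hosp = np.empty(n, dtype=int)
    is_black = race_idx == 1
    hosp[is_black] = rng.choice(len(f), size=int(is_black.sum()), p=w_black / w_black.sum())
    hosp[~is_black] = rng.choice(len(f), size=int((~is_black).sum()), p=w_other / w_other.sum())

    # race-based effects attenuate with the hospital's Black share
    atten = 1.0 - config.composition_attenuation * f[hosp]

    sb = config.group_shifts.get("black", GroupShift())
    sl = config.group_shifts.get("low_income", GroupShift())
    kb = is_black.astype(float) * atten
    kl = income_low.astype(float)

    age = rng.normal(bl.age_mean + kb * sb.age_mean + kl * sl.age_mean, bl.age_sd, size=n)
    age = np.clip(age, 18, 100)
    age[minor] = rng.integers(1, 18, size=int(minor.sum()))

    offset = (config.group_offsets.get("black", 0.0) * kb
              + config.group_offsets.get("low_income", 0.0) * kl)

    return pd.DataFrame({
        "patient_idx": np.arange(n),
        "race_group": np.asarray(RACE_GROUPS)[race_idx],
        "income_group": np.where(income_low, "low", "other"),
        "sex": np.where(female, "female", "male"),
        "age_years": np.round(age, 1),
        "hospital_idx": hosp,
        "group_offset": offset,
        "los_mu": np.maximum(bl.los_mean + kb * sb.los_mean + kl * sl.los_mean, 0.3),
        "charlson_mu": np.maximum(bl.charlson_mean + kb * sb.charlson_mean + kl * sl.charlson_mean, 0.0),
        "ed_mu": np.maximum(bl.ed_mean + kb * sb.ed_mean + kl * sl.ed_mean, 0.0),
        "prior_mu": np.maximum(bl.prior_adm_mean + kb * sb.prior_adm_mean + kl * sl.prior_adm_mean, 0.0),
        "cond_p": np.clip(bl.condition_prob + kb * sb.condition_prob + kl * sl.condition_prob, 0.0, 1.0),
        "n_episodes": rng.poisson(config.mean_admissions_per_patient, size=n),
    })


def _draw_admission_rows(config: GeneratorConfig, patients: pd.DataFrame,
                         pat_of: np.ndarray, rel_admit: np.ndarray,
                         admission_type: np.ndarray, planned_flag: np.ndarray,
                         is_revisit: np.ndarray, episode_of: np.ndarray,
                         rng: np.random.Generator) -> dict:
    """Draw covariates, outcome probability and fate for one round of admissions."""
    bl = config.baseline
    m = len(pat_of)
    p = patients.iloc[pat_of]

    los_mu = p["los_mu"].to_numpy()
    r = bl.los_dispersion
    los = rng.negative_binomial(r, r / (r + los_mu), size=m)
    charlson = rng.poisson(p["charlson_mu"].to_numpy())
    ed = rng.poisson(p["ed_mu"].to_numpy())
    prior = rng.poisson(p["prior_mu"].to_numpy())
    oncology = rng.random(m) < bl.oncology_prob
    procedure = rng.random(m) < bl.procedure_prob
    n_dx = 1 + rng.poisson(bl.n_diagnoses_mean, size=m)
    cond = (rng.random((m, config.n_condition_vars)) < p["cond_p"].to_numpy()[:, None]).astype(np.int8)
    cohort = rng.choice(len(COHORTS), size=m, p=np.asarray(config.cohort_mix, dtype=float))

    eff = config.covariate_effects
    lp = (config.base_logit
          + eff.get("age_decade", 0.0) * (p["age_years"].to_numpy() - 60.0) / 10.0
          + eff.get("los_days", 0.0) * los
          + eff.get("charlson", 0.0) * charlson
          + eff.get("ed_visits_6mo", 0.0) * ed
          + eff.get("admissions_prior_year", 0.0) * prior
          + cond @ config.condition_effects
          + p["group_offset"].to_numpy())
    prob = _expit(lp)

    u_death = rng.random(m)
    death = u_death < config.death_prob
    ama = (~death) & (u_death < config.death_prob + config.ama_prob)
    facility = (~death) & (~ama) & (rng.random(m) < bl.facility_prob)
    disposition = np.where(death, "death", np.where(ama, "ama", np.where(facility, "facility", "home")))

    fired = (rng.random(m) < prob) & ~death
    planned_spawn = (~fired) & (~death) & (rng.random(m) < config.planned_revisit_prob)
    gap = rng.integers(1, 31, size=m)

    return {
        "pat_of": pat_of, "episode_of": episode_of, "rel_admit": rel_admit,
        "los_days": los, "charlson": charlson, "ed_visits_6mo": ed,
        "admissions_prior_year": prior, "oncology_discharge": oncology.astype(int),
        "any_procedure": procedure.astype(int), "n_diagnoses": n_dx,
        "cond": cond, "cohort_label": np.asarray(COHORTS)[cohort],
        "admission_type": admission_type, "planned_flag": planned_flag.astype(int),
        "is_revisit": is_revisit, "discharge_disposition": disposition,
        "true_event_prob": prob, "event_fired": fired, "planned_spawn": planned_spawn,
        "gap": gap,
    }


def generate_discharges(config: GeneratorConfig,
                        hospitals: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the discharge table and its per-record ground truth.

    Returns ``(records, truth)`` where ``truth`` carries, per ``record_id``,
    the true 30-day unplanned-revisit probability and whether the event
    actually fired.  An admission's fired revisit and its planned revisit are
    mutually exclusive (a planned revisit is only drawn when the unplanned
    event did not fire), so among admissions with complete follow-up and
    intact linkage the observed unplanned label equals the fired flag exactly.
    """
    config.validate()
    if len(hospitals) == 0:
        raise ConfigurationError("hospitals table is empty")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    patients = _patient_frame(config, hospitals, rng)

    # episode skeleton: one chain of admissions per episode
    n_ep = patients["n_episodes"].to_numpy()
    ep_pat = np.repeat(patients["patient_idx"].to_numpy(), n_ep)
    n_episodes = len(ep_pat)
    if n_episodes == 0:
        raise ConfigurationError("mean_admissions_per_patient too low: no admissions drawn")

    rounds = []
    pat_of = ep_pat
    episode_of = np.arange(n_episodes)
    rel_admit = np.zeros(n_episodes, dtype=int)
    emergent = rng.random(n_episodes) < config.baseline.emergent_prob
    admission_type = np.where(emergent, "emergent", "elective")
    planned_flag = np.zeros(n_episodes, dtype=bool)
    is_revisit = np.zeros(n_episodes, dtype=bool)

    for _ in range(_MAX_CHAIN_ROUNDS):
        rd = _draw_admission_rows(config, patients, pat_of, rel_admit, admission_type,
                                  planned_flag, is_revisit, episode_of, rng)
        rounds.append(rd)
        spawn = rd["event_fired"] | rd["planned_spawn"]
        if not spawn.any():
            break
        pat_of = rd["pat_of"][spawn]
        episode_of = rd["episode_of"][spawn]
        rel_admit = rd["rel_admit"][spawn] + rd["los_days"][spawn] + rd["gap"][spawn]
        planned_flag = rd["planned_spawn"][spawn]
        admission_type = np.where(planned_flag, "elective", "emergent")
        is_revisit = np.ones(len(pat_of), dtype=bool)

    def cat(key):
        return np.concatenate([rd[key] for rd in rounds])

    adm = pd.DataFrame({k: cat(k) for k in rounds[0] if k != "cond"})
    cond = np.concatenate([rd["cond"] for rd in rounds], axis=0)

    # lay episodes on the timeline: sequential per patient, >=31-day gap
    # between a chain's end and the next episode so labels stay controlled
    chain_end = (adm["rel_admit"] + adm["los_days"]).groupby(adm["episode_of"]).max()
    ep = pd.DataFrame({"episode": np.arange(n_episodes), "patient": ep_pat})
    ep["span"] = chain_end.reindex(ep["episode"]).to_numpy()
    ep["gap_after"] = 31 + rng.exponential(120.0, size=n_episodes).astype(int)
    first_start = rng.integers(0, config.study_days, size=len(patients))
    block = ep["span"] + ep["gap_after"]
    ep["start"] = (first_start[ep["patient"].to_numpy()]
                   + block.groupby(ep["patient"]).cumsum().to_numpy()
                   - block.to_numpy())

    adm["admit_day"] = ep["start"].to_numpy()[adm["episode_of"].to_numpy()] + adm["rel_admit"]
    adm["discharge_day"] = adm["admit_day"] + adm["los_days"]
    keep = adm["admit_day"].to_numpy() <= config.study_days
    adm = adm.loc[keep].reset_index(drop=True)
    cond = cond[keep]

    # a death ends the patient's record stream: drop everything after it
    order = np.lexsort((adm["discharge_day"].to_numpy(), adm["admit_day"].to_numpy(),
                        adm["pat_of"].to_numpy()))
    adm = adm.iloc[order].reset_index(drop=True)
    cond = cond[order]
    died = (adm["discharge_disposition"] == "death").to_numpy().astype(int)
    prior_deaths = died.cumsum() - died
    pat_arr = adm["pat_of"].to_numpy()
    starts = np.r_[0, np.flatnonzero(np.diff(pat_arr)) + 1]
    base = np.repeat(prior_deaths[starts], np.diff(np.r_[starts, len(pat_arr)]))
    alive = (prior_deaths - base) == 0
    adm = adm.loc[alive].reset_index(drop=True)
    cond = cond[alive]

    n = len(adm)
    p = patients.iloc[adm["pat_of"].to_numpy()]
    link = np.array([f"P{i:06d}" for i in p["patient_idx"]], dtype=object)
    link[rng.random(n) < config.missing_link_prob] = None

    records = pd.DataFrame({
        "record_id": [f"R{i:07d}" for i in range(n)],
        "patient_link_id": link,
        "hospital_id": hospitals["hospital_id"].to_numpy()[p["hospital_idx"].to_numpy()],
        "admit_day": adm["admit_day"].astype(int),
        "los_days": adm["los_days"].astype(int),
        "discharge_day": adm["discharge_day"].astype(int),
        "age_years": p["age_years"].to_numpy(),
        "sex": p["sex"].to_numpy(),
        "race_group": p["race_group"].to_numpy(),
        "income_group": p["income_group"].to_numpy(),
        "payer": _assign_payer(p["age_years"].to_numpy(), p["income_group"].to_numpy(), rng),
        "admission_type": adm["admission_type"],
        "charlson": adm["charlson"].astype(int),
        "ed_visits_6mo": adm["ed_visits_6mo"].astype(int),
        "admissions_prior_year": adm["admissions_prior_year"].astype(int),
        "oncology_discharge": adm["oncology_discharge"].astype(int),
        "any_procedure": adm["any_procedure"].astype(int),
        "n_diagnoses": adm["n_diagnoses"].astype(int),
        "discharge_disposition": adm["discharge_disposition"],
        "planned_flag": adm["planned_flag"].astype(int),
        "cohort_label": adm["cohort_label"],
    })
    for j in range(config.n_condition_vars):
        records[f"cond_{j:02d}"] = cond[:, j]

    truth = pd.DataFrame({
        "record_id": records["record_id"],
        "true_event_prob": adm["true_event_prob"],
        "event_fired": adm["event_fired"].astype(bool),
        "is_spawned_revisit": adm["is_revisit"].astype(bool),
    })
    return records, truth


def _assign_payer(age: np.ndarray, income: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = len(age)
    u = rng.random(n)
    senior = age >= 65
    low = income == "low"
    out = np.empty(n, dtype=object)
    # seniors: overwhelmingly medicare
    out[senior] = np.select(
        [u[senior] < 0.92, u[senior] < 0.97], ["medicare", "private"], default="other")
    yl = (~senior) & low
    out[yl] = np.select(
        [u[yl] < 0.40, u[yl] < 0.75, u[yl] < 0.85], ["medicaid", "private", "medicare"],
        default="other")
    yo = (~senior) & (~low)
    out[yo] = np.select(
        [u[yo] < 0.12, u[yo] < 0.74, u[yo] < 0.84], ["medicaid", "private", "medicare"],
        default="other")
    return out


# ---------------------------------------------------------------------------
# I/O


def write_discharges(records: pd.DataFrame, path) -> None:
    """Write the discharge table as CSV; missing linkage becomes an empty field."""
    records.to_csv(path, index=False)


def read_discharges(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_link_id": "string"})
    df["patient_link_id"] = df["patient_link_id"].astype(object).where(
        df["patient_link_id"].notna(), None)
    return df
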