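"""Synthetic cohort generation.

Simulates a prospective cohort of postmenopausal women followed for
incident fractures, with per-subject femur phantoms, so that the entire
analysis chain (structural parameters, FE strength, adjudication, survival
statistics, surface maps) can be exercised end to end without patient data.

Structure of the generator:

* One latent "bone quality" factor per subject, ``q ~ N(0, 1)``.  Every
  densitometric/structural parameter is drawn from a single-factor Gaussian
  model ``X = mu + sd * (lambda * q + sqrt(1 - lambda^2) * eps)`` whose
  marginal mean/SD are the configured calibration targets (the control-group
  marginals of the emulated study); the default loading gives a
  strength-aBMD correlation of about 0.7.
* Fracture outcomes follow an exponential proportional-hazards model whose
  per-SD hazard ratio for the fall-configuration strength is planted at a
  configurable value; the baseline rate is calibrated so the expected event
  count matches the configured rate.  Major osteoporotic fractures (MOF)
  are a subset of low-trauma (LT) fractures.
* Follow-up is truncated normal (mean 5.7 y, SD 1.5 y, floor 0.5 y).
* Per-subject phantoms are generated from the same latent factor, so
  image-derived quantities co-vary coherently with the tabulated ones.

All randomness flows from one master seed through named substreams.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import fractures as fr
from .phantom import PhantomConfig, generate_phantom

#: Control-group calibration targets (mean, SD) for the tabulated subject
#: parameters.  Densities mg/cm^3, aBMD g/cm^2, strengths N, CTh mm; the
#: FN cross-section properties use the source's scaled units (1e3 mm^2 for
#: CSA/SA, 1e4 mm^4 for CSMI, 1e3 mm^3 for Z).
CONTROL_MARGINALS: dict[str, tuple[float, float]] = {
    "age": (65.1, 1.5),
    "bmi": (25.1, 4.5),
    "th_abmd": (0.849, 0.112),
    "fn_abmd": (0.713, 0.108),
    "strength_fall": (3563.0, 980.0),
    "strength_stance": (6583.0, 1574.0),
    "th_vbmd": (302.0, 49.0),
    "fn_vbmd": (341.0, 67.0),
    "th_tb_vbmd": (162.0, 34.0),
    "fn_tb_vbmd": (202.0, 51.0),
    "th_ct_vbmd": (830.0, 69.0),
    "fn_ct_vbmd": (843.0, 89.0),
    "th_ct_sbmd": (155.0, 21.0),
    "fn_ct_sbmd": (133.0, 22.0),
    "th_cth": (1.859, 0.143),
    "fn_cth": (1.605, 0.188),
    "fn_csa": (0.977, 0.177),
    "fn_csmi": (1.202, 0.290),
    "fn_z": (0.648, 0.142),
}

#: Factor loadings on the latent quality factor; 0.837^2 ~ 0.7 pairwise
#: correlation between any two bone parameters.  Age and BMI are
#: uncorrelated with the factor.
DEFAULT_LOADING = 0.837
ZERO_LOADING_PARAMS = ("age", "bmi")

#: Planted per-SD-decrease hazard ratios for the default outcome simulation
#: (driven by fall-configuration strength).
DEFAULT_PLANTED_HR = {"lt": 1.32, "mof": 1.50}

#: Site composition of incident fractures: MOF counts and the residual
#: non-MOF low-trauma sites.
MOF_SITE_WEIGHTS = {"forearm": 19, "humerus": 16, "proximal_femur": 5, "vertebra": 4}
LT_ONLY_SITE_WEIGHTS = {"rib": 0.15, "other": 0.85}


@dataclass(frozen=True)
class CohortConfig:
    n_subjects: int = 740
    marginals: tuple = tuple(CONTROL_MARGINALS.items())
    loading: float = DEFAULT_LOADING
    planted_hr: tuple = tuple(DEFAULT_PLANTED_HR.items())
    lt_event_fraction: float = 100.0 / 740.0
    mof_fraction_of_lt: float = 44.0 / 100.0
    followup_mean: float = 5.7
    followup_sd: float = 1.5
    followup_floor: float = 0.5
    seed: int = 0
    phantom: PhantomConfig = PhantomConfig()

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        for name, (mu, sd) in self.marginals:
            if sd <= 0:
                raise ValueError(f"SD for {name} must be positive")

    @property
    def marginal_dict(self):
        return dict(self.marginals)

    @property
    def planted_hr_dict(self):
        return dict(self.planted_hr)


@dataclass
class SubjectRecord:
    id: str
    age: float
    bmi: float
    latent_quality: float
    followup_years: float
    event_lt: int = 0
    event_mof: int = 0
    event_time: float = np.nan
    fracture_site: str | None = None
    trauma: str | None = None
    excluded_reason: str | None = None


def _rng(seed: int, *stream) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *map(int, stream)]))


def sample_followup(n: int, config: CohortConfig, rng) -> np.ndarray:
    """Truncated-normal follow-up times (years), floored at 0.5 y."""
    a = (config.followup_floor - config.followup_mean) / config.followup_sd
    return stats.truncnorm.rvs(a, np.inf, loc=config.followup_mean,
                               scale=config.followup_sd, size=n, random_state=rng)


def calibrate_baseline_rate(z: np.ndarray, followup: np.ndarray,
                            log_hr_per_sd: float, target_fraction: float) -> float:
    """Baseline exponential rate giving the target expected event fraction.

    ``z`` is the standardized predictor (per-SD-decrease effect: hazard is
    multiplied by exp(log_hr) per SD *below* the mean).
    """
    if not (0 < target_fraction < 1):
        raise ValueError("target_fraction must lie in (0, 1)")
    rel = np.exp(log_hr_per_sd * (-z))

    def expected(log_h0):
        return np.mean(1.0 - np.exp(-np.exp(log_h0) * rel * followup)) - target_fraction

    return float(np.exp(optimize.brentq(expected, -15.0, 5.0)))


def simulate_outcomes(z: np.ndarray, followup: np.ndarray,
                      log_hr_per_sd: float, baseline_rate: float, seed: int = 0,
                      rng: np.random.Generator | None = None):
    """Exponential proportional-hazards event simulation.

    The hazard of subject i is ``baseline_rate * exp(log_hr_per_sd * (-z_i))``
    (risk increases per SD decrease of the predictor); events are censored
    at the end of follow-up.  Returns ``(event, time)`` arrays.
    """
    if baseline_rate <= 0:
        raise ValueError("baseline_rate must be positive")
    z = np.asarray(z, float)
    followup = np.asarray(followup, float)
    rng = rng if rng is not None else _rng(seed, 11)
    hazard = baseline_rate * np.exp(log_hr_per_sd * (-z))
    t = rng.exponential(1.0 / hazard)
    event = (t <= followup).astype(int)
    time = np.minimum(t, followup)
    return event, time


def generate_cohort_table(config: CohortConfig) -> pd.DataFrame:
    """Generate the per-subject cohort table (no phantom images).

    Columns: subject covariates, all tabulated parameters, T-scores,
    follow-up, and adjudicated LT/MOF outcome flags with event times and
    sites.  Deterministic given the config (seed included).
    """
    n = config.n_subjects
    rng = _rng(config.seed, 1)
    q = rng.standard_normal(n)

    data = {"id": [f"S{i:05d}" for i in range(n)], "latent_quality": q}
    for name, (mu, sd) in config.marginals:
        lam = 0.0 if name in ZERO_LOADING_PARAMS else config.loading
        eps = rng.standard_normal(n)
        data[name] = mu + sd * (lam * q + np.sqrt(1.0 - lam ** 2) * eps)
    df = pd.DataFrame(data)

    # T-scores follow deterministically from aBMD via the frozen references
    from .structural import REFERENCE_CURVES, t_score
    df["th_tscore"] = [t_score(v, REFERENCE_CURVES["TH"]) for v in df["th_abmd"]]
    df["fn_tscore"] = [t_score(v, REFERENCE_CURVES["FN"]) for v in df["fn_abmd"]]

    rng_f = _rng(config.seed, 2)
    df["followup_years"] = sample_followup(n, config, rng_f)

    # outcomes driven by standardized fall strength
    z = (df["strength_fall"] - df["strength_fall"].mean()) / df["strength_fall"].std()
    z = z.to_numpy()
    hrs = config.planted_hr_dict
    beta_lt = np.log(hrs["lt"])
    beta_mof = np.log(hrs["mof"])
    h0 = calibrate_baseline_rate(z, df["followup_years"].to_numpy(), beta_lt,
                                 config.lt_event_fraction)
    ev_lt, t_lt = simulate_outcomes(z, df["followup_years"].to_numpy(), beta_lt,
                                    h0, rng=_rng(config.seed, 3))
    df["event_lt"] = ev_lt
    df["time_lt"] = t_lt

    # MOF subset of LT events; membership probability tilted by the extra
    # log-hazard so the planted MOF effect exceeds the LT one
    rng_m = _rng(config.seed, 4)
    ev_mof = np.zeros(n, int)
    lt_idx = np.flatnonzero(ev_lt == 1)
    if len(lt_idx):
        w = np.exp((beta_mof - beta_lt) * (-z[lt_idx]))
        p = config.mof_fraction_of_lt * w / w.mean()
        p = np.clip(p, 0.0, 1.0)
        ev_mof[lt_idx] = (rng_m.random(len(lt_idx)) < p).astype(int)
    df["event_mof"] = ev_mof
    df["time_mof"] = np.where(ev_mof == 1, t_lt, df["followup_years"])

    # fracture sites
    sites = np.array([None] * n, object)
    mof_sites = list(MOF_SITE_WEIGHTS)
    mof_p = np.array(list(MOF_SITE_WEIGHTS.values()), float)
    mof_p /= mof_p.sum()
    lt_sites = list(LT_ONLY_SITE_WEIGHTS)
    lt_p = np.array(list(LT_ONLY_SITE_WEIGHTS.values()), float)
    lt_p /= lt_p.sum()
    rng_s = _rng(config.seed, 5)
    for i in range(n):
        if ev_mof[i]:
            sites[i] = rng_s.choice(mof_sites, p=mof_p)
        elif ev_lt[i]:
            sites[i] = rng_s.choice(lt_sites, p=lt_p)
    df["fracture_site"] = sites
    df["trauma"] = np.where(ev_lt == 1, fr.LOW_TRAUMA, None)
    return df


def generate_cohort(config: CohortConfig, with_phantoms: bool = True):
    """Yield ``(SubjectRecord, FemurPhantom | None)`` pairs for the cohort.

    Phantom generation is lazy (one image at a time) because a full cohort
    of voxel images does not fit in memory at once; pass
    ``with_phantoms=False`` for the table-only fast path.
    """
    df = generate_cohort_table(config)
    for i, row in df.iterrows():
        rec = SubjectRecord(
            id=row["id"], age=row["age"], bmi=row["bmi"],
            latent_quality=row["latent_quality"],
            followup_years=row["followup_years"],
            event_lt=int(row["event_lt"]), event_mof=int(row["event_mof"]),
            event_time=row["time_lt"] if row["event_lt"] else np.nan,
            fracture_site=row["fracture_site"], trauma=row["trauma"])
        phantom = None
        if with_phantoms:
            phantom = generate_phantom(config.phantom, row["latent_quality"],
                                       seed=int(_rng(config.seed, 6, i).integers(2 ** 31)))
        yield rec, phantom


# ---------------------------------------------------------------------------
# roster fixture reproducing the recruitment flow


def reference_roster() -> list[fr.RosterEntry]:
    """Deterministic roster reproducing the study recruitment flow.

    833 recruited subjects: 9 with missing DXA, 34 lost to follow-up, 50
    with an incident traumatic fracture, leaving 740 analysed; of those,
    100 sustain a low-trauma clinical fracture of which 44 are MOFs
    (forearm 19, humerus 16, proximal femur 5, vertebra 4), and a handful
    of controls carry excluded-site (finger/toe) events that do not remove
    them from the control group.
    """
    roster: list[fr.RosterEntry] = []
    k = 0

    def add(**kw):
        nonlocal k
        roster.append(fr.RosterEntry(id=f"R{k:04d}", **kw))
        k += 1

    for _ in range(9):
        add(has_dxa=False)
    for _ in range(34):
        add(followed_up=False)
    for i in range(50):
        site = ["forearm", "humerus", "rib", "other"][i % 4]
        add(events=[fr.FractureEvent(site=site, trauma=fr.HIGH_TRAUMA, time=1.0 + i % 4)])
    # MOF cases (also LT by definition)
    for site, count in MOF_SITE_WEIGHTS.items():
        for i in range(count):
            add(events=[fr.FractureEvent(site=site, time=0.5 + (i % 9) * 0.5)])
    # LT-only cases
    for i in range(56):
        site = "rib" if i % 7 == 0 else "other"
        add(events=[fr.FractureEvent(site=site, time=0.5 + (i % 10) * 0.5)])
    # controls, a few with excluded-site events
    for i in range(640):
        events = []
        if i % 80 == 0:
            events = [fr.FractureEvent(site="finger" if i % 160 else "toe", time=2.0)]
        add(events=events)
    assert len(roster) == 833
    return roster


# ---------------------------------------------------------------------------
# fast per-subject surface maps (no voxel phantoms)


def generate_vertex_maps(df: pd.DataFrame, template_cth: np.ndarray,
                         template_sbmd: np.ndarray, config: CohortConfig,
                         noise_frac: float = 0.12):
    """Per-subject vertex maps of CTh and sBMD from the latent factor.

    A fast surrogate for casting rays through every subject's voxel image:
    each subject's map is the template scaled by the phantom's latent-quality
    sensitivities plus independent multiplicative vertex noise.  Returns
    ``(cth_maps, sbmd_maps)`` with shape (n_subjects, n_vertices).
    """
    pc = config.phantom
    q = df["latent_quality"].to_numpy()
    rng = _rng(config.seed, 7)
    n, v = len(q), len(template_cth)
    noise_c = 1.0 + noise_frac * rng.standard_normal((n, v))
    noise_s = 1.0 + noise_frac * rng.standard_normal((n, v))
    cth = np.exp(pc.sens_cth * q)[:, None] * template_cth[None, :] * noise_c
    sbmd = (np.exp((pc.sens_cth + pc.sens_ct_vbmd) * q)[:, None]
            * template_sbmd[None, :] * noise_s)
    return np.clip(cth, 0.05, None), np.clip(sbmd, 0.5, None)
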