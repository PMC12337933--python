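"""Synthetic dispensing-data generator with known ground truth.

Real pharmacy-dispensing databases of this kind are proprietary, so every
downstream stage (cohort building, PDC, pattern classification, clustering,
prediction, survival) is exercised against simulated patients whose adherence
behaviour, utilization-pattern archetype, and covariate effects are planted
and recorded in a truth table.

The generative model, in order:

1. Covariates first: age band, sex, comorbidity flags, and an index date
   (hence calendar period) are drawn per patient.
2. A planted binary high-adherence label ``H`` is drawn from a logistic link
   on the covariates (``covariate_effects`` holds the log-odds).  ``H`` maps
   to a refill *propensity* band; the inter-dispensing delay factor is
   ``1/propensity + U(-jitter, +jitter)``, so the year-1 PDC lands on the
   intended side of the 0.8 threshold with margin.
3. An archetype (continuer / discontinuer / switcher / adder) and an exposure
   class are drawn (marginally by default; optional logit shifts create
   confounding for weighting experiments).
4. The dispensing history is generated per archetype: continuers refill until
   supply reaches the horizon; discontinuers stop after a truncated
   Geometric(0.3) number of dispensings; switchers start a different class
   ``U(1, 180)`` days after their last supply ends; adders start a second
   class on a day strictly inside ongoing initial-class coverage.
5. Comorbidity-drug dispensings are emitted inside the first 180 days for
   each flagged comorbidity.

With a fixed seed the three output tables are byte-identical across runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .classmap import (
    EXPOSURE_CLASSES,
    REPRESENTATIVE_COMORBIDITY_ATC,
    REPRESENTATIVE_EXPOSURE_ATC,
    REPRESENTATIVE_FDC_ATC,
)
from .cohort import COMORBIDITY_NAMES, calendar_period
from .coverage import covered_intervals

ARCHETYPES = ("continuer", "discontinuer", "switcher", "adder")


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


DEFAULT_ARCHETYPE_MIX = {
    "continuer": 0.35,
    "discontinuer": 0.35,
    "switcher": 0.15,
    "adder": 0.15,
}

DEFAULT_COVARIATE_EFFECTS = {
    "intercept": 1.0,
    "age_middle": 0.4,
    "age_older": 0.5,
    "sex_M": -0.1,
    "diabetes": 0.5,
    "asthma_copd": 0.3,
    "psycholeptics": -0.5,
    "period_2000_2010": 0.3,
    "period_2010_2020": 0.4,
}

DEFAULT_COMORBIDITY_PREVALENCE = {
    "diabetes": 0.08,
    "ra": 0.04,
    "asthma_copd": 0.10,
    "antiepileptics": 0.03,
    "antiparkinson": 0.02,
    "psycholeptics": 0.12,
    "psychoanaleptics": 0.10,
    "addictive_disorders": 0.02,
    "antineoplastics": 0.02,
}


@dataclass
class SimulationConfig:
    n_patients: int = 1000
    seed: int = 0
    archetype_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ARCHETYPE_MIX)
    )
    exposure_mix: dict[str, float] = field(
        default_factory=lambda: {c: 0.2 for c in EXPOSURE_CLASSES}
    )
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS)
    )
    comorbidity_prevalence: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMORBIDITY_PREVALENCE)
    )
    # refill-delay model
    days_supply: dict[str, int] = field(
        default_factory=lambda: {c: 90 for c in EXPOSURE_CLASSES}
    )
    jitter: float = 0.1
    high_propensity_band: tuple[float, float] = (0.92, 1.0)
    low_propensity_band: tuple[float, float] = (0.55, 0.70)
    # archetype event timing
    disc_refill_p: float = 0.3
    max_event_refills: int = 8
    switch_fdc_prob: float = 0.1
    # late adherence improvement: per-180-day-window chance that an initially
    # low-adherent persister jumps to the high-propensity band, from day 360
    improvement_prob: float = 0.15
    improvement_start: int = 360
    # study window
    study_start: str = "1996-01-01"
    study_end: str = "2020-12-31"
    min_observation_days: int = 1800
    # demographics
    age_band_mix: dict[str, float] = field(
        default_factory=lambda: {"young": 0.25, "middle": 0.55, "older": 0.20}
    )
    male_fraction: float = 0.5
    # optional covariate-linked assignment (log-odds shifts), for confounding
    exposure_logit_shift: dict[str, dict[str, float]] | None = None
    archetype_logit_shift: dict[str, dict[str, float]] | None = None

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        for name, mix, keys in (
            ("archetype_mix", self.archetype_mix, ARCHETYPES),
            ("exposure_mix", self.exposure_mix, EXPOSURE_CLASSES),
        ):
            if not set(mix) <= set(keys):
                raise ConfigurationError(f"{name} has unknown keys: {set(mix) - set(keys)}")
            if any(v < 0 for v in mix.values()):
                raise ConfigurationError(f"{name} has negative proportions")
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ConfigurationError(f"{name} must sum to 1 (got {sum(mix.values())})")

    def replace(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass
class TruthLabel:
    patient_id: str
    archetype: str
    true_high_adherence_prob: float
    planted_event_days: dict[str, int]


# ---------------------------------------------------------------------------
# per-patient history
# ---------------------------------------------------------------------------

def _delay(rng: np.random.Generator, propensity: float, jitter: float) -> float:
    return 1.0 / propensity + rng.uniform(-jitter, jitter)


def _refill_days(
    rng: np.random.Generator,
    supply: int,
    propensity: float,
    jitter: float,
    n_dispensings: int | None = None,
    cover_until: int | None = None,
    boost_at: int | None = None,
    boost_propensity: float | None = None,
) -> list[int]:
    """Dispensing days starting at day 0 under the delay-factor refill model.

    Stops after ``n_dispensings`` dispensings, or once banked (carryover)
    supply reaches ``cover_until``; in the latter case trailing refills are
    placed exactly at supply exhaustion so coverage is guaranteed to reach
    the target day.  From ``boost_at`` onwards the refill propensity switches
    to ``boost_propensity`` (late adherence improvement).
    """
    days = [0]
    cover_end = supply
    d = 0
    while True:
        if n_dispensings is not None and len(days) >= n_dispensings:
            break
        if cover_until is not None and cover_end >= cover_until:
            break
        prop = (
            boost_propensity
            if boost_at is not None and boost_propensity is not None and d >= boost_at
            else propensity
        )
        step = max(1, int(round(supply * _delay(rng, prop, jitter))))
        nxt = d + step
        if cover_until is not None and nxt >= cover_until:
            nxt = cover_end  # refill exactly at exhaustion near the horizon
        d = nxt
        days.append(d)
        cover_end = max(cover_end, d) + supply
    return days


def simulate_patient_history(
    archetype: str,
    drug_class: str,
    propensity: float,
    horizon: int,
    rng: np.random.Generator,
    config: SimulationConfig,
    improvement_day: int | None = None,
) -> tuple[list[tuple[int, str, int]], dict[str, object]]:
    """Exposure-drug dispensings ``(day, atc, days_supply)`` for one patient.

    Returns the dispensing list plus the planted events
    (``disc_day``/``switch_day``/``switch_target``/``addon_day``/``addon_target``).
    """
    if archetype not in ARCHETYPES:
        raise ConfigurationError(f"unknown archetype {archetype!r}")
    supply = config.days_supply[drug_class]
    atc = REPRESENTATIVE_EXPOSURE_ATC[drug_class]
    events: dict[str, object] = {}
    disp: list[tuple[int, str, int]] = []

    def other_target() -> tuple[str, str]:
        if rng.random() < config.switch_fdc_prob:
            return "fdc", REPRESENTATIVE_FDC_ATC
        choices = [c for c in EXPOSURE_CLASSES if c != drug_class]
        t = choices[rng.integers(len(choices))]
        return t, REPRESENTATIVE_EXPOSURE_ATC[t]

    boost = (
        {"boost_at": improvement_day, "boost_propensity": config.high_propensity_band[0]}
        if improvement_day is not None
        else {}
    )

    if archetype == "continuer":
        days = _refill_days(
            rng, supply, propensity, config.jitter, cover_until=horizon, **boost
        )
        disp += [(d, atc, supply) for d in days]

    elif archetype in ("discontinuer", "switcher"):
        n = int(min(rng.geometric(config.disc_refill_p), config.max_event_refills))
        days = _refill_days(rng, supply, propensity, config.jitter, n_dispensings=n)
        disp += [(d, atc, supply) for d in days]
        disc_day = max(e for _, e in covered_intervals([(d, supply) for d in days]))
        events["disc_day"] = disc_day
        if archetype == "switcher":
            target, target_atc = other_target()
            switch_day = disc_day + int(rng.integers(1, 181))
            n2 = int(rng.integers(2, 5))
            t_days = _refill_days(rng, supply, propensity, config.jitter, n_dispensings=n2)
            disp += [(switch_day + d, target_atc, supply) for d in t_days]
            events["switch_day"] = switch_day
            events["switch_target"] = target

    else:  # adder
        days = _refill_days(
            rng, supply, propensity, config.jitter, cover_until=horizon, **boost
        )
        disp += [(d, atc, supply) for d in days]
        intervals = covered_intervals([(d, supply) for d in days])
        lo = 30
        hi = min(horizon - 1, max(e for _, e in intervals) - 1)
        cand = int(rng.integers(lo, max(lo + 1, hi)))
        addon_day = None
        for s, e in intervals:
            if s <= cand < e:
                addon_day = cand
                break
            if s > cand:
                addon_day = s  # snap forward to the next covered day
                break
        if addon_day is None:
            addon_day = intervals[-1][0]
        target, target_atc = other_target()
        n2 = int(rng.integers(2, 5))
        t_days = _refill_days(rng, supply, propensity, config.jitter, n_dispensings=n2)
        disp += [(addon_day + d, target_atc, supply) for d in t_days]
        events["addon_day"] = int(addon_day)
        events["addon_target"] = target

    return sorted(disp), events


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------

_AGE_RANGES = {"young": (18, 39), "middle": (40, 69), "older": (70, 88)}


def _draw_from_mix(rng, mix: dict[str, float], shift: dict[str, float] | None = None):
    keys = list(mix)
    logits = np.log(np.clip([mix[k] for k in keys], 1e-12, None))
    if shift:
        logits = logits + np.array([shift.get(k, 0.0) for k in keys])
    p = np.exp(logits - logits.max())
    p /= p.sum()
    return keys[rng.choice(len(keys), p=p)]


def _covariate_value(name: str, cov: dict[str, object]) -> float:
    """Value of a named indicator (e.g. 'age_older', 'sex_M', 'diabetes')."""
    if name == "intercept":
        return 1.0
    if name.startswith("age_"):
        return float(cov["age_band"] == name.removeprefix("age_"))
    if name.startswith("sex_"):
        return float(cov["sex"] == name.removeprefix("sex_"))
    if name.startswith("period_"):
        return float(cov["calendar_period"] == name.removeprefix("period_").replace("_", "-"))
    if name in COMORBIDITY_NAMES:
        return float(cov[name])
    raise ConfigurationError(f"unknown covariate effect name {name!r}")


def simulate_population(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate ``(patients, dispensings, truth)`` tables.

    ``patients``: patient_id, birth_date, sex.
    ``dispensings``: patient_id, dispense_date, atc_code, days_supply.
    ``truth``: planted archetype, exposure class, adherence label and
    propensity, and every planted event day (offsets from index).
    """
    rng = np.random.default_rng(config.seed)
    study_start = pd.Timestamp(config.study_start)
    study_end = pd.Timestamp(config.study_end)
    index_span = (study_end - study_start).days - config.min_observation_days
    if index_span < 1:
        raise ConfigurationError("study window shorter than min_observation_days")

    patients, dispensings, truth = [], [], []
    for i in range(config.n_patients):
        pid = f"P{i:06d}"
        index_date = study_start + pd.Timedelta(days=int(rng.integers(0, index_span)))
        horizon = min(3780, (study_end - index_date).days + 1)

        age_band_ = _draw_from_mix(rng, config.age_band_mix)
        lo, hi = _AGE_RANGES[age_band_]
        age = int(rng.integers(lo, hi + 1))
        # offset in [45, 320) keeps completed years at index equal to `age`
        birth_date = index_date - pd.Timedelta(days=365 * age + int(rng.integers(45, 320)))
        sex = "M" if rng.random() < config.male_fraction else "F"
        cov: dict[str, object] = {
            "age_band": age_band_,
            "sex": sex,
            "calendar_period": calendar_period(index_date),
        }
        for name in COMORBIDITY_NAMES:
            cov[name] = bool(
                rng.random() < config.comorbidity_prevalence.get(name, 0.0)
            )

        lp = sum(
            beta * _covariate_value(name, cov)
            for name, beta in config.covariate_effects.items()
        )
        p_high = _sigmoid(lp)
        high = bool(rng.random() < p_high)
        band = config.high_propensity_band if high else config.low_propensity_band
        propensity = float(rng.uniform(*band))

        shift_cfg = config.exposure_logit_shift
        expo_shift = (
            {
                cls: sum(b * _covariate_value(nm, cov) for nm, b in shifts.items())
                for cls, shifts in shift_cfg.items()
            }
            if shift_cfg
            else None
        )
        exposure = _draw_from_mix(rng, config.exposure_mix, expo_shift)

        arch_cfg = config.archetype_logit_shift
        arch_shift = (
            {
                a: sum(b * _covariate_value(nm, cov) for nm, b in shifts.items())
                for a, shifts in arch_cfg.items()
            }
            if arch_cfg
            else None
        )
        archetype = _draw_from_mix(rng, config.archetype_mix, arch_shift)

        improvement_day = None
        if not high and archetype in ("continuer", "adder") and config.improvement_prob > 0:
            j = int(rng.geometric(config.improvement_prob))
            cand_day = config.improvement_start + (j - 1) * 180
            if cand_day < horizon:
                improvement_day = cand_day

        disp, events = simulate_patient_history(
            archetype, exposure, propensity, horizon, rng, config,
            improvement_day=improvement_day,
        )
        for day, atc, supply in disp:
            dispensings.append(
                (pid, index_date + pd.Timedelta(days=day), atc, supply)
            )
        # comorbidity-drug dispensings inside the first 180 days
        for name in COMORBIDITY_NAMES:
            if cov[name]:
                for _ in range(int(rng.integers(1, 3))):
                    day = int(rng.integers(0, 181))
                    dispensings.append(
                        (
                            pid,
                            index_date + pd.Timedelta(days=day),
                            REPRESENTATIVE_COMORBIDITY_ATC[name],
                            30,
                        )
                    )

        patients.append((pid, birth_date, sex))
        truth.append(
            {
                "patient_id": pid,
                "archetype": archetype,
                "exposure_class": exposure,
                "index_date": index_date,
                "horizon": horizon,
                "true_high_adherence_prob": p_high,
                "high_adherence": high,
                "propensity": propensity,
                "improvement_day": improvement_day,
                "disc_day": events.get("disc_day"),
                "switch_day": events.get("switch_day"),
                "switch_target": events.get("switch_target"),
                "addon_day": events.get("addon_day"),
                "addon_target": events.get("addon_target"),
                **{name: cov[name] for name in COMORBIDITY_NAMES},
                "age_band": age_band_,
                "sex": sex,
                "calendar_period": cov["calendar_period"],
            }
        )

    patients_df = pd.DataFrame(patients, columns=["patient_id", "birth_date", "sex"])
    disp_df = pd.DataFrame(
        dispensings, columns=["patient_id", "dispense_date", "atc_code", "days_supply"]
    ).sort_values(["patient_id", "dispense_date", "atc_code"], kind="mergesort")
    disp_df = disp_df.reset_index(drop=True)
    truth_df = pd.DataFrame(truth)
    return patients_df, disp_df, truth_df


# ---------------------------------------------------------------------------
# auxiliary simulators used by validation studies
# ---------------------------------------------------------------------------

def random_dispensing_history(
    rng: np.random.Generator,
    max_dispensings: int = 12,
    horizon: int = 1500,
    max_supply: int = 120,
) -> list[tuple[int, int]]:
    """Arbitrary messy ``(day, supply)`` history for oracle cross-checks."""
    n = int(rng.integers(1, max_dispensings + 1))
    days = np.sort(rng.integers(0, horizon, size=n))
    supplies = rng.integers(1, max_supply + 1, size=n)
    return [(int(d), int(s)) for d, s in zip(days, supplies)]


def random_pattern_case(
    rng: np.random.Generator, horizon: int = 1800
) -> dict[str, object]:
    """Random same-class + other-class dispensings for classifier cross-checks.

    Day gaps are drawn around the 180-day decision boundary so discontinuation,
    switch and add-on branches are all exercised.
    """
    n_same = int(rng.integers(1, 9))
    days, d = [], 0
    for _ in range(n_same):
        days.append(d)
        d += int(rng.integers(20, 320))
    supplies = rng.integers(30, 121, size=n_same)
    same = [(int(a), int(s)) for a, s in zip(days, supplies)]
    n_other = int(rng.integers(0, 4))
    others = [
        (int(rng.integers(0, horizon)), str(rng.choice(["acei", "arb", "ccb", "fdc"])))
        for _ in range(n_other)
    ]
    return {"same_class": same, "others": sorted(others), "observe_end": horizon}


def simulate_categorical_archetypes(
    n: int,
    k: int,
    n_vars: int = 12,
    noise: float = 0.1,
    seed: int = 0,
    levels: tuple[int, ...] = (2, 3),
) -> tuple[pd.DataFrame, np.ndarray]:
    """Categorical table with ``k`` planted archetype profiles.

    Each patient copies one of ``k`` distinct profiles and each variable is
    then resampled uniformly with probability ``noise``.  Profiles are
    rejected until every pair differs on at least half the variables, so the
    planted structure is recoverable.  Returns the table and true labels.
    """
    rng = np.random.default_rng(seed)
    n_levels = np.array([levels[rng.integers(len(levels))] for _ in range(n_vars)])
    profiles = []
    for _ in range(1000):
        cand = np.array([rng.integers(L) for L in n_levels])
        if all((cand != p).mean() >= 0.5 for p in profiles):
            profiles.append(cand)
        if len(profiles) == k:
            break
    if len(profiles) < k:
        raise ConfigurationError("could not place k well-separated profiles")
    labels = np.arange(n) % k
    rng.shuffle(labels)
    data = np.stack([profiles[g].copy() for g in labels])
    flip = rng.random(data.shape) < noise
    resample = np.stack([rng.integers(L, size=n) for L in n_levels], axis=1)
    data[flip] = resample[flip]
    df = pd.DataFrame(
        {f"v{j}": pd.Categorical(data[:, j]) for j in range(n_vars)}
    )
    return df, labels


def simulate_confounded_survival(
    n: int,
    true_hr: float = 2.0,
    confounder_hr: float = 2.5,
    p_exposed_given_z: tuple[float, float] = (0.3, 0.7),
    baseline_rate: float = 1 / 500,
    censor_rate: float = 1 / 2500,
    admin_censor: int = 1080,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-class exponential survival with a binary confounder.

    ``z`` raises both the chance of the non-reference exposure and the event
    hazard, so the crude hazard ratio over-states ``true_hr`` while
    weighting by inverse propensity recovers it (up to non-collapsibility).
    """
    rng = np.random.default_rng(seed)
    z = rng.random(n) < 0.5
    p_a = np.where(z, p_exposed_given_z[1], p_exposed_given_z[0])
    a = rng.random(n) < p_a
    rate = baseline_rate * np.where(a, true_hr, 1.0) * np.where(z, confounder_hr, 1.0)
    t_event = rng.exponential(1.0 / rate)
    t_cens = rng.exponential(1.0 / censor_rate)
    t_cens = np.minimum(t_cens, admin_censor)
    time = np.minimum(t_event, t_cens)
    event = t_event <= t_cens
    return pd.DataFrame(
        {
            "time": np.maximum(time, 0.5),
            "event": event,
            "exposure": np.where(a, "ccb", "bb"),
            "z": pd.Categorical(np.where(z, "1", "0")),
        }
    )


def simulate_piecewise_survival(
    n: int,
    log_hrs: dict[tuple[int, int], float] | None = None,
    baseline_rate: float = 1 / 400,
    censor_rate: float = 1 / 4000,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-group survival with a piecewise-constant group effect.

    Defaults plant an early benefit and a late harm for the non-reference
    group (log-HR +0.7 on days 0-180, 0 on 180-540, -0.7 on 540-1080), so a
    Cox model with interval-specific coefficients should recover the sign
    flip while a proportional model averages it away.
    """
    if log_hrs is None:
        log_hrs = {(0, 180): 0.7, (180, 540): 0.0, (540, 1080): -0.7}
    rng = np.random.default_rng(seed)
    cuts = sorted(log_hrs)
    horizon = cuts[-1][1]
    a = rng.random(n) < 0.5
    times = np.empty(n)
    reached = np.zeros(n, dtype=bool)
    for i in range(n):
        target = rng.exponential(1.0)
        acc, t = 0.0, float(horizon)
        for (lo, hi), beta in sorted(log_hrs.items()):
            h = baseline_rate * math.exp(beta * a[i])
            seg = h * (hi - lo)
            if acc + seg >= target:
                t = lo + (target - acc) / h
                reached[i] = True
                break
            acc += seg
        times[i] = t
    t_cens = np.minimum(rng.exponential(1.0 / censor_rate, size=n), horizon)
    time = np.minimum(times, t_cens)
    event = reached & (times <= t_cens)
    return pd.DataFrame(
        {
            "time": np.maximum(time, 0.5),
            "event": event,
            "exposure": np.where(a, "ccb", "bb"),
        }
    )
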