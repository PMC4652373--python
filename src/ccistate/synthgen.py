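"""Synthetic cohorts with known transition coefficients.

The registry data the methodology was developed on (treatment, entry and
event dates, daily-resolution CCI increments) are not publicly available, so
this module generates cohorts with the same record structure from a fully
known truth: baseline marginals shaped like a three-arm prostate-cancer
cohort (arm sizes, per-arm age and baseline-CCI distributions) and event
histories drawn from the exact discrete-time transition law used everywhere
else in the package.  Every default number here is a synthetic emulation
choice, not an estimate from real data.

Because real inputs arrive as per-disease events with weights in {1, 2, 3,
6}, each simulated per-step CCI jump is decomposed greedily (largest weight
first) into weight-valued events, each dated at a uniformly random day
within its step interval — which also exercises the discretizer's pooling
logic realistically.
"""

from __future__ import annotations

import dataclasses
import datetime
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import poisson

from .cohort import Cohort, StepConfig, TREATMENTS
from .fitting import TransitionParameterSet, make_parameter_set
from .microsim import _CLOCK_NONE, _ETA_CLIP, _Predictor, _clock_code

__all__ = ["SyntheticTruth", "default_truth", "generate_cohort", "km_first_increase", "KMCurve"]

_DAYS_PER_YEAR = 365.25


@dataclasses.dataclass(frozen=True)
class SyntheticTruth:
    """Complete generating law: transition coefficients + baseline marginals."""

    params: TransitionParameterSet
    arm_probs: dict  # treatment -> probability
    age_mean: dict  # treatment -> years
    age_sd: dict
    cci_probs: dict  # treatment -> probabilities over baseline CCI 0/1/2/3
    horizon_steps: int = 130
    step_days: int = 28
    entry_start: datetime.date = datetime.date(2003, 1, 1)
    entry_span_days: int = 3652

    def __post_init__(self) -> None:
        for d in (self.arm_probs, self.age_mean, self.age_sd, self.cci_probs):
            if set(d) != set(TREATMENTS):
                raise ValueError(f"distribution spec must cover arms {TREATMENTS}")
        if not np.isclose(sum(self.arm_probs.values()), 1.0):
            raise ValueError("arm probabilities must sum to 1")
        for a, p in self.cci_probs.items():
            if len(p) != 4 or not np.isclose(sum(p), 1.0):
                raise ValueError(f"baseline-CCI probabilities for {a} must sum to 1")
        if any(self.age_sd[a] < 0 for a in TREATMENTS):
            raise ValueError("age sd must be >= 0")

    @property
    def config(self) -> StepConfig:
        return StepConfig(step_days=self.step_days)

    # -- key-value text serialization (same style as the parameter sets) ----
    def to_yaml(self, path) -> None:
        import yaml

        d = {
            "format": "ccistate-truth-v1",
            "params": self.params.to_dict(),
            "baseline": {
                "arm_probs": {k: float(v) for k, v in self.arm_probs.items()},
                "age_mean": {k: float(v) for k, v in self.age_mean.items()},
                "age_sd": {k: float(v) for k, v in self.age_sd.items()},
                "cci_probs": {k: [float(x) for x in v] for k, v in self.cci_probs.items()},
            },
            "followup": {
                "horizon_steps": int(self.horizon_steps),
                "step_days": int(self.step_days),
                "entry_start": self.entry_start.isoformat(),
                "entry_span_days": int(self.entry_span_days),
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticTruth":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh)
        if d.get("format") != "ccistate-truth-v1":
            raise ValueError("not a ccistate truth file")
        b, f = d["baseline"], d["followup"]
        return cls(
            params=TransitionParameterSet.from_dict(d["params"]),
            arm_probs=b["arm_probs"],
            age_mean=b["age_mean"],
            age_sd=b["age_sd"],
            cci_probs={k: tuple(v) for k, v in b["cci_probs"].items()},
            horizon_steps=f["horizon_steps"],
            step_days=f["step_days"],
            entry_start=datetime.date.fromisoformat(f["entry_start"]),
            entry_span_days=f["entry_span_days"],
        )


def default_truth(horizon_steps: int = 130) -> SyntheticTruth:
    """Default synthetic truth.

    Baseline marginals mimic a three-arm low-risk prostate-cancer cohort
    (active surveillance / prostatectomy / radiotherapy arm shares about
    37/49/14%, arm-specific age means near 61-65 years, 83-90% starting at
    CCI 0).  Transition coefficients are chosen so that, per four-week step
    at age 65 and CCI 0: death probability ~0.1% (about 1.5%/year), change
    probability ~0.4%/step on surveillance with a transient several-fold
    elevation in the months right after prostatectomy/radiotherapy via the
    procedure clocks, mean transformed size ~0.25, and ~7% of changes >= 6.
    """
    params = make_parameter_set(
        death={"intercept": -11.0, "age": 0.065, "cci": 0.25, "age:cci": -0.002},
        change={
            "intercept": -8.0,
            "treatment[RP]": 0.9,
            "treatment[RT]": 0.7,
            "age": 0.038,
            "cci_cat[1]": 0.25,
            "cci_cat[2]": 0.45,
            "cci_cat[3]": 0.6,
            "cci_cat[4+]": 0.8,
            "t_chg[1]": 0.7,
            "t_chg[2-3]": 0.45,
            "t_chg[4-6]": 0.2,
            "t_rp[1]": 1.3,
            "t_rp[2-3]": 0.8,
            "t_rp[4-6]": 0.4,
            "t_rt[1]": 1.0,
            "t_rt[2-3]": 0.7,
            "t_rt[4-6]": 0.35,
            "age:treatment[RP]": -0.012,
            "age:treatment[RT]": -0.008,
        },
        size={
            "intercept": -2.8,
            "treatment[RP]": 0.10,
            "treatment[RT]": 0.12,
            "age": 0.022,
            "cci_cat[1]": 0.08,
            "cci_cat[2]": 0.12,
            "cci_cat[3]": 0.15,
            "cci_cat[4+]": 0.20,
            "t_chg[1]": 0.15,
            "t_chg[2-3]": 0.10,
            "t_chg[4-6]": 0.05,
            "t_rp[1]": 0.12,
            "t_rp[2-3]": 0.08,
            "t_rp[4-6]": 0.04,
            "t_rt[1]": 0.10,
            "t_rt[2-3]": 0.07,
            "t_rt[4-6]": 0.03,
            "age:treatment[RP]": -0.002,
            "age:treatment[RT]": -0.001,
        },
        ge6={
            "intercept": -4.6,
            "treatment[RP]": 0.15,
            "treatment[RT]": 0.20,
            "cci_grp[1]": 0.15,
            "cci_grp[2+]": 0.20,
            "cci": 0.04,
            "t_chg[1]": 0.25,
            "t_chg[2-3]": 0.15,
            "t_chg[4-6]": 0.08,
            "age": 0.03,
        },
    )
    # three-arm shares 7544 : 9959 : 2734
    tot = 7544 + 9959 + 2734
    return SyntheticTruth(
        params=params,
        arm_probs={"AS": 7544 / tot, "RP": 9959 / tot, "RT": 2734 / tot},
        age_mean={"AS": 65.4, "RP": 61.7, "RT": 64.8},
        age_sd={"AS": 6.0, "RP": 5.9, "RT": 5.7},
        cci_probs={
            "AS": _norm4(83.4, 9.7, 4.9, 2.0),
            "RP": _norm4(90.5, 6.0, 2.7, 0.9),
            "RT": _norm4(83.2, 10.8, 4.0, 2.0),
        },
        horizon_steps=horizon_steps,
    )


def _norm4(*w: float) -> tuple[float, ...]:
    s = sum(w)
    return tuple(x / s for x in w)


def decompose_weight(delta: int) -> tuple[int, ...]:
    """Greedy largest-first decomposition of a pooled jump into CCI weights.

    Sizes 1, 2, 3 and 6 are emitted directly; anything else splits into
    {6, 3, 2, 1} parts (e.g. 5 -> (3, 2), 8 -> (6, 2))."""
    d = int(delta)
    if d < 1:
        raise ValueError("change size must be >= 1")
    out = []
    for w in (6, 3, 2, 1):
        while d >= w:
            # avoid leaving a remainder of 0 < r < min weight: impossible
            # here since weight 1 is available
            out.append(w)
            d -= w
    return tuple(out)


def generate_cohort(truth: SyntheticTruth, n_subjects: int, seed: int) -> Cohort:
    """Generate a cohort of ``n_subjects`` subject records from the truth.

    Deterministic given the seed.  Returns a :class:`~ccistate.cohort.Cohort`
    (use ``.to_records()`` for :class:`SubjectRecord` objects, ``.to_csv()``
    for the two-file external interface).
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    ss = np.random.SeedSequence(seed)
    rng, rng_days = (np.random.default_rng(s) for s in ss.spawn(2))
    n = n_subjects
    config = truth.config
    step_days = config.step_days
    pred = _Predictor(truth.params)

    arm_p = np.array([truth.arm_probs[a] for a in TREATMENTS])
    arm = rng.choice(3, size=n, p=arm_p)
    mean = np.array([truth.age_mean[a] for a in TREATMENTS])[arm]
    sd = np.array([truth.age_sd[a] for a in TREATMENTS])[arm]
    age0 = rng.normal(mean, sd)
    cum = np.cumsum([truth.cci_probs[a] for a in TREATMENTS], axis=1)
    cci0 = (rng.random(n)[:, None] > cum[arm]).sum(axis=1)
    entry_off = rng.integers(0, truth.entry_span_days, size=n)

    cci = cci0.astype(np.int64).copy()
    alive = np.ones(n, dtype=bool)
    since = np.full(n, _CLOCK_NONE, dtype=np.int64)
    end_off = np.full(n, truth.horizon_steps * step_days - 1, dtype=np.int64)
    status = np.full(n, "censored", dtype=object)

    ev_sub: list[int] = []
    ev_day: list[int] = []
    ev_w: list[int] = []

    has_rp = arm == 1
    has_rt = arm == 2
    for k in range(truth.horizon_steps):
        age_k = age0 + k * step_days / _DAYS_PER_YEAR
        chg_code = _clock_code(since, config)
        # procedure clocks: procedure at entry; qualifying from step 1 on
        qual = 1 <= k
        rp_code = np.where(has_rp & qual, _clock_code(np.array([max(k, 1)]), config)[0], 3)
        rt_code = np.where(has_rt & qual, _clock_code(np.array([max(k, 1)]), config)[0], 3)

        p_d = expit(np.clip(pred.lp_death(age_k, cci), -_ETA_CLIP, _ETA_CLIP))
        p_c = expit(
            np.clip(
                pred.lp_change(age_k, arm, cci, chg_code, rp_code, rt_code),
                -_ETA_CLIP, _ETA_CLIP,
            )
        )
        mu = np.exp(
            np.clip(
                pred.lp_size(age_k, arm, cci, chg_code, rp_code, rt_code),
                -_ETA_CLIP, _ETA_CLIP,
            )
        )
        p6 = expit(np.clip(pred.lp_ge6(age_k, arm, cci, chg_code), -_ETA_CLIP, _ETA_CLIP))

        u_death = rng.random(n)
        u_change = rng.random(n)
        u_size = rng.random(n)
        u_ge6 = rng.random(n)

        new_dead = alive & (u_death < p_d)
        changed = alive & ~new_dead & (u_change < p_c)
        idx = np.flatnonzero(new_dead)
        if idx.size:
            end_off[idx] = k * step_days + (u_death[idx] / p_d[idx] * step_days).astype(
                np.int64
            ).clip(0, step_days - 1)
            status[idx] = "died"
        idx = np.flatnonzero(changed)
        if idx.size:
            y = poisson.ppf(u_size[idx], mu[idx]).astype(np.int64)
            big = u_ge6[idx] < p6[idx]
            delta = y + np.where(big, 6, 1)
            cci[idx] += delta
            for i, d in zip(idx, delta):
                for w in decompose_weight(int(d)):
                    ev_sub.append(int(i))
                    ev_day.append(k * step_days + int(rng_days.integers(0, step_days)))
                    ev_w.append(w)
        alive &= ~new_dead
        since = np.where(changed, 1, np.minimum(since + 1, _CLOCK_NONE))

    entry = np.datetime64(truth.entry_start, "D") + entry_off
    width = max(7, len(str(n)))
    sids = np.array([f"S{i:0{width}d}" for i in range(n)])
    rp_dates = entry.copy()
    rp_dates[~has_rp] = np.datetime64("NaT")
    rt_dates = entry.copy()
    rt_dates[~has_rt] = np.datetime64("NaT")
    subjects = pd.DataFrame(
        {
            "subject_id": sids,
            "treatment": np.array(TREATMENTS)[arm],
            "entry_date": entry,
            "age_at_entry": age0,
            "baseline_cci": cci0,
            "rp_date": rp_dates,
            "rt_date": rt_dates,
            "end_date": entry + end_off,
            "end_status": status,
        }
    )
    ev_sub_arr = np.array(ev_sub, dtype=np.int64)
    events = pd.DataFrame(
        {
            "subject_id": sids[ev_sub_arr] if len(ev_sub) else np.array([], dtype=str),
            "event_date": (entry[ev_sub_arr] + np.array(ev_day, dtype=np.int64))
            if len(ev_sub)
            else np.array([], dtype="datetime64[D]"),
            "weight": np.array(ev_w, dtype=np.int64),
        }
    )
    events = events.sort_values(["subject_id", "event_date"], kind="stable").reset_index(
        drop=True
    )
    return Cohort(subjects, events)


# ---------------------------------------------------------------------------
# Kaplan-Meier for time to first CCI increase


@dataclasses.dataclass
class KMCurve:
    """Product-limit estimate: step function S(t) = P(T > t) on daily times."""

    times: np.ndarray  # event/censor day offsets (sorted, unique)
    survival: np.ndarray  # S(t) just after each time
    n_at_risk: np.ndarray
    n_events: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t) = P(T > t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        if idx < 0:
            return 1.0
        return float(self.survival[idx])


def km_first_increase(cohort: Cohort) -> KMCurve:
    """Kaplan-Meier curve for time (days since entry) to first CCI increase.

    Death before any increase counts as right-censoring, as does
    administrative end of follow-up."""
    from lifelines import KaplanMeierFitter

    if cohort.n_subjects == 0:
        raise ValueError("empty cohort")
    subs = cohort.subjects
    entry = subs.set_index("subject_id")["entry_date"]
    first_ev = cohort.events.groupby("subject_id")["event_date"].min()
    first_off = (first_ev - entry.reindex(first_ev.index)).dt.days

    duration = (subs["end_date"] - subs["entry_date"]).dt.days.to_numpy(float)
    observed = np.zeros(len(subs), dtype=bool)
    off = first_off.reindex(subs["subject_id"])
    has = off.notna().to_numpy()
    duration[has] = off.to_numpy(float)[has]
    observed[has] = True

    kmf = KaplanMeierFitter()
    kmf.fit(duration, event_observed=observed)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(float)
    surv = sf.iloc[:, 0].to_numpy(float)
    ev_table = kmf.event_table
    return KMCurve(
        times=times,
        survival=surv,
        n_at_risk=ev_table["at_risk"].to_numpy(float),
        n_events=ev_table["observed"].to_numpy(float),
    )
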