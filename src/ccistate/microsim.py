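"""Forward simulation of CCI trajectories and state-occupancy curves.

Given a :class:`~ccistate.fitting.TransitionParameterSet` and a cohort
profile (treatment, age at start, initial CCI), each subject advances in
discrete steps: a death draw (model 1), then — if alive — a change draw
(model 2), then — if changed — a Poisson size draw (model 3a) and a
Bernoulli >=6 draw (model 3b), giving a CCI jump ``y + 1`` or ``y + 6``.
Age advances deterministically; the change clock resets on every change and
saturates in the ">6/none" category.

Two engines compute occupancy:

* :func:`simulate_cohort` — Monte-Carlo microsimulation.  All randomness is
  drawn as per-step uniform vectors and mapped through inverse CDFs, so the
  stream consumed is independent of the coefficient values; with a common
  seed, runs under perturbed coefficients are coupled (common random
  numbers), which the unscented-transform intervals rely on.
* :func:`exact_occupancy` — exact forward propagation over the finite
  expanded state space (CCI level x change-clock value) once CCI is capped;
  probability pushed beyond the cap accumulates in an absorbing overflow
  state reported separately.  This is the verification oracle for the
  simulator.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import poisson

from .cohort import StepConfig, TREATMENTS
from .fitting import CHANGE_TERMS, FittedModel, GE6_TERMS, TransitionParameterSet

__all__ = [
    "Profile",
    "OccupancyCurve",
    "simulate_cohort",
    "exact_occupancy",
    "occupancy_functional",
    "contrast",
    "model_implied_first_increase",
]

_DAYS_PER_YEAR = 365.25
_ETA_CLIP = 30.0

#: change-clock value used for "no previous event" (any value > last break).
_CLOCK_NONE = 7


@dataclasses.dataclass(frozen=True)
class Profile:
    """A pre-defined cohort profile: treatment, age and CCI at start.

    ``rp_at_start``/``rt_at_start`` mark whether the procedure happened at
    follow-up start (so its clock starts ticking); they default to matching
    the treatment arm.
    """

    treatment: str
    age_at_start: float
    initial_cci: int = 0
    rp_at_start: Optional[bool] = None
    rt_at_start: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if self.initial_cci < 0:
            raise ValueError("initial_cci must be >= 0")
        if self.rp_at_start is None:
            object.__setattr__(self, "rp_at_start", self.treatment == "RP")
        if self.rt_at_start is None:
            object.__setattr__(self, "rt_at_start", self.treatment == "RT")


@dataclasses.dataclass
class OccupancyCurve:
    """Per-step probability mass over states {CCI levels} + dead (+ overflow).

    Index ``k`` of every array is the state distribution at time ``k`` steps
    after start (``k = 0`` is the degenerate initial distribution); a curve
    over ``n`` steps has ``n + 1`` entries.
    """

    initial_cci: int
    cci_levels: np.ndarray  # sorted ints
    probs: np.ndarray  # (n_steps+1, len(cci_levels)) alive mass per level
    dead: np.ndarray  # (n_steps+1,)
    overflow: Optional[np.ndarray] = None  # oracle only: mass beyond the cap

    @property
    def n_steps(self) -> int:
        return self.probs.shape[0] - 1

    def alive(self, step: int) -> float:
        return float(self.probs[step].sum())

    def mass(self, step: int, state) -> float:
        if state == "dead":
            return float(self.dead[step])
        if state == "overflow":
            return 0.0 if self.overflow is None else float(self.overflow[step])
        idx = np.searchsorted(self.cci_levels, int(state))
        if idx >= len(self.cci_levels) or self.cci_levels[idx] != int(state):
            return 0.0
        return float(self.probs[step, idx])

    def validate(self, atol: float = 1e-9) -> None:
        total = self.probs.sum(axis=1) + self.dead
        if self.overflow is not None:
            total = total + self.overflow
        if not np.allclose(total, 1.0, atol=atol):
            raise AssertionError("occupancy masses do not sum to 1")
        if np.any(np.diff(self.dead) < -atol):
            raise AssertionError("dead mass must be non-decreasing")
        below = self.cci_levels < self.initial_cci
        if below.any() and self.probs[:, below].any():
            raise AssertionError("mass below the initial CCI level")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k in range(self.n_steps + 1):
            for j, v in enumerate(self.cci_levels):
                rows.append((k, str(int(v)), self.probs[k, j]))
            rows.append((k, "dead", self.dead[k]))
            if self.overflow is not None:
                rows.append((k, "overflow", self.overflow[k]))
        return pd.DataFrame(rows, columns=["step", "state", "probability"])


# ---------------------------------------------------------------------------
# fast linear predictors from coefficient lookups


class _Predictor:
    """Pre-extracted coefficient tables for vectorized linear predictors."""

    def __init__(self, params: TransitionParameterSet):
        d = params.death
        self.d0 = d.coef("intercept")
        self.d_age = d.coef("age")
        self.d_cci = d.coef("cci")
        self.d_int = d.coef("age:cci")

        def tables(m: FittedModel):
            trt = np.array([0.0, m.coef("treatment[RP]"), m.coef("treatment[RT]")])
            ccic = np.array([0.0] + [m.coef(f"cci_cat[{v}]") for v in ("1", "2", "3", "4+")])
            clk = lambda p: np.array(
                [m.coef(f"{p}[1]"), m.coef(f"{p}[2-3]"), m.coef(f"{p}[4-6]"), 0.0]
            )
            atrt = np.array(
                [0.0, m.coef("age:treatment[RP]"), m.coef("age:treatment[RT]")]
            )
            return (
                m.coef("intercept"), m.coef("age"), trt, ccic,
                clk("t_chg"), clk("t_rp"), clk("t_rt"), atrt,
            )

        self.change = tables(params.change)
        self.size = tables(params.size)
        g = params.ge6
        self.g0 = g.coef("intercept")
        self.g_trt = np.array([0.0, g.coef("treatment[RP]"), g.coef("treatment[RT]")])
        self.g_c1 = g.coef("cci_grp[1]")
        self.g_c2 = g.coef("cci_grp[2+]")
        self.g_lin = g.coef("cci")
        self.g_clk = np.array(
            [g.coef("t_chg[1]"), g.coef("t_chg[2-3]"), g.coef("t_chg[4-6]"), 0.0]
        )
        self.g_age = g.coef("age")

    def lp_death(self, age, cci):
        return self.d0 + self.d_age * age + (self.d_cci + self.d_int * age) * cci

    @staticmethod
    def _lp_19(tab, age, trt_code, cci, chg_code, rp_code, rt_code):
        b0, b_age, trt, ccic, chg, rp, rt, atrt = tab
        lp = (
            b0
            + b_age * age
            + trt[trt_code]
            + ccic[np.minimum(cci, 4)]
            + chg[chg_code]
            + rp[rp_code]
            + rt[rt_code]
            + atrt[trt_code] * age
        )
        return lp

    def lp_change(self, *args):
        return self._lp_19(self.change, *args)

    def lp_size(self, *args):
        return self._lp_19(self.size, *args)

    def lp_ge6(self, age, trt_code, cci, chg_code):
        return (
            self.g0
            + self.g_trt[trt_code]
            + self.g_c1 * (cci == 1)
            + self.g_c2 * (cci >= 2)
            + self.g_lin * cci
            + self.g_clk[chg_code]
            + self.g_age * age
        )


def _clock_code(since, config: StepConfig):
    """Map clock values (>= last break + 1 meaning '>6/none') to category codes."""
    b = config.category_breaks
    return np.digitize(since, [b[0] + 1, b[1] + 1, b[2] + 1])


def _proc_clock_code(k: int, active: bool, config: StepConfig) -> int:
    """Deterministic RP/RT clock code at step k for a procedure at start."""
    if not active or k < 1:
        return 3  # ">6/none"
    return int(_clock_code(np.array([k]), config)[0])


# ---------------------------------------------------------------------------
# Monte-Carlo engine


def simulate_cohort(
    params: TransitionParameterSet,
    profile: Profile,
    n_subjects: int,
    n_steps: int,
    seed: int,
    *,
    cci_cap: int = 100,
    config: StepConfig = StepConfig(),
    return_trajectories: bool = False,
):
    """Microsimulate ``n_subjects`` trajectories; return an :class:`OccupancyCurve`.

    Identical seed and inputs give bit-identical output.  With
    ``return_trajectories=True`` also returns the (n_subjects, n_steps+1)
    integer state matrix (CCI level, or -1 once dead).
    """
    if n_subjects < 1 or n_steps < 1:
        raise ValueError("n_subjects and n_steps must be >= 1")
    pred = _Predictor(params)
    rng = np.random.default_rng(seed)
    trt_code = TREATMENTS.index(profile.treatment)
    n = n_subjects

    cci = np.full(n, profile.initial_cci, dtype=np.int64)
    alive = np.ones(n, dtype=bool)
    since = np.full(n, _CLOCK_NONE, dtype=np.int64)  # "no previous change"

    counts = np.zeros((n_steps + 1, cci_cap + 1), dtype=np.int64)
    dead_counts = np.zeros(n_steps + 1, dtype=np.int64)
    counts[0] = np.bincount(cci, minlength=cci_cap + 1)
    traj = None
    if return_trajectories:
        traj = np.full((n, n_steps + 1), -1, dtype=np.int32)
        traj[:, 0] = cci

    for k in range(n_steps):
        age_k = profile.age_at_start + k * config.step_days / _DAYS_PER_YEAR
        chg_code = _clock_code(since, config)
        rp_code = _proc_clock_code(k, profile.rp_at_start, config)
        rt_code = _proc_clock_code(k, profile.rt_at_start, config)

        p_d = expit(np.clip(pred.lp_death(age_k, cci), -_ETA_CLIP, _ETA_CLIP))
        p_c = expit(
            np.clip(
                pred.lp_change(age_k, trt_code, cci, chg_code, rp_code, rt_code),
                -_ETA_CLIP, _ETA_CLIP,
            )
        )
        mu = np.exp(
            np.clip(
                pred.lp_size(age_k, trt_code, cci, chg_code, rp_code, rt_code),
                -_ETA_CLIP, _ETA_CLIP,
            )
        )
        p6 = expit(np.clip(pred.lp_ge6(age_k, trt_code, cci, chg_code), -_ETA_CLIP, _ETA_CLIP))

        # fixed stream consumption: 4 uniform vectors per step
        u_death = rng.random(n)
        u_change = rng.random(n)
        u_size = rng.random(n)
        u_ge6 = rng.random(n)

        new_dead = alive & (u_death < p_d)
        changed = alive & ~new_dead & (u_change < p_c)
        idx = np.flatnonzero(changed)
        if idx.size:
            y = poisson.ppf(u_size[idx], mu[idx]).astype(np.int64)
            big = u_ge6[idx] < p6[idx]
            cci[idx] += y + np.where(big, 6, 1)
            if int(cci[idx].max()) > cci_cap:
                raise ValueError(
                    f"simulated CCI exceeded the safety cap {cci_cap}; "
                    "check the size-model coefficients or raise cci_cap"
                )
        alive &= ~new_dead
        since = np.where(changed, 1, np.minimum(since + 1, _CLOCK_NONE))

        counts[k + 1] = np.bincount(cci[alive], minlength=cci_cap + 1)
        dead_counts[k + 1] = n - int(alive.sum())
        if return_trajectories:
            traj[alive, k + 1] = cci[alive]

    top = int(max(cci.max(), profile.initial_cci))
    levels = np.arange(profile.initial_cci, top + 1)
    curve = OccupancyCurve(
        initial_cci=profile.initial_cci,
        cci_levels=levels,
        probs=counts[:, profile.initial_cci : top + 1] / n,
        dead=dead_counts / n,
    )
    curve.validate()
    return (curve, traj) if return_trajectories else curve


# ---------------------------------------------------------------------------
# exact forward-propagation oracle


def exact_occupancy(
    params: TransitionParameterSet,
    profile: Profile,
    n_steps: int,
    cci_cap: int,
    *,
    config: StepConfig = StepConfig(),
    max_states: int = 100_000,
) -> OccupancyCurve:
    """Exact occupancy by forward propagation over (CCI level, change clock).

    The change clock saturates at {1..6, >6/none}, so with CCI capped at
    ``cci_cap`` the expanded alive state space is finite; mass that would
    jump beyond the cap is routed to an absorbing overflow state and
    reported separately.
    """
    if (cci_cap + 1) * _CLOCK_NONE > max_states:
        raise ValueError("cci_cap too large for the configured state budget")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    pred = _Predictor(params)
    trt_code = TREATMENTS.index(profile.treatment)
    if profile.initial_cci > cci_cap:
        raise ValueError("initial CCI above cci_cap")

    # D[v, c]: alive mass at CCI v with clock value c+1 (c = 6 is ">6/none")
    D = np.zeros((cci_cap + 1, _CLOCK_NONE))
    D[profile.initial_cci, _CLOCK_NONE - 1] = 1.0
    dead = 0.0
    overflow = 0.0

    probs = np.zeros((n_steps + 1, cci_cap + 1))
    dead_curve = np.zeros(n_steps + 1)
    over_curve = np.zeros(n_steps + 1)
    probs[0] = D.sum(axis=1)

    v_grid = np.arange(cci_cap + 1)
    clock_vals = np.arange(1, _CLOCK_NONE + 1)
    chg_codes = _clock_code(clock_vals, config)  # code per clock value

    for k in range(n_steps):
        age_k = profile.age_at_start + k * config.step_days / _DAYS_PER_YEAR
        rp_code = _proc_clock_code(k, profile.rp_at_start, config)
        rt_code = _proc_clock_code(k, profile.rt_at_start, config)
        p_d = expit(np.clip(pred.lp_death(age_k, v_grid), -_ETA_CLIP, _ETA_CLIP))

        Dn = np.zeros_like(D)
        for ci, (cval, ccode) in enumerate(zip(clock_vals, chg_codes)):
            col = D[:, ci]
            nz = np.flatnonzero(col)
            if not nz.size:
                continue
            v = v_grid[nz]
            m = col[nz]
            dead += float(np.sum(m * p_d[nz]))
            m_alive = m * (1.0 - p_d[nz])
            p_c = expit(
                np.clip(
                    pred.lp_change(age_k, trt_code, v, ccode, rp_code, rt_code),
                    -_ETA_CLIP, _ETA_CLIP,
                )
            )
            mu = np.exp(
                np.clip(
                    pred.lp_size(age_k, trt_code, v, ccode, rp_code, rt_code),
                    -_ETA_CLIP, _ETA_CLIP,
                )
            )
            p6 = expit(
                np.clip(pred.lp_ge6(age_k, trt_code, v, ccode), -_ETA_CLIP, _ETA_CLIP)
            )
            # no change: clock advances (saturating)
            nc_idx = min(cval + 1, _CLOCK_NONE) - 1
            np.add.at(Dn[:, nc_idx], nz, m_alive * (1.0 - p_c))
            # change: distribute over jump sizes; new clock value is 1
            m_change = m_alive * p_c
            for j, vi in enumerate(v):
                if m_change[j] == 0.0:
                    continue
                smax = cci_cap - vi
                if smax >= 1:
                    s = np.arange(1, smax + 1)
                    ps = (1.0 - p6[j]) * poisson.pmf(s - 1, mu[j]) + p6[j] * poisson.pmf(
                        s - 6, mu[j]
                    )
                    Dn[vi + 1 : vi + smax + 1, 0] += m_change[j] * ps
                    overflow += m_change[j] * max(1.0 - float(ps.sum()), 0.0)
                else:
                    overflow += m_change[j]
        D = Dn
        probs[k + 1] = D.sum(axis=1)
        dead_curve[k + 1] = dead
        over_curve[k + 1] = overflow

    curve = OccupancyCurve(
        initial_cci=profile.initial_cci,
        cci_levels=v_grid[profile.initial_cci :],
        probs=probs[:, profile.initial_cci :],
        dead=dead_curve,
        overflow=over_curve,
    )
    curve.validate()
    return curve


# ---------------------------------------------------------------------------
# functionals


def occupancy_functional(curve: OccupancyCurve, step: int, kind: str) -> float:
    """Summaries of an occupancy curve at one step.

    * ``alive_at_initial`` — unconditional probability of being alive and
      still at the initial CCI level.
    * ``stay_initial`` — same, conditional on being alive (NaN if no alive
      mass remains).
    * ``died_or_changed`` — 1 minus ``alive_at_initial``.
    """
    if not (0 <= step <= curve.n_steps):
        raise ValueError(f"step {step} outside curve range 0..{curve.n_steps}")
    at_init = curve.mass(step, curve.initial_cci)
    if kind == "alive_at_initial":
        return at_init
    if kind == "died_or_changed":
        return 1.0 - at_init
    if kind == "stay_initial":
        a = curve.alive(step)
        return at_init / a if a > 0 else float("nan")
    raise ValueError(f"unknown functional kind {kind!r}")


def contrast(curve_a: OccupancyCurve, curve_b: OccupancyCurve, step: int, kind: str) -> float:
    """Difference of a functional between two curves on the same step grid."""
    if curve_a.n_steps != curve_b.n_steps:
        raise ValueError("curves have mismatched step grids")
    return occupancy_functional(curve_a, step, kind) - occupancy_functional(
        curve_b, step, kind
    )


def model_implied_first_increase(
    params: TransitionParameterSet,
    profile: Profile,
    n_steps: int,
    *,
    death: str = "censor",
    config: StepConfig = StepConfig(),
) -> np.ndarray:
    """Exact model-implied survival curve for time to first CCI increase.

    Before the first change the covariate path is deterministic (CCI fixed at
    the initial level, change clock at ">6/none", age and procedure clocks
    advancing with the step index), so the curve is a simple product over
    per-step probabilities.  ``death="censor"`` treats death as
    right-censoring (discrete hazard of change ``(1-p_death) * p_change``
    among those at risk); ``death="composite"`` returns the probability of
    being alive and change-free.
    """
    if death not in ("censor", "composite"):
        raise ValueError("death must be 'censor' or 'composite'")
    pred = _Predictor(params)
    trt_code = TREATMENTS.index(profile.treatment)
    v = np.array([profile.initial_cci])
    S = np.ones(n_steps + 1)
    surv = 1.0
    for k in range(n_steps):
        age_k = profile.age_at_start + k * config.step_days / _DAYS_PER_YEAR
        rp_code = _proc_clock_code(k, profile.rp_at_start, config)
        rt_code = _proc_clock_code(k, profile.rt_at_start, config)
        p_d = float(expit(np.clip(pred.lp_death(age_k, v), -_ETA_CLIP, _ETA_CLIP))[0])
        p_c = float(
            expit(
                np.clip(
                    pred.lp_change(age_k, trt_code, v, 3, rp_code, rt_code),
                    -_ETA_CLIP, _ETA_CLIP,
                )
            )[0]
        )
        if death == "censor":
            surv *= 1.0 - (1.0 - p_d) * p_c
        else:
            surv *= (1.0 - p_d) * (1.0 - p_c)
        S[k + 1] = surv
    return S
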