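"""Transition regressions on the person-period table.

Four models jointly define the discrete-time transition law:

* **death** — logistic; outcome: died during the step; terms: intercept, age,
  CCI (both linear) and their interaction (4 coefficients).
* **change** — logistic, on steps survived; outcome: any CCI change; terms:
  intercept, treatment (ref AS), age, CCI category (ref 0), the three clocks
  (time since CCI change / RP / RT; ref >6/none), age x treatment
  (19 coefficients under reference coding).
* **size** — log-link Poisson, on steps with a change; outcome: the
  transformed change size (see :func:`encode_change`); same 19-term design.
* **ge6** — logistic, on steps with a change; outcome: change >= 6; terms:
  intercept, treatment, CCI as 0/1/2+ dummies plus a linear term, the change
  clock, age (10 coefficients).

The change-size transform maps an observed jump ``c >= 1`` to a non-negative
count suited to the Poisson model: sizes >= 6 (driven by weight-6 diseases)
are shifted by 6, all others by 1, with a Bernoulli indicator recording which
shift applies.  :func:`decode_change` inverts it.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Callable, Optional, Union

import numpy as np
import pandas as pd
import scipy.linalg
import yaml

from ._glmfit import FitError, fit_glm
from .cohort import CCI_LABELS, CLOCK_LABELS, TREATMENTS

__all__ = [
    "FitError",
    "FittedModel",
    "TransitionParameterSet",
    "encode_change",
    "decode_change",
    "fit_death_model",
    "fit_change_model",
    "fit_size_model",
    "fit_ge6_model",
    "fit_transition_models",
    "change_size_histogram",
    "DEATH_TERMS",
    "CHANGE_TERMS",
    "GE6_TERMS",
]

# ---------------------------------------------------------------------------
# change-size transform


def encode_change(change_size: int) -> tuple[int, bool]:
    """Transform an observed CCI jump into (transformed_size, ge6).

    All changes are decreased by 1, except changes of size >= 6, which are
    decreased by 6; the boolean records which shift was applied, so the
    smallest transformed outcome 0 corresponds to a change of 1 or 6.
    """
    c = int(change_size)
    if c < 1:
        raise ValueError(f"a recorded CCI change must be >= 1, got {change_size}")
    ge6 = c >= 6
    return c - (6 if ge6 else 1), ge6


def decode_change(transformed_size: int, ge6: bool) -> int:
    """Invert :func:`encode_change`: add back 6 if ge6 else 1."""
    t = int(transformed_size)
    if t < 0:
        raise ValueError(f"transformed size must be >= 0, got {transformed_size}")
    return t + (6 if ge6 else 1)


# ---------------------------------------------------------------------------
# term specifications (reference coding; order is part of the contract)

DEATH_TERMS = ("intercept", "age", "cci", "age:cci")

CHANGE_TERMS = (
    "intercept",
    "treatment[RP]",
    "treatment[RT]",
    "age",
    "cci_cat[1]",
    "cci_cat[2]",
    "cci_cat[3]",
    "cci_cat[4+]",
    "t_chg[1]",
    "t_chg[2-3]",
    "t_chg[4-6]",
    "t_rp[1]",
    "t_rp[2-3]",
    "t_rp[4-6]",
    "t_rt[1]",
    "t_rt[2-3]",
    "t_rt[4-6]",
    "age:treatment[RP]",
    "age:treatment[RT]",
)

GE6_TERMS = (
    "intercept",
    "treatment[RP]",
    "treatment[RT]",
    "cci_grp[1]",
    "cci_grp[2+]",
    "cci",
    "t_chg[1]",
    "t_chg[2-3]",
    "t_chg[4-6]",
    "age",
)

_MODEL_TERMS = {"death": DEATH_TERMS, "change": CHANGE_TERMS, "size": CHANGE_TERMS, "ge6": GE6_TERMS}
_MODEL_FAMILY = {"death": "logistic", "change": "logistic", "size": "poisson_log", "ge6": "logistic"}


@dataclasses.dataclass(frozen=True)
class FittedModel:
    """A fitted (or specified) regression: terms, coefficients, covariance."""

    family: str  # "logistic" | "poisson_log"
    term_names: tuple[str, ...]
    coefficients: np.ndarray
    covariance: np.ndarray
    n_obs: int = 0
    dropped_terms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        coefs = np.asarray(self.coefficients, dtype=float)
        cov = np.asarray(self.covariance, dtype=float)
        object.__setattr__(self, "coefficients", coefs)
        object.__setattr__(self, "covariance", cov)
        p = len(self.term_names)
        if coefs.shape != (p,):
            raise ValueError("coefficient length does not match term_names")
        if cov.shape != (p, p):
            raise ValueError("covariance dimensions do not match coefficients")
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError("covariance must be symmetric (tolerance 1e-10)")

    @property
    def n_coefficients(self) -> int:
        return len(self.coefficients)

    def coef(self, name: str, default: float = 0.0) -> float:
        """Coefficient by term name; dropped/absent terms count as 0."""
        try:
            return float(self.coefficients[self.term_names.index(name)])
        except ValueError:
            return default

    def as_series(self) -> pd.Series:
        return pd.Series(self.coefficients, index=list(self.term_names))

    @classmethod
    def from_terms(
        cls,
        kind: str,
        coefs: dict[str, float],
        covariance: Optional[np.ndarray] = None,
        n_obs: int = 0,
    ) -> "FittedModel":
        """Build a model of the given kind ("death"/"change"/"size"/"ge6")
        from a name->value mapping; unnamed terms are 0."""
        terms = _MODEL_TERMS[kind]
        unknown = set(coefs) - set(terms)
        if unknown:
            raise ValueError(f"unknown terms for {kind} model: {sorted(unknown)}")
        vec = np.array([coefs.get(t, 0.0) for t in terms])
        cov = np.zeros((len(terms), len(terms))) if covariance is None else covariance
        return cls(_MODEL_FAMILY[kind], terms, vec, cov, n_obs)


@dataclasses.dataclass(frozen=True)
class TransitionParameterSet:
    """The four fitted models, stackable into one joint coefficient vector
    with block-diagonal covariance (models fitted independently)."""

    death: FittedModel
    change: FittedModel
    size: FittedModel
    ge6: FittedModel

    _ORDER = ("death", "change", "size", "ge6")

    @property
    def models(self) -> tuple[FittedModel, ...]:
        return tuple(getattr(self, k) for k in self._ORDER)

    @property
    def n_coefficients(self) -> int:
        return sum(m.n_coefficients for m in self.models)

    @property
    def stacked_coefficients(self) -> np.ndarray:
        return np.concatenate([m.coefficients for m in self.models])

    @property
    def stacked_covariance(self) -> np.ndarray:
        return scipy.linalg.block_diag(*[m.covariance for m in self.models])

    @property
    def stacked_names(self) -> list[str]:
        return [f"{k}:{t}" for k in self._ORDER for t in getattr(self, k).term_names]

    def with_stacked_coefficients(self, theta: np.ndarray) -> "TransitionParameterSet":
        """A copy with coefficients replaced by slices of ``theta``
        (covariances and term specs unchanged)."""
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_coefficients,):
            raise ValueError("stacked coefficient vector has wrong length")
        out = {}
        pos = 0
        for k, m in zip(self._ORDER, self.models):
            out[k] = dataclasses.replace(m, coefficients=theta[pos : pos + m.n_coefficients])
            pos += m.n_coefficients
        return TransitionParameterSet(**out)

    # -- key-value text serialization --------------------------------------
    def to_dict(self) -> dict:
        return {
            "format": "ccistate-params-v1",
            "models": {
                k: {
                    "family": m.family,
                    "n_obs": int(m.n_obs),
                    "terms": list(m.term_names),
                    "dropped_terms": list(m.dropped_terms),
                    "coefficients": [float(v) for v in m.coefficients],
                    "covariance": [[float(v) for v in row] for row in m.covariance],
                }
                for k, m in zip(self._ORDER, self.models)
            },
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "TransitionParameterSet":
        if d.get("format") != "ccistate-params-v1":
            raise ValueError("not a ccistate parameter file")
        kw = {}
        for k in cls._ORDER:
            m = d["models"][k]
            kw[k] = FittedModel(
                family=m["family"],
                term_names=tuple(m["terms"]),
                coefficients=np.array(m["coefficients"], dtype=float),
                covariance=np.array(m["covariance"], dtype=float),
                n_obs=int(m.get("n_obs", 0)),
                dropped_terms=tuple(m.get("dropped_terms", ())),
            )
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "TransitionParameterSet":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def make_parameter_set(
    death: dict[str, float],
    change: dict[str, float],
    size: dict[str, float],
    ge6: dict[str, float],
) -> TransitionParameterSet:
    """Convenience constructor from name->coefficient mappings (zero covariance)."""
    return TransitionParameterSet(
        death=FittedModel.from_terms("death", death),
        change=FittedModel.from_terms("change", change),
        size=FittedModel.from_terms("size", size),
        ge6=FittedModel.from_terms("ge6", ge6),
    )


# ---------------------------------------------------------------------------
# design matrices


def _cat_codes(col: pd.Series, categories) -> np.ndarray:
    if isinstance(col.dtype, pd.CategoricalDtype):
        codes = col.cat.codes.to_numpy()
    else:
        codes = pd.Categorical(col, categories=categories).codes
    if (codes < 0).any():
        raise ValueError(f"column has values outside categories {categories}")
    return codes


def build_death_design(df: pd.DataFrame) -> np.ndarray:
    age = df["age"].to_numpy(float)
    cci = df["cci"].to_numpy(float)
    X = np.empty((len(df), 4))
    X[:, 0] = 1.0
    X[:, 1] = age
    X[:, 2] = cci
    X[:, 3] = age * cci
    return X


def build_change_design(df: pd.DataFrame) -> np.ndarray:
    n = len(df)
    age = df["age"].to_numpy(float)
    trt = _cat_codes(df["treatment"], TREATMENTS)
    ccic = _cat_codes(df["cci_cat"], CCI_LABELS)
    tch = _cat_codes(df["t_since_change_cat"], CLOCK_LABELS)
    trp = _cat_codes(df["t_since_rp_cat"], CLOCK_LABELS)
    trtc = _cat_codes(df["t_since_rt_cat"], CLOCK_LABELS)
    X = np.zeros((n, 19))
    X[:, 0] = 1.0
    X[:, 1] = trt == 1
    X[:, 2] = trt == 2
    X[:, 3] = age
    for j, lev in enumerate((1, 2, 3, 4)):
        X[:, 4 + j] = ccic == lev
    for j in range(3):  # clock categories "1","2-3","4-6" (ref ">6/none")
        X[:, 8 + j] = tch == j
        X[:, 11 + j] = trp == j
        X[:, 14 + j] = trtc == j
    X[:, 17] = age * (trt == 1)
    X[:, 18] = age * (trt == 2)
    return X


def build_ge6_design(df: pd.DataFrame) -> np.ndarray:
    n = len(df)
    age = df["age"].to_numpy(float)
    cci = df["cci"].to_numpy(float)
    trt = _cat_codes(df["treatment"], TREATMENTS)
    tch = _cat_codes(df["t_since_change_cat"], CLOCK_LABELS)
    X = np.zeros((n, 10))
    X[:, 0] = 1.0
    X[:, 1] = trt == 1
    X[:, 2] = trt == 2
    X[:, 3] = cci == 1
    X[:, 4] = cci >= 2
    X[:, 5] = cci
    for j in range(3):
        X[:, 6 + j] = tch == j
    X[:, 9] = age
    return X


_BUILDERS: dict[str, Callable[[pd.DataFrame], np.ndarray]] = {
    "death": build_death_design,
    "change": build_change_design,
    "size": build_change_design,
    "ge6": build_ge6_design,
}


def design_rank(X: np.ndarray) -> int:
    """Numerical rank of a design matrix (via its Gram matrix)."""
    return int(np.linalg.matrix_rank(X.T @ X))


def _fit(kind: str, df: pd.DataFrame, y: np.ndarray, tol: float) -> FittedModel:
    terms = _MODEL_TERMS[kind]
    X = _BUILDERS[kind](df)
    # drop structurally empty dummy columns (all-zero) with a warning so that
    # reduced synthetic scenarios remain fittable
    nonzero = np.array([np.any(X[:, j]) for j in range(X.shape[1])])
    dropped = tuple(t for t, nz in zip(terms, nonzero) if not nz)
    kept_terms = tuple(t for t, nz in zip(terms, nonzero) if nz)
    if dropped:
        warnings.warn(
            f"{kind} model: dropping empty design columns {dropped}", stacklevel=3
        )
        X = X[:, nonzero]
    family = "binomial" if _MODEL_FAMILY[kind] == "logistic" else "poisson"
    res = fit_glm(X, y, family, tol=tol, model_name=f"{kind} model")
    return FittedModel(
        family=_MODEL_FAMILY[kind],
        term_names=kept_terms,
        coefficients=res.coefficients,
        covariance=res.covariance,
        n_obs=res.n_obs,
        dropped_terms=dropped,
    )


def fit_death_model(steps: pd.DataFrame, tol: float = 1e-8) -> FittedModel:
    """Step-1 logistic model for vital status at the end of each step."""
    y = steps["died"].to_numpy(bool)
    if y.all() or not y.any():
        raise FitError("death model: outcome takes a single value (separation)")
    return _fit("death", steps, y.astype(float), tol)


def fit_change_model(steps: pd.DataFrame, tol: float = 1e-8) -> FittedModel:
    """Step-2 logistic model for any CCI change, on steps survived."""
    alive = steps[~steps["died"].to_numpy(bool)]
    y = alive["changed"].to_numpy(bool)
    if y.all() or not y.any():
        raise FitError("change model: outcome takes a single value (separation)")
    return _fit("change", alive, y.astype(float), tol)


def fit_size_model(steps: pd.DataFrame, tol: float = 1e-8) -> FittedModel:
    """Step-3a Poisson model for the transformed change size, on changed steps."""
    changed = steps[steps["changed"].to_numpy(bool)]
    if len(changed) == 0:
        raise FitError("size model: no changed rows")
    y = changed["transformed_size"].to_numpy(dtype=float)
    if (y < 0).any():
        raise ValueError("transformed sizes must be >= 0")
    if not (y > 0).any():
        raise FitError(
            "size model: all transformed sizes are 0 (every change of size 1 or 6); "
            "the Poisson intercept is unbounded below"
        )
    return _fit("size", changed, y, tol)


def fit_ge6_model(steps: pd.DataFrame, tol: float = 1e-8) -> FittedModel:
    """Step-3b logistic model for whether a change is >= 6, on changed steps."""
    changed = steps[steps["changed"].to_numpy(bool)]
    if len(changed) == 0:
        raise FitError("ge6 model: no changed rows")
    y = changed["ge6"].to_numpy(dtype=bool)
    if not y.any():
        raise FitError(
            "ge6 model: no changes >= 6 observed; check the generator's weight-6 rate"
        )
    if y.all():
        raise FitError("ge6 model: all changes are >= 6 (separation)")
    return _fit("ge6", changed, y.astype(float), tol)


def fit_transition_models(steps: pd.DataFrame, tol: float = 1e-8) -> TransitionParameterSet:
    """Fit all four transition models on one person-period table."""
    return TransitionParameterSet(
        death=fit_death_model(steps, tol),
        change=fit_change_model(steps, tol),
        size=fit_size_model(steps, tol),
        ge6=fit_ge6_model(steps, tol),
    )


# ---------------------------------------------------------------------------
# diagnostic: observed vs model-implied change-size distribution


def change_size_histogram(
    steps: pd.DataFrame,
    size_model: FittedModel,
    ge6_model: FittedModel,
    max_size: Optional[int] = None,
) -> pd.DataFrame:
    """Observed vs model-implied distribution of CCI change sizes.

    The implied distribution is the mixture of the two shifted Poissons,
    averaged over the changed rows' covariates and renormalized over the
    reported support (truncation correction).
    """
    from scipy.stats import poisson

    changed = steps[steps["changed"].to_numpy(bool)]
    if len(changed) == 0:
        raise ValueError("no changed rows")
    sizes = changed["change_size"].to_numpy(dtype=int)
    if max_size is None:
        max_size = max(int(sizes.max()) + 4, 10)

    Xs = build_change_design(changed)
    keep_s = [CHANGE_TERMS.index(t) for t in size_model.term_names]
    mu = np.exp(np.clip(Xs[:, keep_s] @ size_model.coefficients, -30, 30))
    Xg = build_ge6_design(changed)
    keep_g = [GE6_TERMS.index(t) for t in ge6_model.term_names]
    p6 = 1.0 / (1.0 + np.exp(-np.clip(Xg[:, keep_g] @ ge6_model.coefficients, -30, 30)))

    support = np.arange(1, max_size + 1)
    implied = np.empty(len(support))
    for i, s in enumerate(support):
        small = poisson.pmf(s - 1, mu) if s - 1 >= 0 else 0.0
        large = poisson.pmf(s - 6, mu) if s - 6 >= 0 else 0.0
        implied[i] = float(np.mean((1 - p6) * small + p6 * large))
    implied /= implied.sum()

    observed = np.bincount(sizes, minlength=max_size + 1)[1 : max_size + 1]
    return pd.DataFrame(
        {
            "size": support,
            "observed_count": observed,
            "observed_freq": observed / observed.sum(),
            "implied_prob": implied,
        }
    )
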