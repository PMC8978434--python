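"""Data-generating process for the treatment-effect-modification simulation.

Each simulated cohort contains three standard-normal confounders (X1-X3),
three binary confounders (X4-X6), a binary effect moderator M, a binary
treatment T assigned with probability given by a logistic model, and a
continuous outcome Y from a linear model.  The moderator can modify the
effect of X1 on treatment receipt (``alpha_mx1``) and/or on the outcome
(``beta_mx1``); when either is non-zero and unaccounted for, downstream
adjustment methods can return biased subgroup and interaction effects.

Treatment-assignment model (logit scale)::

    logit(p) = a0 + aM*M + aMX1*M*X1 + sum_j aXj*Xj + e1,   e1 ~ N(0, sigma_e1)

Outcome model::

    Y ~ N(b0 + bT*T + bM*M + bTM*T*M + bMX1*M*X1 + sum_j bXj*Xj, sigma_y)

The latent noise ``e1`` is part of the generating truth only; estimation
never observes it, so every fitted propensity model is (mildly) misspecified
in the same way as in a real observational study.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = ["DGPCoefficients", "Cohort", "treatment_probability", "outcome_mean", "generate_cohort"]

_X_COLS = ("X1", "X2", "X3", "X4", "X5", "X6")


@dataclass(frozen=True)
class DGPCoefficients:
    """Coefficients, prevalences and noise scales of the generating models.

    Defaults are the base scenario of the simulation study: a realistic
    observational cohort of n=1000 with moderate confounding on both the
    treatment and outcome scales and no moderator-confounder interaction
    (``alpha_mx1 = beta_mx1 = 0``).
    """

    alpha0: float = 0.1
    alpha_m: float = 0.3
    alpha_mx1: float = 0.0
    alpha_x: tuple[float, ...] = (0.3, 0.2, -0.1, 0.4, -0.2, 0.3)
    beta0: float = 0.25
    beta_t: float = 1.5
    beta_m: float = 0.5
    beta_tm: float = 0.3
    beta_mx1: float = 0.0
    beta_x: tuple[float, ...] = (0.5, 0.5, -0.3, 1.0, 0.6, 1.0)
    prev_m: float = 0.5
    prev_x456: tuple[float, float, float] = (0.1, 0.25, 0.5)
    sigma_e1: float = 0.2  # SD of latent noise in the treatment log-odds
    sigma_y: float = 0.2   # SD of the outcome noise
    n: int = 1000

    def __post_init__(self) -> None:
        object.__setattr__(self, "alpha_x", tuple(float(v) for v in self.alpha_x))
        object.__setattr__(self, "beta_x", tuple(float(v) for v in self.beta_x))
        object.__setattr__(self, "prev_x456", tuple(float(v) for v in self.prev_x456))
        if len(self.alpha_x) != 6 or len(self.beta_x) != 6:
            raise ValueError("alpha_x and beta_x must each have 6 entries (X1..X6)")
        if len(self.prev_x456) != 3:
            raise ValueError("prev_x456 must have 3 entries (X4, X5, X6)")
        for p in (self.prev_m, *self.prev_x456):
            if not 0.0 < p < 1.0:
                raise ValueError(f"prevalence {p} must lie strictly in (0, 1)")
        if self.n < 2:
            raise ValueError("cohort size n must be at least 2")
        if self.sigma_e1 < 0 or self.sigma_y < 0:
            raise ValueError("noise scales must be nonnegative")
        for name in ("alpha0", "alpha_m", "alpha_mx1", "beta0", "beta_t",
                     "beta_m", "beta_tm", "beta_mx1"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not (np.all(np.isfinite(self.alpha_x)) and np.all(np.isfinite(self.beta_x))):
            raise ValueError("coefficient vectors must be finite")

    @property
    def true_effect_m0(self) -> float:
        """True treatment effect in the M=0 subgroup."""
        return self.beta_t

    @property
    def true_effect_m1(self) -> float:
        """True treatment effect in the M=1 subgroup."""
        return self.beta_t + self.beta_tm

    def with_(self, **kwargs) -> "DGPCoefficients":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {
            "alpha0": self.alpha0, "alpha_m": self.alpha_m, "alpha_mx1": self.alpha_mx1,
            "alpha_x": list(self.alpha_x),
            "beta0": self.beta0, "beta_t": self.beta_t, "beta_m": self.beta_m,
            "beta_tm": self.beta_tm, "beta_mx1": self.beta_mx1, "beta_x": list(self.beta_x),
            "prev_m": self.prev_m, "prev_x456": list(self.prev_x456),
            "sigma_e1": self.sigma_e1, "sigma_y": self.sigma_y, "n": self.n,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DGPCoefficients":
        d = dict(d)
        for key in ("alpha_x", "beta_x", "prev_x456"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class Cohort:
    """One simulated dataset: confounders, moderator, treatment and outcome.

    ``p`` is the *true* assignment probability (including the latent noise
    e1); it is carried along for diagnostics but never used by estimators.
    """

    X: np.ndarray            # (n, 6) confounder matrix, columns X1..X6
    M: np.ndarray            # (n,) binary moderator
    p: np.ndarray            # (n,) true treatment probability
    T: np.ndarray            # (n,) binary treatment
    Y: np.ndarray            # (n,) continuous outcome
    coeffs: DGPCoefficients | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        n = len(self.M)
        if not (self.X.shape == (n, 6) and len(self.p) == len(self.T) == len(self.Y) == n):
            raise ValueError("cohort vectors must share one length n; X must be (n, 6)")
        if np.any((self.p <= 0) | (self.p >= 1)):
            raise ValueError("treatment probabilities must lie strictly in (0, 1)")
        for name, v in (("M", self.M), ("T", self.T)):
            if not np.isin(v, (0, 1)).all():
                raise ValueError(f"{name} must be binary")
        if not np.isin(self.X[:, 3:6], (0, 1)).all():
            raise ValueError("X4..X6 must be binary")

    def __len__(self) -> int:
        return len(self.M)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(_X_COLS))
        df["M"] = self.M
        df["p"] = self.p
        df["T"] = self.T
        df["Y"] = self.Y
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, coeffs: DGPCoefficients | None = None) -> "Cohort":
        X = df[list(_X_COLS)].to_numpy(dtype=float)
        return cls(
            X=X,
            M=df["M"].to_numpy(dtype=int),
            p=df["p"].to_numpy(dtype=float),
            T=df["T"].to_numpy(dtype=int),
            Y=df["Y"].to_numpy(dtype=float),
            coeffs=coeffs,
        )


def _as_matrix(x: Sequence | np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[1] != 6:
        raise ValueError("expected 6 confounder columns X1..X6")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite covariate value")
    return x


def treatment_probability(coeffs: DGPCoefficients, x, m, noise=0.0) -> np.ndarray:
    """True probability of treatment given covariates and latent noise.

    Inverse-logit of ``a0 + aM*M + aMX1*M*X1 + sum_j aXj*Xj + noise``.
    Accepts a single covariate row or stacked rows; returns an array of
    probabilities strictly inside (0, 1).
    """
    x = _as_matrix(x)
    m = np.asarray(m, dtype=float).ravel()
    noise = np.broadcast_to(np.asarray(noise, dtype=float), m.shape)
    if not (np.all(np.isfinite(m)) and np.all(np.isfinite(noise))):
        raise ValueError("non-finite covariate or noise value")
    logit = (
        coeffs.alpha0
        + coeffs.alpha_m * m
        + coeffs.alpha_mx1 * m * x[:, 0]
        + x @ np.asarray(coeffs.alpha_x)
        + noise
    )
    return expit(logit)


def outcome_mean(coeffs: DGPCoefficients, t, m, x) -> np.ndarray:
    """Conditional mean of the outcome given treatment, moderator and confounders."""
    x = _as_matrix(x)
    t = np.asarray(t, dtype=float).ravel()
    m = np.asarray(m, dtype=float).ravel()
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(m))):
        raise ValueError("non-finite covariate value")
    return (
        coeffs.beta0
        + coeffs.beta_t * t
        + coeffs.beta_m * m
        + coeffs.beta_tm * t * m
        + coeffs.beta_mx1 * m * x[:, 0]
        + x @ np.asarray(coeffs.beta_x)
    )


def generate_cohort(coeffs: DGPCoefficients, seed) -> Cohort:
    """Draw one cohort from the generating models.

    ``seed`` may be an int, a ``numpy.random.SeedSequence`` or a
    ``numpy.random.Generator``; identical (coeffs, seed) give bit-identical
    cohorts.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = coeffs.n
    X = np.empty((n, 6))
    X[:, 0:3] = rng.standard_normal((n, 3))
    for j, prev in enumerate(coeffs.prev_x456):
        X[:, 3 + j] = rng.binomial(1, prev, size=n)
    M = rng.binomial(1, coeffs.prev_m, size=n)
    e1 = rng.normal(0.0, coeffs.sigma_e1, size=n) if coeffs.sigma_e1 > 0 else np.zeros(n)
    p = treatment_probability(coeffs, X, M, e1)
    T = rng.binomial(1, p)
    mu = outcome_mean(coeffs, T, M, X)
    Y = rng.normal(mu, coeffs.sigma_y) if coeffs.sigma_y > 0 else mu
    return Cohort(X=X, M=M, p=p, T=T, Y=Y, coeffs=coeffs)
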