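"""Effect-size distributions.

Each causal site receives a raw effect size drawn from one of five
univariate distributions (normal, fixed, exponential, gamma, student-t),
or from a multivariate normal when one site affects several correlated
traits (pleiotropy).  Because effect sizes must admit negative values,
the one-sided exponential and gamma draws are sign-symmetrized by
default: each draw is multiplied by +1 or -1 with equal probability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

__all__ = [
    "TraitModel",
    "TraitNormal",
    "TraitFixed",
    "TraitExponential",
    "TraitGamma",
    "TraitStudentT",
    "TraitMultivariateNormal",
    "trait_model",
    "TraitModelError",
]


class TraitModelError(ValueError):
    """A trait-model parameter is invalid."""


@dataclass(frozen=True)
class TraitModel:
    """Base class; subclasses draw one effect-size vector per causal site."""

    @property
    def num_traits(self) -> int:
        return 1

    @property
    def name(self) -> str:
        raise NotImplementedError

    def validate(self) -> "TraitModel":
        return self

    def draw(self, rng: np.random.Generator) -> np.ndarray:
        """One draw, returned as a length-``num_traits`` float array."""
        raise NotImplementedError


@dataclass(frozen=True)
class TraitNormal(TraitModel):
    mean: float = 0.0
    var: float = 1.0

    name = "normal"

    def validate(self):
        if not self.var > 0:
            raise TraitModelError(f"normal: var must be > 0, got {self.var}")
        if not np.isfinite(self.mean):
            raise TraitModelError("normal: mean must be finite")
        return self

    def draw(self, rng):
        return np.array([rng.normal(self.mean, np.sqrt(self.var))])


@dataclass(frozen=True)
class TraitFixed(TraitModel):
    """Deterministic effect size; every draw returns ``value``."""

    value: float = 0.0

    name = "fixed"

    def validate(self):
        if not np.isfinite(self.value):
            raise TraitModelError("fixed: value must be finite")
        return self

    def draw(self, rng):
        return np.array([float(self.value)])


@dataclass(frozen=True)
class TraitExponential(TraitModel):
    scale: float = 1.0
    random_sign: bool = True

    name = "exponential"

    def validate(self):
        if not self.scale > 0:
            raise TraitModelError(
                f"exponential: scale must be > 0, got {self.scale}")
        return self

    def draw(self, rng):
        beta = rng.exponential(self.scale)
        if self.random_sign:
            beta *= rng.choice([-1.0, 1.0])
        return np.array([beta])


@dataclass(frozen=True)
class TraitGamma(TraitModel):
    shape: float = 1.0
    scale: float = 1.0
    random_sign: bool = True

    name = "gamma"

    def validate(self):
        if not self.shape > 0:
            raise TraitModelError(f"gamma: shape must be > 0, got {self.shape}")
        if not self.scale > 0:
            raise TraitModelError(f"gamma: scale must be > 0, got {self.scale}")
        return self

    def draw(self, rng):
        beta = rng.gamma(self.shape, self.scale)
        if self.random_sign:
            beta *= rng.choice([-1.0, 1.0])
        return np.array([beta])


@dataclass(frozen=True)
class TraitStudentT(TraitModel):
    """Student-t effect sizes: a standard-t draw scaled to the requested
    variance and shifted by the mean.  Requires df > 2 so the variance
    exists (Var(t_df) = df/(df-2))."""

    mean: float = 0.0
    var: float = 1.0
    df: float = 10.0

    name = "student-t"

    def validate(self):
        if not self.var > 0:
            raise TraitModelError(f"student-t: var must be > 0, got {self.var}")
        if not self.df > 2:
            raise TraitModelError(
                f"student-t: df must be > 2 for finite variance, got {self.df}")
        return self

    def draw(self, rng):
        t = rng.standard_t(self.df)
        return np.array([self.mean + t * np.sqrt(self.var * (self.df - 2) / self.df)])


@dataclass(frozen=True)
class TraitMultivariateNormal(TraitModel):
    """Joint effect sizes for ``k`` pleiotropic traits of one causal site."""

    mean: tuple = (0.0,)
    cov: tuple = ((1.0,),)

    name = "multivariate-normal"

    @property
    def num_traits(self):
        return len(self.mean)

    def _arrays(self):
        return np.asarray(self.mean, dtype=float), np.asarray(self.cov, dtype=float)

    def validate(self):
        mean, cov = self._arrays()
        if mean.ndim != 1 or len(mean) < 1:
            raise TraitModelError("multivariate-normal: mean must be a vector")
        k = len(mean)
        if cov.shape != (k, k):
            raise TraitModelError(
                f"multivariate-normal: cov must be {k}x{k}, got {cov.shape}")
        if not np.allclose(cov, cov.T):
            raise TraitModelError("multivariate-normal: cov must be symmetric")
        eigvals = np.linalg.eigvalsh(cov)
        if eigvals.min() < -1e-9 * max(1.0, abs(eigvals).max()):
            raise TraitModelError(
                f"multivariate-normal: cov is not positive semi-definite "
                f"(min eigenvalue {eigvals.min():.3g})")
        return self

    def draw(self, rng):
        mean, cov = self._arrays()
        return rng.multivariate_normal(mean, cov, method="svd")


_MODELS = {
    "normal": TraitNormal,
    "fixed": TraitFixed,
    "exponential": TraitExponential,
    "gamma": TraitGamma,
    "student-t": TraitStudentT,
    "t": TraitStudentT,
    "multivariate-normal": TraitMultivariateNormal,
    "mvn": TraitMultivariateNormal,
}


def trait_model(name: str, **params) -> TraitModel:
    """Create and validate an effect-size model by name.

    >>> model = trait_model("normal", mean=0, var=1)
    """
    key = name.lower()
    if key not in _MODELS:
        raise TraitModelError(
            f"unknown trait model '{name}'; choose from "
            f"{sorted(set(_MODELS) - {'t', 'mvn'})}")
    cls = _MODELS[key]
    if cls is TraitMultivariateNormal:
        if "mean" in params:
            params["mean"] = tuple(np.asarray(params["mean"], dtype=float))
        if "cov" in params:
            params["cov"] = tuple(
                tuple(row) for row in np.asarray(params["cov"], dtype=float))
    try:
        model = cls(**params)
    except TypeError as err:
        raise TraitModelError(f"{name}: {err}") from None
    return model.validate()


ModelLike = Union[TraitModel, str]


def as_model(model: ModelLike) -> TraitModel:
    if isinstance(model, TraitModel):
        return model.validate()
    return trait_model(model)
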