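"""Declarative random-variable specifications and Latin-hypercube sampling.

Every uncertain or variable model input -- a relative risk, an exposure
prevalence, a pollutant concentration -- is described by a small immutable
:class:`DistributionSpec`.  Published summaries are converted to spec
parameters (a median with a 95% CI becomes a lognormal anchored at the
median; an arithmetic mean and sd become a moment-matched lognormal), and
specs are sampled jointly with a stratified Latin-hypercube scheme so that
a modest number of iterations yields stable means and percentile intervals.

Conventions fixed here and documented for reproducibility:

* Percentiles use linear interpolation between order statistics
  (``numpy.percentile`` default).
* A lower truncation bound is honoured by inverse-CDF sampling on the
  truncated support, which preserves Latin-hypercube stratification.
* Each variable consumes an independent random substream derived from the
  root seed and the variable's name, so registering an additional variable
  never perturbs the draws of existing ones.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ParameterError",
    "DistributionSpec",
    "SampleMatrix",
    "Summary",
    "lognormal_from_median_ci",
    "lognormal_from_mean_sd",
    "sample_lhs",
    "summarize",
    "substream",
]

# two-sided 95% normal quantile used to convert CI ratios to log-scale sigmas
_Z975 = float(stats.norm.ppf(0.975))

_KIND_PARAMS = {
    "point": ("value",),
    "uniform": ("lower", "upper"),
    "triangular": ("lower", "mode", "upper"),
    "lognormal": ("mu", "sigma"),
    "normal": ("mean", "sd"),
    "bernoulli": ("probability",),
}


class ParameterError(ValueError):
    """An invalid distribution or model parameter."""


@dataclass(frozen=True)
class DistributionSpec:
    """A declarative description of one random model input.

    Parameters are positional per kind: ``point(value)``,
    ``uniform(lower, upper)``, ``triangular(lower, mode, upper)``,
    ``lognormal(mu, sigma)`` (log scale), ``normal(mean, sd)``,
    ``bernoulli(probability)``.  ``truncate_lower`` is an optional lower
    bound in natural units, applied by inverse-CDF restriction.
    """

    kind: str
    params: tuple
    truncate_lower: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KIND_PARAMS:
            raise ParameterError(f"unknown distribution kind {self.kind!r}")
        params = tuple(float(p) for p in self.params)
        object.__setattr__(self, "params", params)
        names = _KIND_PARAMS[self.kind]
        if len(params) != len(names):
            raise ParameterError(
                f"{self.kind} needs {len(names)} parameters {names}, got {len(params)}"
            )
        p = dict(zip(names, params))
        if self.kind == "uniform" and p["lower"] > p["upper"]:
            raise ParameterError(f"uniform: lower {p['lower']} > upper {p['upper']}")
        if self.kind == "triangular" and not (p["lower"] <= p["mode"] <= p["upper"]):
            raise ParameterError(
                f"triangular: need lower <= mode <= upper, got ({p['lower']}, {p['mode']}, {p['upper']})"
            )
        if self.kind == "lognormal" and p["sigma"] < 0:
            raise ParameterError(f"lognormal: sigma {p['sigma']} < 0")
        if self.kind == "normal" and p["sd"] < 0:
            raise ParameterError(f"normal: sd {p['sd']} < 0")
        if self.kind == "bernoulli" and not (0.0 <= p["probability"] <= 1.0):
            raise ParameterError(f"bernoulli: probability {p['probability']} outside [0, 1]")
        if not all(math.isfinite(v) for v in params):
            raise ParameterError(f"{self.kind}: non-finite parameter in {params}")

    # -- constructors ----------------------------------------------------
    @classmethod
    def point(cls, value: float) -> "DistributionSpec":
        return cls("point", (value,))

    @classmethod
    def uniform(cls, lower: float, upper: float, truncate_lower: float | None = None) -> "DistributionSpec":
        return cls("uniform", (lower, upper), truncate_lower)

    @classmethod
    def triangular(cls, lower: float, mode: float, upper: float,
                   truncate_lower: float | None = None) -> "DistributionSpec":
        return cls("triangular", (lower, mode, upper), truncate_lower)

    @classmethod
    def lognormal(cls, mu: float, sigma: float, truncate_lower: float | None = None) -> "DistributionSpec":
        return cls("lognormal", (mu, sigma), truncate_lower)

    @classmethod
    def normal(cls, mean: float, sd: float, truncate_lower: float | None = None) -> "DistributionSpec":
        return cls("normal", (mean, sd), truncate_lower)

    @classmethod
    def bernoulli(cls, probability: float) -> "DistributionSpec":
        return cls("bernoulli", (probability,))

    # -- introspection ---------------------------------------------------
    def param(self, name: str) -> float:
        names = _KIND_PARAMS[self.kind]
        if name not in names:
            raise ParameterError(f"{self.kind} spec has no parameter {name!r}")
        return self.params[names.index(name)]

    @property
    def is_degenerate(self) -> bool:
        """True when the spec carries no spread (a point mass)."""
        k, p = self.kind, self.params
        if k == "point":
            return True
        if k == "uniform" or k == "triangular":
            return p[0] == p[-1]
        if k in ("lognormal", "normal"):
            return p[1] == 0.0
        return False

    def _degenerate_value(self) -> float:
        k, p = self.kind, self.params
        if k == "point":
            return p[0]
        if k in ("uniform", "triangular"):
            return p[0]
        if k == "lognormal":
            return math.exp(p[0])
        if k == "normal":
            return p[0]
        raise ParameterError(f"{k} spec is not degenerate")

    def _frozen(self):
        k, p = self.kind, self.params
        if k == "uniform":
            return stats.uniform(loc=p[0], scale=p[1] - p[0])
        if k == "triangular":
            scale = p[2] - p[0]
            return stats.triang(c=(p[1] - p[0]) / scale, loc=p[0], scale=scale)
        if k == "lognormal":
            return stats.lognorm(s=p[1], scale=math.exp(p[0]))
        if k == "normal":
            return stats.norm(loc=p[0], scale=p[1])
        if k == "bernoulli":
            return stats.bernoulli(p[0])
        raise ParameterError(f"no scipy distribution for kind {k!r}")

    # -- evaluation ------------------------------------------------------
    def ppf(self, q):
        """Inverse CDF; respects ``truncate_lower`` by support restriction."""
        q = np.asarray(q, dtype=float)
        if np.any((q < 0) | (q > 1)):
            raise ParameterError("quantile outside [0, 1]")
        if self.is_degenerate:
            v = self._degenerate_value()
            if self.truncate_lower is not None and v < self.truncate_lower:
                raise ParameterError(
                    f"point mass {v} below truncation bound {self.truncate_lower}"
                )
            return np.full_like(q, v, dtype=float)
        dist = self._frozen()
        if self.truncate_lower is not None:
            f0 = float(dist.cdf(self.truncate_lower))
            if f0 >= 1.0:
                raise ParameterError(
                    f"truncation bound {self.truncate_lower} removes all mass of {self.kind} spec"
                )
            q = f0 + q * (1.0 - f0)
        x = dist.ppf(q)
        if self.truncate_lower is not None:
            x = np.maximum(x, self.truncate_lower)
        return np.asarray(x, dtype=float)

    def cdf(self, x):
        if self.is_degenerate:
            v = self._degenerate_value()
            return (np.asarray(x, dtype=float) >= v).astype(float)
        return np.asarray(self._frozen().cdf(x), dtype=float)

    def mean(self, _n: int = 8192) -> float:
        """Arithmetic mean (analytic when untruncated, quadrature otherwise)."""
        if self.truncate_lower is not None and not self.is_degenerate:
            q = (np.arange(_n) + 0.5) / _n
            return float(np.mean(self.ppf(q)))
        k, p = self.kind, self.params
        if self.is_degenerate:
            return self._degenerate_value()
        if k == "uniform":
            return 0.5 * (p[0] + p[1])
        if k == "triangular":
            return (p[0] + p[1] + p[2]) / 3.0
        if k == "lognormal":
            return math.exp(p[0] + 0.5 * p[1] ** 2)
        if k == "normal":
            return p[0]
        if k == "bernoulli":
            return p[0]
        raise ParameterError(k)

    def median(self) -> float:
        return float(self.ppf(np.asarray(0.5)))

    # -- serialization ---------------------------------------------------
    def as_dict(self) -> dict:
        d = {"kind": self.kind}
        d.update(zip(_KIND_PARAMS[self.kind], self.params))
        if self.truncate_lower is not None:
            d["truncate_lower"] = self.truncate_lower
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DistributionSpec":
        d = dict(d)
        kind = d.pop("kind", None)
        if kind is None:
            raise ParameterError("distribution mapping is missing 'kind'")
        trunc = d.pop("truncate_lower", None)
        if kind == "lognormal_ci":
            spec = lognormal_from_median_ci(
                d.pop("median"), d.pop("lcl"), d.pop("ucl"),
                require_median_in_ci=d.pop("median_in_ci", True),
            )
        elif kind == "lognormal_meansd":
            spec = lognormal_from_mean_sd(d.pop("mean"), d.pop("sd"))
        elif kind in _KIND_PARAMS:
            names = _KIND_PARAMS[kind]
            missing = [n for n in names if n not in d]
            if missing:
                raise ParameterError(f"{kind}: missing parameter(s) {missing}")
            spec = cls(kind, tuple(d.pop(n) for n in names))
        else:
            raise ParameterError(f"unknown distribution kind {kind!r}")
        if d:
            raise ParameterError(f"{kind}: unexpected key(s) {sorted(d)}")
        if trunc is not None:
            spec = cls(spec.kind, spec.params, float(trunc))
        return spec


def lognormal_from_median_ci(median: float, lcl: float, ucl: float, *,
                             require_median_in_ci: bool = True) -> DistributionSpec:
    """Lognormal spec anchored at a published central estimate and 95% CI.

    The central estimate is treated as the *median* (``mu = ln(median)``),
    preserving the printed point value under the log transform, and the
    log-scale sigma comes from the CI ratio alone:
    ``sigma = ln(ucl / lcl) / (2 * z_0.975)``.
    """
    if median <= 0:
        raise ParameterError(f"median must be positive, got {median}")
    if lcl <= 0:
        raise ParameterError(f"lcl must be positive, got {lcl}")
    if ucl < lcl:
        raise ParameterError(f"ucl {ucl} < lcl {lcl}")
    if require_median_in_ci and not (lcl <= median <= ucl):
        raise ParameterError(f"median {median} outside CI ({lcl}, {ucl})")
    sigma = math.log(ucl / lcl) / (2.0 * _Z975)
    return DistributionSpec.lognormal(math.log(median), sigma)


def lognormal_from_mean_sd(mean: float, sd: float) -> DistributionSpec:
    """Moment-matched lognormal: arithmetic mean and sd equal the inputs."""
    if mean <= 0:
        raise ParameterError(f"mean must be positive, got {mean}")
    if sd < 0:
        raise ParameterError(f"sd must be non-negative, got {sd}")
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - 0.5 * sigma2
    return DistributionSpec.lognormal(mu, math.sqrt(sigma2))


@dataclass(frozen=True)
class SampleMatrix:
    """An iterations-by-variables table of sampled values."""

    draws: np.ndarray
    n: int
    seed: int
    names: tuple

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            j = self.names.index(name)
        except ValueError:
            raise KeyError(name) from None
        return self.draws[:, j]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.draws, columns=list(self.names))


def substream(seed: int, name: str) -> np.random.Generator:
    """A generator deterministically derived from (root seed, stream name)."""
    if seed < 0:
        raise ParameterError(f"seed must be non-negative, got {seed}")
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(str(name).encode())])
    )


def sample_lhs(specs: Sequence[DistributionSpec], n: int, seed: int,
               names: Sequence[str] | None = None, method: str = "lhs") -> SampleMatrix:
    """Sample ``n`` joint draws of ``specs``.

    With ``method="lhs"`` each variable's draws occupy the ``n``
    equiprobable strata of its CDF exactly once (one uniform sub-draw per
    stratum, inverse-CDF transform), with stratum order permuted
    independently across variables.  ``method="srs"`` is plain simple
    random sampling, kept for variance comparisons.
    """
    if n < 1:
        raise ParameterError(f"iteration count must be >= 1, got {n}")
    if method not in ("lhs", "srs"):
        raise ParameterError(f"unknown sampling method {method!r}")
    specs = list(specs)
    if names is None:
        names = tuple(f"x{i}" for i in range(len(specs)))
    else:
        names = tuple(names)
        if len(names) != len(specs):
            raise ParameterError("names and specs length mismatch")
        if len(set(names)) != len(names):
            raise ParameterError("duplicate variable names")
    draws = np.empty((n, len(specs)), dtype=float)
    for j, (spec, name) in enumerate(zip(specs, names)):
        rng = substream(seed, f"{method}/{name}")
        if method == "lhs":
            u = (rng.permutation(n) + rng.random(n)) / n
        else:
            u = rng.random(n)
        draws[:, j] = spec.ppf(u)
    return SampleMatrix(draws=draws, n=n, seed=int(seed), names=names)


@dataclass(frozen=True)
class Summary:
    """Mean with 2.5th/97.5th percentile interval of a draw vector."""

    mean: float
    p2_5: float
    p97_5: float


def summarize(draws) -> Summary:
    """Mean and 95% percentile interval (linear-interpolation quantiles)."""
    x = np.asarray(draws, dtype=float).ravel()
    if x.size == 0:
        raise ParameterError("cannot summarize an empty vector")
    lo, hi = np.percentile(x, [2.5, 97.5])
    return Summary(mean=float(np.mean(x)), p2_5=float(lo), p97_5=float(hi))
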