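"""Parametric duration distributions: sampling, moments, and minimum-SSE fitting.

Processing times in the activation workflow are modelled with one of five
families — constant, uniform, triangular, exponential, lognormal — all in
units of calendar days.  The lognormal is parameterized by the mean and
standard deviation of the variate itself (the convention of commercial
simulation tools), not of the underlying normal.

Family selection from data follows the classic input-modelling recipe:
estimate parameters per candidate family by the method of moments, then
score each candidate by the sum of squared errors (SSE) between the
sample's relative-frequency histogram and the candidate's bin
probabilities, and keep the minimizer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as _st

__all__ = [
    "FAMILIES",
    "DurationDistribution",
    "FitResult",
    "DegenerateSampleError",
    "sample",
    "theoretical_mean",
    "theoretical_variance",
    "fit_distribution",
    "read_samples_csv",
]

FAMILIES = ("constant", "uniform", "triangular", "exponential", "lognormal")

#: number of free parameters per family, used to break SSE ties in favour of
#: the more parsimonious candidate
_N_PARAMS = {
    "constant": 1,
    "exponential": 1,
    "uniform": 2,
    "lognormal": 2,
    "triangular": 3,
}

_MIN_FIT_SIZE = 10
_SSE_TIE = 1e-6


class DegenerateSampleError(ValueError):
    """Raised when a sample has zero variance and no spread-family fit exists."""


def _lognormal_underlying(mean: float, sd: float) -> tuple[float, float]:
    """Convert (mean, sd) of the lognormal variate to (mu, sigma) of log X."""
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


@dataclass(frozen=True)
class DurationDistribution:
    """A processing-time distribution (calendar days).

    Parameters by family:

    ==============  ======================================  ==========
    family          params                                  constraint
    ==============  ======================================  ==========
    ``constant``    (c,)                                    c >= 0
    ``uniform``     (a, b)                                  a < b
    ``triangular``  (min, mode, max)                        min <= mode <= max, min < max
    ``exponential`` (mean,)                                 mean > 0
    ``lognormal``   (mean, sd) of the variate               mean > 0, sd > 0
    ==============  ======================================  ==========
    """

    family: str
    params: tuple[float, ...]

    def __init__(self, family: str, params: Sequence[float]):
        object.__setattr__(self, "family", str(family))
        object.__setattr__(self, "params", tuple(float(p) for p in params))
        self._validate()

    def _validate(self) -> None:
        fam, p = self.family, self.params
        if fam not in FAMILIES:
            raise ValueError(f"unknown distribution family: {fam!r}")
        expected = {"constant": 1, "uniform": 2, "triangular": 3,
                    "exponential": 1, "lognormal": 2}[fam]
        if len(p) != expected:
            raise ValueError(f"{fam} takes {expected} parameters, got {len(p)}")
        if any(not math.isfinite(v) for v in p):
            raise ValueError(f"{fam} parameters must be finite: {p}")
        if fam == "constant" and p[0] < 0:
            raise ValueError(f"constant duration must be >= 0, got {p[0]}")
        if fam == "uniform" and not p[0] < p[1]:
            raise ValueError(f"uniform requires a < b, got {p}")
        if fam == "triangular":
            lo, mode, hi = p
            if not (lo <= mode <= hi) or not lo < hi:
                raise ValueError(f"triangular requires min <= mode <= max, min < max, got {p}")
        if fam in ("exponential", "lognormal") and p[0] <= 0:
            raise ValueError(f"{fam} mean must be > 0, got {p[0]}")
        if fam == "lognormal" and p[1] <= 0:
            raise ValueError(f"lognormal sd must be > 0, got {p[1]}")

    # -- moments ---------------------------------------------------------

    @property
    def mean(self) -> float:
        fam, p = self.family, self.params
        if fam == "constant":
            return p[0]
        if fam == "uniform":
            return (p[0] + p[1]) / 2.0
        if fam == "triangular":
            return (p[0] + p[1] + p[2]) / 3.0
        if fam == "exponential":
            return p[0]
        return p[0]  # lognormal: params already are (mean, sd) of the variate

    @property
    def variance(self) -> float:
        fam, p = self.family, self.params
        if fam == "constant":
            return 0.0
        if fam == "uniform":
            return (p[1] - p[0]) ** 2 / 12.0
        if fam == "triangular":
            lo, m, hi = p
            return (lo * lo + m * m + hi * hi - lo * m - lo * hi - m * hi) / 18.0
        if fam == "exponential":
            return p[0] ** 2
        return p[1] ** 2

    # -- sampling --------------------------------------------------------

    def sample(self, rng: np.random.Generator, size=None):
        """Draw from the distribution; result is nonnegative (calendar days)."""
        fam, p = self.family, self.params
        if fam == "constant":
            return p[0] if size is None else np.full(size, p[0])
        if fam == "uniform":
            return rng.uniform(p[0], p[1], size)
        if fam == "triangular":
            return rng.triangular(p[0], p[1], p[2], size)
        if fam == "exponential":
            return rng.exponential(p[0], size)
        mu, sigma = _lognormal_underlying(*p)
        return rng.lognormal(mu, sigma, size)

    # -- density (for SSE scoring) ---------------------------------------

    def frozen(self):
        """scipy frozen distribution (undefined for ``constant``)."""
        fam, p = self.family, self.params
        if fam == "uniform":
            return _st.uniform(loc=p[0], scale=p[1] - p[0])
        if fam == "triangular":
            lo, mode, hi = p
            return _st.triang((mode - lo) / (hi - lo), loc=lo, scale=hi - lo)
        if fam == "exponential":
            return _st.expon(scale=p[0])
        if fam == "lognormal":
            mu, sigma = _lognormal_underlying(*p)
            return _st.lognorm(sigma, scale=math.exp(mu))
        raise ValueError("constant distribution has no density")

    def pdf(self, x):
        return self.frozen().pdf(x)

    def __str__(self) -> str:  # e.g. "Exponential (28.5)"
        body = ", ".join(f"{v:g}" for v in self.params)
        return f"{self.family.capitalize()} ({body})"


def sample(dist: DurationDistribution, rng: np.random.Generator, size=None):
    """Draw ``size`` durations (days) from ``dist`` using ``rng``."""
    return dist.sample(rng, size)


def theoretical_mean(dist: DurationDistribution) -> float:
    """Closed-form mean of the distribution in calendar days."""
    return dist.mean


def theoretical_variance(dist: DurationDistribution) -> float:
    return dist.variance


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FitResult:
    """Outcome of minimum-SSE family selection on a duration sample."""

    family: str
    params: tuple[float, ...]
    sse: float
    n: int
    degenerate: bool = False
    candidates: dict = field(default_factory=dict, compare=False)

    @property
    def distribution(self) -> DurationDistribution:
        return DurationDistribution(self.family, self.params)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "params": list(self.params),
            "sse": self.sse,
            "n": self.n,
            "degenerate": self.degenerate,
        }


def _moment_estimate(samples: np.ndarray, family: str) -> DurationDistribution:
    """Method-of-moments parameter estimate of ``family`` for ``samples``."""
    if family == "exponential":
        return DurationDistribution("exponential", (samples.mean(),))
    if family == "uniform":
        return DurationDistribution("uniform", (samples.min(), samples.max()))
    if family == "lognormal":
        # moments in log space are far more stable for the heavy-tailed
        # variate than raw mean/SD; convert back to the (mean, sd) convention
        logs = np.log(samples[samples > 0])
        mu, sigma = logs.mean(), logs.std(ddof=1)
        mean = math.exp(mu + sigma ** 2 / 2.0)
        sd = mean * math.sqrt(math.expm1(sigma ** 2))
        return DurationDistribution("lognormal", (mean, sd))
    if family == "triangular":
        lo, hi = samples.min(), samples.max()
        counts, edges = np.histogram(samples, bins=_sturges_bins(samples.size))
        mode = (edges[np.argmax(counts)] + edges[np.argmax(counts) + 1]) / 2.0
        mode = min(max(mode, lo), hi)
        return DurationDistribution("triangular", (lo, mode, hi))
    if family == "constant":
        return DurationDistribution("constant", (samples.mean(),))
    raise ValueError(f"unknown distribution family: {family!r}")


def _sturges_bins(n: int) -> int:
    return int(math.ceil(math.log2(n))) + 1


def _sse_against_histogram(dist: DurationDistribution, samples: np.ndarray) -> float:
    """Sum of squared errors between relative frequencies and fitted bin
    probabilities over a Sturges-binned histogram.

    Comparing bin probabilities (CDF increments) rather than point densities
    keeps the score meaningful for strongly skewed candidates, where the
    density varies by orders of magnitude inside one bin.
    """
    counts, edges = np.histogram(samples, bins=_sturges_bins(samples.size))
    freq = counts / samples.size
    cdf = dist.frozen().cdf(edges)
    return float(np.sum((freq - np.diff(cdf)) ** 2))


def fit_distribution(samples, candidates: Sequence[str] | None = None) -> FitResult:
    """Select the minimum-SSE duration distribution for a sample.

    Parameters are estimated per candidate family by the method of moments
    (log-space moments for the lognormal); each candidate is scored by the
    SSE between the sample's relative-frequency histogram (Sturges binning)
    and the candidate's bin probabilities.  Ties within 1e-6 go to the
    family with fewer parameters.

    Raises
    ------
    ValueError
        On fewer than 10 samples or any negative duration.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    if x.size < _MIN_FIT_SIZE:
        raise ValueError(f"need at least {_MIN_FIT_SIZE} samples to fit, got {x.size}")
    if np.any(x < 0):
        raise ValueError("durations must be nonnegative")

    if candidates is None:
        candidates = ("uniform", "triangular", "exponential", "lognormal")
    unknown = set(candidates) - set(FAMILIES)
    if unknown:
        raise ValueError(f"unknown distribution family: {sorted(unknown)}")

    if np.ptp(x) == 0.0:
        # zero variance: only the degenerate family describes the data
        return FitResult("constant", (float(x[0]),), 0.0, int(x.size), degenerate=True)

    scored: dict[str, tuple[DurationDistribution, float]] = {}
    for fam in candidates:
        if fam == "constant":
            continue  # cannot describe data with spread
        try:
            est = _moment_estimate(x, fam)
        except ValueError:
            continue  # sample incompatible with the family's constraints
        scored[fam] = (est, _sse_against_histogram(est, x))

    if not scored:
        raise ValueError("no candidate family admits a valid fit")

    best_sse = min(s for _, s in scored.values())
    near = [fam for fam, (_, s) in scored.items() if s - best_sse < _SSE_TIE]
    winner = min(near, key=lambda fam: (_N_PARAMS[fam], fam))
    est, sse = scored[winner]
    return FitResult(
        winner, est.params, sse, int(x.size),
        candidates={fam: {"params": list(d.params), "sse": s} for fam, (d, s) in scored.items()},
    )


def read_samples_csv(path) -> np.ndarray:
    """Read a single-column CSV of durations (header optional)."""
    import pandas as pd

    df = pd.read_csv(path)
    if df.shape[1] != 1:
        raise ValueError(f"expected a single-column CSV, got {df.shape[1]} columns")
    return df.iloc[:, 0].to_numpy(dtype=float)
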