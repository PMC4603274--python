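"""Analytic number-weighted size distributions.

The distribution P(x) describes how many scatterers per unit volume carry a
size-parameter value x; it integrates to the number-density scale N (not to
one).  The set of kinds is fixed — a deliberate design choice, since robust
adaptive integration ranges cannot be guaranteed for arbitrary user-defined
densities:

monodisperse
    All scatterers share the single value X0; only N and X0 are defined.
gaussian
    N / (s sqrt(2 pi)) * exp(-(x - X0)^2 / (2 s^2)).  Location X0 and width
    s carry length units.  The density is *not* renormalized after
    truncation at x >= 0; closed-form (untruncated) moments are used
    throughout, which is the convention under which the concentration /
    mass-fraction chain reproduces its reference values.
lognormal
    Median X0 (length), log-standard-deviation s (dimensionless).
schulz_zimm
    Mean X0 (length), relative width s (dimensionless); shape k = 1/s^2.

Moments are closed form; quadrature is used only as a cross-check and to
integrate form factors over the distribution (linear subdivision with
composite Simpson over an adaptively chosen range).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "SizeDistribution",
    "pdf",
    "moments",
    "integration_range",
    "tail_mass",
    "range_is_sufficient",
    "quadrature_nodes",
]

KINDS = ("monodisperse", "gaussian", "lognormal", "schulz_zimm")

#: fraction of N allowed outside the integration range
TAIL_TOL = 1e-6
#: subdivision count limits for the linear subdivision of the range
N_SUB_MIN, N_SUB_MAX = 50, 5000
#: subdivisions per unit of (range width / distribution sd)
N_SUB_PER_SD = 12


@dataclass(frozen=True)
class SizeDistribution:
    """Named analytic number distribution with scale N, location X0, width s."""

    kind: str
    N: float = 1.0
    X0: float = 1.0
    s: float = 0.0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown distribution kind {self.kind!r}; "
                             f"available: {KINDS}")
        if self.N < 0:
            raise ValueError("N must be >= 0")
        if self.s < 0:
            raise ValueError("s must be >= 0")
        if self.kind != "monodisperse" and self.X0 <= 0 and self.kind != "gaussian":
            raise ValueError("X0 must be > 0")

    @property
    def effective_kind(self) -> str:
        """s = 0 collapses every continuous kind to a delta at X0."""
        return "monodisperse" if self.s == 0 else self.kind

    @property
    def sd(self) -> float:
        """Standard deviation in length units (0 for monodisperse)."""
        k = self.effective_kind
        if k == "monodisperse":
            return 0.0
        if k == "gaussian":
            return self.s
        if k == "lognormal":
            es2 = math.exp(self.s**2)
            return self.X0 * math.exp(self.s**2 / 2.0) * math.sqrt(es2 - 1.0)
        return self.X0 * self.s  # schulz_zimm: relative width s


def _scipy_dist(dist: SizeDistribution):
    k = dist.effective_kind
    if k == "gaussian":
        return stats.norm(loc=dist.X0, scale=dist.s)
    if k == "lognormal":
        return stats.lognorm(s=dist.s, scale=dist.X0)
    if k == "schulz_zimm":
        shape = 1.0 / dist.s**2
        return stats.gamma(a=shape, scale=dist.X0 / shape)
    return None


def pdf(dist: SizeDistribution, x) -> np.ndarray:
    """Number density per unit size, integrating to N over x >= 0.

    The monodisperse limit (including s = 0 of a continuous kind) is a
    delta at X0, represented as inf at x == X0 and 0 elsewhere.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("sizes x must be >= 0")
    d = _scipy_dist(dist)
    if d is None:
        return np.where(x == dist.X0, np.inf, 0.0) * (1.0 if dist.N else 0.0)
    return dist.N * d.pdf(x)


def _raw_moments(dist: SizeDistribution, kmax: int = 6):
    """Closed-form raw moments E[x^k] (number-weighted, N factored out)."""
    kd = dist.effective_kind
    X0, s = dist.X0, dist.s
    if kd == "monodisperse":
        return [X0**k for k in range(1, kmax + 1)]
    if kd == "gaussian":
        # untruncated normal: m_k = X0 m_{k-1} + (k-1) s^2 m_{k-2}
        m = [1.0, X0]
        for k in range(2, kmax + 1):
            m.append(X0 * m[k - 1] + (k - 1) * s**2 * m[k - 2])
        return m[1:]
    if kd == "lognormal":
        out = []
        for k in range(1, kmax + 1):
            try:
                out.append(X0**k * math.exp(k * k * s * s / 2.0))
            except OverflowError:
                out.append(math.inf)  # marked undefined by moments()
        return out
    # schulz_zimm (gamma with mean X0, shape a = 1/s^2):
    a = 1.0 / s**2
    out, acc = [], 1.0
    for k in range(1, kmax + 1):
        acc *= (a + k - 1) / a
        out.append(X0**k * acc)
    return out


def moments(dist: SizeDistribution) -> dict:
    """Mean, variance, raw moments 1-6 and mean sphere volume <V>.

    <V> = (4 pi / 3) E[x^3], in cubic length units of X0 — the caller owns
    unit conversion.  Non-finite (undefined) moments are reported as None
    rather than a number.
    """
    raw = _raw_moments(dist, 6)
    raw = [m if math.isfinite(m) else None for m in raw]
    mean = raw[0]
    var = (raw[1] - raw[0] ** 2) if raw[1] is not None else None
    mv = (4.0 * math.pi / 3.0) * raw[2] if raw[2] is not None else None
    return {
        "mean": mean,
        "variance": var,
        "raw": raw,
        "mean_volume": mv,
        "N": dist.N,
    }


def tail_mass(dist: SizeDistribution, x_lo: float, x_hi: float) -> float:
    """Probability mass (fraction of N) outside [x_lo, x_hi]."""
    d = _scipy_dist(dist)
    if d is None:
        return 0.0 if x_lo <= dist.X0 <= x_hi else 1.0
    return float(d.cdf(x_lo) + d.sf(x_hi))


def range_is_sufficient(dist: SizeDistribution, x_lo: float, x_hi: float) -> bool:
    """True iff less than TAIL_TOL of the mass lies outside the range."""
    return tail_mass(dist, x_lo, x_hi) < TAIL_TOL


@dataclass(frozen=True)
class IntegrationRange:
    x_lo: float
    x_hi: float
    n_sub: int


def integration_range(dist: SizeDistribution) -> IntegrationRange:
    """Adaptive extent and granularity of the distribution integral.

    The extent covers all but < 1e-6 of the mass (clipped at x >= 0); the
    linear-subdivision count scales with the range width in units of the
    distribution's standard deviation, bounded to [50, 5000].
    """
    kd = dist.effective_kind
    if kd == "monodisperse":
        return IntegrationRange(dist.X0, dist.X0, 1)
    if kd == "gaussian":
        lo, hi = dist.X0 - 8.0 * dist.s, dist.X0 + 8.0 * dist.s
    elif kd == "lognormal":
        lo = dist.X0 * math.exp(-8.0 * dist.s)
        hi = dist.X0 * math.exp(8.0 * dist.s)
    else:  # schulz_zimm
        d = _scipy_dist(dist)
        lo, hi = d.ppf(1e-8), d.isf(1e-8)
    # sufficiency is judged before clipping: mass below x = 0 is a property
    # of the untruncated closed-form convention, not of the range choice
    if not range_is_sufficient(dist, lo, hi):
        raise ValueError("adaptive integration range leaves more than "
                         f"{TAIL_TOL:g} of the mass uncovered for {dist}")
    lo = max(lo, 0.0)
    sd = dist.sd if dist.sd > 0 else (hi - lo) or 1.0
    n = int(round(N_SUB_PER_SD * (hi - lo) / sd))
    n = min(max(n, N_SUB_MIN), N_SUB_MAX)
    if n % 2:
        n += 1  # composite Simpson needs an even interval count
    return IntegrationRange(lo, hi, n)


def quadrature_nodes(dist: SizeDistribution, n_sub: int | None = None):
    """Nodes x_i and weights w_i with sum_i w_i f(x_i) ~ int P(x) f(x) dx.

    Composite Simpson on the linear subdivision of the adaptive range; the
    weights absorb the density, so sum(w) ~ N.  Monodisperse (or s = 0)
    returns the single node X0 with weight N.
    """
    if dist.effective_kind == "monodisperse":
        return np.array([dist.X0]), np.array([dist.N])
    rng = integration_range(dist)
    n = rng.n_sub if n_sub is None else int(n_sub)
    if n % 2:
        n += 1
    # nudge a zero-clipped lower edge off 0: form factors with open x > 0
    # domains must stay evaluable, and the x -> 0 integrand limit is benign
    lo = rng.x_lo if rng.x_lo > 0 else rng.x_hi * 1e-12
    x = np.linspace(lo, rng.x_hi, n + 1)
    h = (rng.x_hi - lo) / n
    w = np.ones(n + 1)
    w[1:-1:2] = 4.0
    w[2:-1:2] = 2.0
    w *= h / 3.0
    return x, w * pdf(dist, x)
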