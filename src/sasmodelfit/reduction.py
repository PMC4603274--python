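"""Point reduction for oversampled scattering curves.

Three methods, in increasing order of sophistication:

1. ``reduce_ratio`` — uniform decimation, keeping a user-given fraction of
   points.  Fast, for quick-look fitting of very dense SAXS data.
2. ``reduce_distance`` — greedy thinning that maintains a minimal Euclidean
   distance between consecutive kept points, in linear or logarithmic
   (q, I) coordinates.  Preserves curve features better than decimation.
3. ``reduce_adaptive`` — the recommended method: neighbouring points are
   averaged within intervals chosen adaptively from the intensity spread
   (relative to the uncertainties) and the relative q width.  Low q stays
   finely sampled, high q is binned wide, and sharp features survive.

All methods return a new working view; the curve's ``original`` is never
touched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dataio import SASCurve

__all__ = ["ReductionConfig", "reduce_ratio", "reduce_distance", "reduce_adaptive"]


@dataclass
class ReductionConfig:
    """Parameters of the three reduction methods.

    fraction  -- ratio of points kept by method 1, in (0, 1]
    dmin      -- minimal point distance of method 2 (> 0 to have an effect)
    space     -- 'linear' or 'log' coordinates for method 2
    eps_I     -- method 3: intensity difference bound within an interval,
                 in units of the point uncertainties (>= 0)
    eps_q     -- method 3: maximal interval width relative to its position
                 in q (>= 0)
    """

    method: str = "adaptive"
    fraction: float = 0.1
    dmin: float = 0.0
    space: str = "log"
    eps_I: float = 1.0
    eps_q: float = 0.05

    def __post_init__(self):
        if self.method not in ("ratio", "distance", "adaptive"):
            raise ValueError(f"unknown reduction method {self.method!r}")
        if not 0 < self.fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")
        if self.dmin < 0:
            raise ValueError("dmin must be >= 0")
        if self.space not in ("linear", "log"):
            raise ValueError("space must be 'linear' or 'log'")
        if self.eps_I < 0 or self.eps_q < 0:
            raise ValueError("eps_I and eps_q must be >= 0")

    def apply(self, curve: SASCurve) -> SASCurve:
        if self.method == "ratio":
            return reduce_ratio(curve, self.fraction)
        if self.method == "distance":
            return reduce_distance(curve, self.dmin, self.space)
        return reduce_adaptive(curve, self.eps_I, self.eps_q)


def _subset(curve: SASCurve, keep: np.ndarray, note: str) -> SASCurve:
    return curve._derive(
        curve.q[keep], curve.I[keep],
        None if curve.sigma is None else curve.sigma[keep],
        [curve.source[int(i)] for i in np.flatnonzero(np.asarray(keep))]
        if np.asarray(keep).dtype == bool
        else [curve.source[int(i)] for i in keep],
        note,
    )


def reduce_ratio(curve: SASCurve, fraction: float) -> SASCurve:
    """Uniform decimation: keep about ``fraction`` of the points.

    With points numbered i = 1..n, point i is kept iff
    floor(i*fraction) > floor((i-1)*fraction).  fraction = 1 is the
    identity; specifying 0.1 drops 90% of the points.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n = len(curve)
    i = np.arange(1, n + 1)
    keep = np.floor(i * fraction) > np.floor((i - 1) * fraction)
    return _subset(curve, keep, f"reduce_ratio({fraction:g}): {keep.sum()}/{n}")


def reduce_distance(curve: SASCurve, dmin: float, space: str = "linear") -> SASCurve:
    """Greedy thinning by minimal point distance (Pythagoras in 2-D).

    The first point is always kept; each subsequent point is kept iff its
    Euclidean distance from the last *kept* point, computed in linear or
    log10 (q, I) coordinates, is >= dmin.  dmin = 0 is the identity.
    """
    if dmin < 0:
        raise ValueError("dmin must be >= 0")
    if space not in ("linear", "log"):
        raise ValueError("space must be 'linear' or 'log'")
    q, I = curve.q, curve.I
    if space == "log":
        bad = np.flatnonzero((q <= 0) | (I <= 0))
        if bad.size:
            i = int(bad[0])
            raise ValueError(
                "log-space distance needs q, I > 0; offending point "
                f"#{i}: q={q[i]:g}, I={I[i]:g}")
        x, y = np.log10(q), np.log10(I)
    else:
        x, y = q, I

    keep = [0]
    last = 0
    for i in range(1, len(curve)):
        if math.hypot(x[i] - x[last], y[i] - y[last]) >= dmin:
            keep.append(i)
            last = i
    keep = np.array(keep, dtype=int)
    return _subset(curve, keep,
                   f"reduce_distance(dmin={dmin:g}, {space}): {keep.size}/{len(curve)}")


def adaptive_intervals(q, I, sigma, eps_I: float, eps_q: float):
    """Greedy left-to-right maximal intervals of the adaptive binning.

    A point n belongs to the interval opened at point j iff both

        |I_n - I_j| <= eps_I * (sigma_n + sigma_j) / 2
        (q_n - q_j) <= eps_q * q_j

    hold (first-point reference).  Returns a list of (start, stop) index
    pairs, stop exclusive.  eps_I = eps_q = 0 makes every point its own
    interval.
    """
    n = len(q)
    intervals = []
    j = 0
    while j < n:
        k = j + 1
        while k < n:
            ok_I = abs(I[k] - I[j]) <= eps_I * (sigma[k] + sigma[j]) / 2.0
            ok_q = (q[k] - q[j]) <= eps_q * q[j]
            if ok_I and ok_q:
                k += 1
            else:
                break
        intervals.append((j, k))
        j = k
    return intervals


def reduce_adaptive(curve: SASCurve, eps_I: float, eps_q: float) -> SASCurve:
    """Adaptive averaging of neighbouring points (recommended method).

    Each maximal interval (see :func:`adaptive_intervals`) is replaced by a
    single point: inverse-variance weighted mean of I with the sigma of the
    weighted mean, q averaged with the same weights — consistent with the
    chi^2 weighting used in fitting.  For eps_q > 0 the output spacing is
    narrow at low q and wide at high q.
    """
    if curve.sigma is None or np.any(curve.sigma <= 0):
        raise ValueError("adaptive reduction requires positive sigma for "
                         "every point (run estimate_sigma first)")
    if eps_I < 0 or eps_q < 0:
        raise ValueError("eps_I and eps_q must be >= 0")
    q, I, sig = curve.q, curve.I, curve.sigma
    spans = adaptive_intervals(q, I, sig, eps_I, eps_q)

    qo, Io, so, src = [], [], [], []
    for a, b in spans:
        if b - a == 1:  # singleton intervals pass through bit-exact
            qo.append(float(q[a]))
            Io.append(float(I[a]))
            so.append(float(sig[a]))
            src.append(curve.source[a])
            continue
        w = 1.0 / sig[a:b] ** 2
        W = w.sum()
        qo.append(float(np.sum(w * q[a:b]) / W))
        Io.append(float(np.sum(w * I[a:b]) / W))
        so.append(float(1.0 / np.sqrt(W)))
        src.append(f"avg[{curve.source[a]}:{b - a} pts]")

    out = curve._derive(np.array(qo), np.array(Io), np.array(so), src,
                        f"reduce_adaptive(eps_I={eps_I:g}, eps_q={eps_q:g}): "
                        f"{len(spans)}/{len(curve)}")
    return out
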