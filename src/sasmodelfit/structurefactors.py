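"""Interparticle-interference (structure) factors.

The structure factor S(q) modulates a contribution's intensity where
positional correlations between scatterers matter (low q).  Implemented
here is the hard-sphere fluid in the Percus-Yevick closure — the standard
analytic choice in small-angle scattering — together with three
approximations for combining S(q) with a *disperse* form factor:

monodisperse approximation
    I(q) = <F^2(q)> S(q): all particles treated as identical for the
    interference term.
local monodisperse approach
    I(q) = < F^2(q; x) S(q; R_HS x / X0) >: each size fraction sees a
    structure factor with the repulsion radius scaled proportionally to
    its own size.
decoupling approach
    I(q) = <F^2> + <F>^2 (S(q) - 1): requires the scattering amplitude;
    models that only provide an intensity raise an error.

Two further approximations (partial structure factor and its scaling
approximation) exist in the wider literature but are not implemented;
requesting them raises NotImplementedError.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import distributions as _dist
from .formfactors import FormFactorModel, ParameterRangeError

__all__ = [
    "HardSphereParams",
    "SFApproximation",
    "AmplitudeRequiredError",
    "hard_sphere_S",
    "combine",
]

APPROXIMATIONS = ("monodisperse", "local_monodisperse", "decoupling")
NOT_IMPLEMENTED = ("partial_structure_factor", "scaling_partial_structure_factor")


class AmplitudeRequiredError(TypeError):
    """A structure-factor approximation needs a scattering amplitude the
    form factor does not provide."""


@dataclass(frozen=True)
class HardSphereParams:
    """Effective hard-sphere repulsion radius and volume fraction.

    The repulsion radius is usually set slightly larger than the particle
    radius; the volume fraction starts small (e.g. 0.05).  fp is bounded by
    the close-packing limit 0.74.
    """

    R_HS: float
    fp: float

    def __post_init__(self):
        if self.R_HS <= 0:
            raise ParameterRangeError("R_HS", self.R_HS,
                                      "hard-sphere radius must be > 0")
        if not 0.0 <= self.fp < 0.74:
            raise ParameterRangeError("fp", self.fp,
                                      "volume fraction must be in [0, 0.74)")


@dataclass(frozen=True)
class SFApproximation:
    """How a structure factor combines with a disperse form factor."""

    kind: str = "monodisperse"

    def __post_init__(self):
        if self.kind in NOT_IMPLEMENTED:
            raise NotImplementedError(
                f"structure-factor approximation {self.kind!r} is not "
                "implemented; available: " + ", ".join(APPROXIMATIONS))
        if self.kind not in APPROXIMATIONS:
            raise ValueError(f"unknown approximation {self.kind!r}; "
                             f"available: {APPROXIMATIONS}")

    @property
    def requires_amplitude(self) -> bool:
        return self.kind == "decoupling"


def hard_sphere_S(q, p: HardSphereParams) -> np.ndarray:
    """Percus-Yevick structure factor of the hard-sphere fluid.

    S(q) = 1 / (1 + 24 fp G(A)/A) with A = 2 q R_HS and the usual
    combination of trigonometric terms weighted by

        alpha = (1 + 2 fp)^2 / (1 - fp)^4
        beta  = -6 fp (1 + fp/2)^2 / (1 - fp)^4
        gamma = fp alpha / 2.

    S(0) = (1 - fp)^4 / (1 + 2 fp)^2 and S -> 1 at large q; fp = 0 gives
    S = 1 identically.  Small A uses the series expansion of each term
    (the direct expressions cancel catastrophically below A ~ 0.05).
    """
    scalar = np.ndim(q) == 0
    q = np.atleast_1d(np.asarray(q, dtype=float))
    fp = p.fp
    if fp == 0.0:
        out = np.ones_like(q)
        return out[0] if scalar else out

    al = (1.0 + 2.0 * fp) ** 2 / (1.0 - fp) ** 4
    be = -6.0 * fp * (1.0 + fp / 2.0) ** 2 / (1.0 - fp) ** 4
    ga = fp * al / 2.0

    A = 2.0 * q * p.R_HS
    GoA = np.empty_like(A)
    small = A < 0.05
    As = A[small]
    # series of (sin A - A cos A)/A^3 etc. to O(A^4)
    GoA[small] = (al * (1.0 / 3.0 - As**2 / 30.0 + As**4 / 840.0)
                  + be * (0.25 - As**2 / 36.0 + As**4 / 960.0)
                  + ga * (1.0 / 6.0 - As**2 / 48.0 + As**4 / 1200.0))
    Ab = A[~small]
    if Ab.size:
        sA, cA = np.sin(Ab), np.cos(Ab)
        GoA[~small] = (
            al * (sA - Ab * cA) / Ab**3
            + be * (2.0 * Ab * sA + (2.0 - Ab**2) * cA - 2.0) / Ab**4
            + ga * (-(Ab**4) * cA
                    + 4.0 * ((3.0 * Ab**2 - 6.0) * cA
                             + (Ab**3 - 6.0 * Ab) * sA + 6.0)) / Ab**6
        )
    S = 1.0 / (1.0 + 24.0 * fp * GoA)
    return S[0] if scalar else S


def combine(q, dist, ff: FormFactorModel, ff_params: dict, dist_param: str,
            sf: HardSphereParams | None = None,
            approx: SFApproximation | None = None) -> np.ndarray:
    """Intensity of one contribution: size distribution x form factor x S(q).

    ``dist_param`` names the form-factor parameter over which ``dist`` is
    distributed (it must exist in the model's parameter list); ``ff_params``
    holds the remaining, fixed parameter values.  With ``sf`` None the
    result is plain <F^2(q)>.
    """
    if dist_param not in ff.parameter_names:
        raise KeyError(f"model {ff.name!r} has no parameter {dist_param!r} "
                       "to distribute over")
    if approx is None:
        approx = SFApproximation("monodisperse")
    if sf is not None and approx.requires_amplitude and not ff.has_amplitude:
        raise AmplitudeRequiredError(
            f"structure-factor approximation {approx.kind!r} attempted in "
            f"combination with a form factor ({ff.name!r}) for which the "
            "scattering amplitude is not known")

    q = np.atleast_1d(np.asarray(q, dtype=float))
    x, w = _dist.quadrature_nodes(dist)
    fixed = {k: v for k, v in ff_params.items() if k != dist_param}

    # evaluate on the (node, q) product grid in one shot
    X = x[:, None]
    Q = q[None, :]
    I_nodes = ff.intensity(Q, **fixed, **{dist_param: X})
    F2 = w @ I_nodes  # <F^2>(q), scaled by N

    if sf is None:
        return F2

    if approx.kind == "monodisperse":
        return F2 * hard_sphere_S(q, sf)

    if approx.kind == "local_monodisperse":
        S_nodes = np.empty_like(I_nodes)
        for i, xi in enumerate(x):
            pi = HardSphereParams(R_HS=sf.R_HS * xi / dist.X0, fp=sf.fp)
            S_nodes[i] = hard_sphere_S(q, pi)
        return w @ (I_nodes * S_nodes)

    # decoupling: N [ <F^2>_1 + <F>_1^2 (S - 1) ]; the quadrature weights
    # carry the scale N, so the amplitude average must be renormalized
    if dist.N == 0:
        return F2
    F_nodes = ff.amplitude(Q, **fixed, **{dist_param: X})
    F1 = w @ F_nodes
    return F2 + F1**2 / dist.N * (hard_sphere_S(q, sf) - 1.0)
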