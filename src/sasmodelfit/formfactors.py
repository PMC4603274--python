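"""Form-factor models and the model registry.

A form factor describes the scattering of a single particle.  Some models
expose the scattering *amplitude* F(q) (the sphere does), others only the
intensity |F(q)|^2 — the distinction matters because certain
structure-factor approximations (the decoupling approach) need the
amplitude and must fail cleanly when only an intensity is available.

The registry mirrors a plug-in system: user models are registered under a
"by plug-ins" namespace, must declare parameters with range checks, start
out as templates that evaluate to zero until an evaluation contract is
attached, and may declare and call other registered models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import special

__all__ = [
    "Parameter",
    "ParameterRangeError",
    "FormFactorModel",
    "Registry",
    "REGISTRY",
    "sphere_amplitude",
    "sphere_intensity",
    "hammouda_branched_intensity",
    "register_model",
    "make_template",
    "SPHERE",
    "HAMMOUDA_BRANCHED",
]


class ParameterRangeError(ValueError):
    """A model parameter (or q) is outside its valid domain."""

    def __init__(self, param: str, value, message: str):
        self.param = param
        self.value = value
        super().__init__(f"parameter {param!r} = {value!r}: {message}")


@dataclass(frozen=True)
class Parameter:
    """One model parameter with its valid range.

    Bounds are inclusive unless ``open_lo``/``open_hi``; infinite bounds
    only require finiteness of the value.  Every parameter carries a range
    check — registration refuses models without one.
    """

    name: str
    description: str
    default: float
    lo: float = -math.inf
    hi: float = math.inf
    open_lo: bool = False
    open_hi: bool = False

    def check(self, value) -> None:
        v = np.asarray(value, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ParameterRangeError(self.name, value, "must be finite")
        bad = (v < self.lo) | (v > self.hi)
        if self.open_lo:
            bad |= v == self.lo
        if self.open_hi:
            bad |= v == self.hi
        if np.any(bad):
            lb = "(" if self.open_lo else "["
            rb = ")" if self.open_hi else "]"
            raise ParameterRangeError(
                self.name, value,
                f"outside valid range {lb}{self.lo:g}, {self.hi:g}{rb}")

    @property
    def help(self) -> str:
        return f"{self.name}: {self.description} (default {self.default:g})"


def _check_q(q) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ParameterRangeError("q", float(np.min(q)),
                                  "scattering vector magnitude q < 0")
    return q


@dataclass
class FormFactorModel:
    """A named scattering model: parameters + evaluation contract.

    ``evaluate_amplitude``/``evaluate_intensity`` map (q, parameter dict)
    to arrays; a freshly created template has neither and evaluates to
    zero.  ``uses`` declares other registered models the evaluation may
    call; they are handed over as the ``models`` dict.
    """

    name: str
    parameters: tuple
    description: str = ""
    evaluate_amplitude: object = None
    evaluate_intensity: object = None
    uses: tuple = ()
    _registry: object = field(default=None, repr=False)

    @property
    def has_amplitude(self) -> bool:
        return self.evaluate_amplitude is not None

    @property
    def parameter_names(self):
        return tuple(p.name for p in self.parameters)

    def defaults(self) -> dict:
        return {p.name: p.default for p in self.parameters}

    def check_params(self, params: dict) -> dict:
        vals = self.defaults()
        for k, v in params.items():
            if k not in vals:
                raise KeyError(f"model {self.name!r} has no parameter {k!r}; "
                               f"expected {self.parameter_names}")
            vals[k] = v
        for p in self.parameters:
            p.check(vals[p.name])
        return vals

    def _imports(self) -> dict:
        if not self.uses:
            return {}
        if self._registry is None:
            raise RuntimeError(f"model {self.name!r} declares imports {self.uses} "
                               "but is not registered")
        return {n: self._registry.get(n) for n in self.uses}

    def amplitude(self, q, **params) -> np.ndarray:
        if not self.has_amplitude:
            raise NotImplementedError(
                f"the scattering amplitude is not known for model {self.name!r}")
        q = _check_q(q)
        vals = self.check_params(params)
        if self.uses:
            return np.asarray(self.evaluate_amplitude(q, models=self._imports(), **vals))
        return np.asarray(self.evaluate_amplitude(q, **vals))

    def intensity(self, q, **params) -> np.ndarray:
        q = _check_q(q)
        vals = self.check_params(params)
        if self.evaluate_intensity is not None:
            if self.uses:
                return np.asarray(self.evaluate_intensity(q, models=self._imports(), **vals))
            return np.asarray(self.evaluate_intensity(q, **vals))
        if self.evaluate_amplitude is not None:
            return self.amplitude(q, **params) ** 2
        return np.zeros_like(q, dtype=float)  # bare template

    def help_text(self) -> str:
        lines = [f"{self.name}: {self.description or '(no description)'}"]
        lines += ["  " + p.help for p in self.parameters]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# sphere

def sphere_amplitude(q, R: float, eta: float = 1.0) -> np.ndarray:
    """Scattering amplitude of a homogeneous sphere.

    F(q) = eta * (4 pi / 3) R^3 * 3 [sin(qR) - qR cos(qR)] / (qR)^3

    eta is the scattering contrast (length^-2); the removable singularity
    at q = 0 is handled by the series 1 - x^2/10 + x^4/280 for qR < 1e-3,
    giving the forward limit F(0) = eta V.
    """
    R = np.asarray(R, dtype=float)
    if np.any(R <= 0):
        raise ParameterRangeError("R", R, "sphere radius must be > 0")
    # the kernel is even in q, so the bare function is defined for any sign;
    # the registered model wrapper still enforces q >= 0
    q = np.asarray(q, dtype=float)
    x = np.abs(q * R)
    V = 4.0 * math.pi / 3.0 * R**3
    small = x < 1e-3
    xs = np.where(small, 1.0, x)  # avoid 0/0 in the masked branch
    k = 3.0 * (np.sin(xs) - xs * np.cos(xs)) / xs**3
    k = np.where(small, 1.0 - x**2 / 10.0 + x**4 / 280.0, k)
    return eta * V * k


def sphere_intensity(q, R: float, eta: float = 1.0) -> np.ndarray:
    return sphere_amplitude(q, R=R, eta=eta) ** 2


# ---------------------------------------------------------------------------
# branched polymer (Hammouda): mass-fractal minimum path for the backbone

def hammouda_branched_intensity(q, Rg: float, v: float, c: float) -> np.ndarray:
    """Normalized form factor P(q) of a branched polymer.

    Integral form (the minimum path treated as a mass fractal with
    excluded-volume parameter v and scaling factor c):

        P(q) = (1/N) * int_0^1 c n^(c-1) (1 - n) exp(-u n^(2v)) dn,
        u    = q^2 Rg^2 (2v + 1)(2v + 2) / 6,
        N    = 1 / (c + 1)   (so that P(0) = 1).

    Substituting t = u n^(2v) turns the integral into lower incomplete
    gamma functions:

        P(q) = (c+1) (c / 2v) [ u^(-c/2v)     gamma(c/2v,     u)
                              - u^(-(c+1)/2v) gamma((c+1)/2v, u) ]

    Valid for Rg > 0 and v, c > 0 (the gamma-function arguments c/2v and
    (c+1)/2v must be positive).  q < 0 raises a range error naming q.
    """
    q = _check_q(q)
    Rg = np.asarray(Rg, dtype=float)
    if np.any(Rg <= 0):
        raise ParameterRangeError("Rg", Rg, "radius of gyration must be > 0")
    if v <= 0:
        raise ParameterRangeError("v", v, "excluded-volume parameter must be > 0")
    if c <= 0:
        raise ParameterRangeError("c", c, "scaling factor must be > 0")

    scalar = q.ndim == 0 and Rg.ndim == 0
    u = np.atleast_1d(q * q * Rg * Rg * (2.0 * v + 1.0) * (2.0 * v + 2.0) / 6.0)
    a1 = c / (2.0 * v)
    a2 = (c + 1.0) / (2.0 * v)
    out = np.ones_like(u, dtype=float)
    big = u > 1e-10  # below that P = 1 to machine accuracy
    ub = u[big]
    if ub.size:
        g1 = special.gammainc(a1, ub) * special.gamma(a1)
        g2 = special.gammainc(a2, ub) * special.gamma(a2)
        out[big] = (c + 1.0) * a1 * (ub ** -a1 * g1 - ub ** -a2 * g2)
    return out[0] if scalar else out


# ---------------------------------------------------------------------------
# registry

class Registry:
    """Enumerable store of form-factor models, grouped by namespace."""

    def __init__(self):
        self._models: dict[str, FormFactorModel] = {}
        self._namespace: dict[str, str] = {}

    def register(self, model: FormFactorModel,
                 namespace: str = "by plug-ins") -> FormFactorModel:
        if model.name in self._models:
            raise ValueError(f"a model named {model.name!r} is already registered")
        if not model.parameters:
            raise ValueError(f"model {model.name!r} defines no parameters; "
                             "at least one is required")
        for p in model.parameters:
            if not isinstance(p, Parameter):
                raise ValueError(f"model {model.name!r}: parameter {p!r} carries "
                                 "no range check; registration refused")
        for dep in model.uses:
            if dep not in self._models:
                raise ValueError(f"model {model.name!r} imports unknown model {dep!r}")
        model._registry = self
        self._models[model.name] = model
        self._namespace[model.name] = namespace
        return model

    def get(self, name: str) -> FormFactorModel:
        try:
            return self._models[name]
        except KeyError:
            raise KeyError(f"no model named {name!r}; known: "
                           f"{sorted(self._models)}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._models

    def list(self) -> dict:
        """Namespace -> sorted model names."""
        out: dict[str, list] = {}
        for name, ns in self._namespace.items():
            out.setdefault(ns, []).append(name)
        return {ns: sorted(names) for ns, names in sorted(out.items())}


def make_template(name: str, parameters) -> FormFactorModel:
    """A freshly created model without functionality: evaluates to zero."""
    return FormFactorModel(name=name, parameters=tuple(parameters),
                           description="template (no evaluation attached)")


SPHERE = FormFactorModel(
    name="sphere",
    description="homogeneous sphere of radius R and scattering contrast eta",
    parameters=(
        Parameter("R", "sphere radius (length)", 1.0, lo=0.0, open_lo=True),
        Parameter("eta", "scattering contrast (length^-2)", 1.0),
    ),
    evaluate_amplitude=lambda q, R, eta: sphere_amplitude(q, R=R, eta=eta),
    evaluate_intensity=lambda q, R, eta: sphere_intensity(q, R=R, eta=eta),
)

HAMMOUDA_BRANCHED = FormFactorModel(
    name="hammouda_branched",
    description=("branched polymer, mass-fractal minimum path; intensity "
                 "only (no scattering amplitude available)"),
    parameters=(
        Parameter("Rg", "radius of gyration (length)", 2.0, lo=0.0, open_lo=True),
        Parameter("v", "excluded-volume parameter", 0.588, lo=0.0, open_lo=True),
        Parameter("c", "scaling factor", 1.0, lo=0.0, open_lo=True),
    ),
    evaluate_intensity=lambda q, Rg, v, c: hammouda_branched_intensity(q, Rg=Rg, v=v, c=c),
)

#: default registry with the shipped models
REGISTRY = Registry()
REGISTRY.register(SPHERE, namespace="built-in")
REGISTRY.register(HAMMOUDA_BRANCHED, namespace="built-in")


def register_model(model: FormFactorModel, registry: Registry | None = None,
                   namespace: str = "by plug-ins") -> FormFactorModel:
    """Register a user model (range-checked parameters required)."""
    return (registry or REGISTRY).register(model, namespace=namespace)
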