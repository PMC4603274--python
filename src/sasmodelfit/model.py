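"""Total model intensity assembled from independent scattering contributions.

The model intensity is the sum over contributions

    I_model(q) = sum_c (+/-1) * int P_c(x) F_c^2(q, x) dx * [S_c(q)] + bkg

where each contribution couples a form factor, a number-weighted size
distribution applied to one named form-factor parameter, and an optional
structure factor with its combining approximation.  Contributions can be
disabled (``apply=False``, equivalent to removal), held constant during a
fit (``fixed``), or subtracted instead of added (``subtracted`` — the model
may then go negative, which is fine for display and flagged for fitting).

The distribution integral uses composite Simpson on the linear subdivision
of the adaptive integration range (see :mod:`sasmodelfit.distributions`).
A constant background term is included as an option (default 0) because
absolute-scaled experimental curves commonly need one.
"""

from __future__ import annotations

import configparser
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import distributions as _dist
from . import structurefactors as _sf
from .distributions import SizeDistribution
from .formfactors import REGISTRY, FormFactorModel
from .structurefactors import HardSphereParams, SFApproximation

__all__ = [
    "Contribution",
    "ModelConfig",
    "model_intensity",
    "distribution_quadrature",
    "save_config",
    "load_config",
]


@dataclass
class Contribution:
    """One scatterer population: form factor + distribution + optional S(q)."""

    form_factor: FormFactorModel
    params: dict = field(default_factory=dict)
    dist_param: str = "R"
    distribution: SizeDistribution = None
    structure_factor: HardSphereParams | None = None
    sf_approximation: SFApproximation | None = None
    apply: bool = True
    fixed: bool = False
    subtracted: bool = False

    def __post_init__(self):
        if self.distribution is None:
            self.distribution = SizeDistribution("monodisperse", N=1.0, X0=1.0)
        if self.dist_param not in self.form_factor.parameter_names:
            raise KeyError(
                f"distributed parameter {self.dist_param!r} is not a parameter "
                f"of model {self.form_factor.name!r} "
                f"(has {self.form_factor.parameter_names})")
        if self.structure_factor is not None and self.sf_approximation is None:
            self.sf_approximation = SFApproximation("monodisperse")

    def intensity(self, q) -> np.ndarray:
        try:
            return _sf.combine(q, self.distribution, self.form_factor,
                               self.params, self.dist_param,
                               sf=self.structure_factor,
                               approx=self.sf_approximation)
        except (FloatingPointError, ValueError) as exc:
            raise RuntimeError(
                f"integration failed for contribution {self.form_factor.name!r} "
                f"with distribution {self.distribution}: {exc}") from exc


@dataclass
class ModelConfig:
    """Ordered list of contributions plus an optional flat background."""

    contributions: list = field(default_factory=list)
    background: float = 0.0

    # ---- parameter addressing (used by fitting and the CLI) -------------
    # names: "c<i>.<ff param>", "c<i>.N|X0|s", "c<i>.R_HS|fp", "background"

    def param_names(self, include_fixed: bool = True) -> list:
        names = []
        for i, c in enumerate(self.contributions):
            if not include_fixed and c.fixed:
                continue
            for p in c.form_factor.parameters:
                if p.name != c.dist_param:
                    names.append(f"c{i}.{p.name}")
            names.append(f"c{i}.N")
            names.append(f"c{i}.X0")
            if c.distribution.kind != "monodisperse":
                names.append(f"c{i}.s")
            if c.structure_factor is not None:
                names.extend([f"c{i}.R_HS", f"c{i}.fp"])
        names.append("background")
        return names

    def _locate(self, name: str):
        if name == "background":
            return None, "background"
        head, _, pname = name.partition(".")
        if not head.startswith("c") or not pname:
            raise KeyError(f"bad parameter path {name!r}")
        return int(head[1:]), pname

    def get_param(self, name: str) -> float:
        i, pname = self._locate(name)
        if i is None:
            return self.background
        c = self.contributions[i]
        if pname in ("N", "X0", "s"):
            return getattr(c.distribution, pname)
        if pname in ("R_HS", "fp"):
            return getattr(c.structure_factor, pname)
        if pname in c.form_factor.parameter_names:
            return c.params.get(pname, c.form_factor.defaults()[pname])
        raise KeyError(f"unknown parameter {name!r}")

    def set_param(self, name: str, value: float) -> None:
        i, pname = self._locate(name)
        if i is None:
            self.background = float(value)
            return
        c = self.contributions[i]
        if pname in ("N", "X0", "s"):
            c.distribution = replace(c.distribution, **{pname: float(value)})
        elif pname in ("R_HS", "fp"):
            c.structure_factor = replace(c.structure_factor, **{pname: float(value)})
        elif pname in c.form_factor.parameter_names:
            c.params[pname] = float(value)
        else:
            raise KeyError(f"unknown parameter {name!r}")

    def n_applied(self) -> int:
        return sum(1 for c in self.contributions if c.apply)


def model_intensity(q, config: ModelConfig) -> np.ndarray:
    """Evaluate I_model on a q grid: signed sum of contributions + background."""
    q = np.atleast_1d(np.asarray(q, dtype=float))
    total = np.full(q.shape, float(config.background))
    for c in config.contributions:
        if not c.apply:
            continue
        sign = -1.0 if c.subtracted else 1.0
        total = total + sign * c.intensity(q)
    return total


def distribution_quadrature(contribution: Contribution, q, rel_tol: float = 1e-4):
    """<F^2>(q) and, when the amplitude exists, <F>(q) for one contribution.

    Both moments are computed in one pass over the quadrature nodes; the
    result is checked against a doubled subdivision count and a warning is
    raised if it has not converged to ``rel_tol`` relative.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    ff = contribution.form_factor
    dist = contribution.distribution
    fixed = {k: v for k, v in contribution.params.items()
             if k != contribution.dist_param}

    def eval_at(n_sub):
        x, w = _dist.quadrature_nodes(dist, n_sub=n_sub)
        X = x[:, None]
        F2 = w @ ff.intensity(q[None, :], **fixed, **{contribution.dist_param: X})
        F1 = (w @ ff.amplitude(q[None, :], **fixed, **{contribution.dist_param: X})
              if ff.has_amplitude else None)
        return F2, F1

    if dist.effective_kind == "monodisperse":
        return eval_at(None)

    n0 = _dist.integration_range(dist).n_sub
    F2a, F1a = eval_at(n0)
    F2b, F1b = eval_at(2 * n0)
    scale = np.max(np.abs(F2b)) or 1.0
    err = np.max(np.abs(F2b - F2a)) / scale
    if err > rel_tol:
        warnings.warn(
            f"distribution quadrature not converged to {rel_tol:g} "
            f"(relative change {err:.2e} on doubling); using refined value")
    return F2b, F1b


# ---------------------------------------------------------------------------
# plain-text project files (key = value sections, one per contribution)

def save_config(config: ModelConfig, path) -> None:
    cp = configparser.ConfigParser()
    cp["model"] = {"background": repr(float(config.background)),
                   "n_contributions": str(len(config.contributions))}
    for i, c in enumerate(config.contributions):
        sec = f"contribution{i}"
        cp[sec] = {
            "form_factor": c.form_factor.name,
            "dist_param": c.dist_param,
            "params": ", ".join(f"{k}={float(v)!r}"
                                for k, v in sorted(c.params.items())),
            "distribution": c.distribution.kind,
            "N": repr(float(c.distribution.N)),
            "X0": repr(float(c.distribution.X0)),
            "s": repr(float(c.distribution.s)),
            "apply": str(c.apply),
            "fixed": str(c.fixed),
            "subtracted": str(c.subtracted),
        }
        if c.structure_factor is not None:
            cp[sec]["structure_factor"] = "hard_sphere"
            cp[sec]["R_HS"] = repr(float(c.structure_factor.R_HS))
            cp[sec]["fp"] = repr(float(c.structure_factor.fp))
            cp[sec]["approximation"] = c.sf_approximation.kind
    with open(str(path), "w") as fh:
        cp.write(fh)


def load_config(path, registry=None) -> ModelConfig:
    registry = registry or REGISTRY
    cp = configparser.ConfigParser()
    read = cp.read(str(path))
    if not read or "model" not in cp:
        raise ValueError(f"not a model project file: {path!r}")
    config = ModelConfig(background=float(cp["model"].get("background", "0")))
    n = int(cp["model"].get("n_contributions", "0"))
    for i in range(n):
        sec = cp[f"contribution{i}"]
        params = {}
        for item in filter(None, (t.strip() for t in sec.get("params", "").split(","))):
            k, _, v = item.partition("=")
            params[k.strip()] = float(v)
        sf = appr = None
        if sec.get("structure_factor"):
            sf = HardSphereParams(R_HS=float(sec["R_HS"]), fp=float(sec["fp"]))
            appr = SFApproximation(sec.get("approximation", "monodisperse"))
        config.contributions.append(Contribution(
            form_factor=registry.get(sec["form_factor"]),
            params=params,
            dist_param=sec.get("dist_param", "R"),
            distribution=SizeDistribution(
                sec.get("distribution", "monodisperse"),
                N=float(sec.get("N", "1")), X0=float(sec.get("X0", "1")),
                s=float(sec.get("s", "0"))),
            structure_factor=sf,
            sf_approximation=appr,
            apply=sec.getboolean("apply", True),
            fixed=sec.getboolean("fixed", False),
            subtracted=sec.getboolean("subtracted", False),
        ))
    return config
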