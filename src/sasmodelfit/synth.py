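"""Synthetic scattering curves with known ground truth.

The generator emulates absolute-scaled SAXS curves of dilute nanoparticle
dispersions: a model intensity evaluated on a log-spaced q grid in
[0.057, 3.0] nm^-1 (the measured range of the reference data sets) with
heteroscedastic Gaussian noise,

    I_obs(q) = I_model(q) + eps,  eps ~ Normal(0, sigma(q)),
    sigma(q) = max(floor * I_model, counting * sqrt(I_model)),

written as the third column.  Gaussian (not Poisson) noise matches the
normality assumption behind the chi^2 weighting and the standard-error
interpretation of the fit.  Everything is reproducible from the seed and
the truth parameters travel with the curve for recovery tests.

The gold-like default reproduces the study conditions of a monomodal gold
dispersion: sphere contrast eta = 1.13e12 cm^-2, Gaussian radius
distribution N = 7.68e-30 (fitted units), X0 = 4.48 nm, s = 0.44 nm,
2% relative noise floor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .dataio import SASCurve
from .distributions import SizeDistribution
from .formfactors import REGISTRY
from .model import Contribution, ModelConfig, model_intensity

__all__ = [
    "SynthSpec",
    "gold_like_config",
    "gold_like_spec",
    "generate",
    "write_fixture",
    "write_manifest",
]

GOLD_TRUTH = {"N": 7.68e-30, "X0": 4.48, "s": 0.44, "eta": 1.13e12}


def gold_like_config(N: float = GOLD_TRUTH["N"], X0: float = GOLD_TRUTH["X0"],
                     s: float = GOLD_TRUTH["s"],
                     eta: float = GOLD_TRUTH["eta"]) -> ModelConfig:
    """Sphere + Gaussian radius distribution with gold-dispersion parameters."""
    return ModelConfig(contributions=[Contribution(
        form_factor=REGISTRY.get("sphere"),
        params={"eta": eta},
        dist_param="R",
        distribution=SizeDistribution("gaussian", N=N, X0=X0, s=s),
    )])


@dataclass
class SynthSpec:
    """Truth model + q grid + noise model + seed."""

    config: ModelConfig
    n_points: int = 500
    qmin: float = 0.057
    qmax: float = 3.0
    spacing: str = "log"
    noise_floor: float = 0.02   # relative sigma/I floor
    counting: float = 0.0       # counting-statistics term, sigma = counting*sqrt(I)
    seed: int = 0

    def __post_init__(self):
        if self.qmin <= 0:
            raise ValueError("qmin must be > 0")
        if self.n_points < 10:
            raise ValueError("n_points must be >= 10")
        if self.noise_floor < 0 or self.counting < 0:
            raise ValueError("noise parameters must be >= 0")
        if self.spacing not in ("linear", "log"):
            raise ValueError("spacing must be 'linear' or 'log'")

    def q_grid(self) -> np.ndarray:
        if self.spacing == "log":
            return np.geomspace(self.qmin, self.qmax, self.n_points)
        return np.linspace(self.qmin, self.qmax, self.n_points)


def gold_like_spec(n_points: int = 500, seed: int = 0,
                   noise_floor: float = 0.02, **truth) -> SynthSpec:
    return SynthSpec(config=gold_like_config(**truth), n_points=n_points,
                     noise_floor=noise_floor, seed=seed)


def _truth_record(spec: SynthSpec) -> dict:
    rec = {"seed": spec.seed, "n_points": spec.n_points,
           "qmin": spec.qmin, "qmax": spec.qmax,
           "noise_floor": spec.noise_floor, "counting": spec.counting,
           "background": spec.config.background, "contributions": []}
    for c in spec.config.contributions:
        rec["contributions"].append({
            "form_factor": c.form_factor.name,
            "params": dict(c.params),
            "dist_param": c.dist_param,
            "distribution": {"kind": c.distribution.kind, "N": c.distribution.N,
                             "X0": c.distribution.X0, "s": c.distribution.s},
        })
    return rec


def generate(spec: SynthSpec):
    """Simulate one curve; returns (SASCurve, truth record dict)."""
    q = spec.q_grid()
    I_true = model_intensity(q, spec.config)
    sigma = np.maximum(spec.noise_floor * np.abs(I_true),
                       spec.counting * np.sqrt(np.abs(I_true)))
    rng = np.random.default_rng(spec.seed)
    I_obs = I_true + (rng.normal(0.0, 1.0, q.size) * sigma
                      if sigma.max() > 0 else 0.0)
    # keep sigma strictly positive so the curve is directly fittable
    sig_out = np.maximum(sigma, 1e-12 * np.maximum(np.abs(I_true), 1e-300))
    curve = SASCurve(q, I_obs, sig_out,
                     source=tuple(f"synth(seed={spec.seed})" for _ in q))
    curve.log.append(f"generated: seed={spec.seed}, n={spec.n_points}, "
                     f"noise_floor={spec.noise_floor}, counting={spec.counting}")
    return curve, _truth_record(spec)


def write_fixture(curve: SASCurve, path, dialect: str = "ascii",
                  truth: dict | None = None) -> None:
    """Write a curve as a test fixture, re-readable by dataio.read_curve.

    dialect='ascii' uses '# '-comment headers; dialect='pdh' prepends
    PDH-style non-numeric header lines (no comment markers) to exercise
    the float-parse rule of the reader.
    """
    if dialect not in ("ascii", "pdh"):
        raise ValueError("dialect must be 'ascii' or 'pdh'")
    with open(str(path), "w") as fh:
        if dialect == "pdh":
            fh.write("synthetic scattering curve (pdh-like header)\n")
            fh.write("SAXS columns: q I sigma\n")
            if truth is not None:
                fh.write("truth: " + json.dumps(truth) + "\n")
            else:
                fh.write("no truth record attached\n")
        else:
            fh.write("# synthetic scattering curve\n")
            if truth is not None:
                fh.write("# truth: " + json.dumps(truth) + "\n")
        for qi, Ii, si in zip(curve.q, curve.I, curve.sigma):
            fh.write(f"{float(qi)!r} {float(Ii)!r} {float(si)!r}\n")


def write_manifest(records, path) -> None:
    """JSON manifest of seeds and truth parameters for a fixture batch."""
    with open(str(path), "w") as fh:
        json.dump(list(records), fh, indent=1)
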