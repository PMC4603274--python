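"""Weighted least-squares fitting with Levenberg-Marquardt and full
fit-quality / parameter-uncertainty reporting.

The quantity minimized is the reduced chi-squared

    chi2_red = 1/(N - M) * sum_i [ (I_exp(q_i) - I_model(q_i)) / sigma_i ]^2

with N data points inside the fit window and M free parameters.  Reported
alongside the best fit:

Q factor
    Q((N-M)/2, chi2/2), the regularized upper incomplete gamma function —
    the probability that random data of the same size would produce a chi2
    at least as large.  Good fits land roughly in 0.01-0.5 with
    chi2_red ~ 1.
R value / wR value
    Crystallography-style residual norms,
    R  = sum |I_exp - I_model| / sum |I_exp| and
    wR = sqrt( sum w (I_exp - I_model)^2 / sum w I_exp^2 ), w = 1/sigma^2.
covariance / correlation
    C is the inverse of the approximate Hessian J^T J of the weighted
    residuals; stderr_i = sqrt(C_ii); cc_ij = C_ij / sqrt(C_ii C_jj).
    Pairs with |cc| > 0.95 are flagged; an (almost) singular Hessian gets a
    degeneracy diagnostic naming the correlated subset and undefined
    stderr for the parameters involved.

Two bound-handling modes exist: the default ``interrupt`` mode stops the
fit with a named error as soon as a parameter leaves its range; the opt-in
``bounded`` mode maps two-sided ranges through a sine transform so the
optimizer can never leave them.

The recommended stepwise workflow (scale first on the low-q part, then
size on the central part, then both jointly, then size + width) is
available through :func:`three_step_workflow` / :func:`run_workflow`.
"""

from __future__ import annotations

import copy
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

from .dataio import SASCurve
from .model import ModelConfig, model_intensity

__all__ = [
    "FitProblem",
    "FitResult",
    "FitInterrupted",
    "UnderdeterminedError",
    "fit",
    "chi2_reduced",
    "q_factor",
    "r_values",
    "covariance_report",
    "WorkflowStep",
    "run_workflow",
    "three_step_workflow",
    "default_bounds",
]

STDERR_CAVEAT = ("standard errors assume independent, normally distributed "
                 "measurement errors and uncorrelated parameters")

#: relative step of the central-difference derivatives
DERIV_REL_STEP = 1e-6
#: LM convergence tolerances and iteration cap
XTOL, FTOL, MAX_ITER = 1e-8, 1e-10, 500
#: |correlation| above which a parameter pair is flagged
CORR_FLAG = 0.95


class FitInterrupted(RuntimeError):
    """A parameter left its defined range during optimization."""

    def __init__(self, param: str, value: float, lo: float, hi: float):
        self.param = param
        self.value = value
        super().__init__(
            f"fit interrupted: parameter {param!r} = {value:g} left its "
            f"range [{lo:g}, {hi:g}]")


class UnderdeterminedError(ValueError):
    """Fewer data points than free parameters."""


@dataclass
class FitProblem:
    """Data + model + choice of free parameters for one fit step."""

    data: SASCurve
    config: ModelConfig
    active: list
    bounds: dict = field(default_factory=dict)
    q_window: tuple | None = None

    def windowed(self):
        d = self.data
        if self.q_window is not None:
            d = d.with_window(*self.q_window)
        if d.sigma is None or np.any(d.sigma <= 0):
            raise ValueError("fitting requires positive sigma on the fit "
                             "window (run estimate_sigma first)")
        return d


@dataclass
class FitResult:
    """Best-fit parameters with uncertainties and fit-quality measures."""

    params: dict
    stderr: dict
    covariance: np.ndarray
    correlation: np.ndarray
    chi2: float
    chi2red: float
    Qfactor: float
    R: float
    wR: float
    n_points: int
    n_params: int
    n_eval: int
    flagged_pairs: list
    degenerate: list
    log: list
    caveat: str = STDERR_CAVEAT
    success: bool = True

    def report(self) -> str:
        lines = [f"fit of {self.n_params} parameter(s) on {self.n_points} points",
                 f"chi2red = {self.chi2red:.6g}   Q factor = {self.Qfactor:.6g}",
                 f"R value = {self.R:.6g}   wR value = {self.wR:.6g}"]
        for name in self.params:
            se = self.stderr[name]
            se_s = f"{se:.3g}" if np.isfinite(se) else "undefined"
            lines.append(f"  {name} = {self.params[name]:.9g} +/- {se_s}")
        for a, b, cc in self.flagged_pairs:
            lines.append(f"  warning: |cc({a}, {b})| = {abs(cc):.4f} > {CORR_FLAG}")
        if self.degenerate:
            lines.append("  degeneracy: correlated subset " + ", ".join(self.degenerate))
        lines.append(f"note: {self.caveat}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# fit statistics

def chi2_reduced(I_exp, I_model, sigma, M: int) -> float:
    """Reduced chi-squared: weighted SSR over N - M degrees of freedom."""
    I_exp, I_model, sigma = map(np.asarray, (I_exp, I_model, sigma))
    N = I_exp.size
    if N <= M:
        raise UnderdeterminedError(f"N = {N} points <= M = {M} parameters")
    return float(np.sum(((I_exp - I_model) / sigma) ** 2) / (N - M))


def q_factor(chi2: float, N: int, M: int) -> float:
    """Goodness probability Q((N-M)/2, chi2/2): chance of a chi2 this large.

    Monotone decreasing in chi2; Q(chi2=0) = 1.
    """
    if N <= M:
        raise UnderdeterminedError(f"N = {N} points <= M = {M} parameters")
    return float(special.gammaincc((N - M) / 2.0, chi2 / 2.0))


def r_values(I_exp, I_model, sigma) -> dict:
    """Crystallography-style R and weighted wR residual norms."""
    I_exp, I_model, sigma = map(np.asarray, (I_exp, I_model, sigma))
    denom = np.sum(np.abs(I_exp))
    if denom == 0:
        raise ValueError("R value undefined for all-zero data")
    R = float(np.sum(np.abs(I_exp - I_model)) / denom)
    w = 1.0 / sigma**2
    wR = float(math.sqrt(np.sum(w * (I_exp - I_model) ** 2)
                         / np.sum(w * I_exp**2)))
    return {"R": R, "wR": wR}


# ---------------------------------------------------------------------------
# covariance / correlation

def covariance_report(jacobian: np.ndarray, names) -> dict:
    """Covariance, stderr and correlation from the weighted-residual Jacobian.

    C = (J^T J)^(-1), the inverse approximate Hessian.  A (near-)singular
    Hessian yields undefined (NaN) stderr for the parameters spanning the
    degenerate direction, plus a diagnostic naming them; the correlation
    matrix is then computed from a minimally ridged Hessian so the
    offending |cc| -> 1 entries remain visible.
    """
    names = list(names)
    H = jacobian.T @ jacobian
    # scale disparity between parameters can reach ~10^60 in H; the
    # degeneracy test must therefore act on the correlation-normalized
    # Hessian, not on raw eigenvalues
    dH = np.sqrt(np.diag(H))
    degenerate: list = []
    if np.any(dH == 0):
        degenerate = [n for n, z in zip(names, dH == 0) if z]
        dH = np.where(dH == 0, 1.0, dH)
    Hn = H / np.outer(dH, dH)
    evals, evecs = np.linalg.eigh(Hn)
    if evals[0] <= evals[-1] * 1e-12 or evals[0] <= 0:
        null = evecs[:, 0]
        involved = np.abs(null) > 0.1 * np.max(np.abs(null))
        degenerate = sorted(set(degenerate)
                            | {n for n, m in zip(names, involved) if m})
        Hn = Hn + max(evals[-1], 1.0) * 1e-14 * np.eye(len(names))
    Cn = np.linalg.inv(Hn)
    C = Cn / np.outer(dH, dH)
    d = np.sqrt(np.diag(C))
    cc = Cn / np.outer(np.sqrt(np.diag(Cn)), np.sqrt(np.diag(Cn)))
    np.fill_diagonal(cc, 1.0)
    stderr = {n: (math.nan if (degenerate and n in degenerate) else float(s))
              for n, s in zip(names, d)}
    flagged = [(names[i], names[j], float(cc[i, j]))
               for i in range(len(names)) for j in range(i + 1, len(names))
               if abs(cc[i, j]) > CORR_FLAG]
    return {"covariance": C, "correlation": cc, "stderr": stderr,
            "flagged_pairs": flagged, "degenerate": degenerate}


def _central_jacobian(resid, x: np.ndarray) -> np.ndarray:
    """Central differences with relative step DERIV_REL_STEP."""
    r0 = resid(x)
    J = np.empty((r0.size, x.size))
    for j in range(x.size):
        # purely relative step: parameters span ~30 orders of magnitude
        h = DERIV_REL_STEP * abs(x[j]) if x[j] != 0 else DERIV_REL_STEP
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] -= h
        J[:, j] = (resid(xp) - resid(xm)) / (2.0 * h)
    return J


# ---------------------------------------------------------------------------
# bound transforms (bounded mode)

def _to_internal(x, lo, hi):
    if math.isfinite(lo) and math.isfinite(hi):
        frac = (x - lo) / (hi - lo)
        frac = min(max(frac, 1e-12), 1 - 1e-12)
        return math.asin(2.0 * frac - 1.0)
    return x


def _to_external(t, lo, hi):
    if math.isfinite(lo) and math.isfinite(hi):
        return lo + (hi - lo) * (math.sin(t) + 1.0) / 2.0
    return t


# ---------------------------------------------------------------------------
# the fit itself

def fit(problem: FitProblem, mode: str = "interrupt", seed=None) -> FitResult:
    """Minimize chi^2 over the active parameters by Levenberg-Marquardt.

    mode='interrupt' (default): the fit stops with :class:`FitInterrupted`
    naming the parameter as soon as any active parameter leaves its bounds
    (starting outside is caught immediately).  mode='bounded': parameters
    with finite two-sided bounds are optimized through a sine transform
    and can never leave them.

    On success the best-fit values are written back into
    ``problem.config`` so workflow steps can share one configuration.
    ``seed`` is accepted for interface symmetry with stochastic restarts;
    the plain LM path is deterministic.
    """
    if mode not in ("interrupt", "bounded"):
        raise ValueError("mode must be 'interrupt' or 'bounded'")
    names = list(problem.active)
    if not names:
        raise ValueError("at least one active parameter required")
    fixed_contribs = {i for i, c in enumerate(problem.config.contributions) if c.fixed}
    for n in names:
        if n.startswith("c") and "." in n:
            ci = int(n.partition(".")[0][1:])
            if ci in fixed_contribs:
                raise ValueError(f"parameter {n!r} belongs to a fixed contribution")

    data = problem.windowed()
    q, I_exp, sigma = data.q, data.I, data.sigma
    N, M = q.size, len(names)
    if N <= M:
        raise UnderdeterminedError(f"N = {N} points <= M = {M} parameters")

    config = problem.config
    bounds = {n: problem.bounds.get(n, (-math.inf, math.inf)) for n in names}
    x0 = np.array([config.get_param(n) for n in names], dtype=float)

    n_eval = [0]

    def set_params(x):
        for n, v in zip(names, x):
            config.set_param(n, float(v))

    def resid(x):
        set_params(x)
        n_eval[0] += 1
        Im = model_intensity(q, config)
        return (I_exp - Im) / sigma

    def resid_checked(x):
        for n, v in zip(names, x):
            lo, hi = bounds[n]
            if not lo <= v <= hi:
                raise FitInterrupted(n, float(v), lo, hi)
        return resid(x)

    r0 = resid_checked(x0) if mode == "interrupt" else resid(x0)
    if not np.all(np.isfinite(r0)):
        raise ValueError("invalid start point: model is not finite at the "
                         "starting parameters")

    log = [f"start: chi2red = {np.sum(r0**2) / (N - M):.6g}"]

    if mode == "interrupt":
        sol = optimize.least_squares(resid_checked, x0, method="lm",
                                     xtol=XTOL, ftol=FTOL, gtol=1e-12,
                                     max_nfev=MAX_ITER * (M + 1))
        x_best = sol.x
    else:
        for n in names:
            lo, hi = bounds[n]
            if math.isfinite(lo) != math.isfinite(hi):
                raise ValueError(f"bounded mode needs two-sided finite bounds "
                                 f"(or none) for {n!r}")
        t0 = np.array([_to_internal(v, *bounds[n]) for v, n in zip(x0, names)])

        def resid_t(t):
            return resid(np.array([_to_external(ti, *bounds[n])
                                   for ti, n in zip(t, names)]))

        sol = optimize.least_squares(resid_t, t0, method="lm",
                                     xtol=XTOL, ftol=FTOL, gtol=1e-12,
                                     max_nfev=MAX_ITER * (M + 1))
        x_best = np.array([_to_external(ti, *bounds[n])
                           for ti, n in zip(sol.x, names)])

    set_params(x_best)
    r_best = resid(x_best)
    chi2 = float(np.sum(r_best**2))
    log.append(f"converged after {n_eval[0]} model evaluations: "
               f"chi2red = {chi2 / (N - M):.6g} ({sol.message})")

    # uncertainties from the Hessian approximation in *external* space
    J = _central_jacobian(resid, x_best)
    set_params(x_best)  # jacobian probing moved the config; restore best fit
    cov = covariance_report(J, names)

    Im_best = model_intensity(q, config)
    rv = r_values(I_exp, Im_best, sigma)
    return FitResult(
        params={n: float(v) for n, v in zip(names, x_best)},
        stderr=cov["stderr"],
        covariance=cov["covariance"],
        correlation=cov["correlation"],
        chi2=chi2,
        chi2red=chi2 / (N - M),
        Qfactor=q_factor(chi2, N, M),
        R=rv["R"],
        wR=rv["wR"],
        n_points=N,
        n_params=M,
        n_eval=n_eval[0],
        flagged_pairs=cov["flagged_pairs"],
        degenerate=cov["degenerate"],
        log=log,
        success=bool(sol.success),
    )


# ---------------------------------------------------------------------------
# stepwise workflow

@dataclass
class WorkflowStep:
    """One step of the stepwise fitting procedure."""

    active: list
    q_window: tuple | None = None
    label: str = ""


def default_bounds(config: ModelConfig, names) -> dict:
    """Generous two-sided bounds around the current values (for bounded mode)."""
    out = {}
    for n in names:
        v = config.get_param(n)
        if n.endswith(".N"):
            out[n] = (v / 1e3, v * 1e3)
        elif n.endswith(".X0"):
            out[n] = (v / 5.0, v * 5.0)
        elif n.endswith(".s"):
            out[n] = (v / 50.0, v * 20.0)
        elif n.endswith(".fp"):
            out[n] = (0.0, 0.739)
        else:
            scale = abs(v) if v else 1.0
            out[n] = (v - 10 * scale, v + 10 * scale)
    return out


def _index_window(q: np.ndarray, lo_frac: float, hi_frac: float) -> tuple:
    n = q.size
    i0 = int(lo_frac * (n - 1))
    i1 = int(round(hi_frac * (n - 1)))
    return (float(q[i0]), float(q[i1]))


def three_step_workflow(data: SASCurve, N_name: str, X0_name: str,
                        s_name: str) -> list:
    """The recommended stepwise procedure as a list of workflow steps.

    (1) scale N on the beginning (low-q fifth) of the curve;
    (2) size X0 on the central part;
    (3) N and X0 together over the first two-thirds;
    then X0 with the width s on the central part, and a concluding joint
    refinement of all three over the full window (the repeat-until-good
    cycle collapsed into one final step, which also provides uncertainties
    that include the N-X0-s correlations).
    """
    q = data.q
    return [
        WorkflowStep([N_name], _index_window(q, 0.0, 0.2), "scale at low q"),
        WorkflowStep([X0_name], _index_window(q, 0.3, 0.7), "size, central part"),
        WorkflowStep([N_name, X0_name], _index_window(q, 0.0, 2.0 / 3.0),
                     "scale + size, first two-thirds"),
        WorkflowStep([X0_name, s_name], _index_window(q, 0.25, 0.75),
                     "size + width, central part"),
        WorkflowStep([N_name, X0_name, s_name], None, "joint refinement"),
    ]


def run_workflow(data: SASCurve, config: ModelConfig, steps,
                 bounds: dict | None = None, mode: str = "bounded") -> list:
    """Run fit steps in sequence on one shared model configuration.

    Each step starts from the previous step's best fit (``fit`` writes back
    into ``config``).  Returns the list of per-step :class:`FitResult`.
    """
    results = []
    for step in steps:
        b = dict(bounds) if bounds else {}
        if mode == "bounded":
            auto = default_bounds(config, step.active)
            for n in step.active:
                b.setdefault(n, auto[n])
        problem = FitProblem(data=data, config=config, active=step.active,
                             bounds=b, q_window=step.q_window)
        res = fit(problem, mode=mode)
        res.log.append(f"workflow step: {step.label or step.active}")
        results.append(res)
    return results
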