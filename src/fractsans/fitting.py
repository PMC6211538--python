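"""Model intensities 1-4, resolution smearing, weighted fits and F-tests.

Four nested descriptions of a curve, all in absolute units:

1. single particle:            I = K n P(q) + B
2. particle + fractal oligomers of it:
                               I = K n [(1-g) P + g P S'(q)] + B
3. two-state mixture:          I = K n [(1-a) P_atm + a P_em] + B
4. two states, each also forming oligomers (models 2 and 3 combined).

P(q) is stored unnormalized (it carries the squared excess scattering
length), n is the particle number density, K a concentration correction
factor and B a flat background.  Oligomer mixing is per-particle
number-fraction mixing: a fraction g of particles sits in fractal oligomers
whose per-particle intensity is P(q) S'(q), with S' the decoupled Teixeira
structure factor.  This reduces exactly to model 1 at g = 0 and makes the
oligomer excess vanish as S' -> 1.

Resolution smearing is a Gaussian convolution in q with the per-point widths
sigma_q from the data file (21-point Gauss-Legendre over +-3 sigma).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .curves import SANSCurve
from .fractal import FractalModel, teixeira_sq, xi_from_rg
from .scattering import FormFactorTable

__all__ = [
    "ModelSpec",
    "FitResult",
    "FTestResult",
    "model_intensity",
    "smear",
    "smear_model",
    "chi_square",
    "fit",
    "f_test",
    "MODEL_PARAMS",
]

MODEL_PARAMS: dict[int, tuple[str, ...]] = {
    1: ("K", "B"),
    2: ("K", "B", "rg_olig", "gamma"),
    3: ("K", "B", "alpha"),
    4: ("K", "B", "rg_olig", "gamma", "alpha"),
}

_DEFAULT_START = {"K": 1.0, "B": 0.0, "rg_olig": 300.0, "gamma": 0.01, "alpha": 0.1}
_DEFAULT_BOUNDS = {
    "K": (1e-8, 10.0),
    "B": (-0.1, 0.1),
    "rg_olig": (10.0, 2000.0),
    "gamma": (0.0, 1.0),
    "alpha": (0.0, 1.0),
}
_X_SCALE = {"K": 1.0, "B": 0.001, "rg_olig": 100.0, "gamma": 0.01, "alpha": 0.1}


@dataclass
class ModelSpec:
    """Which model to evaluate and from what ingredients.

    ``components`` maps "atomic" (and "em" for models 3/4) to form-factor
    tables; ``fractal`` carries the fixed fractal parameters (D, k, subunit
    distance r) for models 2/4; ``concentration_n`` is the particle number
    density in 1/cm^3.
    """

    model_id: int
    components: dict[str, FormFactorTable]
    concentration_n: float
    fractal: FractalModel | None = None

    def __post_init__(self):
        if self.model_id not in MODEL_PARAMS:
            raise ValueError(f"model_id must be 1-4, got {self.model_id}")
        if "atomic" not in self.components:
            raise ValueError("'atomic' component table is required")
        if self.model_id in (3, 4) and "em" not in self.components:
            raise ValueError(f"model {self.model_id} requires an 'em' component")
        if self.model_id in (2, 4) and self.fractal is None:
            raise ValueError(f"model {self.model_id} requires fractal parameters")
        if self.concentration_n <= 0:
            raise ValueError("concentration_n must be positive")

    @property
    def param_names(self) -> tuple[str, ...]:
        return MODEL_PARAMS[self.model_id]


def _component_intensity(
    table: FormFactorTable, q: np.ndarray, gamma: float, S: np.ndarray | None
) -> np.ndarray:
    P = table.interp_P(q)
    if gamma == 0.0 or S is None:
        return P
    beta = table.interp_beta(q)
    s_eff = 1.0 + beta * (S - 1.0)
    return (1.0 - gamma) * P + gamma * P * s_eff


def model_intensity(spec: ModelSpec, params: dict, q_grid) -> np.ndarray:
    """Unsmeared model intensity in 1/cm on ``q_grid``."""
    q = np.atleast_1d(np.asarray(q_grid, dtype=float))
    K, B = params["K"], params["B"]
    gamma = float(params.get("gamma", 0.0)) if spec.model_id in (2, 4) else 0.0
    alpha = float(params.get("alpha", 0.0)) if spec.model_id in (3, 4) else 0.0
    S = None
    if spec.model_id in (2, 4) and gamma != 0.0:
        fr = spec.fractal
        rg = float(params.get("rg_olig", fr.rg_olig))
        S = teixeira_sq(q, fr.D, fr.r, xi_from_rg(rg, fr.D))
    I = (1.0 - alpha) * _component_intensity(spec.components["atomic"], q, gamma, S)
    if alpha != 0.0:
        I = I + alpha * _component_intensity(spec.components["em"], q, gamma, S)
    return K * spec.concentration_n * I + B


def _gauss_nodes(n_quad: int, half_width: float = 3.0):
    x, w = np.polynomial.legendre.leggauss(n_quad)
    u = x * half_width  # node offsets in units of sigma
    wt = w * np.exp(-0.5 * u**2)
    return u, wt / wt.sum()


def smear_model(func, q_grid, sigma_q, n_quad: int = 21) -> np.ndarray:
    """Gaussian resolution smearing of a model callable.

    ``func`` is evaluated at |q'| for quadrature nodes q' = q + u sigma_q(q);
    the mirrored evaluation uses the evenness of I(q).  Points with
    sigma_q = 0 pass through unchanged.
    """
    q = np.asarray(q_grid, dtype=float)
    sq = np.asarray(sigma_q, dtype=float)
    if sq.shape != q.shape:
        raise ValueError("sigma_q must match q_grid in length")
    if np.all(sq == 0):
        return np.asarray(func(q), dtype=float)
    u, wt = _gauss_nodes(n_quad)
    nodes = np.abs(q[:, None] + u[None, :] * sq[:, None])  # (n_q, n_quad)
    flat = func(nodes.ravel()).reshape(nodes.shape)
    out = (flat * wt[None, :]).sum(axis=1)
    zero = sq == 0
    if np.any(zero):
        out[zero] = np.asarray(func(q[zero]), dtype=float)
    return out


def smear(model_values, q_grid, sigma_q, n_quad: int = 21) -> np.ndarray:
    """Smear already-tabulated model values (interpolating on the grid).

    Quadrature nodes outside the tabulated range clamp to the edge values;
    for accurate smearing near the edges evaluate the model on an extended
    grid and use :func:`smear_model` instead.
    """
    q = np.asarray(q_grid, dtype=float)
    I = np.asarray(model_values, dtype=float)

    def interp(qq):
        return np.interp(np.clip(qq, q[0], q[-1]), q, I)

    return smear_model(interp, q, sigma_q, n_quad=n_quad)


def chi_square(data: SANSCurve, model_values, n_params: int = 0):
    """(chi2, reduced chi2, dof) of model values against a curve."""
    model_values = np.asarray(model_values, dtype=float)
    resid = (model_values - data.I) / data.sigma
    chi2 = float(np.sum(resid**2))
    dof = len(data) - n_params
    chi2_red = chi2 / dof if dof > 0 else np.inf
    return chi2, chi2_red, dof


@dataclass
class FitResult:
    """Fitted parameters with curvature-based uncertainties and fit quality."""

    model_id: int
    params: dict[str, float]
    errors: dict[str, float]
    chi2: float
    chi2_reduced: float
    dof: int
    n_points: int
    n_params: int
    converged: bool = True
    message: str = ""
    correlation: np.ndarray | None = None
    free_names: tuple[str, ...] = ()
    fixed: dict[str, float] = field(default_factory=dict)
    #: asymmetric profile-likelihood uncertainties {name: (minus, plus)},
    #: filled in when fit() is asked to profile specific parameters
    profile_errors: dict[str, tuple[float, float]] = field(default_factory=dict)

    def residuals(self, data: SANSCurve, spec: ModelSpec) -> np.ndarray:
        return (evaluate(spec, self.params, data) - data.I) / data.sigma

    def to_dict(self) -> dict:
        corr = None
        if self.correlation is not None:
            corr = [[round(float(c), 6) for c in row] for row in self.correlation]
        return {
            "model_id": self.model_id,
            "params": {k: float(v) for k, v in self.params.items()},
            "errors": {k: float(v) for k, v in self.errors.items()},
            "fixed": {k: float(v) for k, v in self.fixed.items()},
            "chi2": float(self.chi2),
            "chi2_reduced": float(self.chi2_reduced),
            "dof": self.dof,
            "n_points": self.n_points,
            "n_params": self.n_params,
            "converged": self.converged,
            "message": self.message,
            "free_params": list(self.free_names),
            "correlation": corr,
            "profile_errors": {
                k: [float(v[0]), float(v[1])] for k, v in self.profile_errors.items()
            },
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)


def evaluate(spec: ModelSpec, params: dict, data: SANSCurve) -> np.ndarray:
    """Model intensity on a curve's grid, smeared when the curve has sigma_q."""
    if data.sigma_q is not None and np.any(data.sigma_q > 0):
        return smear_model(
            lambda qq: model_intensity(spec, params, _clip_to_tables(spec, qq)),
            data.q,
            data.sigma_q,
        )
    return model_intensity(spec, params, data.q)


def _clip_to_tables(spec: ModelSpec, q: np.ndarray) -> np.ndarray:
    lo = max(t.q[0] for t in spec.components.values())
    hi = min(t.q[-1] for t in spec.components.values())
    return np.clip(q, lo, hi)


def fit(
    spec: ModelSpec,
    data: SANSCurve,
    start: dict | None = None,
    bounds: dict | None = None,
    fix: dict | None = None,
    multistart: int = 0,
    seed: int | None = None,
    max_nfev: int = 2000,
    profile: tuple[str, ...] = (),
    profile_delta_chi2: float = 1.0,
) -> FitResult:
    """Weighted least-squares fit of a model to a curve.

    ``fix`` pins named parameters to constants (they do not count as free
    parameters).  ``multistart`` adds that many extra random starts drawn
    uniformly from the bounds (seeded); the best optimum is kept.
    Non-convergence is flagged on the result rather than raised.

    ``errors`` on the result are local-curvature (Wald) standard
    uncertainties.  For strongly correlated, non-linear parameters (the
    oligomer fraction and its R_g are the canonical pair) these can badly
    understate one side of the confidence region, so ``profile`` names
    parameters for which asymmetric profile-likelihood uncertainties (the
    delta chi2 = ``profile_delta_chi2`` crossings; 1 for 1-sigma, 9 for the
    3-sigma interval of a non-quadratic profile) are also computed and
    stored in ``profile_errors``.
    """
    fix = dict(fix or {})
    names = [p for p in spec.param_names if p not in fix]
    if not names:
        raise ValueError("no free parameters")
    n_free = len(names)
    if len(data) <= n_free:
        raise ValueError("dof must be positive")
    start_all = {**_DEFAULT_START, **(start or {})}
    bounds_all = {**_DEFAULT_BOUNDS, **(bounds or {})}
    lo = np.array([bounds_all[p][0] for p in names])
    hi = np.array([bounds_all[p][1] for p in names])
    x0 = np.clip(np.array([start_all[p] for p in names]), lo, hi)

    def unpack(x) -> dict:
        p = {n: v for n, v in zip(names, x)}
        p.update(fix)
        return p

    def resid(x):
        return (evaluate(spec, unpack(x), data) - data.I) / data.sigma

    starts = [x0]
    if multistart > 0:
        rng = np.random.default_rng(seed)
        for _ in range(multistart):
            starts.append(lo + rng.random(n_free) * (hi - lo))

    best = None
    for s in starts:
        res = least_squares(
            resid,
            s,
            bounds=(lo, hi),
            x_scale=[_X_SCALE[p] for p in names],
            max_nfev=max_nfev,
        )
        if best is None or res.cost < best.cost:
            best = res

    chi2 = float(2.0 * best.cost)
    dof = len(data) - n_free
    jtj = best.jac.T @ best.jac
    try:
        cov = np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(jtj)
    perr = np.sqrt(np.clip(np.diag(cov), 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = cov / np.outer(perr, perr)
    params = unpack(best.x)
    result = FitResult(
        model_id=spec.model_id,
        params=params,
        errors={n: float(e) for n, e in zip(names, perr)},
        chi2=chi2,
        chi2_reduced=chi2 / dof,
        dof=dof,
        n_points=len(data),
        n_params=n_free,
        converged=bool(best.status > 0),
        message=best.message,
        correlation=corr,
        free_names=tuple(names),
        fixed=fix,
    )
    for name in profile:
        if name in names:
            result.profile_errors[name] = _profile_uncertainty(
                spec, data, result, name, bounds_all, max_nfev,
                delta_chi2=profile_delta_chi2,
            )
    return result


def _profile_uncertainty(
    spec: ModelSpec,
    data: SANSCurve,
    result: FitResult,
    name: str,
    bounds_all: dict,
    max_nfev: int,
    delta_chi2: float = 1.0,
) -> tuple[float, float]:
    """Asymmetric 1-sigma bounds from the delta chi2 = 1 profile crossings.

    Each side expands geometrically from the optimum until the profiled chi2
    exceeds chi2_opt + delta_chi2 (re-minimizing over all other parameters),
    then bisects to the crossing.  A side that reaches its box bound without
    crossing reports the distance to the bound.
    """
    v0 = result.params[name]
    lo, hi = bounds_all[name]
    target = result.chi2 + delta_chi2
    sigma0 = result.errors.get(name) or 0.0
    if not np.isfinite(sigma0) or sigma0 <= 0:
        sigma0 = 0.05 * max(abs(v0), hi - lo)

    def chi2_at(v: float) -> float:
        sub = fit(spec, data, start=result.params, fix={**result.fixed, name: v},
                  max_nfev=max_nfev)
        return sub.chi2

    out = []
    for direction in (-1.0, +1.0):
        bound = lo if direction < 0 else hi
        step = sigma0
        inner, outer = v0, None
        for _ in range(40):
            cand = v0 + direction * step
            if (direction < 0 and cand <= bound) or (direction > 0 and cand >= bound):
                cand = bound
            if chi2_at(cand) >= target:
                outer = cand
                break
            inner = cand
            if cand == bound:
                break
            step *= 2.0
        if outer is None:  # no crossing inside the box
            out.append(abs(bound - v0))
            continue
        for _ in range(20):
            mid = 0.5 * (inner + outer)
            if chi2_at(mid) >= target:
                outer = mid
            else:
                inner = mid
            if abs(outer - inner) <= 0.02 * abs(outer - v0) + 1e-12:
                break
        out.append(abs(0.5 * (inner + outer) - v0))
    return (out[0], out[1])


@dataclass(frozen=True)
class FTestResult:
    F: float
    p_value: float
    significant: bool
    mode: str
    dof_num: int
    dof_den: int

    def to_dict(self) -> dict:
        return {
            "F": float(self.F),
            "p_value": float(self.p_value),
            "significant_at_5pct": self.significant,
            "mode": self.mode,
            "dof": [self.dof_num, self.dof_den],
        }


def f_test(
    fit_simple: FitResult, fit_complex: FitResult, mode: str = "auto", level: float = 0.05
) -> FTestResult:
    """One-sided upper-tail F-test between two fits of the same data.

    Nested mode (different parameter counts): tests whether the extra
    parameters reduce chi2 more than chance,
    F = [(chi2_s - chi2_c)/(f_s - f_c)] / [chi2_c / f_c].  A complex fit
    that is no better gives P = 1.

    Equal-parameter mode (same count, e.g. the same model with two different
    input structures): variance ratio F = chi2r_worse / chi2r_better on
    (f, f) degrees of freedom.  Identical fits give F = 1, P = 0.5 under
    this one-sided convention.
    """
    if fit_simple.n_points != fit_complex.n_points:
        raise ValueError("F-test requires fits of the same data")
    if mode == "auto":
        mode = "nested" if fit_simple.n_params != fit_complex.n_params else "equal"
    if mode == "nested":
        if fit_complex.n_params < fit_simple.n_params:
            fit_simple, fit_complex = fit_complex, fit_simple
        df_num = fit_simple.dof - fit_complex.dof
        df_den = fit_complex.dof
        delta = fit_simple.chi2 - fit_complex.chi2
        if delta <= 0:
            return FTestResult(0.0, 1.0, False, mode, df_num, df_den)
        F = (delta / df_num) / (fit_complex.chi2 / df_den)
        p = float(stats.f.sf(F, df_num, df_den))
    elif mode == "equal":
        worse, better = fit_simple, fit_complex
        if worse.chi2_reduced < better.chi2_reduced:
            worse, better = better, worse
        F = worse.chi2_reduced / better.chi2_reduced
        df_num, df_den = worse.dof, better.dof
        p = float(stats.f.sf(F, df_num, df_den))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return FTestResult(float(F), p, p < level, mode, df_num, df_den)
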