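"""Experimental-curve analyses.

Covers the model-free toolbox applied to a reduced curve before and beside
structure-based fitting:

* regularized indirect Fourier transform (evidence-driven choice of the
  smoothness weight and D_max, background co-fitted) giving p(r), R_g, I(0);
* Guinier analysis with automatic self-consistent range (q R_g <= 1.3);
* Kratky representation q^2 I(q);
* Porod-plot background (slope of q^4 I vs q^4 at high q) and the scattering
  invariant Q = integral q^2 [I(q) - B] dq with low-q Guinier extension;
* three molecular-weight estimators: from I(0)/c, from the truncated
  invariant with a Porod tail correction (size-aware), and from the Porod
  volume with the empirical volume-per-dalton rule;
* multiplicative merging of curves measured at different instrument
  settings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from . import tables
from .curves import SANSCurve
from .scattering import PrResult, _sinc
from .units import AVOGADRO

__all__ = [
    "GuinierResult",
    "MWReport",
    "ift_pr",
    "guinier",
    "kratky",
    "porod_background",
    "invariant_q",
    "mw_from_i0",
    "mw_fischer",
    "mw_porod_petoukhov",
    "mw_report",
    "merge_settings",
]


# --------------------------------------------------------------------------
# Guinier analysis
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GuinierResult:
    rg: float
    i0: float
    q_range_used: tuple[float, float]
    qrg_max: float
    n_points: int
    valid: bool

    def to_dict(self) -> dict:
        return {
            "rg_A": float(self.rg),
            "i0_invcm": float(self.i0),
            "q_range_used": [float(self.q_range_used[0]), float(self.q_range_used[1])],
            "qrg_max": float(self.qrg_max),
            "n_points": self.n_points,
            "valid": self.valid,
        }


def guinier(
    data: SANSCurve, qrg_max: float = 1.3, min_points: int = 5
) -> GuinierResult:
    """Low-q linear fit of ln I vs q^2 on the widest self-consistent window.

    Starting from the lowest q, the window is grown while the fitted R_g
    keeps q_max R_g <= qrg_max.  ``valid`` is False when no window of at
    least ``min_points`` satisfies the criterion (e.g. an aggregation upturn
    at low q inflates R_g beyond any admissible window).
    """
    q, I = data.q, data.I
    pos = I > 0
    best = None
    for n in range(min_points, len(data) + 1):
        idx = np.arange(n)
        if not np.all(pos[idx]):
            break
        slope, intercept = np.polyfit(q[idx] ** 2, np.log(I[idx]), 1)
        if slope >= 0:
            continue
        rg = float(np.sqrt(-3.0 * slope))
        if q[n - 1] * rg <= qrg_max:
            best = (rg, float(np.exp(intercept)), n)
        elif best is not None:
            break
    if best is None:
        return GuinierResult(np.nan, np.nan, (q[0], q[0]), qrg_max, 0, False)
    rg, i0, n = best
    return GuinierResult(rg, i0, (float(q[0]), float(q[n - 1])), qrg_max, n, True)


def kratky(data: SANSCurve) -> np.ndarray:
    """(q, q^2 I(q)) pairs for the folded-ness check; shape (n, 2)."""
    if len(data) == 0:
        raise ValueError("empty curve")
    return np.column_stack([data.q, data.q**2 * data.I])


# --------------------------------------------------------------------------
# Indirect Fourier transform
# --------------------------------------------------------------------------

def _ift_design(q, r, dr, sigma_q=None):
    """Kernel A[i,k] = sinc(q_i r_k) dr, resolution-smeared per row if given."""
    A = _sinc(q[:, None] * r[None, :]) * dr
    if sigma_q is not None and np.any(sigma_q > 0):
        from .fitting import _gauss_nodes

        u, wt = _gauss_nodes(21)
        nodes = np.abs(q[:, None] + u[None, :] * sigma_q[:, None])  # (nq, nu)
        K = _sinc(nodes[:, :, None] * r[None, None, :]) * dr
        A = np.einsum("iuk,u->ik", K, wt)
    return A


def _smoothness_operator(n_r: int) -> np.ndarray:
    """Second-difference rows plus soft pinning of both endpoints to zero."""
    L = np.zeros((n_r, n_r))
    for i in range(1, n_r - 1):
        L[i, i - 1 : i + 2] = (1.0, -2.0, 1.0)
    L[0, 0] = L[-1, -1] = 1.0
    return L


def _ift_solve(data: SANSCurve, dmax: float, n_r: int, alpha: float, fit_background: bool,
               _cache: dict | None = None):
    """One regularized non-negative solve; returns (r, p, background, chi2, log_ev).

    The background enters as a +-column pair so the whole problem stays a
    non-negative least-squares solve.  log_ev is the Gaussian-approximation
    log-evidence used to rank (dmax, alpha) candidates.
    """
    from scipy.optimize import nnls

    # work on the intensity scale of the data so the smoothness weight is
    # dimensionless: solve for p/scale, which is O(1/dmax)
    scale = float(np.max(np.abs(data.I)))
    key = (dmax, n_r)
    if _cache is not None and key in _cache:
        r, dr, Aw, L, H, Mm = _cache[key]
    else:
        r = np.linspace(0.0, dmax, n_r)
        dr = r[1] - r[0]
        A = _ift_design(data.q, r, dr, data.sigma_q)
        Aw = scale * A / data.sigma[:, None]
        L = _smoothness_operator(n_r)
        H = L.T @ L
        Mm = Aw.T @ Aw
        if _cache is not None:
            _cache[key] = (r, dr, Aw, L, H, Mm)
    yw = data.I / data.sigma
    cols = [Aw]
    if fit_background:
        one_w = (scale / data.sigma)[:, None]
        cols += [one_w, -one_w]
    top = np.hstack(cols)
    n_cols = top.shape[1]
    Lpad = np.zeros((n_r, n_cols))
    Lpad[:, :n_r] = np.sqrt(alpha) * L
    M = np.vstack([top, Lpad])
    y = np.r_[yw, np.zeros(n_r)]
    try:
        x, _ = nnls(M, y)
    except RuntimeError:  # NNLS iteration limit on pathological input
        return r, np.zeros(n_r), 0.0, np.inf, -np.inf
    p = scale * x[:n_r]
    background = scale * float(x[n_r] - x[n_r + 1]) if fit_background else 0.0
    resid = top @ x - yw
    chi2 = float(resid @ resid)
    Hp = alpha * H
    eps = 1e-12 * max(np.trace(Hp) / n_r, 1.0)
    s1 = np.linalg.slogdet(Hp + eps * np.eye(n_r))[1]
    s2 = np.linalg.slogdet(Hp + Mm + eps * np.eye(n_r))[1]
    ps = x[:n_r]  # scale-normalized solution, the quantity the prior acts on
    log_ev = -0.5 * chi2 - 0.5 * float(ps @ Hp @ ps) + 0.5 * s1 - 0.5 * s2
    return r, p, background, chi2, log_ev


def _pr_moments(r, p, dr):
    integral = float(p.sum() * dr)
    if integral <= 0:
        return integral, np.nan
    rg = float(np.sqrt((r**2 * p).sum() * dr / (2.0 * integral)))
    return integral, rg


def ift_pr(
    data: SANSCurve,
    dmax: float | None = None,
    n_r: int = 100,
    alpha: float | None = None,
    fit_background: bool = True,
) -> PrResult:
    """Regularized indirect Fourier transform of a measured curve.

    p(r) on an ``n_r``-point grid is found by non-negative least squares
    with a second-derivative smoothness prior; a flat background is
    co-fitted by default.  (dmax, alpha) candidates whose chi2 is within a
    3-sigma band of the best achievable chi2 are ranked by the
    Gaussian-approximation evidence, so the reported solution is the
    smoothest, most compact p(r) still consistent with the data.
    Deterministic given the data and settings.
    """
    if len(data) < 30:
        raise ValueError("ift_pr needs at least 30 points")
    if dmax is not None and dmax <= 0:
        raise ValueError("dmax must be positive")

    if dmax is None:
        g = guinier(data, qrg_max=1.5)
        rg0 = g.rg if g.valid else 1.5 / data.q[min(10, len(data) - 1)]
        base = 3.2 * rg0
        dmax_grid = np.array([0.7, 0.85, 1.0, 1.15, 1.3, 1.5, 1.75, 2.0]) * base
    else:
        dmax_grid = np.array([dmax])
    if alpha is None:
        alpha_grid = np.logspace(-6, 8, 15)
    else:
        alpha_grid = np.array([alpha])

    cache: dict = {}
    candidates = []
    for dm in dmax_grid:
        for al in alpha_grid:
            r, p, bg, chi2, log_ev = _ift_solve(data, dm, n_r, al, fit_background, cache)
            if np.isfinite(log_ev):
                candidates.append((log_ev, chi2, dm, al, r, p, bg))
    if not candidates:
        raise RuntimeError("evidence surface degenerate; supply alpha explicitly")
    chi2_min = min(c[1] for c in candidates)
    band = chi2_min + max(9.0, 0.02 * chi2_min)  # ~3-sigma acceptability
    accepted = [c for c in candidates if c[1] <= band]
    log_ev, chi2, dm, al, r, p, bg = max(accepted, key=lambda c: c[0])
    dr = r[1] - r[0]
    integral, rg = _pr_moments(r, p, dr)
    nz = np.nonzero(p > 1e-6 * p.max())[0]
    dmax_eff = float(r[nz[-1]]) if nz.size else float(dm)
    return PrResult(
        r=r,
        p=p,
        dmax=dmax_eff,
        rg=rg,
        i0=integral,
        source="experimental",
        background=bg,
        alpha=float(al),
        chi2_reduced=chi2 / max(len(data) - n_r // 4, 1),
    )


# --------------------------------------------------------------------------
# Porod background, invariant, molecular weights
# --------------------------------------------------------------------------

def porod_background(data: SANSCurve, q_window: tuple[float, float] | None = None) -> float:
    """Flat background from the Porod plot: slope of q^4 I(q) vs q^4.

    Default window is the upper third of the measured q range.
    """
    if q_window is None:
        q_window = (data.q[-1] * (2.0 / 3.0), data.q[-1])
    mask = (data.q >= q_window[0]) & (data.q <= q_window[1])
    if mask.sum() < 3:
        raise ValueError("Porod window contains fewer than 3 points")
    x = data.q[mask] ** 4
    y = x * data.I[mask]
    slope, _ = np.polyfit(x, y, 1)
    return float(slope)


def _invariant_sigma(data: SANSCurve) -> float:
    """Propagated 1-sigma uncertainty of the trapezoid invariant."""
    q = data.q
    w = np.zeros_like(q)
    w[:-1] += 0.5 * np.diff(q)
    w[1:] += 0.5 * np.diff(q)
    return float(np.sqrt(np.sum((w * q**2 * data.sigma) ** 2)))


def _porod_amplitude(data: SANSCurve, background: float) -> float:
    """Porod constant A = lim q^4 (I - B), from the upper third of the range."""
    mask = data.q >= data.q[-1] * (2.0 / 3.0)
    return float(np.mean(data.q[mask] ** 4 * (data.I[mask] - background)))


def invariant_q(
    data: SANSCurve,
    background: float = 0.0,
    extrapolation: "PrResult | GuinierResult | None" = None,
    high_q_tail: bool = False,
) -> float:
    """Scattering invariant Q = integral q^2 [I(q) - B] dq (units 1/(cm A^3)).

    Trapezoid rule on the measured grid; below q_min the integrand is
    extended with the Guinier or p(r) model when given; with
    ``high_q_tail`` the range above q_max is extended assuming a Porod
    q^-4 tail (contributing A/q_max).
    """
    q, I = data.q, data.I - background
    total = float(np.trapezoid(q**2 * I, q))
    if extrapolation is not None:
        q_lo = np.linspace(0.0, q[0], 50)
        if isinstance(extrapolation, GuinierResult):
            if extrapolation.valid:
                I_lo = extrapolation.i0 * np.exp(-(q_lo**2) * extrapolation.rg**2 / 3.0)
                total += float(np.trapezoid(q_lo**2 * I_lo, q_lo))
        else:  # PrResult
            from .scattering import pr_intensity

            I_lo = pr_intensity(extrapolation, q_lo)
            total += float(np.trapezoid(q_lo**2 * I_lo, q_lo))
    if high_q_tail:
        A = _porod_amplitude(data, background)
        if A > 0:
            total += A / q[-1]
    return total


def mw_from_i0(i0: float, c: float, delta_rho: float, rho_p: float | None = None) -> float:
    """Molecular weight (kDa) from forward scattering, concentration and contrast.

    MW = [I(0)/c] N_A rho_p^2 / delta_rho^2 with I(0) in 1/cm, c in g/cm^3,
    delta_rho in 1/cm^2 and the average protein density rho_p in g/cm^3.
    """
    if delta_rho == 0:
        raise ZeroDivisionError("delta_rho must be non-zero")
    if c <= 0:
        raise ValueError("concentration must be positive")
    if rho_p is None:
        rho_p = tables.mw_constants()["rho_protein"]
    mw_da = (i0 / c) * AVOGADRO * rho_p**2 / delta_rho**2
    return mw_da / 1e3


def _volume_to_kda(volume_a3: float, rho_p: float) -> float:
    # mass of one particle: rho_p * V; in Da via Avogadro
    return rho_p * volume_a3 * 1e-24 * AVOGADRO / 1e3


def mw_fischer(
    data: SANSCurve,
    i0: float,
    background: float = 0.0,
    rg: float | None = None,
    extrapolation: "PrResult | GuinierResult | None" = None,
) -> float:
    """Size-aware molecular weight (kDa) from the truncated Porod invariant.

    The invariant is evaluated up to q_max = 8/R_g (so particles of
    different size are integrated over comparable q R_g ranges) and the
    missing tail is restored analytically assuming Porod q^-4 behaviour.
    The apparent volume V = 2 pi^2 I(0)/Q converts to mass with the average
    protein density.  Returns NaN (with a warning) when the invariant is
    non-positive (e.g. pure noise).
    """
    consts = tables.mw_constants()
    if rg is None:
        if extrapolation is not None and hasattr(extrapolation, "rg"):
            rg = extrapolation.rg
        else:
            g = guinier(data)
            rg = g.rg if g.valid else np.nan
    if not np.isfinite(rg) or rg <= 0:
        warnings.warn("mw_fischer: no usable R_g; result unreliable")
        return float("nan")
    qmax = consts["fischer_qmax_rg"] / rg
    mask = data.q <= qmax
    if mask.sum() < 10:
        mask = np.ones(len(data), dtype=bool)
    trunc = data.select(mask)
    Q = invariant_q(trunc, background, extrapolation, high_q_tail=True)
    if Q <= 2.0 * _invariant_sigma(trunc):
        warnings.warn("mw_fischer: invariant indistinguishable from noise; "
                      "result unreliable")
        return float("nan")
    volume = 2.0 * np.pi**2 * i0 / Q
    return _volume_to_kda(volume, consts["rho_protein"])


def mw_porod_petoukhov(
    data: SANSCurve,
    i0: float,
    background: float = 0.0,
    extrapolation: "PrResult | GuinierResult | None" = None,
) -> float:
    """Molecular weight (kDa) from the Porod volume and the empirical
    volume-per-dalton rule (1.6 A^3/Da).

    Q uses the full measured range with a q^-4 tail extension.  Returns NaN
    with a warning for a non-positive invariant.
    """
    consts = tables.mw_constants()
    Q = invariant_q(data, background, extrapolation, high_q_tail=True)
    if Q <= 2.0 * _invariant_sigma(data):
        warnings.warn("mw_porod_petoukhov: invariant indistinguishable from noise; "
                      "result unreliable")
        return float("nan")
    volume = 2.0 * np.pi**2 * i0 / Q
    return volume / consts["porod_volume_per_dalton"] / 1e3


@dataclass(frozen=True)
class MWReport:
    mw_i0: float
    mw_fischer: float
    mw_porod: float
    q_invariant: float
    background_used: float
    c: float | None
    delta_rho: float | None
    rho_p: float

    def to_dict(self) -> dict:
        return {
            "mw_i0_kDa": float(self.mw_i0),
            "mw_fischer_kDa": float(self.mw_fischer),
            "mw_porod_kDa": float(self.mw_porod),
            "invariant_Q": float(self.q_invariant),
            "background_invcm": float(self.background_used),
            "concentration_g_cm3": None if self.c is None else float(self.c),
            "delta_rho_invcm2": None if self.delta_rho is None else float(self.delta_rho),
            "rho_protein_g_cm3": float(self.rho_p),
        }


def mw_report(
    data: SANSCurve,
    i0: float,
    c: float | None = None,
    delta_rho: float | None = None,
    background: float | None = None,
    extrapolation: "PrResult | GuinierResult | None" = None,
) -> MWReport:
    """All molecular-weight estimators in one pass."""
    rho_p = tables.mw_constants()["rho_protein"]
    if background is None:
        background = porod_background(data)
    mw_i = float("nan")
    if c is not None and delta_rho is not None:
        mw_i = mw_from_i0(i0, c, delta_rho, rho_p)
    return MWReport(
        mw_i0=mw_i,
        mw_fischer=mw_fischer(data, i0, background, extrapolation=extrapolation),
        mw_porod=mw_porod_petoukhov(data, i0, background, extrapolation=extrapolation),
        q_invariant=invariant_q(data, background, extrapolation, high_q_tail=True),
        background_used=background,
        c=c,
        delta_rho=delta_rho,
        rho_p=rho_p,
    )


# --------------------------------------------------------------------------
# Inter-setting merging
# --------------------------------------------------------------------------

def merge_settings(
    curves: list[SANSCurve], reference_index: int = 0
) -> tuple[SANSCurve, list[float]]:
    """Merge curves from several instrument settings with per-curve factors.

    The reference curve keeps factor 1.  Curves overlapping the reference
    (or the already-merged set) in q get their factor from weighted least
    squares on the overlap; a curve with no overlap is scaled by minimizing
    the misfit of a joint smooth p(r) fit (with a warning, since the factor
    is then only weakly constrained).  Returns the concatenated q-sorted
    curve and the factors in input order.
    """
    if not curves:
        raise ValueError("no curves to merge")
    factors = [1.0] * len(curves)
    order = [reference_index] + [i for i in range(len(curves)) if i != reference_index]
    merged = curves[reference_index]
    for i in order[1:]:
        cur = curves[i]
        lo = max(merged.q[0], cur.q[0])
        hi = min(merged.q[-1], cur.q[-1])
        if lo < hi:
            m_ref = (merged.q >= lo) & (merged.q <= hi)
            if m_ref.sum() >= 2:
                I_ref = np.interp(cur.q, merged.q[m_ref], merged.I[m_ref])
                m_cur = (cur.q >= lo) & (cur.q <= hi)
                w = 1.0 / cur.sigma[m_cur] ** 2
                f = float(
                    np.sum(w * cur.I[m_cur] * I_ref[m_cur]) / np.sum(w * cur.I[m_cur] ** 2)
                )
            else:
                f = _factor_from_joint_ift(merged, cur)
        else:
            warnings.warn("curves have no q overlap; factor from joint p(r) smoothness")
            f = _factor_from_joint_ift(merged, cur)
        factors[i] = f
        merged = _concat(merged, cur, f)
    return merged, factors


def _concat(a: SANSCurve, b: SANSCurve, f: float) -> SANSCurve:
    q = np.r_[a.q, b.q]
    I = np.r_[a.I, f * b.I]
    s = np.r_[a.sigma, f * b.sigma]
    sq = None
    if a.sigma_q is not None and b.sigma_q is not None:
        sq = np.r_[a.sigma_q, b.sigma_q]
    order = np.argsort(q, kind="stable")
    # nudge exact duplicates apart to keep q strictly increasing
    qs = q[order]
    dup = np.nonzero(np.diff(qs) <= 0)[0]
    for j in dup:
        qs[j + 1] = np.nextafter(qs[j], np.inf)
    return SANSCurve(qs, I[order], s[order], None if sq is None else sq[order],
                     label=f"{a.label}+{b.label}")


def _factor_from_joint_ift(ref: SANSCurve, other: SANSCurve) -> float:
    def misfit(log_f):
        joint = _concat(ref, other, float(np.exp(log_f)))
        try:
            pr = ift_pr(joint, n_r=60, alpha=1.0)
        except (ValueError, RuntimeError):
            return 1e30
        return pr.chi2_reduced

    res = minimize_scalar(misfit, bounds=(np.log(0.2), np.log(5.0)), method="bounded",
                          options={"xatol": 1e-3})
    return float(np.exp(res.x))
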