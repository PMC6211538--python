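"""Orientationally averaged scattering from point sets.

The Debye formula gives the form factor of a rigid assembly of point
scatterers averaged over orientations,

    P(q) = sum_jk b_j b_k sinc(q r_jk),        sinc(x) = sin(x)/x,

together with the zeroth-order amplitude A00(q) = sum_j b_j sinc(q |r_j - r_c|)
about the b-weighted centroid r_c, and beta(q) = A00(q)^2 / P(q), the
orientational-coupling factor used by the decoupling approximation.

P(q) is stored unnormalized (absolute b^2, units cm^2), so the forward value
P(0) = (sum b)^2 is the squared excess scattering length of the particle.

The theoretical pair distance distribution p(r) is the b_j b_k-weighted
histogram of pairwise distances; its sine transform returns P(q), and the
operational maximum dimension D_max is the first r past the peak where p(r)
falls below 1% of its maximum (distant atom pairs carry too little weight to
be detectable, so the geometric maximum distance is not comparable with
experiment).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure import PointSet

__all__ = [
    "FormFactorTable",
    "PrResult",
    "form_factor",
    "amplitude_a00",
    "beta_factor",
    "form_factor_table",
    "radius_of_gyration",
    "theoretical_pr",
    "pr_intensity",
]

#: switch from the exact O(n^2 m) double sum to the histogram-accelerated sum
_EXACT_LIMIT = 600
#: distance-histogram bin width for the accelerated Debye sum, A
_ACCEL_BIN_A = 0.02


def _sinc(x: np.ndarray) -> np.ndarray:
    return np.sinc(x / np.pi)


def _pair_distances(points: PointSet, chunk: int = 512):
    """Yield (distances, weights 2*b_j*b_k) over all unordered pairs j<k."""
    pos, b = points.positions, points.b
    n = len(points)
    for i0 in range(0, n, chunk):
        i1 = min(i0 + chunk, n)
        d = np.linalg.norm(pos[i0:i1, None, :] - pos[None, :, :], axis=-1)
        w = b[i0:i1, None] * b[None, :]
        rows = np.arange(i0, i1)
        mask = np.arange(n)[None, :] > rows[:, None]
        yield d[mask], 2.0 * w[mask]


@dataclass
class FormFactorTable:
    """Tabulated P(q) (cm^2), A00(q) (cm) and beta(q) for one component."""

    q: np.ndarray
    P: np.ndarray
    A00: np.ndarray
    beta: np.ndarray = field(default=None)  # type: ignore[assignment]
    label: str = ""

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        self.A00 = np.asarray(self.A00, dtype=float)
        if self.beta is None:
            with np.errstate(divide="ignore", invalid="ignore"):
                self.beta = np.where(self.P > 0, self.A00**2 / self.P, 1.0)
        self.beta = np.asarray(self.beta, dtype=float)

    def interp_P(self, q: np.ndarray) -> np.ndarray:
        self._check_range(q)
        return np.interp(q, self.q, self.P)

    def interp_A00(self, q: np.ndarray) -> np.ndarray:
        self._check_range(q)
        return np.interp(q, self.q, self.A00)

    def interp_beta(self, q: np.ndarray) -> np.ndarray:
        self._check_range(q)
        return np.interp(q, self.q, self.beta)

    def _check_range(self, q: np.ndarray) -> None:
        q = np.asarray(q)
        if q.size and (q.min() < self.q[0] - 1e-12 or q.max() > self.q[-1] + 1e-12):
            raise ValueError(
                f"q outside tabulated range [{self.q[0]:g}, {self.q[-1]:g}]"
            )

    def to_text(self) -> str:
        lines = [
            f"# form factor table {self.label}",
            "# q_invA P_cm2 A00_cm beta",
        ]
        for q, p, a, bt in zip(self.q, self.P, self.A00, self.beta):
            lines.append(f"{q:.6e} {p:.8e} {a:.8e} {bt:.8e}")
        return "\n".join(lines) + "\n"


def _validate_q(q_grid) -> np.ndarray:
    q = np.asarray(q_grid, dtype=float)
    if q.ndim != 1 or q.size == 0:
        raise ValueError("q grid must be a non-empty 1-d array")
    if np.any(q < 0):
        raise ValueError("q must be non-negative")
    if np.any(np.diff(q) <= 0):
        raise ValueError("q grid must be strictly increasing")
    return q


def form_factor(points: PointSet, q_grid, *, method: str = "auto") -> np.ndarray:
    """Debye form factor P(q) in cm^2 on ``q_grid`` (1/A).

    ``method`` is "exact" (pairwise double sum), "histogram" (distance
    histogram on a 0.02 A grid, matching the exact sum to ~1e-4 relative for
    q below ~1 1/A), or "auto".
    """
    if len(points) == 0:
        raise ValueError("empty PointSet")
    q = _validate_q(q_grid)
    if method == "auto":
        method = "exact" if len(points) <= _EXACT_LIMIT else "histogram"
    self_term = float(np.sum(points.b**2))
    out = np.full(q.shape, self_term)
    if len(points) == 1:
        return out
    if method == "exact":
        for d, w in _pair_distances(points):
            out += (w[None, :] * _sinc(q[:, None] * d[None, :])).sum(axis=1)
    elif method == "histogram":
        centers, weights = _distance_histogram(points, _ACCEL_BIN_A)
        out += (weights[None, :] * _sinc(q[:, None] * centers[None, :])).sum(axis=1)
    else:
        raise ValueError(f"unknown method {method!r}")
    return out


def _distance_histogram(points: PointSet, bin_width: float):
    pos = points.positions
    span = np.linalg.norm(pos.max(axis=0) - pos.min(axis=0))
    edges = np.arange(0.0, span + 2 * bin_width, bin_width)
    hist = np.zeros(edges.size - 1)
    for d, w in _pair_distances(points):
        hist += np.histogram(d, bins=edges, weights=w)[0]
    centers = 0.5 * (edges[:-1] + edges[1:])
    keep = hist != 0
    return centers[keep], hist[keep]


def amplitude_a00(points: PointSet, q_grid) -> np.ndarray:
    """Zeroth-order spherical-harmonic amplitude A00(q) in cm.

    Expansion origin is the excess-scattering-length-weighted centroid; at
    q = 0 this returns the total excess scattering length.
    """
    if len(points) == 0:
        raise ValueError("empty PointSet")
    if points.total_b == 0:
        raise ValueError("total_b is zero; weighted center undefined")
    q = _validate_q(q_grid)
    center = (points.b[:, None] * points.positions).sum(axis=0) / points.total_b
    radii = np.linalg.norm(points.positions - center, axis=1)
    return (points.b[None, :] * _sinc(q[:, None] * radii[None, :])).sum(axis=1)


def beta_factor(points: PointSet, q_grid) -> np.ndarray:
    """Decoupling factor beta(q) = A00(q)^2 / P(q), in [0, 1]."""
    P = form_factor(points, q_grid)
    A = amplitude_a00(points, q_grid)
    return A**2 / P


def form_factor_table(points: PointSet, q_grid, *, method: str = "auto") -> FormFactorTable:
    """P, A00 and beta tabulated together on one grid."""
    q = _validate_q(q_grid)
    P = form_factor(points, q, method=method)
    A = amplitude_a00(points, q)
    return FormFactorTable(q=q, P=P, A00=A, label=points.label)


def radius_of_gyration(points: PointSet) -> float:
    """Contrast-weighted radius of gyration, A: sqrt(sum b |r - r_c|^2 / sum b).

    With mixed-sign excess scattering lengths (e.g. a negative-contrast
    protein carrying positive-contrast hydration beads) the weighted second
    moment can become indefinite; NaN is returned with a warning then.
    """
    if points.total_b == 0:
        raise ValueError("radius of gyration undefined at zero total contrast")
    center = (points.b[:, None] * points.positions).sum(axis=0) / points.total_b
    r2 = np.sum((points.positions - center) ** 2, axis=1)
    val = (points.b * r2).sum() / points.total_b
    if val < 0:
        import warnings

        warnings.warn("indefinite contrast-weighted second moment; R_g is NaN")
        return float("nan")
    return float(np.sqrt(val))


@dataclass
class PrResult:
    """Pair distance distribution on an r grid with derived quantities.

    ``p`` integrates (dr) to the interference part of the forward scattering;
    for theoretical curves ``b2_self`` carries the self term sum(b^2) so that
    i0 = integral(p) + b2_self = (sum b)^2.
    """

    r: np.ndarray
    p: np.ndarray
    dmax: float
    rg: float
    i0: float
    source: str = "theoretical"
    b2_self: float = 0.0
    background: float = 0.0
    alpha: float | None = None
    chi2_reduced: float | None = None

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        self.p = np.asarray(self.p, dtype=float)

    def to_text(self) -> str:
        lines = [
            f"# p(r): source={self.source} dmax={self.dmax:.3f} A "
            f"rg={self.rg:.3f} A i0={self.i0:.6e}",
            "# r_A p_r",
        ]
        for r, p in zip(self.r, self.p):
            lines.append(f"{r:.4f} {p:.8e}")
        return "\n".join(lines) + "\n"


def _dmax_from_threshold(r: np.ndarray, p: np.ndarray, threshold: float) -> float:
    pmax = p.max()
    if pmax <= 0:
        return float(r[-1])
    imax = int(np.argmax(p))
    below = np.nonzero(p[imax:] < threshold * pmax)[0]
    if below.size == 0:
        nonzero = np.nonzero(p)[0]
        return float(r[nonzero[-1]])
    return float(r[imax + below[0]])


def theoretical_pr(
    points: PointSet,
    bin_width: float = 1.0,
    dmax_threshold: float = 0.01,
) -> PrResult:
    """p(r) of a point set, with the 1%-of-peak operational D_max.

    R_g comes from the second moment of p(r); i0 from its integral plus the
    self term.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if len(points) < 2:
        raise ValueError("p(r) needs at least two points")
    centers, weights = _distance_histogram_binned(points, bin_width)
    p = weights / bin_width  # density per A
    integral = float(p.sum() * bin_width)
    b2_self = float(np.sum(points.b**2))
    rg2 = (centers**2 * p).sum() * bin_width / (2.0 * integral) if integral != 0 else np.nan
    rg = float(np.sqrt(rg2)) if rg2 >= 0 else float("nan")
    i0 = integral + b2_self
    dmax = _dmax_from_threshold(centers, p, dmax_threshold)
    return PrResult(
        r=centers, p=p, dmax=dmax, rg=rg, i0=i0, source="theoretical", b2_self=b2_self
    )


def _distance_histogram_binned(points: PointSet, bin_width: float):
    pos = points.positions
    span = np.linalg.norm(pos.max(axis=0) - pos.min(axis=0))
    n_bins = max(1, int(np.ceil(span / bin_width)) + 1)
    edges = np.arange(0.0, (n_bins + 0.5) * bin_width, bin_width)
    hist = np.zeros(edges.size - 1)
    for d, w in _pair_distances(points):
        hist += np.histogram(d, bins=edges, weights=w)[0]
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, hist


def pr_intensity(pr: PrResult, q_grid) -> np.ndarray:
    """Sine transform of p(r): I(q) = b2_self + integral p(r) sinc(qr) dr."""
    q = _validate_q(q_grid)
    dr = pr.r[1] - pr.r[0] if pr.r.size > 1 else 1.0
    kernel = _sinc(q[:, None] * pr.r[None, :])
    return pr.b2_self + (kernel * pr.p[None, :]).sum(axis=1) * dr
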