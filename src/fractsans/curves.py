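"""Reduced scattering curves: container and plain-text I/O.

Curves are 3- or 4-column ASCII: q (1/A), I(q) (1/cm), sigma(I) (1/cm) and
optionally the beamline resolution width sigma_q (1/A).  "#"-comment headers
and either whitespace or comma separation are accepted (SASBDB .dat
compatible); non-numeric header lines are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["SANSCurve", "load_curve", "parse_curve", "save_curve", "truncate_low_q"]


@dataclass
class SANSCurve:
    """One reduced scattering data set in absolute units."""

    q: np.ndarray          # 1/A, strictly increasing
    I: np.ndarray          # 1/cm
    sigma: np.ndarray      # 1/cm, > 0
    sigma_q: np.ndarray | None = None  # 1/A resolution widths
    label: str = ""

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.sigma_q is not None:
            self.sigma_q = np.asarray(self.sigma_q, dtype=float)
        n = self.q.size
        if not (self.I.size == n and self.sigma.size == n):
            raise ValueError("q, I, sigma must have equal lengths")
        if self.sigma_q is not None and self.sigma_q.size != n:
            raise ValueError("sigma_q length mismatch")
        if n == 0:
            raise ValueError("empty curve")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive")
        if self.sigma_q is not None and np.any(self.sigma_q < 0):
            raise ValueError("sigma_q must be non-negative")

    def __len__(self) -> int:
        return self.q.size

    def select(self, mask: np.ndarray, label: str | None = None) -> "SANSCurve":
        return SANSCurve(
            self.q[mask],
            self.I[mask],
            self.sigma[mask],
            None if self.sigma_q is None else self.sigma_q[mask],
            label if label is not None else self.label,
        )


def parse_curve(text: str, label: str = "") -> SANSCurve:
    """Parse 3/4-column curve text; tolerant of headers and comma separation."""
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith(("#", ";", "%")):
            continue
        toks = line.replace(",", " ").split()
        try:
            vals = [float(t) for t in toks]
        except ValueError:
            continue  # header / footer prose
        if len(vals) >= 3:
            rows.append(vals[:4])
    if not rows:
        raise ValueError("no data rows found in curve text")
    ncol = min(len(r) for r in rows)
    arr = np.asarray([r[:ncol] for r in rows], dtype=float)
    order = np.argsort(arr[:, 0], kind="stable")
    arr = arr[order]
    sigma_q = arr[:, 3] if ncol >= 4 else None
    return SANSCurve(arr[:, 0], arr[:, 1], arr[:, 2], sigma_q, label=label)


def load_curve(path, label: str | None = None) -> SANSCurve:
    with open(path) as fh:
        text = fh.read()
    return parse_curve(text, label=label if label is not None else str(path))


def save_curve(curve: SANSCurve, path, header: str = "") -> None:
    cols = "q_invA I_invcm sigma_invcm" + (
        " sigmaq_invA" if curve.sigma_q is not None else ""
    )
    lines = []
    if header:
        lines += [f"# {h}" for h in header.splitlines()]
    lines += [f"# {curve.label}", f"# {cols}"]
    for i in range(len(curve)):
        row = f"{curve.q[i]:.6e} {curve.I[i]:.8e} {curve.sigma[i]:.8e}"
        if curve.sigma_q is not None:
            row += f" {curve.sigma_q[i]:.6e}"
        lines.append(row)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def truncate_low_q(curve: SANSCurve, n_points: int) -> SANSCurve:
    """Drop the first ``n_points`` rows (suppresses low-q aggregation signal)."""
    if n_points < 0:
        raise ValueError("n_points must be >= 0")
    if n_points >= len(curve):
        raise ValueError(f"cannot drop {n_points} of {len(curve)} points")
    if n_points == 0:
        return replace(curve)
    mask = np.zeros(len(curve), dtype=bool)
    mask[n_points:] = True
    return curve.select(mask, label=f"{curve.label} (first {n_points} points removed)")
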