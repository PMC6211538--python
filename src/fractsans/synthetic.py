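"""Synthetic inputs for the whole pipeline: point assemblies, mock
membrane-receptor structures and simulated mixture curves.

Everything is generated deterministically from a seed, so each pipeline
stage can be exercised against known ground truth without any downloads.
The default conditions mirror a dilute detergent-solubilized tetrameric
receptor in D2O buffer: a ~370 kDa particle (R_g about 56 A, D_max about
180 A) at ~0.5 uM, measured on 0.006-0.2 1/A with a 10% FWHM wavelength
spread and percent-level counting errors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .curves import SANSCurve, save_curve
from .fitting import ModelSpec, model_intensity, smear_model, _clip_to_tables
from .fractal import FractalModel
from .scattering import form_factor_table, FormFactorTable
from .structure import PointSet
from .units import molar_to_number_density

__all__ = [
    "SyntheticSpec",
    "NoiseSpec",
    "make_assembly",
    "simulate_curve",
    "corpus",
    "default_q_grid",
    "extended_q_grid",
    "write_mock_pdb",
    "RECEPTOR_LAYERS",
    "RECEPTOR_LAYERS_OPEN",
    "DEFAULT_CONCENTRATION_N",
    "SUBUNIT_RADIUS_A",
]

#: stacked cylinders (radius, z_lo, z_hi) for the compact mock receptor:
#: membrane-embedded channel slab, then two wider extracellular layers
RECEPTOR_LAYERS = ((32.0, -30.0, 10.0), (48.0, 10.0, 65.0), (52.0, 65.0, 120.0))
#: splayed-open variant with expanded extracellular layers
RECEPTOR_LAYERS_OPEN = ((32.0, -30.0, 10.0), (55.0, 10.0, 78.0), (62.0, 78.0, 152.0))
#: z-range of the detergent-embedded slab of the mock receptor
RECEPTOR_SLAB_Z = (-30.0, 10.0)
#: equivalent-sphere radius of the ~370 kDa mock subunit, A
SUBUNIT_RADIUS_A = 47.0
#: number density at 0.54 uM, 1/cm^3
DEFAULT_CONCENTRATION_N = molar_to_number_density(0.54e-6)


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a toy point-scatterer assembly."""

    shape: str  # "sphere" | "shell" | "two_points" | "mock_receptor" | "custom"
    geometry: dict = field(default_factory=dict)
    n_points: int = 1100
    b_per_point: float = 1.0e-11  # cm
    seed: int = 0

    def __post_init__(self):
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise model for simulated curves.

    sigma_i = relative_floor * max(I) + i_dependent_coeff * I_i, additive
    Gaussian; the resolution column is sigma_q = fwhm * q / 2.355 (a 10%
    FWHM wavelength spread rendered as a Gaussian width).
    """

    relative_floor: float = 0.002
    i_dependent_coeff: float = 0.02
    sigma_q_fwhm: float = 0.10
    seed: int = 0

    def __post_init__(self):
        for name in ("relative_floor", "i_dependent_coeff", "sigma_q_fwhm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _cylinder_points(rng, n, radius, z_lo, z_hi):
    r = radius * np.sqrt(rng.random(n))
    th = 2.0 * np.pi * rng.random(n)
    z = z_lo + (z_hi - z_lo) * rng.random(n)
    return np.column_stack([r * np.cos(th), r * np.sin(th), z])


def make_assembly(spec: SyntheticSpec) -> PointSet:
    """Deterministic point assembly for the requested shape."""
    rng = np.random.default_rng(spec.seed)
    g = spec.geometry
    if spec.shape == "two_points":
        d = float(g.get("d", 50.0))
        pos = np.array([[0.0, 0.0, -d / 2.0], [0.0, 0.0, d / 2.0]])
    elif spec.shape == "sphere":
        R = float(g.get("radius", 50.0))
        pos = []
        while len(pos) < spec.n_points:
            cand = rng.uniform(-R, R, size=(2 * spec.n_points, 3))
            cand = cand[np.einsum("ij,ij->i", cand, cand) <= R * R]
            pos.extend(cand.tolist())
        pos = np.asarray(pos[: spec.n_points])
    elif spec.shape == "shell":
        R = float(g.get("radius", 50.0))
        v = rng.normal(size=(spec.n_points, 3))
        pos = R * v / np.linalg.norm(v, axis=1)[:, None]
    elif spec.shape == "mock_receptor":
        layers = g.get("layers", RECEPTOR_LAYERS_OPEN if g.get("open") else RECEPTOR_LAYERS)
        vols = np.array([rad**2 * (hi - lo) for rad, lo, hi in layers])
        counts = np.maximum(1, np.round(spec.n_points * vols / vols.sum()).astype(int))
        counts[-1] += spec.n_points - counts.sum()
        pos = np.vstack(
            [_cylinder_points(rng, c, *lay) for c, lay in zip(counts, layers)]
        )
    elif spec.shape == "custom":
        pos = np.asarray(g["positions"], dtype=float)
    else:
        raise ValueError(f"unknown shape {spec.shape!r}")
    b = np.full(len(pos), spec.b_per_point)
    return PointSet(pos, b, label=f"{spec.shape}(seed={spec.seed})")


def default_q_grid(n: int = 120, q_min: float = 0.006, q_max: float = 0.2) -> np.ndarray:
    """Logarithmic measurement grid covering the instrument's nominal range."""
    return np.geomspace(q_min, q_max, n)


def extended_q_grid(q_grid, fwhm: float = 0.10, n: int = 220) -> np.ndarray:
    """Grid wide enough that +-3 sigma_q smearing nodes stay tabulated."""
    q = np.asarray(q_grid, dtype=float)
    pad = 3.2 * fwhm / 2.355
    return np.geomspace(q[0] * (1.0 - pad), q[-1] * (1.0 + pad), n)


def simulate_curve(
    spec: ModelSpec,
    params: dict,
    q_grid,
    noise: NoiseSpec | None = None,
    label: str = "simulated",
) -> SANSCurve:
    """Evaluate a model, smear it with the emitted sigma_q column and add
    seeded Gaussian noise.  Zero noise coefficients return the smeared model
    exactly (with a small positive sigma column so the curve stays valid)."""
    if noise is None:
        noise = NoiseSpec()
    q = np.asarray(q_grid, dtype=float)
    sigma_q = noise.sigma_q_fwhm * q / 2.355
    I = smear_model(
        lambda qq: model_intensity(spec, params, _clip_to_tables(spec, qq)), q, sigma_q
    )
    sigma_stat = noise.relative_floor * np.abs(I).max() + noise.i_dependent_coeff * np.abs(I)
    rng = np.random.default_rng(noise.seed)
    I_noisy = I + np.where(sigma_stat > 0, rng.normal(0.0, 1.0, q.size) * sigma_stat, 0.0)
    sigma = np.maximum(sigma_stat, 1e-8 * np.abs(I).max())
    return SANSCurve(q, I_noisy, sigma, sigma_q, label=label)


def write_mock_pdb(points: PointSet, path) -> None:
    """Write an assembly as a PDB of pseudo-atom glycine CA carbons."""
    if len(points) > 9999:
        raise ValueError("mock PDB limited to 9999 residues")
    lines = ["REMARK   1 fractsans synthetic mock structure (pseudo-atoms)"]
    for i, (x, y, z) in enumerate(points.positions, start=1):
        lines.append(
            f"ATOM  {i:>5d}  CA  GLY A{i:>4d}    "
            f"{x:>8.3f}{y:>8.3f}{z:>8.3f}{1.0:>6.2f}{0.0:>6.2f}          "
            f"{'C':>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def _receptor_tables(seed: int, q_table) -> tuple[PointSet, PointSet, FormFactorTable, FormFactorTable]:
    closed = make_assembly(SyntheticSpec("mock_receptor", seed=seed))
    open_ = make_assembly(SyntheticSpec("mock_receptor", geometry={"open": True}, seed=seed + 1))
    return closed, open_, form_factor_table(closed, q_table), form_factor_table(open_, q_table)


def corpus(seed: int, out_dir) -> dict:
    """Write the standard fixture set and return (and save) its manifest.

    Contents: compact and open mock-receptor structures, simulated curves
    for models 1-4 (the model-2 case carries a 1.5% oligomer fraction, the
    dilute-oligomer regime of interest), and a heavily aggregated curve with
    no valid Guinier region.  Regeneration at the same seed is
    byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    q = default_q_grid()
    q_table = extended_q_grid(q)
    closed, open_, tab_c, tab_o = _receptor_tables(seed, q_table)
    write_mock_pdb(closed, out / "mock_receptor.pdb")
    write_mock_pdb(open_, out / "mock_receptor_open.pdb")

    fractal = FractalModel(r=SUBUNIT_RADIUS_A)
    n_dens = DEFAULT_CONCENTRATION_N
    cases = {
        "curve_model1.dat": (
            ModelSpec(1, {"atomic": tab_c}, n_dens),
            {"K": 1.0, "B": 0.001},
        ),
        "curve_model2.dat": (
            ModelSpec(2, {"atomic": tab_c}, n_dens, fractal),
            {"K": 1.0, "B": 0.001, "gamma": 0.015, "rg_olig": 300.0},
        ),
        "curve_model3.dat": (
            ModelSpec(3, {"atomic": tab_c, "em": tab_o}, n_dens),
            {"K": 1.0, "B": 0.001, "alpha": 0.3},
        ),
        "curve_model4.dat": (
            ModelSpec(4, {"atomic": tab_c, "em": tab_o}, n_dens, fractal),
            {"K": 1.0, "B": 0.001, "gamma": 0.015, "rg_olig": 300.0, "alpha": 0.2},
        ),
        "curve_no_guinier.dat": (
            ModelSpec(2, {"atomic": tab_c}, n_dens, fractal),
            {"K": 1.0, "B": 0.001, "gamma": 0.2, "rg_olig": 600.0},
        ),
    }
    manifest: dict = {
        "seed": seed,
        "concentration_n_per_cm3": n_dens,
        "subunit_radius_A": SUBUNIT_RADIUS_A,
        "structures": {
            "mock_receptor.pdb": {"shape": "mock_receptor", "open": False, "seed": seed},
            "mock_receptor_open.pdb": {"shape": "mock_receptor", "open": True, "seed": seed + 1},
        },
        "curves": {},
    }
    for i, (name, (mspec, params)) in enumerate(cases.items()):
        noise = NoiseSpec(seed=seed + 10 + i)
        curve = simulate_curve(mspec, params, q, noise, label=name)
        save_curve(curve, out / name, header=f"synthetic corpus seed={seed}")
        manifest["curves"][name] = {
            "model_id": mspec.model_id,
            "params": params,
            "noise_seed": noise.seed,
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
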