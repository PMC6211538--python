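import numpy as np
import pytest

from fractsans import FractalModel, SANSCurve
from fractsans import fitting as ft
from fractsans import synthetic as syn

SPHERE_R = 50.0
SPHERE_I0 = 0.04


def sphere_intensity(q, i0=SPHERE_I0, radius=SPHERE_R):
    """Analytic uniform-sphere scattering curve (absolute units)."""
    x = np.atleast_1d(np.asarray(q, dtype=float)) * radius
    amp = np.where(x > 1e-8, 3.0 * (np.sin(x) - x * np.cos(x)) / np.maximum(x, 1e-30) ** 3, 1.0)
    return i0 * amp**2


def sphere_pr_true(r, radius=SPHERE_R):
    """Analytic p(r) of a uniform sphere (unnormalized)."""
    x = np.asarray(r, dtype=float) / (2.0 * radius)
    return np.where(x <= 1.0, r**2 * (1.0 - 1.5 * x + 0.5 * x**3), 0.0)


@pytest.fixture(scope="session")
def sphere_curve():
    """Noise-free sphere curve with tight uncertainties (IFT/Guinier oracle)."""
    q = np.geomspace(0.005, 0.35, 150)
    I = sphere_intensity(q)
    sigma = 1e-4 * SPHERE_I0 + 1e-3 * I
    return SANSCurve(q, I, sigma, label="analytic sphere R=50")


@pytest.fixture(scope="session")
def receptor_setup():
    """Mock-receptor assemblies, form-factor tables and model specs."""
    q = syn.default_q_grid()
    q_table = syn.extended_q_grid(q)
    closed, open_, tab_c, tab_o = syn._receptor_tables(0, q_table)
    fractal = FractalModel(r=syn.SUBUNIT_RADIUS_A)
    n = syn.DEFAULT_CONCENTRATION_N
    specs = {
        1: ft.ModelSpec(1, {"atomic": tab_c}, n),
        2: ft.ModelSpec(2, {"atomic": tab_c}, n, fractal),
        3: ft.ModelSpec(3, {"atomic": tab_c, "em": tab_o}, n),
        4: ft.ModelSpec(4, {"atomic": tab_c, "em": tab_o}, n, fractal),
    }
    return {
        "q": q,
        "q_table": q_table,
        "closed": closed,
        "open": open_,
        "tab_closed": tab_c,
        "tab_open": tab_o,
        "fractal": fractal,
        "n": n,
        "specs": specs,
    }


@pytest.fixture(scope="session")
def corpus_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("corpus") / "fixtures"
    manifest = syn.corpus(0, out)
    return out, manifest
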