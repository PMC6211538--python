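"""Unit conventions and physical constants.

All positions are in angstrom (A), momentum transfer q in 1/A, scattering
lengths in cm (1 fm = 1e-13 cm), scattering length densities in 1/cm^2 and
intensities in absolute units of 1/cm.  Every conversion lives here.
"""

FM_TO_CM = 1.0e-13          # scattering length: fm -> cm
A3_TO_CM3 = 1.0e-24         # volume: A^3 -> cm^3
AVOGADRO = 6.02214076e23    # 1/mol
MOLAR_TO_PER_CM3 = 1.0e-3 * AVOGADRO  # mol/L -> molecules/cm^3


def molar_to_number_density(molar: float) -> float:
    """Convert a molar concentration (mol/L) to a number density (1/cm^3)."""
    return molar * MOLAR_TO_PER_CM3
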