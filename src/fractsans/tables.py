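"""Loaders for the versioned plain-text data tables shipped with the package.

Tables: coherent neutron scattering lengths (fm), van der Waals volumes
(A^3), implicit-hydrogen counts per residue/atom, and the molecular-weight
constants used by the Porod-invariant estimators.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources


def _read_rows(name: str) -> list[list[str]]:
    text = resources.files("fractsans").joinpath(f"data/{name}").read_text()
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows


@lru_cache(maxsize=None)
def scattering_lengths_fm() -> dict[str, float]:
    """Coherent neutron scattering length per element symbol, in fm."""
    return {el.upper(): float(b) for el, b in _read_rows("neutron_scattering_lengths.tsv")}


@lru_cache(maxsize=None)
def vdw_volumes_a3() -> dict[str, float]:
    """Van der Waals volume per element symbol, in A^3."""
    return {el.upper(): float(v) for el, v in _read_rows("vdw_volumes.tsv")}


@lru_cache(maxsize=None)
def residue_hydrogens() -> dict[tuple[str, str], tuple[int, int]]:
    """(residue, atom name) -> (total bound H, labile bound H)."""
    return {
        (res.upper(), atom.upper()): (int(nh), int(nl))
        for res, atom, nh, nl in _read_rows("residue_hydrogens.tsv")
    }


@lru_cache(maxsize=None)
def mw_constants() -> dict[str, float]:
    """Constants for the molecular-weight estimators (see data file for sources)."""
    return {row[0]: float(row[1]) for row in _read_rows("mw_constants.tsv")}
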