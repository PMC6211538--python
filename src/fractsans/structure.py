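"""Atomic structures to excess point scatterers.

Reads PDB files, assigns excess neutron scattering lengths (atom plus
implicit bound hydrogens minus the displaced solvent), applies H/D exchange
of labile hydrogens, and adds the membrane-aware hydration shell of dummy
water beads.  The result is a :class:`PointSet` that the scattering layer
consumes.

Deposited structures generally lack hydrogens, so bound H are attached
implicitly from a residue template, split into labile H (on N, O, S; these
exchange with the solvent) and non-labile H (on C).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

from . import tables
from .units import A3_TO_CM3, FM_TO_CM

__all__ = [
    "AtomRecord",
    "PointSet",
    "SolventSpec",
    "MembraneSlab",
    "load_structure",
    "assign_scattering",
    "add_hydration_shell",
    "water_scattering_length",
]

#: molecular volume of one water, A^3
WATER_VOLUME_A3 = 30.0
#: water molecules represented by one hydration bead
WATERS_PER_BEAD = 4.13
#: hydration-layer density excess over bulk water
SHELL_DENSITY_EXCESS = 0.10
#: water-probe radius used for bead placement, A
PROBE_RADIUS_A = 1.4
#: thickness of the single hydration layer, A (about one water diameter)
SHELL_THICKNESS_A = 3.0

_WATER_NAMES = {"HOH", "DOD", "WAT", "H2O", "D2O"}


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom from a structure file (hydrogens are implicit)."""

    element: str
    position: np.ndarray  # (3,) in A
    residue_name: str
    atom_name: str
    chain_id: str
    is_hetero: bool = False
    occupancy: float = 1.0

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"invalid position for atom {self.atom_name}: {self.position}")
        object.__setattr__(self, "position", pos)
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy outside [0, 1]: {self.occupancy}")


@dataclass
class PointSet:
    """Excess point scatterers: positions (A) and excess scattering lengths (cm)."""

    positions: np.ndarray  # (n, 3) A
    b: np.ndarray          # (n,) cm
    label: str = ""

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.b = np.atleast_1d(np.asarray(self.b, dtype=float))
        if self.positions.shape != (self.b.size, 3):
            raise ValueError("positions and b have mismatched shapes")
        if not (np.all(np.isfinite(self.positions)) and np.all(np.isfinite(self.b))):
            raise ValueError("non-finite coordinates or scattering lengths")

    def __len__(self) -> int:
        return self.b.size

    @property
    def total_b(self) -> float:
        """Total excess scattering length, cm."""
        return float(self.b.sum())

    def to_text(self) -> str:
        """Whitespace-separated x y z b_excess table (A, A, A, cm)."""
        lines = [f"# PointSet {self.label}", "# x_A y_A z_A b_excess_cm"]
        for (x, y, z), b in zip(self.positions, self.b):
            lines.append(f"{x:.6f} {y:.6f} {z:.6f} {b:.8e}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str, label: str = "") -> "PointSet":
        rows = [
            [float(tok) for tok in line.split()]
            for line in text.splitlines()
            if line.strip() and not line.lstrip().startswith("#")
        ]
        arr = np.asarray(rows, dtype=float)
        return cls(arr[:, :3], arr[:, 3], label=label)


def water_scattering_length(d2o_fraction: float) -> float:
    """Scattering length of one solvent water molecule, cm.

    The two water hydrogens are H or D according to ``d2o_fraction``.
    """
    b = tables.scattering_lengths_fm()
    b_h2 = 2.0 * ((1.0 - d2o_fraction) * b["H"] + d2o_fraction * b["D"])
    return (b_h2 + b["O"]) * FM_TO_CM


@dataclass(frozen=True)
class SolventSpec:
    """Solvent composition for excess-scattering-length calculations.

    Parameters
    ----------
    d2o_fraction
        Fraction of water that is D2O, in [0, 1].  Default 1.0 (pure D2O
        buffer, the usual match-out condition for deuterated detergents).
    exchange_fraction
        Fraction of labile (N/O/S-bound) hydrogens that actually exchange
        with the solvent.  Default 0.9, the common accessible-exchange
        assumption for folded proteins.
    solvent_sld
        Scattering length density of the solvent in 1/cm^2.  Computed from
        ``d2o_fraction`` and the 30 A^3 water volume when not given.
    """

    d2o_fraction: float = 1.0
    exchange_fraction: float = 0.9
    solvent_sld: float | None = None

    def __post_init__(self):
        for name in ("d2o_fraction", "exchange_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} outside [0, 1]: {v}")
        if self.solvent_sld is None:
            sld = water_scattering_length(self.d2o_fraction) / (WATER_VOLUME_A3 * A3_TO_CM3)
            object.__setattr__(self, "solvent_sld", sld)


@dataclass(frozen=True)
class MembraneSlab:
    """Detergent/membrane-embedded region along ``axis``; the hydration shell
    is suppressed inside it.  Bounds are coordinates along the (unit) axis."""

    z_min: float
    z_max: float
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self):
        if not self.z_min < self.z_max:
            raise ValueError("slab requires z_min < z_max")
        axis = np.asarray(self.axis, dtype=float)
        norm = np.linalg.norm(axis)
        if norm == 0:
            raise ValueError("slab axis must be non-zero")
        object.__setattr__(self, "axis", axis / norm)

    def contains(self, positions: np.ndarray) -> np.ndarray:
        z = np.atleast_2d(positions) @ self.axis
        return (z >= self.z_min) & (z <= self.z_max)


class StructureParseError(ValueError):
    pass


def load_structure(
    pdb_text: str,
    *,
    drop_waters: bool = True,
    drop_hetero: bool = True,
) -> list[AtomRecord]:
    """Parse fixed-column PDB text into a list of :class:`AtomRecord`.

    ATOM and HETATM records are accepted.  For alternate locations, the
    highest-occupancy conformer is kept (ties resolved towards altloc "A").
    Waters, and by default all hetero compounds (detergents, ions, ligands),
    are dropped: the scattering model describes the bare protein.
    Explicit hydrogen/deuterium atoms are skipped; hydrogens are attached
    implicitly later from the residue template.
    """
    try:
        structure = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"PDB parse error: {exc}") from exc
    if len(structure) == 0:
        raise StructureParseError("structure contains no models")

    records: list[AtomRecord] = []
    model = structure[0]
    for chain in model:
        for residue in chain:
            resname = residue.name.strip().upper()
            is_water = residue.is_water() or resname in _WATER_NAMES
            is_het = residue.het_flag == "H"
            if is_water and drop_waters:
                continue
            if is_het and not is_water and drop_hetero:
                continue
            # altloc selection per atom name
            by_name: dict[str, gemmi.Atom] = {}
            for atom in residue:
                key = atom.name
                prev = by_name.get(key)
                if prev is None:
                    by_name[key] = atom
                elif atom.occ > prev.occ or (
                    atom.occ == prev.occ and (atom.altloc or "A") < (prev.altloc or "A")
                ):
                    by_name[key] = atom
            for atom in by_name.values():
                element = atom.element.name.upper()
                if element in ("H", "D"):
                    continue
                pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                if not np.all(np.isfinite(pos)):
                    raise StructureParseError(
                        f"non-finite coordinates for atom {atom.name} in {resname}"
                    )
                records.append(
                    AtomRecord(
                        element=element,
                        position=pos,
                        residue_name=resname,
                        atom_name=atom.name.strip().upper(),
                        chain_id=chain.name,
                        is_hetero=is_het,
                        occupancy=float(min(max(atom.occ, 0.0), 1.0)),
                    )
                )
    if not records:
        raise StructureParseError("no atoms accepted from structure")
    return records


def _implicit_hydrogens(atom: AtomRecord, strict: bool) -> tuple[int, int]:
    template = tables.residue_hydrogens()
    key = (atom.residue_name, atom.atom_name)
    if key in template:
        return template[key]
    if strict and not atom.is_hetero:
        raise KeyError(
            f"no implicit-hydrogen template entry for {atom.residue_name}/{atom.atom_name}"
        )
    return (0, 0)


def assign_scattering(
    atoms: list[AtomRecord],
    solvent: SolventSpec | None = None,
    *,
    strict: bool = True,
    label: str = "",
) -> PointSet:
    """Excess scattering length per atom: b_atom + bound H - displaced solvent.

    For each heavy atom, implicit bound hydrogens come from the residue
    template.  A labile hydrogen contributes
    ``b_H + exchange_fraction * d2o_fraction * (b_D - b_H)``; the excluded
    volume is the atom's vdW volume plus one H volume per bound hydrogen,
    multiplied by the solvent scattering length density.
    """
    if solvent is None:
        solvent = SolventSpec()
    if not atoms:
        raise ValueError("empty atom list")
    b_tab = tables.scattering_lengths_fm()
    v_tab = tables.vdw_volumes_a3()
    b_h, b_d = b_tab["H"], b_tab["D"]
    b_labile = b_h + solvent.exchange_fraction * solvent.d2o_fraction * (b_d - b_h)

    unknown = sorted(
        {a.element for a in atoms if a.element not in b_tab or a.element not in v_tab}
    )
    if unknown:
        raise KeyError(f"element(s) without scattering-length/volume entry: {unknown}")

    positions = np.empty((len(atoms), 3))
    b_excess = np.empty(len(atoms))
    for i, atom in enumerate(atoms):
        n_h, n_labile = _implicit_hydrogens(atom, strict)
        n_nonlabile = n_h - n_labile
        b_fm = b_tab[atom.element] + n_nonlabile * b_h + n_labile * b_labile
        v_a3 = v_tab[atom.element] + n_h * v_tab["H"]
        positions[i] = atom.position
        b_excess[i] = b_fm * FM_TO_CM - solvent.solvent_sld * v_a3 * A3_TO_CM3
    return PointSet(positions, b_excess, label=label or "structure")


def _shell_bead_centers(
    atoms: list[AtomRecord],
    *,
    spacing: float,
    probe: float,
    thickness: float,
) -> np.ndarray:
    """Deterministic bead centers: cubic-lattice nodes one probe radius outside
    the van der Waals surface, within one layer thickness."""
    from scipy.spatial import cKDTree

    v_tab = tables.vdw_volumes_a3()
    pos = np.array([a.position for a in atoms])
    radii = np.array([(3.0 * v_tab[a.element] / (4.0 * np.pi)) ** (1.0 / 3.0) for a in atoms])
    r_max = radii.max()
    pad = r_max + probe + thickness
    lo = np.floor((pos.min(axis=0) - pad) / spacing) * spacing
    hi = pos.max(axis=0) + pad
    axes = [np.arange(l, h + spacing, spacing) for l, h in zip(lo, hi)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)

    tree = cKDTree(pos)
    cutoff = r_max + probe + thickness
    # nearest few atoms are enough to evaluate min(|p - x_j| - r_j)
    k = min(len(atoms), 16)
    dist, idx = tree.query(grid, k=k, distance_upper_bound=cutoff)
    if k == 1:
        dist, idx = dist[:, None], idx[:, None]
    valid = idx < len(atoms)
    surf = np.where(valid, dist - radii[np.clip(idx, 0, len(atoms) - 1)], np.inf)
    d_min = surf.min(axis=1)
    keep = (d_min >= probe) & (d_min < probe + thickness)
    return grid[keep]


def add_hydration_shell(
    points: PointSet,
    atoms: list[AtomRecord],
    solvent: SolventSpec | None = None,
    slab: MembraneSlab | None = None,
    *,
    waters_per_bead: float = WATERS_PER_BEAD,
    water_volume: float = WATER_VOLUME_A3,
    probe: float = PROBE_RADIUS_A,
    thickness: float = SHELL_THICKNESS_A,
) -> PointSet:
    """Add the hydration layer as dummy water beads on the protein surface.

    The layer is a single shell of water at 10% higher density than bulk;
    each bead stands for ``waters_per_bead`` waters, so its excess scattering
    length is ``0.10 * waters_per_bead * b_water``.  Beads are placed on a
    deterministic cubic lattice whose spacing gives each bead the volume of
    ``waters_per_bead`` waters; beads inside the membrane slab (the
    detergent-embedded belt) are omitted.
    """
    if solvent is None:
        solvent = SolventSpec()
    if len(points) == 0:
        raise ValueError("empty PointSet")
    spacing = (waters_per_bead * water_volume) ** (1.0 / 3.0)
    centers = _shell_bead_centers(atoms, spacing=spacing, probe=probe, thickness=thickness)
    if slab is not None and centers.size:
        centers = centers[~slab.contains(centers)]
    if centers.size == 0:
        warnings.warn("hydration shell is empty (slab covers the whole surface?)")
        return replace(points, label=points.label + "+shell(empty)")
    b_bead = SHELL_DENSITY_EXCESS * waters_per_bead * water_scattering_length(
        solvent.d2o_fraction
    )
    return PointSet(
        np.vstack([points.positions, centers]),
        np.concatenate([points.b, np.full(len(centers), b_bead)]),
        label=points.label + "+shell",
    )
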