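import numpy as np
import pytest

from fractsans import tables
from fractsans.structure import (
    AtomRecord,
    MembraneSlab,
    PointSet,
    SolventSpec,
    StructureParseError,
    add_hydration_shell,
    assign_scattering,
    load_structure,
    water_scattering_length,
)
from fractsans.units import FM_TO_CM


def _pdb_line(serial, name, resname, resseq, x, y, z, element, occ=1.0, altloc=" ",
              record="ATOM"):
    return (
        f"{record:<6s}{serial:>5d} {name:<4s}{altloc}{resname:<3s} A{resseq:>4d}    "
        f"{x:>8.3f}{y:>8.3f}{z:>8.3f}{occ:>6.2f}{0.0:>6.2f}          {element:>2s}"
    )


SINGLE_CA = _pdb_line(1, " CA ", "ALA", 1, 1.0, 2.0, 3.0, "C")


class TestLoadStructure:
    def test_single_atom(self):
        atoms = load_structure(SINGLE_CA)
        assert len(atoms) == 1
        a = atoms[0]
        assert a.element == "C"
        assert a.atom_name == "CA"
        assert np.allclose(a.position, [1.0, 2.0, 3.0])

    def test_altloc_keeps_highest_occupancy(self):
        # 10 atom lines; CB appears twice (A occ 0.6, B occ 0.4) -> 9 records
        lines = []
        names = [" N  ", " CA ", " C  ", " O  "]
        els = ["N", "C", "C", "O"]
        for i, (nm, el) in enumerate(zip(names, els)):
            lines.append(_pdb_line(i + 1, nm, "ALA", 1, float(i), 0.0, 0.0, el))
        lines.append(_pdb_line(5, " CB ", "ALA", 1, 0.0, 1.0, 0.0, "C", occ=0.6, altloc="A"))
        lines.append(_pdb_line(6, " CB ", "ALA", 1, 0.5, 1.0, 0.0, "C", occ=0.4, altloc="B"))
        for i, (nm, el) in enumerate(zip(names, els)):
            lines.append(_pdb_line(7 + i, nm, "GLY", 2, float(i), 3.0, 0.0, el))
        atoms = load_structure("\n".join(lines))
        assert len(atoms) == 9
        cb = [a for a in atoms if a.atom_name == "CB"]
        assert len(cb) == 1
        assert cb[0].occupancy == pytest.approx(0.6)
        assert cb[0].position[0] == pytest.approx(0.0)  # altloc A kept

    def test_waters_only_raises(self):
        text = _pdb_line(1, " O  ", "HOH", 1, 0.0, 0.0, 0.0, "O", record="HETATM")
        with pytest.raises(StructureParseError):
            load_structure(text)

    def test_hetero_dropped_by_default_kept_on_request(self):
        text = "\n".join([
            SINGLE_CA,
            _pdb_line(2, "ZN  ", "ZN", 2, 5.0, 5.0, 5.0, "ZN", record="HETATM"),
        ])
        assert len(load_structure(text)) == 1
        assert len(load_structure(text, drop_hetero=False)) == 2

    def test_garbage_raises(self):
        with pytest.raises(StructureParseError):
            load_structure("not a pdb at all\n")


class TestAssignScattering:
    def test_bare_carbon_zero_excluded_volume(self):
        # zero solvent SLD isolates the atomic coherent scattering length
        atom = AtomRecord("C", [0, 0, 0], "LIG", "C1", "A", is_hetero=True)
        ps = assign_scattering([atom], SolventSpec(1.0, 0.9, solvent_sld=0.0),
                               strict=False)
        assert ps.total_b == pytest.approx(6.6460 * FM_TO_CM, rel=1e-12)

    @pytest.mark.parametrize(
        "d2o,ef,expected_h",
        [(0.0, 1.0, "H"), (1.0, 1.0, "D")],
        ids=["no-exchange", "full-exchange"],
    )
    def test_labile_hydrogen_exchange_limits(self, d2o, ef, expected_h):
        b = tables.scattering_lengths_fm()
        atom = AtomRecord("N", [0, 0, 0], "ALA", "N", "A")  # backbone N, 1 labile H
        ps = assign_scattering([atom], SolventSpec(d2o, ef, solvent_sld=0.0))
        assert ps.total_b == pytest.approx((b["N"] + b[expected_h]) * FM_TO_CM, rel=1e-12)

    def test_exchange_linearity_in_d2o_fraction(self):
        atoms = load_structure(SINGLE_CA)
        totals = [
            assign_scattering(atoms, SolventSpec(f, 0.9)).total_b
            for f in (0.0, 0.5, 1.0)
        ]
        assert totals[1] == pytest.approx(0.5 * (totals[0] + totals[2]), rel=1e-10)

    def test_unknown_residue_atom_raises_with_offender(self):
        atom = AtomRecord("C", [0, 0, 0], "XYZ", "Q9", "A")
        with pytest.raises(KeyError, match="XYZ"):
            assign_scattering([atom], SolventSpec())

    def test_excluded_volume_subtracted(self):
        v = tables.vdw_volumes_a3()
        b = tables.scattering_lengths_fm()
        atom = AtomRecord("C", [0, 0, 0], "LIG", "C1", "A", is_hetero=True)
        sld = 6.0e10
        ps = assign_scattering([atom], SolventSpec(1.0, solvent_sld=sld), strict=False)
        expected = b["C"] * FM_TO_CM - sld * v["C"] * 1e-24
        assert ps.total_b == pytest.approx(expected, rel=1e-12)


class TestHydrationShell:
    def _ala(self):
        return load_structure(SINGLE_CA)

    def test_bead_b_value_and_monotonicity(self):
        atoms = self._ala()
        sol = SolventSpec()
        base = assign_scattering(atoms, sol)
        hyd = add_hydration_shell(base, atoms, sol)
        assert len(hyd) > len(base)
        # existing points and weights untouched
        assert np.array_equal(hyd.positions[: len(base)], base.positions)
        assert np.array_equal(hyd.b[: len(base)], base.b)
        expected = 0.10 * 4.13 * water_scattering_length(1.0)
        assert np.allclose(hyd.b[len(base):], expected)

    def test_slab_covering_everything_gives_empty_shell(self):
        atoms = self._ala()
        sol = SolventSpec()
        base = assign_scattering(atoms, sol)
        slab = MembraneSlab(-1000.0, 1000.0)
        with pytest.warns(UserWarning, match="empty"):
            hyd = add_hydration_shell(base, atoms, sol, slab)
        assert len(hyd) == len(base)

    def test_partial_slab_removes_only_inside_beads(self):
        atoms = self._ala()
        sol = SolventSpec()
        base = assign_scattering(atoms, sol)
        full = add_hydration_shell(base, atoms, sol)
        z_mid = float(np.median(full.positions[len(base):, 2]))
        slab = MembraneSlab(z_mid - 2.0, z_mid + 2.0)
        part = add_hydration_shell(base, atoms, sol, slab)
        assert len(base) < len(part) < len(full)
        beads = part.positions[len(base):]
        assert not np.any((beads[:, 2] >= slab.z_min) & (beads[:, 2] <= slab.z_max))

    def test_single_atom_bead_count_matches_lattice_oracle(self):
        # independent brute-force count of lattice nodes in the shell annulus
        atom = AtomRecord("C", [0.3, -0.2, 0.7], "LIG", "C1", "A", is_hetero=True)
        base = PointSet([[0.3, -0.2, 0.7]], [1e-12])
        hyd = add_hydration_shell(base, [atom], SolventSpec())
        r_vdw = (3.0 * tables.vdw_volumes_a3()["C"] / (4 * np.pi)) ** (1 / 3)
        a = (4.13 * 30.0) ** (1 / 3)
        pad = r_vdw + 1.4 + 3.0
        lo = np.floor((atom.position - pad) / a) * a
        count = 0
        for i in range(20):
            for j in range(20):
                for k in range(20):
                    p = lo + a * np.array([i, j, k])
                    if np.any(p > atom.position + pad + a):
                        continue
                    d = np.linalg.norm(p - atom.position) - r_vdw
                    if 1.4 <= d < 4.4:
                        count += 1
        assert len(hyd) - 1 == count

    def test_d2o_ratio_of_bead_weights(self):
        atoms = self._ala()
        b1 = add_hydration_shell(assign_scattering(atoms, SolventSpec(1.0)), atoms,
                                 SolventSpec(1.0)).b[-1]
        b0 = add_hydration_shell(assign_scattering(atoms, SolventSpec(0.0)), atoms,
                                 SolventSpec(0.0)).b[-1]
        assert b1 / b0 == pytest.approx(
            water_scattering_length(1.0) / water_scattering_length(0.0), rel=1e-12
        )

    def test_reproducibility_bit_identical(self):
        atoms = self._ala()
        sol = SolventSpec()
        base = assign_scattering(atoms, sol)
        h1 = add_hydration_shell(base, atoms, sol)
        h2 = add_hydration_shell(base, atoms, sol)
        assert np.array_equal(h1.positions, h2.positions)
        assert np.array_equal(h1.b, h2.b)


def test_pointset_text_round_trip():
    ps = PointSet([[0.0, 1.5, -2.25], [3.0, 0.0, 1.0]], [1.5e-12, -2.0e-12], label="toy")
    back = PointSet.from_text(ps.to_text(), label="toy")
    assert np.allclose(back.positions, ps.positions)
    assert np.allclose(back.b, ps.b)


def test_solvent_sld_defaults():
    # pure D2O ~ 6.38e10 cm^-2, pure H2O ~ -0.56e10 cm^-2
    assert SolventSpec(1.0).solvent_sld == pytest.approx(6.38e10, rel=0.01)
    assert SolventSpec(0.0).solvent_sld == pytest.approx(-0.56e10, rel=0.02)
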