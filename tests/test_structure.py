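"""PDB parsing, region extraction, Kabsch superposition, dual RMSD."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from foldswitch_eval import (
    FormatError,
    ParameterError,
    ReferencePair,
    StructureModel,
    ValidationError,
    dual_rmsd,
    extract_region,
    kabsch_superpose,
    map_atoms,
    mean_plddt,
    read_model,
)
from foldswitch_eval.structure import Residue
from foldswitch_eval.synth import build_chain


def _atom_line(serial, name, resname, resnum, xyz, bfactor,
               record="ATOM", altloc=" ", element=None):
    element = element or name[0]
    return (
        f"{record:<6}{serial:>5} {name.center(4)}{altloc}{resname:<3} A"
        f"{resnum:>4}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"{1.0:6.2f}{bfactor:6.2f}          {element:>2}\n"
    )


def write_two_residue_pdb(path, bfactors=(70.0, 80.0)):
    lines = [
        _atom_line(1, "N", "ALA", 1, (0.0, 0.0, 0.0), bfactors[0]),
        _atom_line(2, "CA", "ALA", 1, (1.46, 0.0, 0.0), bfactors[0]),
        _atom_line(3, "C", "ALA", 1, (2.0, 1.4, 0.0), bfactors[0]),
        _atom_line(4, "N", "GLY", 2, (3.3, 1.5, 0.0), bfactors[1]),
        _atom_line(5, "CA", "GLY", 2, (4.2, 2.6, 0.0), bfactors[1]),
        _atom_line(6, "C", "GLY", 2, (5.6, 2.0, 0.0), bfactors[1]),
    ]
    path.write_text("".join(lines) + "END\n")


class TestReadModel:
    def test_plddt_from_ca_bfactor(self, tmp_path):
        p = tmp_path / "m.pdb"
        write_two_residue_pdb(p, bfactors=(70.0, 80.0))
        m = read_model(p)
        assert list(m.per_residue_plddt) == [70.0, 80.0]
        assert m.sequence == "AG"

    def test_fractional_plddt_rescaled(self, tmp_path):
        p = tmp_path / "m.pdb"
        write_two_residue_pdb(p, bfactors=(0.70, 0.80))
        m = read_model(p)
        assert np.allclose(m.per_residue_plddt, [70.0, 80.0])

    def test_hetatm_only_rejected(self, tmp_path):
        p = tmp_path / "m.pdb"
        p.write_text(
            _atom_line(1, "O", "HOH", 1, (0, 0, 0), 0.0, record="HETATM")
            + "END\n"
        )
        with pytest.raises(FormatError):
            read_model(p)

    def test_residue_without_ca_dropped_with_warning(self, tmp_path, caplog):
        p = tmp_path / "m.pdb"
        lines = [
            _atom_line(1, "N", "ALA", 1, (0, 0, 0), 50.0),  # no CA
            _atom_line(2, "N", "GLY", 2, (3.3, 1.5, 0), 60.0),
            _atom_line(3, "CA", "GLY", 2, (4.2, 2.6, 0), 60.0),
            _atom_line(4, "C", "GLY", 2, (5.6, 2.0, 0), 60.0),
        ]
        p.write_text("".join(lines) + "END\n")
        with caplog.at_level("WARNING"):
            m = read_model(p)
        assert len(m) == 1 and m.residues[0].number == 2
        assert "no CA" in caplog.text

    def test_non_primary_altloc_discarded(self, tmp_path):
        p = tmp_path / "m.pdb"
        lines = [
            _atom_line(1, "N", "ALA", 1, (0, 0, 0), 70.0),
            _atom_line(2, "CA", "ALA", 1, (1.46, 0, 0), 70.0, altloc="A"),
            _atom_line(3, "CA", "ALA", 1, (9.0, 9.0, 9.0), 10.0, altloc="B"),
            _atom_line(4, "C", "ALA", 1, (2.0, 1.4, 0), 70.0),
            _atom_line(5, "N", "GLY", 2, (3.3, 1.5, 0), 70.0),
            _atom_line(6, "CA", "GLY", 2, (4.2, 2.6, 0), 70.0),
            _atom_line(7, "C", "GLY", 2, (5.6, 2.0, 0), 70.0),
        ]
        p.write_text("".join(lines) + "END\n")
        m = read_model(p)
        assert np.allclose(m.residues[0].atoms["CA"], [1.46, 0, 0], atol=1e-3)


class TestRegionAndPlddt:
    def test_interval_selects_inclusive_range(self, refs):
        sub = extract_region(refs.ground, (4, 6))
        assert sub.numbers == [4, 5, 6]

    def test_full_interval_is_identity(self, refs):
        sub = extract_region(refs.ground, (1, 60))
        assert len(sub) == len(refs.ground)

    def test_empty_overlap_rejected(self, refs):
        with pytest.raises(ParameterError):
            extract_region(refs.ground, (100, 200))

    def test_mean_plddt_values(self):
        m = build_chain("ACDEG", -57.0, -47.0, plddt=np.array(
            [60.0, 80.0, 55.0, 70.0, 70.0]))
        assert mean_plddt(m, (1, 2)) == 70.0
        assert mean_plddt(m, (3, 3)) == 55.0
        assert mean_plddt(m) == pytest.approx(67.0)


class TestMapAtoms:
    def test_identical_models_pair_all_heavy_atoms(self, refs):
        X, Y, labels = map_atoms(refs.ground, refs.ground)
        assert len(X) == 4 * len(refs.ground)  # backbone N, CA, C, O
        assert np.array_equal(X, Y)

    def test_missing_atom_excluded_from_both(self):
        a = build_chain("ACDEG", -57.0, -47.0)
        b = build_chain("ACDEG", -57.0, -47.0)
        del b.residues[2].atoms["O"]
        X, Y, labels = map_atoms(a, b)
        assert len(X) == 4 * 5 - 1
        assert (3, "O") not in labels

    def test_ca_only_counts_residues(self, refs):
        X, _, _ = map_atoms(refs.ground, refs.alternative, "ca_only")
        assert len(X) == len(refs.ground)

    def test_mutant_sequences_warn_but_pair(self, caplog):
        a = build_chain("ACDEGKLMNP", -57.0, -47.0)
        b = build_chain("ACDEGKLMNQ", -57.0, -47.0)
        with caplog.at_level("WARNING"):
            X, Y, _ = map_atoms(a, b)
        assert len(X) == 40
        assert "identical" in caplog.text

    def test_too_few_atoms_rejected(self):
        a = build_chain("ACDE", -57.0, -47.0)
        b = build_chain("ACDE", -57.0, -47.0)
        for r in b.residues[:3]:
            for name in ("N", "C", "O"):
                del r.atoms[name]
        for name in ("N", "C", "O"):
            del b.residues[3].atoms[name]
        # only CAs remain in b -> 4 pairs, fine; now drop CAs too
        for r in b.residues[1:]:
            del r.atoms["CA"]
        b.residues = b.residues[:1]
        b.per_residue_plddt = b.per_residue_plddt[:1]
        with pytest.raises(ValidationError):
            map_atoms(a, b)


class TestKabsch:
    def test_identity_superposition(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 3))
        R, t, rmsd = kabsch_superpose(X, X)
        assert np.allclose(R, np.eye(3), atol=1e-10)
        assert np.allclose(t, 0, atol=1e-10)
        assert rmsd <= 1e-10

    def test_exact_rigid_motion_recovered(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(8, 3))
        R0 = Rotation.from_euler("z", 37, degrees=True).as_matrix()
        Y = X @ R0.T + np.array([1.0, 2.0, 3.0])
        _, _, rmsd = kabsch_superpose(X, Y)
        assert rmsd <= 1e-6

    def test_rigid_motion_invariance_randomized(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            X = rng.normal(size=(6, 3))
            Y = rng.normal(size=(6, 3))
            _, _, base = kabsch_superpose(X, Y)
            R0 = Rotation.random(random_state=rng.integers(2**31)).as_matrix()
            t0 = rng.normal(size=3) * 10
            _, _, moved = kabsch_superpose(X @ R0.T + t0, Y)
            assert abs(moved - base) <= 1e-6
            _, _, moved_y = kabsch_superpose(X, Y @ R0.T + t0)
            assert abs(moved_y - base) <= 1e-6

    def test_symmetry_after_superposition(self):
        rng = np.random.default_rng(3)
        X, Y = rng.normal(size=(12, 3)), rng.normal(size=(12, 3))
        _, _, ab = kabsch_superpose(X, Y)
        _, _, ba = kabsch_superpose(Y, X)
        assert abs(ab - ba) <= 1e-6

    def test_rotation_is_proper(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            X, Y = rng.normal(size=(5, 3)), rng.normal(size=(5, 3))
            R, _, _ = kabsch_superpose(X, Y)
            assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-8)

    def test_agrees_with_scipy_align_vectors(self):
        # independent route: scipy solves the same least-squares problem
        rng = np.random.default_rng(5)
        X, Y = rng.normal(size=(20, 3)), rng.normal(size=(20, 3))
        _, _, rmsd = kabsch_superpose(X, Y)
        Xc, Yc = X - X.mean(0), Y - Y.mean(0)
        _, rssd = Rotation.align_vectors(Yc, Xc)
        assert rmsd == pytest.approx(rssd / np.sqrt(len(X)), abs=1e-9)

    def test_collinear_points_rejected(self):
        X = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(ParameterError):
            kabsch_superpose(X, X)

    def test_too_few_points_rejected(self):
        X = np.array([[0.0, 0, 0], [1, 0, 0]])
        with pytest.raises(ParameterError):
            kabsch_superpose(X, X)


class TestDualRMSD:
    def test_ground_reference_scores_zero(self, refs):
        d = dual_rmsd(refs.ground, refs)
        assert d.rmsd_ground <= 1e-6
        assert d.rmsd_alt > 5.0

    def test_alternative_reference_scores_zero(self, refs):
        d = dual_rmsd(refs.alternative, refs)
        assert d.rmsd_alt <= 1e-6
        assert d.rmsd_ground > 5.0

    def test_mismatched_region_sequences_rejected(self):
        a = build_chain("ACDEGKLMNPQRSTVWYACD" * 2, -57.0, -47.0)
        b = build_chain("CCDEGKLMNPQRSTVWYACD" * 2, -139.0, 135.0)
        with pytest.raises(ValidationError):
            ReferencePair(ground=a, alternative=b, region=(1, 40))

    def test_interpolation_toward_alternative_is_monotone(self, refs):
        # noiseless interpolation between superposed conformers
        X, Y, labels = map_atoms(refs.ground, refs.alternative)
        R, t, _ = kabsch_superpose(Y, X)  # alt frame -> ground frame
        alt_in_ground = Y @ R.T + t
        rmsds = []
        for frac in (0.0, 0.25, 0.5, 0.75, 1.0):
            coords = (1 - frac) * X + frac * alt_in_ground
            residues, plddt = [], []
            k = 0
            for res in refs.ground.residues:
                atoms = {}
                for name in sorted(res.atoms):  # map_atoms emits sorted names
                    assert labels[k] == (res.number, name)
                    atoms[name] = coords[k]
                    k += 1
                residues.append(Residue(res.number, res.name, atoms))
                plddt.append(90.0)
            model = StructureModel(residues=residues, per_residue_plddt=plddt)
            rmsds.append(dual_rmsd(model, refs).rmsd_alt)
        assert all(b < a for a, b in zip(rmsds, rmsds[1:]))

    def test_whole_chain_fit_mode(self, refs):
        d = dual_rmsd(refs.ground, refs, fit="whole")
        assert d.rmsd_ground <= 1e-6
        # flanks are identical helices, so whole-chain fit inflates the
        # region RMSD relative to region-only fit
        d_region = dual_rmsd(refs.alternative, refs, fit="region")
        d_whole = dual_rmsd(refs.alternative, refs, fit="whole")
        assert d_whole.rmsd_ground >= d_region.rmsd_ground - 1e-9
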