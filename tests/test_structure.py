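"""Structure features against closed forms and brute-force oracles."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ribovelo.structure import (
    ProteinStructure,
    StructureError,
    assign_secondary_structure,
    disorder_scores,
    load_structure,
    local_absolute_contact_order,
    relative_asa,
    residue_feature_table,
    shrake_rupley_asa,
    write_structure,
)
from ribovelo.synthetic import generate_antiparallel_sheet, generate_ideal_structure


def single_atom(element="O", coord=(0.0, 0.0, 0.0)):
    return ProteinStructure(
        gene_id="x",
        res_ids=np.array([1]),
        res_names=np.array(["G"]),
        plddt=np.array([90.0]),
        atom_res_index=np.array([0]),
        atom_names=np.array(["CA"]),
        elements=np.array([element]),
        coords=np.array([coord], dtype=float),
    )


def two_atoms(d, element="O"):
    return ProteinStructure(
        gene_id="x",
        res_ids=np.array([1, 2]),
        res_names=np.array(["G", "G"]),
        plddt=np.array([90.0, 90.0]),
        atom_res_index=np.array([0, 1]),
        atom_names=np.array(["CA", "CA"]),
        elements=np.array([element, element]),
        coords=np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]]),
    )


class TestFileIO:
    def test_pdb_round_trip(self, tmp_path):
        s = generate_ideal_structure("HHHHHCCCEE", seed=2, gene_id="g1")
        path = tmp_path / "g1.pdb"
        write_structure(s, path)
        r = load_structure(path)
        assert r.gene_id == "g1"
        assert np.allclose(r.coords, s.coords, atol=1e-3)
        assert np.array_equal(r.res_names, s.res_names)
        assert np.allclose(r.plddt, s.plddt)

    def test_plddt_from_b_factor(self, tmp_path):
        s = generate_ideal_structure("HHHHHHHH", gene_id="g2")
        s.plddt[:] = 90.0
        path = tmp_path / "g2.pdb"
        write_structure(s, path)
        assert np.all(load_structure(path).plddt == 90.0)

    def test_missing_backbone_atom_named(self, tmp_path):
        s = generate_ideal_structure("HHHH", gene_id="g3")
        keep = ~((s.atom_res_index == 2) & (s.atom_names == "CA"))
        broken = ProteinStructure(
            gene_id="g3",
            res_ids=s.res_ids,
            res_names=s.res_names,
            plddt=s.plddt,
            atom_res_index=s.atom_res_index[keep],
            atom_names=s.atom_names[keep],
            elements=s.elements[keep],
            coords=s.coords[keep],
        )
        path = tmp_path / "g3.pdb"
        write_structure(broken, path)
        with pytest.raises(StructureError, match="residue 3.*CA"):
            load_structure(path)


def kabsch_sander_bonds_oracle(struct):
    """Independent loop-based H-bond enumeration (donor, acceptor) pairs."""
    N = struct.backbone_coords("N")
    C = struct.backbone_coords("C")
    O = struct.backbone_coords("O")
    R = struct.n_residues
    bonds = set()
    for d in range(1, R):
        if struct.res_ids[d] != struct.res_ids[d - 1] + 1:
            continue
        if struct.res_names[d] == "P":
            continue
        co = C[d - 1] - O[d - 1]
        h = N[d] + co / np.linalg.norm(co)
        for a in range(R):
            if abs(a - d) < 2:
                continue
            e = 27.888 * (
                1 / np.linalg.norm(O[a] - N[d])
                + 1 / np.linalg.norm(C[a] - h)
                - 1 / np.linalg.norm(O[a] - h)
                - 1 / np.linalg.norm(C[a] - N[d])
            )
            if e < -0.5:
                bonds.add((d, a))
    return bonds


class TestSecondaryStructure:
    def test_ideal_helix_turn_bonds_and_assignment(self):
        s = generate_ideal_structure("H" * 20)
        bonds = kabsch_sander_bonds_oracle(s)
        # every i -> i+4 turn inside the chain is H-bonded
        for i in range(16):
            assert (i + 4, i) in bonds
        ss = assign_secondary_structure(s)
        assert set(ss[2:18]) == {"H"}  # residues 3..18 (1-based) all helix
        assert "E" not in ss

    def test_two_residue_peptide_is_coil(self):
        s = generate_ideal_structure("HH")
        assert list(assign_secondary_structure(s)) == ["C", "C"]

    def test_antiparallel_strands_form_bridges(self):
        s = generate_antiparallel_sheet(8)
        bonds = kabsch_sander_bonds_oracle(s)
        # registered narrow pairs donate in both directions
        assert any((d, a) in bonds and (a, d) in bonds for d in range(8)
                   for a in range(8, 16))
        ss = assign_secondary_structure(s)
        assert set(ss[1:7]) == {"E"}
        assert set(ss[9:15]) == {"E"}

    def test_coil_chain_has_no_strand(self):
        for seed in range(3):
            s = generate_ideal_structure("C" * 25, seed=seed)
            assert "E" not in assign_secondary_structure(s)

    def test_short_chain_all_coil(self):
        s = generate_ideal_structure("HHHH")
        assert list(assign_secondary_structure(s)) == ["C"] * 4


class TestShrakeRupley:
    def test_isolated_atom_matches_analytic_sphere(self):
        asa = shrake_rupley_asa(single_atom("O"))
        assert asa[0] == pytest.approx(4 * math.pi * (1.52 + 1.4) ** 2, rel=1e-6)

    def test_distant_atoms_fully_exposed(self):
        asa = shrake_rupley_asa(two_atoms(100.0))
        full = 4 * math.pi * (1.52 + 1.4) ** 2
        assert np.allclose(asa, full, rtol=1e-6)

    def test_overlapping_spheres_match_cap_formula(self):
        r_aug = 1.52 + 1.4
        for d in (2.0, 3.0, 4.0, 5.0):
            asa = shrake_rupley_asa(two_atoms(d), n_points=960)
            analytic = 4 * math.pi * r_aug**2 - 2 * math.pi * r_aug * (r_aug - d / 2)
            assert asa[0] == pytest.approx(analytic, rel=0.02)
            assert asa[1] == pytest.approx(analytic, rel=0.02)

    def test_point_count_convergence(self):
        r_aug = 1.52 + 1.4
        analytic = 4 * math.pi * r_aug**2 - 2 * math.pi * r_aug * (r_aug - 1.5)
        errs = [
            abs(shrake_rupley_asa(two_atoms(3.0), n_points=n)[0] - analytic) / analytic
            for n in (96, 240, 960)
        ]
        assert errs[2] < 0.02
        assert errs[2] <= errs[0]

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            shrake_rupley_asa(single_atom(), n_points=5)


class TestRelativeAsa:
    def test_maximum_gives_one(self):
        assert relative_asa(129.0, "A") == pytest.approx(1.0)

    def test_zero_and_clipping(self):
        assert relative_asa(0.0, "W") == 0.0
        assert relative_asa(500.0, "G") == 1.0

    def test_unknown_code_rejected(self):
        with pytest.raises(ValueError):
            relative_asa(10.0, "X")


class TestDisorder:
    def test_full_confidence_gives_zero(self):
        s = generate_ideal_structure("H" * 10)
        s.plddt[:] = 100.0
        assert np.allclose(disorder_scores(s), 0.0)

    def test_constant_low_confidence(self):
        s = generate_ideal_structure("C" * 10)
        s.plddt[:] = 30.0
        assert np.allclose(disorder_scores(s), 0.7)

    def test_step_profile_matches_hand_rolled_average(self):
        s = generate_ideal_structure("H" * 60, seed=0)
        s.plddt[:30] = 90.0
        s.plddt[30:] = 40.0
        raw = 1 - s.plddt / 100
        expected = np.array(
            [raw[max(0, i - 7): i + 8].mean() for i in range(60)]
        )
        assert np.allclose(disorder_scores(s, window=15), expected)

    def test_external_scores_validated(self):
        s = generate_ideal_structure("H" * 5)
        ext = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        assert np.array_equal(disorder_scores(s, external_scores=ext), ext)
        with pytest.raises(ValueError):
            disorder_scores(s, external_scores=np.array([0.1, 0.2, 0.3, 0.4, 1.5]))


def laco_brute_force(struct, cutoff=6.0, min_sep=2):
    R = struct.n_residues
    out = np.full(R, np.nan)
    for i in range(R):
        seps = []
        for j in range(R):
            if abs(i - j) < min_sep:
                continue
            ci = struct.coords[struct.atom_res_index == i]
            cj = struct.coords[struct.atom_res_index == j]
            dmin = np.sqrt(((ci[:, None] - cj[None]) ** 2).sum(-1)).min()
            if dmin < cutoff:
                seps.append(abs(i - j))
        if seps:
            out[i] = np.mean(seps)
    return out


class TestContactOrder:
    def test_extended_chain_all_missing(self):
        # CA trace at 3.8 A spacing: closest pair at separation >= 2 is 7.6 A
        R = 12
        s = ProteinStructure(
            gene_id="ext",
            res_ids=np.arange(1, R + 1),
            res_names=np.array(["A"] * R),
            plddt=np.full(R, 90.0),
            atom_res_index=np.arange(R),
            atom_names=np.array(["CA"] * R),
            elements=np.array(["C"] * R),
            coords=np.column_stack(
                [3.8 * np.arange(R), np.zeros(R), np.zeros(R)]
            ),
        )
        assert np.all(np.isnan(local_absolute_contact_order(s)))

    def test_single_contact_pair(self):
        coords = np.array([[0, 0, 0], [10, 0, 0], [20, 0, 0], [3, 0, 0]], dtype=float)
        s = ProteinStructure(
            gene_id="t",
            res_ids=np.arange(1, 5),
            res_names=np.array(["G"] * 4),
            plddt=np.full(4, 90.0),
            atom_res_index=np.arange(4),
            atom_names=np.array(["CA"] * 4),
            elements=np.array(["C"] * 4),
            coords=coords,
        )
        laco = local_absolute_contact_order(s)
        assert laco[0] == 3.0
        assert laco[3] == 3.0
        assert np.isnan(laco[1]) and np.isnan(laco[2])

    def test_matches_brute_force_on_random_structures(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            R = 30
            centers = rng.normal(scale=4.0, size=(R, 3))
            coords = np.repeat(centers, 2, axis=0) + rng.normal(scale=0.5, size=(2 * R, 3))
            s = ProteinStructure(
                gene_id="r",
                res_ids=np.arange(1, R + 1),
                res_names=np.array(["A"] * R),
                plddt=np.full(R, 90.0),
                atom_res_index=np.repeat(np.arange(R), 2),
                atom_names=np.tile(np.array(["N", "CA"]), R),
                elements=np.tile(np.array(["N", "C"]), R),
                coords=coords,
            )
            got = local_absolute_contact_order(s)
            want = laco_brute_force(s)
            assert np.allclose(got, want, equal_nan=True)


class TestRigidMotionInvariance:
    def test_features_unchanged_under_rotation(self):
        s = generate_ideal_structure("HHHHHHHHCCCCEEEECCHHHHHH", seed=4)
        rot = Rotation.random(random_state=7).as_matrix()
        t = np.array([12.0, -5.0, 30.0])
        moved = s.transformed(rot, t)
        assert np.array_equal(
            assign_secondary_structure(s), assign_secondary_structure(moved)
        )
        assert np.allclose(
            local_absolute_contact_order(s),
            local_absolute_contact_order(moved),
            equal_nan=True,
        )
        a0 = shrake_rupley_asa(s)
        a1 = shrake_rupley_asa(moved)
        # total area is orientation-stable to 0.5%; per-residue values
        # fluctuate more at 960 points because occlusion boundaries shift
        assert a1.sum() == pytest.approx(a0.sum(), rel=0.005)
        assert np.allclose(a0, a1, rtol=0.03)


def test_feature_table_shape():
    s = generate_ideal_structure("HHHHHHHHHHCCCCC", seed=1, gene_id="gX")
    df = residue_feature_table(s, n_points=240)
    assert list(df["residue_index"]) == list(range(1, 16))
    assert set(df.columns) >= {"gene_id", "aa", "ss3", "asa", "rasa", "idr", "laco"}
    assert df["rasa"].between(0, 1).all()
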