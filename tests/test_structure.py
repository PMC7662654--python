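"""Contacts, interaction classification, network diffs and superposition."""

import itertools

import numpy as np
import pytest

from startscan import (
    Interaction,
    InteractionKind,
    StructureModel,
    classify_interactions,
    diff_networks,
    environment_contacts,
    interaction_network,
    kabsch,
    make_toy_structure,
    read_structure,
    superpose_rmsd,
    write_pdb,
)
from startscan.structure import AtomRecord, pdb_text


def atom(chain, res_name, res_seq, atom_name, x, y, z, element=None):
    return AtomRecord(
        chain=chain,
        res_name=res_name,
        res_seq=res_seq,
        atom_name=atom_name,
        element=element or atom_name[0],
        xyz=(float(x), float(y), float(z)),
    )


def structure_from_pdb_text(tmp_path, text, name="fixture"):
    path = tmp_path / f"{name}.pdb"
    path.write_text(text)
    return read_structure(path)


class TestReadStructure:
    def test_three_residue_fixture(self, three_residue_pdb):
        st = read_structure(three_residue_pdb)
        assert len(st.residues()) == 3
        assert len(st.atoms) == 11

    def test_pdb_and_mmcif_agree(self, three_residue_pdb, tmp_path):
        import gemmi

        st_pdb = read_structure(three_residue_pdb)
        g = gemmi.read_structure(str(three_residue_pdb))
        g.setup_entities()
        cif = tmp_path / "same.cif"
        g.make_mmcif_document().write_file(str(cif))
        st_cif = read_structure(cif)
        assert [(a.res_name, a.res_seq, a.atom_name) for a in st_cif.atoms] == [
            (a.res_name, a.res_seq, a.atom_name) for a in st_pdb.atoms
        ]
        np.testing.assert_allclose(st_cif.coords, st_pdb.coords, atol=1e-3)

    def test_waters_only_rejected(self, tmp_path):
        text = (
            "HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O\n"
            "HETATM    2  O   HOH A   2       3.000   0.000   0.000  1.00  0.00           O\n"
            "END\n"
        )
        path = tmp_path / "waters.pdb"
        path.write_text(text)
        with pytest.raises(ValueError, match="no protein atoms"):
            read_structure(path)

    def test_round_trip_through_own_writer(self, three_residue_pdb, tmp_path):
        st = read_structure(three_residue_pdb)
        out = tmp_path / "rewritten.pdb"
        write_pdb(st, out)
        again = read_structure(out)
        assert [(a.res_seq, a.atom_name) for a in again.atoms] == [
            (a.res_seq, a.atom_name) for a in st.atoms
        ]
        np.testing.assert_allclose(again.coords, st.coords, atol=1e-3)


def brute_force_contacts(structure, key, cutoff):
    """O(n^2) oracle over all atom pairs, same exclusions."""
    from startscan.structure import _is_adjacent_backbone_pair

    out = set()
    for a in structure.atoms:
        if a.residue_key != key:
            continue
        for b in structure.atoms:
            if b.residue_key == key or _is_adjacent_backbone_pair(a, b):
                continue
            d = float(np.linalg.norm(np.subtract(a.xyz, b.xyz)))
            if d <= cutoff:
                out.add((a.atom_name, b.residue_key, b.atom_name, round(d, 9)))
    return out


class TestEnvironmentContacts:
    @pytest.mark.parametrize("d, n_expected", [(3.99, 1), (4.01, 0)])
    def test_cutoff_boundary(self, tmp_path, d, n_expected):
        text, _ = make_toy_structure([(InteractionKind.OTHER_CONTACT, d)])
        st = structure_from_pdb_text(tmp_path, text, f"pair{d}")
        contacts = environment_contacts(st, 1, cutoff=4.0)
        assert len(contacts) == n_expected
        if contacts:
            assert contacts[0].distance == pytest.approx(d, abs=0.01)

    def test_equals_brute_force_on_random_cluster(self, rng, tmp_path):
        # ~40 residues x 5 atoms = 200 atoms in a 20 A box
        atoms = []
        names = ["N", "CA", "C", "O", "CB"]
        for r in range(40):
            base = rng.uniform(0, 20, size=3)
            for k, nm in enumerate(names):
                pos = base + rng.normal(scale=1.0, size=3)
                atoms.append(atom("A", "ALA", r + 1, nm, *pos))
        st = StructureModel(atoms=atoms)
        for target in (1, 7, 23, 40):
            got = {
                (c.atom_a.atom_name, c.atom_b.residue_key, c.atom_b.atom_name, round(c.distance, 9))
                for c in environment_contacts(st, target, cutoff=4.0)
            }
            assert got == brute_force_contacts(st, ("A", target), 4.0)

    def test_absent_residue_named_in_error(self, three_residue_pdb):
        st = read_structure(three_residue_pdb)
        with pytest.raises(KeyError, match="99"):
            environment_contacts(st, 99)

    def test_adjacent_backbone_pairs_excluded(self):
        # two sequence-adjacent residues with backbone atoms 2 A apart:
        # backbone-backbone contacts are covalent neighbourhood, not tertiary
        atoms = [
            atom("A", "ALA", 1, "C", 0, 0, 0),
            atom("A", "ALA", 2, "N", 1.33, 0, 0),
            atom("A", "ALA", 2, "CB", 0, 2.0, 0),
        ]
        st = StructureModel(atoms=atoms)
        contacts = environment_contacts(st, 1, cutoff=4.0)
        assert [(c.atom_a.atom_name, c.atom_b.atom_name) for c in contacts] == [("C", "CB")]


class TestClassification:
    @pytest.mark.parametrize(
        "kind, d",
        [
            (InteractionKind.CATION_PI, 3.3),
            (InteractionKind.CATION_PI, 3.8),
            (InteractionKind.HYDROGEN_BOND, 2.9),
            (InteractionKind.HYDROGEN_BOND, 3.1),
            (InteractionKind.HYDROGEN_BOND, 3.2),
        ],
    )
    def test_requested_kind_and_distance_recovered(self, tmp_path, kind, d):
        text, _ = make_toy_structure([(kind, d)])
        st = structure_from_pdb_text(tmp_path, text, f"{kind.value}_{d}")
        net = interaction_network(st, [k[1] for k in st.residues()])
        assert [i.kind for i in net] == [kind]
        assert net[0].distance == pytest.approx(d, abs=0.01)

    def test_beyond_cutoff_yields_nothing(self, tmp_path):
        text, _ = make_toy_structure([(InteractionKind.CATION_PI, 4.5)])
        st = structure_from_pdb_text(tmp_path, text, "far")
        assert interaction_network(st, [k[1] for k in st.residues()]) == []

    def test_hbond_window_bounds(self):
        # donor-acceptor pair below 2.4 A or above 3.6 A is not a hydrogen bond
        def pair_at(d):
            return [
                atom("A", "SER", 1, "OG", 0, 0, 0, element="O"),
                atom("A", "GLN", 5, "OE1", d, 0, 0, element="O"),
            ]

        for d, expected in [(2.3, InteractionKind.OTHER_CONTACT),
                            (2.4, InteractionKind.HYDROGEN_BOND),
                            (3.6, InteractionKind.HYDROGEN_BOND),
                            (3.7, InteractionKind.OTHER_CONTACT)]:
            st = StructureModel(atoms=pair_at(d))
            kinds = [i.kind for i in classify_interactions(environment_contacts(st, 1))]
            assert kinds == [expected], d

    def test_hbond_takes_precedence_over_cation_pi(self):
        # His ring nitrogen vs Arg NH1: donor/acceptor N-N at 3.0 A is both
        # an H-bond candidate and (ring atom vs cation) never arises for ARG->HIS
        # rings, so craft TRP NE1 (ring + donor) vs backbone O acceptor at 3.0
        atoms = [
            atom("A", "TRP", 1, "NE1", 0, 0, 0, element="N"),
            atom("A", "ALA", 5, "O", 3.0, 0, 0, element="O"),
        ]
        st = StructureModel(atoms=atoms)
        kinds = [i.kind for i in classify_interactions(environment_contacts(st, 1))]
        assert kinds == [InteractionKind.HYDROGEN_BOND]

    def test_order_independence(self, tmp_path):
        text, _ = make_toy_structure(
            [
                (InteractionKind.CATION_PI, 3.3),
                (InteractionKind.HYDROGEN_BOND, 3.1),
                (InteractionKind.HYDROGEN_BOND, 2.9),
            ]
        )
        st = structure_from_pdb_text(tmp_path, text, "multi")
        base = interaction_network(st, [k[1] for k in st.residues()])
        shuffled = StructureModel(atoms=list(reversed(st.atoms)))
        again = interaction_network(shuffled, [k[1] for k in shuffled.residues()])
        assert [(i.kind, i.res_a, i.res_b, round(i.distance, 6)) for i in base] == [
            (i.kind, i.res_a, i.res_b, round(i.distance, 6)) for i in again
        ]


class TestInteractionNetwork:
    def test_symmetric_query(self, tmp_path):
        text, _ = make_toy_structure([(InteractionKind.CATION_PI, 3.3)])
        st = structure_from_pdb_text(tmp_path, text, "sym")
        res_ids = [k[1] for k in st.residues()]
        one_way = interaction_network(st, [res_ids[0]])
        other_way = interaction_network(st, [res_ids[1]])
        both = interaction_network(st, res_ids)
        assert one_way == other_way == both

    def test_isolated_residue_empty(self, three_residue_pdb):
        st = read_structure(three_residue_pdb)
        # residue 3 has only N and CA written; anything near is adjacent backbone
        assert interaction_network(st, [3], cutoff=2.0) == []


def make_interaction(kind, seq_a, seq_b, resn_a="ARG", resn_b="PHE", d=3.3):
    return Interaction(
        kind=kind,
        res_a=("A", resn_a, seq_a),
        res_b=("A", resn_b, seq_b),
        atom_a="X",
        atom_b="Y",
        distance=d,
    )


class TestDiffNetworks:
    def test_mutant_bookkeeping(self):
        # wild type: Arg947 cation-pi Phe1078, Arg947 H-bond Gln1081,
        # Ser1077 H-bond Lys1073; Arg->Cys mutant keeps only the last
        wt = [
            make_interaction(InteractionKind.CATION_PI, 947, 1078),
            make_interaction(InteractionKind.HYDROGEN_BOND, 947, 1081, resn_b="GLN", d=3.1),
            make_interaction(InteractionKind.HYDROGEN_BOND, 1077, 1073, "SER", "LYS", d=2.9),
        ]
        mut = [make_interaction(InteractionKind.HYDROGEN_BOND, 1077, 1073, "SER", "LYS", d=2.9)]
        diff = diff_networks(wt, mut)
        assert len(diff.lost) == 2
        assert len(diff.retained) == 1
        assert diff.gained == []

    def test_mutated_residue_name_change_ignored(self):
        wt = [make_interaction(InteractionKind.HYDROGEN_BOND, 1077, 1073, "SER", "LYS")]
        mut = [make_interaction(InteractionKind.HYDROGEN_BOND, 1077, 1073, "PHE", "LYS")]
        diff = diff_networks(wt, mut)
        assert len(diff.retained) == 1 and not diff.lost and not diff.gained

    def test_identical_and_disjoint_networks(self):
        a = [make_interaction(InteractionKind.CATION_PI, 1, 5)]
        b = [make_interaction(InteractionKind.HYDROGEN_BOND, 11, 15, "SER", "GLN")]
        same = diff_networks(a, a)
        assert not same.lost and not same.gained and len(same.retained) == 1
        disjoint = diff_networks(a, b)
        assert not disjoint.retained
        assert len(disjoint.lost) == len(disjoint.gained) == 1

    def test_conservation_counts(self, rng):
        kinds = list(InteractionKind)
        pool = [
            make_interaction(kinds[rng.integers(3)], int(a), int(b))
            for a, b in rng.integers(1, 40, size=(30, 2))
            if a != b
        ]
        wt = pool[:20]
        mut = pool[10:]
        diff = diff_networks(wt, mut)
        wt_keys = {i.pair_key for i in wt}
        mut_keys = {i.pair_key for i in mut}
        assert len(diff.lost) + len(diff.retained) == len(wt_keys)
        assert len(diff.gained) + len(diff.retained) == len(mut_keys)


class TestSuperposition:
    def _random_structure(self, rng, n=25):
        atoms = [
            atom("A", "ALA", i + 1, "CA", *rng.uniform(0, 30, size=3))
            for i in range(n)
        ]
        return StructureModel(atoms=atoms)

    def test_self_superposition_is_zero(self, rng):
        st = self._random_structure(rng)
        assert superpose_rmsd(st, st).rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance(self, rng):
        from scipy.spatial.transform import Rotation

        st = self._random_structure(rng)
        rot = Rotation.random(random_state=3).as_matrix()
        moved = StructureModel(
            atoms=[
                atom("A", a.res_name, a.res_seq, a.atom_name, *(rot @ a.xyz + [5.0, -2.0, 9.0]))
                for a in st.atoms
            ]
        )
        res = superpose_rmsd(moved, st)
        assert res.rmsd == pytest.approx(0.0, abs=1e-6)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_single_atom_displacement_closed_form(self, rng):
        # displacing one of n atoms by d gives RMSD ~= d/sqrt(n); optimal
        # re-centering shrinks it to at most that, converging for large n
        n, d = 400, 2.0
        st = self._random_structure(rng, n=n)
        coords = st.coords.copy()
        coords[0] += [d, 0.0, 0.0]
        moved = StructureModel(
            atoms=[
                atom("A", a.res_name, a.res_seq, a.atom_name, *xyz)
                for a, xyz in zip(st.atoms, coords)
            ]
        )
        res = superpose_rmsd(moved, st)
        assert res.rmsd == pytest.approx(d / np.sqrt(n), rel=0.02)
        assert res.rmsd <= d / np.sqrt(n) + 1e-9

    def test_matches_biopython_svd_superimposer(self, rng):
        from Bio.SVDSuperimposer import SVDSuperimposer

        x = rng.normal(size=(30, 3)) * 10
        y = rng.normal(size=(30, 3)) * 10
        ours = kabsch(x, y)
        sup = SVDSuperimposer()
        sup.set(y, x)  # reference first in biopython's convention
        sup.run()
        assert ours.rmsd == pytest.approx(sup.get_rms(), abs=1e-9)

    def test_too_few_shared_atoms_rejected(self, rng):
        st = self._random_structure(rng, n=2)
        with pytest.raises(ValueError, match="need >= 3"):
            superpose_rmsd(st, st)


class TestToyStructureGenerator:
    def test_unsatisfiable_distance_rejected(self):
        with pytest.raises(ValueError, match="unsatisfiable"):
            make_toy_structure([(InteractionKind.HYDROGEN_BOND, 1.0)])

    def test_pdb_text_is_fixed_width(self):
        text, st = make_toy_structure([(InteractionKind.CATION_PI, 3.3)])
        lines = [l for l in text.splitlines() if l.startswith("ATOM")]
        assert len(lines) == len(st.atoms)
        assert all(len(l) == 80 for l in lines)
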