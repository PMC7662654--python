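"""Tertiary-level interaction analysis of protein structures.

Reads PDB/mmCIF coordinates, enumerates residue environment contacts at
a distance cutoff (default 4.0 Å), classifies hydrogen bonds and
cation–π interactions from heavy-atom geometry, diffs wild-type versus
mutant interaction networks, and superposes structures with the Kabsch
algorithm.

The classifier is purely distance-based: the structures of interest are
hydrogen-free homology models, so donor/acceptor capability is decided
from atom identity and a hydrogen bond is any donor-capable N/O paired
with an acceptor-capable N/O at 2.4–3.6 Å. A cation–π interaction is an
Arg/Lys cationic-group atom within 4.0 Å of an aromatic ring atom of
Phe/Tyr/Trp, reported at the minimum atom–atom distance. No angular
criteria are applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

import gemmi

STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

# Heavy-atom donor/acceptor capability (hydrogen-free models).
SIDECHAIN_DONORS = {
    "ARG": {"NE", "NH1", "NH2"},
    "LYS": {"NZ"},
    "HIS": {"ND1", "NE2"},
    "TRP": {"NE1"},
    "ASN": {"ND2"},
    "GLN": {"NE2"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
}
SIDECHAIN_ACCEPTORS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
    "ASN": {"OD1"},
    "GLN": {"OE1"},
    "HIS": {"ND1", "NE2"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
}

# Cationic side-chain groups and aromatic ring atoms for cation–π calls.
CATION_ATOMS = {
    "ARG": {"NE", "NH1", "NH2", "CZ"},
    "LYS": {"NZ"},
}
RING_ATOMS = {
    "PHE": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TYR": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
}

HBOND_MIN = 2.4
HBOND_MAX = 3.6
CATION_PI_MAX = 4.0
DEFAULT_CUTOFF = 4.0


class InteractionKind(str, Enum):
    HYDROGEN_BOND = "hydrogen_bond"
    CATION_PI = "cation_pi"
    OTHER_CONTACT = "other_contact"


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom with author residue numbering."""

    chain: str
    res_name: str
    res_seq: int
    atom_name: str
    element: str
    xyz: tuple[float, float, float]

    @property
    def residue_key(self) -> tuple[str, int]:
        return (self.chain, self.res_seq)


ResidueKey = tuple[str, int]


@dataclass
class StructureModel:
    """A flat collection of protein heavy atoms (first model, best altloc)."""

    atoms: list[AtomRecord]
    name: str = ""

    def __post_init__(self) -> None:
        self._coords = np.array([a.xyz for a in self.atoms], dtype=float)
        self._by_residue: dict[ResidueKey, list[int]] = {}
        for i, a in enumerate(self.atoms):
            self._by_residue.setdefault(a.residue_key, []).append(i)

    @property
    def coords(self) -> np.ndarray:
        return self._coords

    def residues(self) -> list[ResidueKey]:
        return sorted(self._by_residue)

    def residue_atoms(self, key: ResidueKey) -> list[AtomRecord]:
        if key not in self._by_residue:
            raise KeyError(
                f"residue (chain {key[0]!r}, res_seq {key[1]}) absent from structure {self.name!r}"
            )
        return [self.atoms[i] for i in self._by_residue[key]]

    def residue_name(self, key: ResidueKey) -> str:
        return self.residue_atoms(key)[0].res_name

    def atom_indices(self, key: ResidueKey) -> list[int]:
        if key not in self._by_residue:
            raise KeyError(
                f"residue (chain {key[0]!r}, res_seq {key[1]}) absent from structure {self.name!r}"
            )
        return list(self._by_residue[key])


def _resolve_residue(structure: StructureModel, residue: Union[int, ResidueKey]) -> ResidueKey:
    if isinstance(residue, tuple):
        return residue
    matches = [k for k in structure.residues() if k[1] == residue]
    if not matches:
        raise KeyError(f"residue with res_seq {residue} absent from structure {structure.name!r}")
    if len(matches) > 1:
        raise KeyError(
            f"res_seq {residue} is ambiguous across chains {sorted(c for c, _ in matches)}; "
            "pass (chain, res_seq)"
        )
    return matches[0]


def read_structure(path, fmt: Optional[str] = None, include_het: bool = False) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Only the first model is used. Waters and (by default) heteroatoms
    are excluded; alternate locations are resolved to the highest
    occupancy conformer. Hydrogens are dropped — all downstream geometry
    is heavy-atom.
    """
    path = Path(path)
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    st.remove_waters()
    if not include_het:
        st.remove_ligands_and_waters()
    if len(st) == 0:
        raise ValueError(f"{path}: structure contains no models")
    model = st[0]

    atoms: list[AtomRecord] = []
    for chain in model:
        for res in chain:
            if res.name not in STANDARD_AA and not include_het:
                continue
            # Resolve altlocs: keep highest occupancy per atom name.
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                is_h = atom.element.is_hydrogen
                if is_h() if callable(is_h) else is_h:
                    continue
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            for name in best:
                atom = best[name]
                atoms.append(
                    AtomRecord(
                        chain=chain.name,
                        res_name=res.name,
                        res_seq=res.seqid.num,
                        atom_name=name,
                        element=atom.element.name.upper(),
                        xyz=(atom.pos.x, atom.pos.y, atom.pos.z),
                    )
                )
    if not atoms:
        raise ValueError(f"{path}: no protein atoms found")
    atoms.sort(key=lambda a: (a.chain, a.res_seq, a.atom_name))
    return StructureModel(atoms=atoms, name=path.stem)


@dataclass(frozen=True)
class Contact:
    """An atom pair within the environment cutoff."""

    atom_a: AtomRecord
    atom_b: AtomRecord
    distance: float


def _is_adjacent_backbone_pair(a: AtomRecord, b: AtomRecord) -> bool:
    return (
        a.chain == b.chain
        and abs(a.res_seq - b.res_seq) == 1
        and a.atom_name in BACKBONE_ATOMS
        and b.atom_name in BACKBONE_ATOMS
    )


def environment_contacts(
    structure: StructureModel,
    target_residue: Union[int, ResidueKey],
    cutoff: float = DEFAULT_CUTOFF,
) -> list[Contact]:
    """All atom pairs between a target residue and its environment.

    Returns every (target atom, other atom) pair at Euclidean distance
    <= ``cutoff``, excluding intra-residue pairs and backbone–backbone
    pairs of sequence-adjacent residues (those reflect covalent
    connectivity, not tertiary interactions).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    key = _resolve_residue(structure, target_residue)
    target_idx = structure.atom_indices(key)
    tree = cKDTree(structure.coords)
    contacts: list[Contact] = []
    for i in target_idx:
        a = structure.atoms[i]
        for j in sorted(tree.query_ball_point(structure.coords[i], cutoff)):
            b = structure.atoms[j]
            if b.residue_key == key:
                continue
            if _is_adjacent_backbone_pair(a, b):
                continue
            d = float(np.linalg.norm(structure.coords[i] - structure.coords[j]))
            if d <= cutoff:
                contacts.append(Contact(atom_a=a, atom_b=b, distance=d))
    contacts.sort(
        key=lambda c: (c.atom_b.chain, c.atom_b.res_seq, c.atom_a.atom_name, c.atom_b.atom_name)
    )
    return contacts


def _is_donor(atom: AtomRecord) -> bool:
    if atom.atom_name == "N" and atom.res_name != "PRO":
        return True
    return atom.atom_name in SIDECHAIN_DONORS.get(atom.res_name, ())


def _is_acceptor(atom: AtomRecord) -> bool:
    if atom.atom_name in ("O", "OXT"):
        return True
    return atom.atom_name in SIDECHAIN_ACCEPTORS.get(atom.res_name, ())


def _is_hbond(a: AtomRecord, b: AtomRecord, d: float) -> bool:
    if not (HBOND_MIN <= d <= HBOND_MAX):
        return False
    if a.element not in ("N", "O") or b.element not in ("N", "O"):
        return False
    return (_is_donor(a) and _is_acceptor(b)) or (_is_donor(b) and _is_acceptor(a))


def _is_cation_pi(a: AtomRecord, b: AtomRecord, d: float) -> bool:
    if d > CATION_PI_MAX:
        return False
    for cat, ring in ((a, b), (b, a)):
        if (
            cat.atom_name in CATION_ATOMS.get(cat.res_name, ())
            and ring.atom_name in RING_ATOMS.get(ring.res_name, ())
        ):
            return True
    return False


@dataclass(frozen=True)
class Interaction:
    """A classified residue–residue non-covalent interaction.

    ``distance`` is the minimum atom–atom distance among the contacts
    supporting the call; ``atom_a``/``atom_b`` are the atoms realizing
    it. Residues are ordered so that ``res_a <= res_b`` by
    (chain, res_seq).
    """

    kind: InteractionKind
    res_a: tuple[str, str, int]  # (chain, res_name, res_seq)
    res_b: tuple[str, str, int]
    atom_a: str
    atom_b: str
    distance: float

    @property
    def pair_key(self) -> tuple:
        """Identity key for diffs: kind + residue positions (names ignored,
        so a mutated residue matches its wild-type counterpart)."""
        a = (self.res_a[0], self.res_a[2])
        b = (self.res_b[0], self.res_b[2])
        return (self.kind.value, *sorted((a, b)))


def _classify_contact(c: Contact) -> InteractionKind:
    # Hydrogen bond takes precedence when a contact satisfies both tests
    # (e.g. His ring nitrogens are both aromatic and donor/acceptor).
    if _is_hbond(c.atom_a, c.atom_b, c.distance):
        return InteractionKind.HYDROGEN_BOND
    if _is_cation_pi(c.atom_a, c.atom_b, c.distance):
        return InteractionKind.CATION_PI
    return InteractionKind.OTHER_CONTACT


def classify_interactions(contacts: Iterable[Contact]) -> list[Interaction]:
    """Classify contacts and aggregate them per residue pair and kind.

    Each contact is typed (hydrogen bond, cation–π, other) from the
    tables above; contacts of the same kind between the same residue
    pair are merged, keeping the minimum distance and the atoms that
    realize it. Output order is deterministic and independent of input
    order.
    """
    best: dict[tuple, Contact] = {}
    for c in contacts:
        kind = _classify_contact(c)
        a_key = (c.atom_a.chain, c.atom_a.res_seq)
        b_key = (c.atom_b.chain, c.atom_b.res_seq)
        if a_key <= b_key:
            first, second = c.atom_a, c.atom_b
        else:
            first, second = c.atom_b, c.atom_a
            c = Contact(atom_a=first, atom_b=second, distance=c.distance)
        key = (kind, first.residue_key, second.residue_key)
        prev = best.get(key)
        if (
            prev is None
            or c.distance < prev.distance - 1e-12
            or (
                abs(c.distance - prev.distance) <= 1e-12
                and (c.atom_a.atom_name, c.atom_b.atom_name)
                < (prev.atom_a.atom_name, prev.atom_b.atom_name)
            )
        ):
            best[key] = c
    out = [
        Interaction(
            kind=kind,
            res_a=(c.atom_a.chain, c.atom_a.res_name, c.atom_a.res_seq),
            res_b=(c.atom_b.chain, c.atom_b.res_name, c.atom_b.res_seq),
            atom_a=c.atom_a.atom_name,
            atom_b=c.atom_b.atom_name,
            distance=c.distance,
        )
        for (kind, _, _), c in best.items()
    ]
    out.sort(key=lambda x: (x.res_a, x.res_b, x.kind.value))
    return out


def ring_centroid_distance(
    structure: StructureModel, cation_res: Union[int, ResidueKey], ring_res: Union[int, ResidueKey]
) -> float:
    """Diagnostic: distance from the nearest cationic atom to the aromatic
    ring centroid (complements the minimum atom–atom distance report)."""
    cat_key = _resolve_residue(structure, cation_res)
    ring_key = _resolve_residue(structure, ring_res)
    cat_name = structure.residue_name(cat_key)
    ring_name = structure.residue_name(ring_key)
    cat_atoms = [
        a for a in structure.residue_atoms(cat_key)
        if a.atom_name in CATION_ATOMS.get(cat_name, ())
    ]
    ring_atoms = [
        a for a in structure.residue_atoms(ring_key)
        if a.atom_name in RING_ATOMS.get(ring_name, ())
    ]
    if not cat_atoms or not ring_atoms:
        raise ValueError(
            f"residues {cat_key}/{ring_key} do not form a cation/aromatic pair"
        )
    centroid = np.mean([a.xyz for a in ring_atoms], axis=0)
    return float(min(np.linalg.norm(np.asarray(a.xyz) - centroid) for a in cat_atoms))


def interaction_network(
    structure: StructureModel,
    residues: Sequence[Union[int, ResidueKey]],
    cutoff: float = DEFAULT_CUTOFF,
) -> list[Interaction]:
    """Union of classified interactions over the listed residues.

    De-duplicated on (kind, unordered residue pair); symmetric in the
    query (listing either or both partners yields the same network).
    Plain ``other_contact`` entries are retained so callers can apply
    their own filters.
    """
    merged: dict[tuple, Interaction] = {}
    for residue in residues:
        for inter in classify_interactions(
            environment_contacts(structure, residue, cutoff=cutoff)
        ):
            key = (inter.kind, inter.res_a, inter.res_b)
            prev = merged.get(key)
            if prev is None or inter.distance < prev.distance:
                merged[key] = inter
    out = sorted(merged.values(), key=lambda x: (x.res_a, x.res_b, x.kind.value))
    return out


@dataclass
class InteractionDiff:
    """Wild-type vs mutant interaction bookkeeping."""

    lost: list[Interaction]
    gained: list[Interaction]
    retained: list[Interaction]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for status, group in (("lost", self.lost), ("gained", self.gained), ("retained", self.retained)):
            for i in group:
                rows.append({"status": status, **interaction_row(i)})
        return pd.DataFrame(rows, columns=["status"] + list(INTERACTION_TSV_COLUMNS))


def diff_networks(wt: Sequence[Interaction], mut: Sequence[Interaction]) -> InteractionDiff:
    """Diff two interaction networks with identical residue numbering.

    Interactions are matched on (kind, chain+residue number of both
    partners); residue *names* are deliberately ignored so that a
    mutated residue (e.g. Arg947→Cys947) compares as the same node.
    ``lost`` are wild-type-only, ``gained`` mutant-only, ``retained``
    common (wild-type record kept).
    """
    wt_by_key = {i.pair_key: i for i in wt}
    mut_by_key = {i.pair_key: i for i in mut}
    lost = [i for k, i in sorted(wt_by_key.items()) if k not in mut_by_key]
    gained = [i for k, i in sorted(mut_by_key.items()) if k not in wt_by_key]
    retained = [i for k, i in sorted(wt_by_key.items()) if k in mut_by_key]
    return InteractionDiff(lost=lost, gained=gained, retained=retained)


INTERACTION_TSV_COLUMNS = (
    "kind", "chain_a", "resn_a", "resi_a", "atom_a",
    "chain_b", "resn_b", "resi_b", "atom_b", "distance_A",
)


def interaction_row(i: Interaction) -> dict:
    return {
        "kind": i.kind.value,
        "chain_a": i.res_a[0], "resn_a": i.res_a[1], "resi_a": i.res_a[2],
        "atom_a": i.atom_a,
        "chain_b": i.res_b[0], "resn_b": i.res_b[1], "resi_b": i.res_b[2],
        "atom_b": i.atom_b,
        "distance_A": round(i.distance, 3),
    }


def interactions_to_frame(interactions: Sequence[Interaction]) -> pd.DataFrame:
    return pd.DataFrame(
        [interaction_row(i) for i in interactions], columns=list(INTERACTION_TSV_COLUMNS)
    )


@dataclass(frozen=True)
class Superposition:
    """Optimal rigid-body superposition (mobile onto reference)."""

    rotation: np.ndarray  # (3, 3), proper: det = +1
    translation: np.ndarray  # (3,)
    rmsd: float
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> Superposition:
    """Least-squares rigid superposition of paired coordinate sets.

    Solves for the proper rotation R (det = +1) and translation t
    minimizing ||R x + t - y||^2 over the paired points, via SVD of the
    cross-covariance matrix of the centered sets.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("paired (n, 3) coordinate arrays required")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError(f"at least 3 paired atoms required, got {n}")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    h = (mobile - mc).T @ (reference - rc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = rc - rot @ mc
    moved = mobile @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return Superposition(rotation=rot, translation=trans, rmsd=rmsd, n_atoms=n)


def superpose_rmsd(
    mobile: StructureModel,
    reference: StructureModel,
    atom_name: str = "CA",
) -> Superposition:
    """Kabsch superposition over shared selected atoms (default Cα).

    Atoms are paired by (chain, res_seq, atom_name) present in both
    structures; at least 3 shared atoms are required.
    """
    ref_atoms = {
        (a.chain, a.res_seq): a.xyz for a in reference.atoms if a.atom_name == atom_name
    }
    pairs = [
        (a.xyz, ref_atoms[(a.chain, a.res_seq)])
        for a in mobile.atoms
        if a.atom_name == atom_name and (a.chain, a.res_seq) in ref_atoms
    ]
    if len(pairs) < 3:
        raise ValueError(
            f"only {len(pairs)} shared {atom_name!r} atoms between "
            f"{mobile.name!r} and {reference.name!r}; need >= 3"
        )
    mob = np.array([p[0] for p in pairs])
    ref = np.array([p[1] for p in pairs])
    return kabsch(mob, ref)


_ELEMENT_FROM_NAME = {"N": "N", "O": "O", "C": "C", "S": "S"}


def element_from_atom_name(atom_name: str) -> str:
    """Leading-element convention for standard protein atom names."""
    return _ELEMENT_FROM_NAME.get(atom_name[0], atom_name[0])


def write_pdb(structure: StructureModel, path) -> None:
    """Write fixed-width PDB ATOM records (bit-exact layout)."""
    Path(path).write_text(pdb_text(structure))


def pdb_text(structure: StructureModel) -> str:
    lines = []
    for i, a in enumerate(structure.atoms, start=1):
        name = a.atom_name if len(a.atom_name) == 4 else f" {a.atom_name:<3s}"
        lines.append(
            f"ATOM  {i:5d} {name}{'':1s}{a.res_name:>3s} {a.chain:1s}"
            f"{a.res_seq:4d}    {a.xyz[0]:8.3f}{a.xyz[1]:8.3f}{a.xyz[2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}  "
        )
    lines.append("END")
    return "\n".join(lines) + "\n"
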