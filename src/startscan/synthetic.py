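"""Synthetic alignments, mutation catalogs and toy structures.

Every generator carries known ground truth so each pipeline stage can be
tested end to end without external downloads. The defaults emulate the
study conditions of the DLC START analysis: a 123-sequence vertebrate
ortholog alignment over a 206-residue domain with ~20% identically
conserved columns (at most 2 exception rows each), and somatic-mutation
catalogs whose positional distribution is uniform (null) or enriched on
conserved residues (alternative).

The substitution model for non-conserved columns is i.i.d. uniform over
the 20 residues — deliberately simpler than real phylogeny, since only
the counting behaviour of the classifier is under test; evolutionary
covariance between rows is an explicit non-goal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .catalog import AA1, DomainWindow, MutationCatalog, MutationClass, MutationRecord
from .conservation import (
    DEFAULT_SIMILARITY_GROUPS,
    Alignment,
    ColumnClass,
)
from .enrichment import EnrichmentInput, EnrichmentResult, chi_square_test
from .structure import (
    AtomRecord,
    InteractionKind,
    StructureModel,
    element_from_atom_name,
    pdb_text,
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the simulated study, with known ground truth.

    Defaults mirror the emulated study: 123 ortholog sequences, a
    206-residue domain, 20% planted identically conserved columns with
    at most 2 exception rows each.
    """

    n_seqs: int = 123
    domain_length: int = 206
    conserved_fraction: float = 0.20
    max_exceptions: int = 2
    n_mutations: int = 47
    enrichment_multiplier: float = 1.0
    seed: int = 0
    physicochemical_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.conserved_fraction < 1:
            raise ValueError("conserved_fraction must lie in (0, 1)")
        if self.physicochemical_fraction < 0 or (
            self.conserved_fraction + self.physicochemical_fraction >= 1
        ):
            raise ValueError("conserved + physicochemical fractions must stay below 1")
        if self.enrichment_multiplier < 0:
            raise ValueError("enrichment_multiplier must be >= 0")
        if self.n_seqs < 1 or self.domain_length < 1:
            raise ValueError("n_seqs and domain_length must be positive")
        if self.max_exceptions < 0:
            raise ValueError("max_exceptions must be >= 0")

    def n_conserved(self) -> int:
        return int(self.conserved_fraction * self.domain_length)

    def n_physicochemical(self) -> int:
        return int(self.physicochemical_fraction * self.domain_length)


def simulate_alignment(
    spec: SyntheticSpec,
    groups: Sequence[str] = DEFAULT_SIMILARITY_GROUPS,
) -> tuple[Alignment, list[ColumnClass]]:
    """Simulate a gap-free ortholog alignment with planted column classes.

    Identically conserved columns carry one consensus residue in at
    least ``n_seqs - max_exceptions`` rows, with exception residues drawn
    from outside the consensus residue's similarity group (so the planted
    class is unambiguous). Physicochemically conserved columns draw rows
    uniformly from one multi-residue similarity group. All other columns
    are i.i.d. uniform over the 20 residues. Row 0 is the reference and
    always carries the planted consensus.

    Returns the alignment and the planted per-column classes.
    """
    rng = np.random.default_rng(spec.seed)
    group_of = {aa: g for g in groups for aa in g}
    n, width = spec.n_seqs, spec.domain_length

    n_cons = spec.n_conserved()
    n_phys = spec.n_physicochemical()
    special = rng.choice(width, size=n_cons + n_phys, replace=False)
    conserved_cols = set(int(c) for c in special[:n_cons])
    physico_cols = set(int(c) for c in special[n_cons:])

    columns: list[str] = []
    classes: list[ColumnClass] = []
    multi_groups = [g for g in groups if len(g) > 1]
    for j in range(width):
        if j in conserved_cols:
            consensus = AA1[rng.integers(len(AA1))]
            col = [consensus] * n
            n_exc = int(rng.integers(0, spec.max_exceptions + 1))
            if n_exc and n > 1:
                exc_rows = rng.choice(np.arange(1, n), size=min(n_exc, n - 1), replace=False)
                forbidden = set(group_of.get(consensus, consensus))
                alternatives = [aa for aa in AA1 if aa not in forbidden]
                for r in exc_rows:
                    col[int(r)] = alternatives[int(rng.integers(len(alternatives)))]
            classes.append(ColumnClass.IDENTICAL)
        elif j in physico_cols:
            g = multi_groups[int(rng.integers(len(multi_groups)))]
            draws = rng.integers(len(g), size=n)
            col = [g[int(k)] for k in draws]
            # keep the column below the identical threshold: force at least
            # two distinct residues of the group to appear
            if len(set(col)) == 1:
                col[1 % n] = g[(g.index(col[0]) + 1) % len(g)]
            classes.append(ColumnClass.PHYSICOCHEMICAL)
        else:
            draws = rng.integers(len(AA1), size=n)
            col = [AA1[int(k)] for k in draws]
            classes.append(ColumnClass.NONCONSERVED)
        columns.append("".join(col))

    rows = ["".join(columns[j][i] for j in range(width)) for i in range(n)]
    ids = ["reference_human"] + [f"ortholog_{i:03d}" for i in range(1, n)]
    aln = Alignment(ids=ids, rows=rows, reference_id="reference_human")
    return aln, classes


def _position_weights(
    truth: Sequence[ColumnClass], multiplier: float
) -> np.ndarray:
    w = np.array(
        [multiplier if c is ColumnClass.IDENTICAL else 1.0 for c in truth], dtype=float
    )
    total = w.sum()
    if total <= 0:
        raise ValueError("all position weights are zero; cannot draw mutations")
    return w / total


def simulate_catalog(
    spec: SyntheticSpec,
    window: DomainWindow,
    truth: Sequence[ColumnClass],
    reference_seq: Optional[str] = None,
) -> MutationCatalog:
    """Simulate a missense mutation catalog over a domain window.

    Event positions are drawn independently with probability
    proportional to 1 on non-conserved residues and to
    ``enrichment_multiplier`` on identically conserved residues
    (multiplier 1 is the uniform null). Reference residues follow
    ``reference_seq`` when given (e.g. the simulated alignment's
    reference row), otherwise they are drawn at random; alternate
    residues are random non-reference residues. Patient ids are unique,
    so the catalog is de-duplication-stable.
    """
    if len(truth) != window.length():
        raise ValueError(
            f"ground-truth classes cover {len(truth)} columns but window "
            f"{window.name} spans {window.length()} residues"
        )
    if reference_seq is not None and len(reference_seq) != window.length():
        raise ValueError("reference_seq length must equal the window length")
    rng = np.random.default_rng(spec.seed)
    weights = _position_weights(truth, spec.enrichment_multiplier)
    cols = rng.choice(len(truth), size=spec.n_mutations, p=weights)
    records = []
    for i, col in enumerate(cols):
        pos = window.start + int(col)
        if reference_seq is not None:
            ref = reference_seq[int(col)]
        else:
            ref = AA1[int(rng.integers(len(AA1)))]
        alternatives = [aa for aa in AA1 if aa != ref]
        alt = alternatives[int(rng.integers(len(alternatives)))]
        records.append(
            MutationRecord(
                sample_id=f"SM{i:05d}",
                patient_id=f"PT{i:05d}",
                gene=window.name,
                protein_change=f"p.{ref}{pos}{alt}",
                ref_aa=ref,
                position=pos,
                alt_aa=alt,
                mut_class=MutationClass.MISSENSE,
            )
        )
    return MutationCatalog(
        records=records,
        provenance=f"synthetic catalog (seed={spec.seed}, multiplier={spec.enrichment_multiplier})",
    )


def simulated_enrichment_replicates(
    spec: SyntheticSpec,
    window: DomainWindow,
    truth: Sequence[ColumnClass],
    n_replicates: int,
    seed: int,
) -> list[EnrichmentResult]:
    """Run the enrichment test on many simulated catalogs.

    Each replicate draws a fresh catalog under ``spec`` (with its own
    child seed spawned from ``seed``), counts events on identically
    conserved residues against the planted truth, and applies the
    two-cell chi-square test.
    """
    conserved_cols = {j for j, c in enumerate(truth) if c is ColumnClass.IDENTICAL}
    n_conserved = len(conserved_cols)
    child_seeds = np.random.SeedSequence(seed).generate_state(n_replicates)
    results = []
    for child in child_seeds:
        rep_spec = SyntheticSpec(
            n_seqs=spec.n_seqs,
            domain_length=spec.domain_length,
            conserved_fraction=spec.conserved_fraction,
            max_exceptions=spec.max_exceptions,
            n_mutations=spec.n_mutations,
            enrichment_multiplier=spec.enrichment_multiplier,
            seed=int(child % (2**31)),
            physicochemical_fraction=spec.physicochemical_fraction,
        )
        catalog = simulate_catalog(rep_spec, window, truth)
        n_in = sum(1 for r in catalog if (r.position - window.start) in conserved_cols)
        results.append(
            chi_square_test(
                EnrichmentInput(
                    n_mutations=spec.n_mutations,
                    n_in_conserved=n_in,
                    n_conserved=n_conserved,
                    domain_length=spec.domain_length,
                )
            )
        )
    return results


def rejection_rate(results: Sequence[EnrichmentResult], alpha: float = 0.05) -> float:
    return sum(1 for r in results if r.p_value < alpha) / len(results)


# ---------------------------------------------------------------------------
# Toy structures

_MIN_REQUEST_DISTANCE = 2.0
_PAIR_SPACING = 20.0  # Å between successive planted pairs; >> 4 Å cutoff

# (residue name, interacting side-chain atom) templates per request kind.
_PAIR_TEMPLATES = {
    InteractionKind.CATION_PI: (("ARG", "NH1"), ("PHE", "CG")),
    InteractionKind.HYDROGEN_BOND: (("SER", "OG"), ("GLN", "OE1")),
    InteractionKind.OTHER_CONTACT: (("ALA", "CB"), ("ALA", "CB")),
}


def _residue_atoms(
    res_name: str,
    res_seq: int,
    side_atom: str,
    side_xyz: np.ndarray,
    direction: float,
    y_offset: float,
) -> list[AtomRecord]:
    """Backbone scaffold ~2.5 Å behind the interacting side-chain atom.

    ``direction`` is +1/-1 along x, pointing away from the partner, so
    every scaffold atom sits at least ``d + 2.5`` Å from all partner
    atoms and contributes no contact of its own at a 4 Å cutoff.
    """
    x0 = float(side_xyz[0])
    offsets = {
        "CA": (2.5 * direction, 0.0),
        "N": (3.5 * direction, 1.0),
        "C": (3.5 * direction, -1.0),
        "O": (4.7 * direction, -1.0),
    }
    atoms = [
        AtomRecord(
            chain="A",
            res_name=res_name,
            res_seq=res_seq,
            atom_name=name,
            element=element_from_atom_name(name),
            xyz=(x0 + dx, y_offset + dy, 0.0),
        )
        for name, (dx, dy) in offsets.items()
    ]
    atoms.append(
        AtomRecord(
            chain="A",
            res_name=res_name,
            res_seq=res_seq,
            atom_name=side_atom,
            element=element_from_atom_name(side_atom),
            xyz=(float(side_xyz[0]), float(side_xyz[1]), float(side_xyz[2])),
        )
    )
    return atoms


def make_toy_structure(
    requests: Sequence[tuple[InteractionKind | str, float]],
) -> tuple[str, StructureModel]:
    """Build a minimal PDB realizing exactly the requested interactions.

    Each request ``(kind, distance)`` is realized by one residue pair
    whose interacting side-chain atoms sit exactly ``distance`` Å apart;
    successive pairs are separated by 20 Å so no unrequested interaction
    exists within the 4 Å environment cutoff. Distances beyond 4 Å are
    permitted as deliberate negative controls. Requests below 2 Å are
    rejected as geometrically unsatisfiable for heavy atoms.

    Returns the fixed-width PDB text and the in-memory structure.
    """
    if not requests:
        raise ValueError("at least one interaction request is required")
    atoms: list[AtomRecord] = []
    for i, (kind_in, distance) in enumerate(requests):
        kind = InteractionKind(kind_in)
        if distance < _MIN_REQUEST_DISTANCE:
            raise ValueError(
                f"requested distance {distance} Å is geometrically unsatisfiable "
                f"(heavy atoms closer than {_MIN_REQUEST_DISTANCE} Å would clash)"
            )
        (resn_a, atom_a), (resn_b, atom_b) = _PAIR_TEMPLATES[kind]
        y = _PAIR_SPACING * i
        a_xyz = np.array([0.0, y, 0.0])
        b_xyz = np.array([float(distance), y, 0.0])
        atoms.extend(
            _residue_atoms(resn_a, 10 * i + 1, atom_a, a_xyz, direction=-1.0, y_offset=y)
        )
        atoms.extend(
            _residue_atoms(resn_b, 10 * i + 5, atom_b, b_xyz, direction=+1.0, y_offset=y)
        )
    structure = StructureModel(atoms=atoms, name="toy")
    return pdb_text(structure), structure
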