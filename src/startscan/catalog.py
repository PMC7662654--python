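"""Somatic mutation catalogs restricted to a protein-domain window.

This module parses COSMIC-style mutation tables at the protein level
(HGVS ``p.`` notation), filters them to a domain window, removes
duplicate events from the same patient, tallies per-residue counts and
tests the positional distribution for uniformity with a one-sample
Kolmogorov–Smirnov test.

Coordinates are 1-based and inclusive throughout, in full-length
protein space: a domain spanning residues 880–1083 has length 204 and
both endpoints belong to it. The domain is never re-indexed internally.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

AA1 = "ACDEFGHIKLMNPQRSTVWY"

AA3_TO_1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
    "Ter": "*", "Sec": "U",
}


class MutationClass(str, Enum):
    """Protein-level consequence class of a somatic mutation."""

    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    SYNONYMOUS = "synonymous"
    INTRONIC = "intronic"
    OTHER = "other"


@dataclass(frozen=True)
class DomainWindow:
    """A protein-domain window in 1-based, both-ends-inclusive coordinates."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"window start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"window end {self.end} precedes start {self.start}"
            )

    def length(self) -> int:
        return self.end - self.start + 1

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end

    def positions(self) -> range:
        return range(self.start, self.end + 1)


# Canonical windows used throughout the DLC analyses (HHpred-delimited
# START domains of the dominant human isoforms).
DLC1_WINDOW = DomainWindow("DLC-1", 880, 1083)
DLC2_WINDOW = DomainWindow("DLC-2", 903, 1108)
DLC3_WINDOW = DomainWindow("DLC-3", 893, 1098)


@dataclass(frozen=True)
class MutationRecord:
    """One somatic protein-level mutation event with sample provenance."""

    sample_id: str
    patient_id: str
    gene: str
    protein_change: str
    ref_aa: str
    position: int
    alt_aa: str
    mut_class: MutationClass
    pathogenicity: Optional[Mapping[str, float]] = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.ref_aa not in AA1:
            raise ValueError(f"ref_aa {self.ref_aa!r} is not a standard amino acid")
        if self.mut_class is MutationClass.MISSENSE:
            if self.alt_aa not in AA1:
                raise ValueError(
                    f"missense alt_aa {self.alt_aa!r} is not a standard amino acid"
                )
            if self.alt_aa == self.ref_aa:
                raise ValueError(
                    f"missense record {self.protein_change!r} has alt == ref"
                )


@dataclass
class MutationCatalog:
    """An ordered collection of mutation records with free-text provenance."""

    records: list[MutationRecord] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def positions(self) -> list[int]:
        return [r.position for r in self.records]


_HGVS_RE = re.compile(r"^(?:p\.)?\(?(?P<ref>[A-Za-z*]{1,3})(?P<pos>\d+)(?P<rest>.*?)\)?$")


def _aa_token_to_one(token: str, hgvs: str) -> str:
    """Translate a one- or three-letter residue token to one-letter code."""
    if len(token) == 1:
        code = token.upper()
        if code in AA1 or code == "*":
            return code
    else:
        code = AA3_TO_1.get(token.capitalize())
        if code is not None:
            return code
    raise ValueError(
        f"unparseable protein change {hgvs!r}: unknown residue token {token!r}"
    )


def parse_protein_change(hgvs: str) -> tuple[str, int, str, MutationClass]:
    """Parse an HGVS ``p.`` protein-change string.

    Both the one-letter (``p.R947C``) and three-letter (``p.Arg947Cys``)
    dialects are accepted. ``*``/``Ter`` denotes a stop gain (nonsense),
    a ``fs`` suffix a frameshift, and ``=`` a synonymous change.

    Returns
    -------
    (ref_aa, position, alt_aa, mut_class)
        One-letter reference residue, 1-based position, one-letter
        alternate residue (or ``*``/``fs``/``=`` symbol), and the
        inferred :class:`MutationClass`.
    """
    if not hgvs or not hgvs.strip():
        raise ValueError("empty protein change string")
    text = hgvs.strip()
    m = _HGVS_RE.match(text)
    if not m:
        raise ValueError(f"unparseable protein change {hgvs!r}")
    ref = _aa_token_to_one(m.group("ref"), hgvs)
    if ref == "*":
        raise ValueError(
            f"unparseable protein change {hgvs!r}: reference residue is a stop"
        )
    position = int(m.group("pos"))
    rest = m.group("rest")

    if "fs" in rest:
        return ref, position, "fs", MutationClass.FRAMESHIFT
    if rest in ("", "?"):
        raise ValueError(
            f"unparseable protein change {hgvs!r}: missing alternate residue"
        )
    if rest == "=":
        return ref, position, ref, MutationClass.SYNONYMOUS
    if rest in ("*", "Ter", "ter", "X"):
        return ref, position, "*", MutationClass.NONSENSE
    if re.search(r"del|dup|ins|ext", rest):
        return ref, position, rest, MutationClass.OTHER
    alt = _aa_token_to_one(rest, hgvs)
    if alt == "*":
        return ref, position, "*", MutationClass.NONSENSE
    if alt == ref:
        return ref, position, alt, MutationClass.SYNONYMOUS
    return ref, position, alt, MutationClass.MISSENSE


# COSMIC textual consequence descriptions -> MutationClass.
_DESCRIPTION_PATTERNS = [
    ("missense", MutationClass.MISSENSE),
    ("nonsense", MutationClass.NONSENSE),
    ("frameshift", MutationClass.FRAMESHIFT),
    ("silent", MutationClass.SYNONYMOUS),
    ("synonymous", MutationClass.SYNONYMOUS),
    ("intron", MutationClass.INTRONIC),
]


def classify_description(description: str) -> Optional[MutationClass]:
    """Map a COSMIC "Mutation Description" string to a MutationClass."""
    low = description.lower()
    for token, cls in _DESCRIPTION_PATTERNS:
        if token in low:
            return cls
    return None


#: Default column names of a COSMIC mutation export.
COSMIC_COLUMNS = {
    "sample_id": "Sample name",
    "patient_id": "ID_tumour",
    "gene": "Gene name",
    "protein_change": "Mutation AA",
    "mut_class": "Mutation Description",
}

#: Known pathogenicity-score column names, passed through as annotations.
PATHOGENICITY_COLUMNS = ("CADD", "REVEL")

INTERNAL_COLUMNS = ["sample_id", "patient_id", "gene", "protein_change", "mut_class"]


def _record_from_row(
    sample_id: str,
    patient_id: str,
    gene: str,
    protein_change: str,
    description: Optional[str],
    pathogenicity: Optional[Mapping[str, float]],
) -> MutationRecord:
    ref, pos, alt, parsed_class = parse_protein_change(protein_change)
    mut_class = parsed_class
    if description:
        described = classify_description(str(description))
        if described is not None:
            mut_class = described
    return MutationRecord(
        sample_id=str(sample_id),
        patient_id=str(patient_id),
        gene=str(gene),
        protein_change=str(protein_change),
        ref_aa=ref,
        position=pos,
        alt_aa=alt,
        mut_class=mut_class,
        pathogenicity=pathogenicity,
    )


def read_catalog(
    path,
    fmt: str = "internal",
    columns: Optional[Mapping[str, str]] = None,
    provenance: Optional[str] = None,
) -> MutationCatalog:
    """Read a mutation catalog from a TSV file.

    Parameters
    ----------
    path
        TSV file path.
    fmt
        ``"internal"`` for the 5-column dialect
        (sample_id, patient_id, gene, protein_change, mut_class) or
        ``"cosmic"`` for a COSMIC-export-style table.
    columns
        Optional column-name overrides for the COSMIC dialect
        (keys as in :data:`COSMIC_COLUMNS`).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if fmt == "cosmic":
        colmap = dict(COSMIC_COLUMNS)
        if columns:
            colmap.update(columns)
    elif fmt == "internal":
        colmap = {k: k for k in COSMIC_COLUMNS}
    else:
        raise ValueError(f"unknown catalog format {fmt!r}")

    missing = [c for c in (colmap["sample_id"], colmap["protein_change"]) if c not in df.columns]
    if missing:
        raise ValueError(f"catalog {path} lacks required column(s): {missing}")

    patho_cols = [c for c in PATHOGENICITY_COLUMNS if c in df.columns]
    records = []
    for _, row in df.iterrows():
        patho = None
        if patho_cols:
            patho = {
                c: float(row[c]) for c in patho_cols
                if pd.notna(row[c]) and str(row[c]) != ""
            }
        patient = row.get(colmap["patient_id"])
        if pd.isna(patient) or str(patient) == "":
            patient = ""
        records.append(
            _record_from_row(
                sample_id=row[colmap["sample_id"]],
                patient_id=str(patient),
                gene=str(row.get(colmap["gene"], "")),
                protein_change=row[colmap["protein_change"]],
                description=row.get(colmap["mut_class"]),
                pathogenicity=patho,
            )
        )
    return MutationCatalog(records=records, provenance=provenance or str(path))


def catalog_to_frame(catalog: MutationCatalog) -> pd.DataFrame:
    """Tabulate a catalog in the internal 5-column dialect (plus position)."""
    return pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "patient_id": r.patient_id,
                "gene": r.gene,
                "protein_change": r.protein_change,
                "mut_class": r.mut_class.value,
                "position": r.position,
            }
            for r in catalog
        ],
        columns=INTERNAL_COLUMNS + ["position"],
    )


def write_catalog(catalog: MutationCatalog, path) -> None:
    """Write a catalog as internal-dialect TSV."""
    catalog_to_frame(catalog).to_csv(path, sep="\t", index=False)


DEFAULT_CLASSES = frozenset({MutationClass.MISSENSE})


def filter_catalog(
    catalog: MutationCatalog,
    window: DomainWindow,
    classes: Iterable[MutationClass] = DEFAULT_CLASSES,
) -> MutationCatalog:
    """Restrict a catalog to a domain window and a set of mutation classes.

    Mutations outside the window are removed, as are in-window records
    whose class is not in ``classes`` (by default only missense events
    survive, excluding nonsense, frameshift and intronic records whose
    effects would confound a domain-level analysis). Order is preserved
    and the operation is idempotent.
    """
    keep = frozenset(classes)
    kept = [
        r for r in catalog
        if r.position in window and r.mut_class in keep
    ]
    logger.info(
        "filter_catalog[%s]: %d -> %d records", window.name, len(catalog), len(kept)
    )
    return MutationCatalog(records=kept, provenance=catalog.provenance)


def dedupe_patients(
    catalog: MutationCatalog, key: str = "patient_change"
) -> MutationCatalog:
    """Remove duplicate events from the same patient.

    With ``key="patient_change"`` (default) the first occurrence of each
    (patient_id, protein_change) pair is kept, so distinct mutations in
    one patient all survive; ``key="patient"`` widens the key to the
    patient alone. Records without a patient id are treated as their own
    patient (never merged) and a warning is logged.
    """
    if key not in ("patient_change", "patient"):
        raise ValueError(f"unknown dedupe key {key!r}")
    seen: set = set()
    kept = []
    anonymous = 0
    for i, r in enumerate(catalog):
        if not r.patient_id:
            anonymous += 1
            kept.append(r)
            continue
        k = r.patient_id if key == "patient" else (r.patient_id, r.protein_change)
        if k in seen:
            continue
        seen.add(k)
        kept.append(r)
    if anonymous:
        logger.warning(
            "dedupe_patients: %d record(s) lack a patient id and were kept as "
            "independent events", anonymous,
        )
    logger.info("dedupe_patients: %d -> %d records", len(catalog), len(kept))
    return MutationCatalog(records=kept, provenance=catalog.provenance)


def per_residue_counts(
    catalog: MutationCatalog, window: DomainWindow
) -> dict[int, int]:
    """Count mutation events per residue over every window position.

    Zero-count positions are included, so the returned mapping always has
    ``window.length()`` entries and its values sum to ``len(catalog)``.
    """
    counts = {pos: 0 for pos in window.positions()}
    for r in catalog:
        if r.position not in window:
            raise ValueError(
                f"record {r.protein_change!r} at {r.position} lies outside "
                f"window {window.name} ({window.start}-{window.end}); "
                "filter the catalog first"
            )
        counts[r.position] += 1
    return counts


@dataclass(frozen=True)
class KSResult:
    """One-sample Kolmogorov–Smirnov result for positional uniformity."""

    statistic: float
    p_value: float
    n: int


def ks_uniformity_test(
    positions: Sequence[int], window: DomainWindow
) -> KSResult:
    """Two-sided one-sample K–S test of mutation positions against uniformity.

    The reference distribution is continuous uniform on
    ``[start - 0.5, end + 0.5]`` so that integer residue indices sit at
    bin centers. Each mutation event contributes one sample point; ties
    are retained, which carries the usual anti-conservative bias of the
    K–S test applied to discrete data. The p-value is asymptotic.
    """
    if len(positions) == 0:
        raise ValueError("ks_uniformity_test requires at least one position")
    outside = [p for p in positions if p not in window]
    if outside:
        raise ValueError(
            f"position(s) {sorted(set(outside))} fall outside window "
            f"{window.name} ({window.start}-{window.end})"
        )
    uniform = stats.uniform(loc=window.start - 0.5, scale=window.length())
    res = stats.kstest(list(positions), uniform.cdf, method="asymp")
    return KSResult(statistic=float(res.statistic), p_value=float(res.pvalue), n=len(positions))


def counts_to_frame(
    counts: Mapping[int, int], conserved: Optional[Mapping[int, bool]] = None
) -> pd.DataFrame:
    """Per-residue count table (position, count, is_conserved)."""
    rows = [
        {
            "position": pos,
            "count": c,
            "is_conserved": bool(conserved.get(pos, False)) if conserved else False,
        }
        for pos, c in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["position", "count", "is_conserved"])
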