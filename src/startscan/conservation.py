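"""Alignment-column conservation classification and reference mapping.

A column of an ortholog multiple sequence alignment is *identical* when
a single residue accounts for at least ``ceil(threshold * n_rows)`` rows,
*physicochemical* when a single similarity group does, and
*non-conserved* otherwise. At the stringent default threshold of 0.98
with 123 sequences the required count is 121, i.e. at most 2 rows may
deviate. Gaps count in the denominator but never toward a consensus, so
heavily gapped columns cannot be called conserved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO

from .catalog import AA1

GAP = "-"
ALPHABET = AA1 + GAP

#: Strong physicochemical similarity classes (aliphatic, aromatic,
#: sulfur-containing, small hydroxyl, basic, acidic, amide, proline).
DEFAULT_SIMILARITY_GROUPS = (
    "GAVLI", "FYW", "CM", "ST", "KRH", "DE", "NQ", "P",
)


class ColumnClass(str, Enum):
    """Conservation class of one alignment column."""

    IDENTICAL = "identical"
    PHYSICOCHEMICAL = "physicochemical"
    NONCONSERVED = "nonconserved"


@dataclass
class Alignment:
    """A validated protein multiple sequence alignment.

    Rows are equal-length gapped amino-acid strings; ``reference_id``
    names the row (typically the human paralog) used to map columns to
    full-length protein coordinates.
    """

    ids: list[str]
    rows: list[str]
    reference_id: str

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment has no sequences")
        width = len(self.rows[0])
        for sid, row in zip(self.ids, self.rows):
            if len(row) != width:
                raise ValueError(
                    f"alignment row {sid!r} has length {len(row)}, expected {width}"
                )
            bad = set(row) - set(ALPHABET)
            if bad:
                raise ValueError(
                    f"alignment row {sid!r} contains unknown character(s) "
                    f"{sorted(bad)}"
                )
        if self.reference_id not in self.ids:
            raise ValueError(
                f"reference id {self.reference_id!r} not among sequence ids"
            )

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    def reference_row(self) -> str:
        return self.rows[self.ids.index(self.reference_id)]

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows)


def _normalise_row(seq: str) -> str:
    return seq.upper().replace(".", GAP)


def read_alignment(path, fmt: Optional[str] = None, reference_id: Optional[str] = None) -> Alignment:
    """Read an aligned FASTA or Clustal file into an :class:`Alignment`.

    ``fmt`` may be ``"fasta"`` or ``"clustal"``; when omitted it is
    inferred from the file extension (.aln → Clustal, otherwise FASTA).
    The first sequence is the reference unless ``reference_id`` is given.
    Ragged rows are rejected with the offending identifier named.
    """
    path = Path(path)
    if fmt is None:
        fmt = "clustal" if path.suffix.lower() in (".aln", ".clustal") else "fasta"
    if fmt not in ("fasta", "clustal"):
        raise ValueError(f"unsupported alignment format {fmt!r}")

    try:
        msa = AlignIO.read(str(path), fmt)
        ids = [rec.id for rec in msa]
        rows = [_normalise_row(str(rec.seq)) for rec in msa]
    except ValueError:
        # Ragged input: re-scan sequence by sequence to name the culprit.
        records = list(SeqIO.parse(str(path), fmt))
        if not records:
            raise ValueError(f"{path} contains no sequences")
        width = len(records[0].seq)
        for rec in records:
            if len(rec.seq) != width:
                raise ValueError(
                    f"{path}: sequence {rec.id!r} has length {len(rec.seq)}, "
                    f"expected {width} (alignment rows must be equal length)"
                )
        raise
    return Alignment(ids=ids, rows=rows, reference_id=reference_id or ids[0])


def write_alignment(aln: Alignment, path, fmt: str = "fasta") -> None:
    """Write an alignment as aligned FASTA or Clustal."""
    from Bio.Align import MultipleSeqAlignment
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    msa = MultipleSeqAlignment(
        [SeqRecord(Seq(row), id=sid, description="") for sid, row in zip(aln.ids, aln.rows)]
    )
    AlignIO.write(msa, str(path), fmt)


def required_count(threshold: float, n_rows: int) -> int:
    """Minimum row count for a consensus at ``threshold`` (count-based ceiling)."""
    # Guard against float artifacts such as 0.98 * 123 = 120.53999...9
    return int(math.ceil(round(threshold * n_rows, 9)))


@dataclass
class ConservationProfile:
    """Per-column conservation classes, consensus residues and frequencies."""

    classes: list[ColumnClass]
    consensus: list[str]
    frequencies: np.ndarray  # (n_cols, len(ALPHABET)), rows sum to 1
    threshold: float
    n_rows: int
    groups: tuple[str, ...] = DEFAULT_SIMILARITY_GROUPS
    alphabet: str = ALPHABET

    @property
    def n_cols(self) -> int:
        return len(self.classes)

    def identical_columns(self) -> list[int]:
        return [j for j, c in enumerate(self.classes) if c is ColumnClass.IDENTICAL]

    def n_identical(self) -> int:
        return len(self.identical_columns())

    def pct_identical(self) -> float:
        return 100.0 * self.n_identical() / self.n_cols

    def max_freq(self, j: int) -> float:
        # Highest non-gap residue frequency in column j.
        return float(self.frequencies[j, : len(AA1)].max())

    def to_frame(self, residue_map: Optional["ResidueMap"] = None) -> pd.DataFrame:
        """Tidy per-column table (column, ref_position, class, consensus, max_freq)."""
        rows = []
        for j in range(self.n_cols):
            rows.append(
                {
                    "column": j,
                    "ref_position": residue_map.col_to_res.get(j) if residue_map else None,
                    "class": self.classes[j].value,
                    "consensus": self.consensus[j],
                    "max_freq": round(self.max_freq(j), 6),
                }
            )
        return pd.DataFrame(rows, columns=["column", "ref_position", "class", "consensus", "max_freq"])


def classify_columns(
    aln: Alignment,
    threshold: float = 0.98,
    groups: Sequence[str] = DEFAULT_SIMILARITY_GROUPS,
) -> ConservationProfile:
    """Classify every alignment column at a consensus threshold.

    A column is ``identical`` iff some single residue occurs in at least
    ``ceil(threshold * n_rows)`` rows; failing that, ``physicochemical``
    iff some similarity group reaches the same count; else
    ``nonconserved``. The identical class takes precedence (a group is a
    superset of its residues). Gaps are counted in ``n_rows`` but never
    toward a consensus.
    """
    if not 0.5 < threshold <= 1.0:
        raise ValueError(f"threshold must lie in (0.5, 1], got {threshold}")
    seen = set()
    for g in groups:
        for aa in g:
            if aa not in AA1:
                raise ValueError(f"similarity group {g!r} contains non-residue {aa!r}")
            if aa in seen:
                raise ValueError(f"residue {aa!r} appears in more than one group")
            seen.add(aa)

    n = aln.n_rows
    need = required_count(threshold, n)
    group_of = {aa: g for g in groups for aa in g}

    idx = {ch: k for k, ch in enumerate(ALPHABET)}
    counts = np.zeros((aln.n_cols, len(ALPHABET)), dtype=np.int64)
    for row in aln.rows:
        for j, ch in enumerate(row):
            counts[j, idx[ch]] += 1

    classes: list[ColumnClass] = []
    consensus: list[str] = []
    for j in range(aln.n_cols):
        res_counts = counts[j, : len(AA1)]
        best = int(res_counts.argmax())
        if res_counts[best] >= need:
            classes.append(ColumnClass.IDENTICAL)
            consensus.append(AA1[best])
            continue
        group_counts: dict[str, int] = {}
        for k, aa in enumerate(AA1):
            c = int(res_counts[k])
            if c:
                g = group_of.get(aa)
                if g is not None:
                    group_counts[g] = group_counts.get(g, 0) + c
        best_group = max(group_counts, key=lambda g: (group_counts[g], g), default=None)
        if best_group is not None and group_counts[best_group] >= need:
            classes.append(ColumnClass.PHYSICOCHEMICAL)
            consensus.append(best_group)
        else:
            classes.append(ColumnClass.NONCONSERVED)
            consensus.append(AA1[best] if res_counts[best] > 0 else GAP)

    frequencies = counts / float(n)
    return ConservationProfile(
        classes=classes,
        consensus=consensus,
        frequencies=frequencies,
        threshold=threshold,
        n_rows=n,
        groups=tuple(groups),
    )


@dataclass
class ResidueMap:
    """Bijection between alignment columns and reference residue numbers.

    ``col_to_res`` maps a 0-based alignment column to the 1-based
    full-length residue number of the reference protein; columns where
    the reference row is gapped are absent. Both coordinates increase
    strictly.
    """

    col_to_res: dict[int, int]
    res_to_col: dict[int, int] = field(init=False)

    def __post_init__(self) -> None:
        self.res_to_col = {r: c for c, r in self.col_to_res.items()}

    def __len__(self) -> int:
        return len(self.col_to_res)


def map_columns_to_reference(aln: Alignment, ref_start: int) -> ResidueMap:
    """Map alignment columns to reference residue numbers.

    The k-th non-gap character of the reference row is assigned residue
    number ``ref_start + k - 1`` (1-based, full-length protein space).
    """
    if ref_start < 1:
        raise ValueError(f"ref_start must be >= 1, got {ref_start}")
    ref_row = aln.reference_row()
    col_to_res = {}
    k = 0
    for j, ch in enumerate(ref_row):
        if ch != GAP:
            col_to_res[j] = ref_start + k
            k += 1
    if not col_to_res:
        raise ValueError(
            f"reference row {aln.reference_id!r} is all gaps; cannot build a residue map"
        )
    return ResidueMap(col_to_res=col_to_res)


def consensus_logo(profile: ConservationProfile) -> pd.DataFrame:
    """Tidy per-column residue-frequency table for logo rendering.

    One row per (column, residue) with frequency > 0; the gap character
    is included so frequencies per column sum to 1.
    """
    rows = []
    for j in range(profile.n_cols):
        for k, ch in enumerate(profile.alphabet):
            f = float(profile.frequencies[j, k])
            if f > 0:
                rows.append({"column": j, "residue": ch, "frequency": f})
    return pd.DataFrame(rows, columns=["column", "residue", "frequency"])


@dataclass
class AnnotatedCounts:
    """Per-residue mutation counts joined with conservation classes."""

    table: pd.DataFrame  # columns: position, count, column, class
    unmapped: list[int]  # mutated positions with no alignment column

    @property
    def n_in_conserved(self) -> int:
        t = self.table
        return int(t.loc[t["class"] == ColumnClass.IDENTICAL.value, "count"].sum())

    @property
    def n_mutations(self) -> int:
        return int(self.table["count"].sum())


def annotate_mutations(
    counts: Mapping[int, int],
    residue_map: ResidueMap,
    profile: ConservationProfile,
) -> AnnotatedCounts:
    """Join per-residue mutation counts with column conservation classes.

    Every position of ``counts`` is reported. Positions with no mapped
    alignment column are listed in ``unmapped`` (and classed
    ``unaligned`` in the table) rather than silently dropped; they carry
    no conservation call, so they never contribute to ``n_in_conserved``.
    """
    rows = []
    unmapped = []
    for pos in sorted(counts):
        col = residue_map.res_to_col.get(pos)
        if col is None:
            if counts[pos] > 0:
                unmapped.append(pos)
            rows.append(
                {"position": pos, "count": counts[pos], "column": None, "class": "unaligned"}
            )
        else:
            rows.append(
                {
                    "position": pos,
                    "count": counts[pos],
                    "column": col,
                    "class": profile.classes[col].value,
                }
            )
    table = pd.DataFrame(rows, columns=["position", "count", "column", "class"])
    return AnnotatedCounts(table=table, unmapped=unmapped)


def conserved_positions(
    profile: ConservationProfile,
    residue_map: ResidueMap,
    include_physicochemical: bool = False,
) -> list[int]:
    """Reference residue numbers of conserved columns (identical class,
    optionally pooling the physicochemical class)."""
    wanted = {ColumnClass.IDENTICAL}
    if include_physicochemical:
        wanted.add(ColumnClass.PHYSICOCHEMICAL)
    return sorted(
        res for col, res in residue_map.col_to_res.items()
        if profile.classes[col] in wanted
    )


def conserved_track_bed(
    profile: ConservationProfile,
    residue_map: ResidueMap,
    name: str = "conserved",
) -> pd.DataFrame:
    """BED-like 0-based half-open track of identically conserved stretches."""
    positions = conserved_positions(profile, residue_map)
    rows = []
    run_start = prev = None
    for p in positions:
        if run_start is None:
            run_start = p
        elif p != prev + 1:
            rows.append({"chrom": name, "start": run_start - 1, "end": prev, "name": "identical"})
            run_start = p
        prev = p
    if run_start is not None:
        rows.append({"chrom": name, "start": run_start - 1, "end": prev, "name": "identical"})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
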