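"""Overrepresentation of mutations in conserved residues.

Under a uniform null, the expected number of mutation events landing on
conserved residues is

    E_cons = n_mutations * n_conserved / domain_length

and the complement E_noncons = n_mutations - E_cons. Departure from the
null is scored with the two-cell Pearson chi-square statistic

    X^2 = (E_cons - O_cons)^2 / E_cons + (E_noncons - O_noncons)^2 / E_noncons

on 1 degree of freedom, without continuity correction. "Conserved"
means the identically conserved class by default; the physicochemical
class can optionally be pooled in.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from scipy import stats


@dataclass(frozen=True)
class EnrichmentInput:
    """Counts feeding the conserved-residue enrichment test."""

    n_mutations: int
    n_in_conserved: int
    n_conserved: int
    domain_length: int

    def __post_init__(self) -> None:
        if self.domain_length <= 0:
            raise ValueError("domain_length must be positive")
        if not 0 < self.n_conserved < self.domain_length:
            raise ValueError(
                f"n_conserved must lie strictly between 0 and domain_length "
                f"({self.n_conserved} vs {self.domain_length})"
            )
        if not 0 <= self.n_in_conserved <= self.n_mutations:
            raise ValueError(
                f"n_in_conserved ({self.n_in_conserved}) must lie between 0 and "
                f"n_mutations ({self.n_mutations})"
            )


@dataclass(frozen=True)
class EnrichmentResult:
    """Expected counts, chi-square statistic and p-value (df = 1)."""

    inputs: EnrichmentInput
    expected_conserved: float
    expected_nonconserved: float
    chi_square: float
    df: int
    p_value: float
    pct_in_conserved: Optional[float]
    low_expected_count: bool = False

    def as_dict(self) -> dict:
        return {
            "n_mutations": self.inputs.n_mutations,
            "n_in_conserved": self.inputs.n_in_conserved,
            "n_conserved": self.inputs.n_conserved,
            "domain_length": self.inputs.domain_length,
            "expected_conserved": self.expected_conserved,
            "expected_nonconserved": self.expected_nonconserved,
            "chi_square": self.chi_square,
            "df": self.df,
            "p_value": self.p_value,
            "p_value_3dp": round(self.p_value, 3),
            "pct_in_conserved": self.pct_in_conserved,
            "low_expected_count": self.low_expected_count,
        }


def expected_counts(inp: EnrichmentInput) -> tuple[float, float]:
    """Expected events on conserved and non-conserved residues under the null."""
    e_cons = inp.n_mutations * inp.n_conserved / inp.domain_length
    return e_cons, inp.n_mutations - e_cons


def pct_in_conserved(inp: EnrichmentInput) -> float:
    """Observed percentage of events on conserved residues, to one decimal."""
    if inp.n_mutations == 0:
        raise ValueError("percentage undefined for an empty catalog")
    return round(100.0 * inp.n_in_conserved / inp.n_mutations, 1)


def chi_square_test(inp: EnrichmentInput) -> EnrichmentResult:
    """Two-cell chi-square test of conserved-residue overrepresentation.

    Sums (Expected - Observed)^2 / Expected over the conserved and
    non-conserved cells and refers the total to chi-square with 1 df
    (upper tail, no continuity correction). When either expected cell
    falls below 1 the result is flagged ``low_expected_count`` but still
    computed.
    """
    e_cons, e_non = expected_counts(inp)
    if e_cons <= 0 or e_non <= 0:
        raise ValueError("both expected cells must be positive")
    o_cons = inp.n_in_conserved
    o_non = inp.n_mutations - inp.n_in_conserved
    chi = (e_cons - o_cons) ** 2 / e_cons + (e_non - o_non) ** 2 / e_non
    p = float(stats.chi2.sf(chi, df=1))
    return EnrichmentResult(
        inputs=inp,
        expected_conserved=e_cons,
        expected_nonconserved=e_non,
        chi_square=float(chi),
        df=1,
        p_value=p,
        pct_in_conserved=pct_in_conserved(inp) if inp.n_mutations else None,
        low_expected_count=(e_cons < 1 or e_non < 1),
    )


def fisher_diagnostic(inp: EnrichmentInput) -> float:
    """Exact binomial tail diagnostic (two-sided) for small-count inputs.

    Not part of the headline analysis; provided as a cross-check when an
    expected cell is small.
    """
    p0 = inp.n_conserved / inp.domain_length
    res = stats.binomtest(inp.n_in_conserved, inp.n_mutations, p0, alternative="two-sided")
    return float(res.pvalue)
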