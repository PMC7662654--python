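# Methods

## Scope and data model

`startscan` analyses protein-level somatic mutation catalogs against the
evolutionary conservation and tertiary structure of a protein domain.
Everything operates in 1-based, both-ends-inclusive full-length protein
coordinates (a domain "880–1083" has length 204 and is never re-indexed
internally); alignment columns are 0-based and tied to residue numbers
through an explicit column↔residue map built from the reference row.
Genomic/transcript coordinates, isoform liftover, alignment construction
and homology modelling are out of scope: alignments and structures are
consumed, not built.

## Catalog filtering and de-duplication

Mutation records are parsed from HGVS `p.` strings (one- and
three-letter dialects; `*`/`Ter` → nonsense, `fs` → frameshift, `=` →
synonymous; `del`/`dup`/`ins`/`ext` → other). A COSMIC-style export is
read with configurable column names (defaults `Sample name`,
`ID_tumour`, `Mutation AA`, `Mutation Description`); when a textual
consequence description is present it overrides the class inferred from
the HGVS string. CADD/REVEL columns are carried through as annotations,
never computed.

Domain filtering keeps records with `start ≤ position ≤ end` and a
selected class set (default: missense only — nonsense and frameshift
events are excluded because their strong truncating effects confound a
domain-level analysis, and intronic records carry no protein position).
De-duplication keeps the first record per `(patient_id, protein_change)`
pair, the narrowest reading of "independent events per patient": two
samples of the same tumour contribute once, but two distinct mutations
in one patient both count. An option widens the key to the patient
alone. Records without a patient identifier are retained as independent
events with a logged warning.

## Hotspot (uniformity) testing

Positional clustering is tested with a two-sided one-sample
Kolmogorov–Smirnov test of event positions against the continuous
uniform distribution on `[start − 0.5, end + 0.5]`, treating integer
residue indices as bin centres. Each event is one sample point and ties
are retained; this carries the standard anti-conservative bias of the
K–S test on discrete data (measured in the test suite: at 200 events
over a 204-residue window the null rejection rate at α = 0.05 is ≈ 0.04,
i.e. the bias is negligible at these tie densities). The p-value is the
asymptotic Kolmogorov distribution tail. Event positions, not
per-residue counts, are the sample — the one-sample convention of
standard statistics packages.

## Conservation classification

For an alignment of n rows a column needs a count of
`need = ⌈t · n⌉` to be conserved at threshold t (count-based ceiling;
t = 0.98, n = 123 gives need = 121, i.e. at most two deviating rows). A
column is **identical** if a single residue reaches `need`, else
**physicochemical** if a single similarity group does, else
**non-conserved**; identical takes precedence since a group is a
superset of each of its residues. Gaps count in the denominator and
never toward any consensus, so a column with more than `n − need` gaps
cannot be conserved — the stringent convention, flagged here because
shading tools differ. The ceiling is computed on the product rounded to
nine decimals first, guarding against binary float artifacts
(0.98 × 123 = 120.539…99).

The similarity partition is not standardized by alignment-shading
tools, so the default is the familiar strong-similarity partition
{GAVLI, FYW, CM, ST, KRH, DE, NQ, P} (aliphatic, aromatic,
sulfur-containing, small hydroxyl, basic, acidic, amide, proline). It is
overridable everywhere and echoed into every report and manifest so a
run's grouping is always auditable.

Conserved-column counts are reported both as alignment-column counts and
as mapped reference-residue counts: the two differ when the reference
row contains gaps, and a domain's "percent conserved" depends on which
denominator is meant.

## Enrichment statistic

With N in-window missense events, C identically conserved residues and
domain length L, the expected count on conserved residues under a
uniform null is `E = N·C/L`; the complement is `N − E`. The test
statistic sums `(E − O)²/E` over the conserved and non-conserved cells
and is referred to χ² with 1 df, upper tail, **without** Yates
continuity correction — back-calculation from the reference p-values
(0.006 at N = 47, C = 41, L = 204; 0.005 at N = 33, C = 41, L = 206) is
consistent only with the uncorrected statistic. The two-cell form is
algebraically identical to the one-proportion z² statistic
`N(O/N − p₀)²/(p₀(1−p₀))` with `p₀ = C/L`, which the test suite uses as
an independent oracle. Per-paralog domain lengths are the
window lengths (204/206/206), not a shared nominal length. "Conserved"
means the identical class only; pooling the physicochemical class is an
option, off by default. Expected cells below 1 flag the result rather
than suppressing it; an exact binomial diagnostic is available
separately. No multiple-testing correction is applied across paralogs.

Because the conserved-cell count is an integer, the test's true size at
small N departs from the nominal α: at N = 47, p₀ = 41/204 exact
enumeration over the binomial null gives size 0.0658 at α = 0.05. The
calibration tests therefore compare Monte-Carlo rejection rates against
the nominal level with bands wide enough only for this discreteness at
the default replicate count; the effect is a property of the statistic,
not of the implementation.

## Structural interaction analysis

Structures (PDB or mmCIF, via gemmi) are reduced to first-model protein
heavy atoms; waters and heteroatoms are excluded and alternate locations
resolved to highest occupancy. Environment contacts of a target residue
are all atom pairs within a cutoff (default 4.0 Å, KD-tree accelerated,
verified against an all-pairs oracle), excluding intra-residue pairs and
backbone–backbone pairs of sequence-adjacent residues, which reflect
covalent connectivity rather than tertiary interactions.

Classification is purely distance-based because the intended inputs are
hydrogen-free homology models; no angular criteria are applied:

- **hydrogen bond** — one donor-capable and one acceptor-capable N/O at
  2.4–3.6 Å. Backbone N donates (except proline), backbone O/OXT
  accepts; the side-chain table is: donors Arg NE/NH1/NH2, Lys NZ, His
  ND1/NE2, Trp NE1, Asn ND2, Gln NE2, Ser OG, Thr OG1, Tyr OH;
  acceptors Asp OD1/OD2, Glu OE1/OE2, Asn OD1, Gln OE1, His ND1/NE2,
  Ser OG, Thr OG1, Tyr OH.
- **cation–π** — an Arg (NE/NH1/NH2/CZ) or Lys (NZ) atom within 4.0 Å of
  a Phe/Tyr/Trp ring atom. The reported distance is the **minimum
  atom–atom distance** over the supporting contacts, matching how single
  distances are conventionally printed for such interactions; a
  ring-centroid distance is available as a diagnostic
  (`ring_centroid_distance`).
- everything else within the cutoff is **other_contact**.

A contact satisfying both tests (possible for His/Trp ring nitrogens) is
reported as a hydrogen bond. Interactions are aggregated per unordered
residue pair and kind; output is deterministic and independent of atom
input order.

Network diffs match interactions on `(kind, chain+residue number of both
partners)`, deliberately ignoring residue *names* so that a mutated
residue compares as the same node as its wild-type counterpart. Mutant
structures are supplied by the user; in-silico side-chain mutation is
intentionally not performed.

Superposition uses the Kabsch algorithm (SVD of the cross-covariance of
centred paired sets, determinant-corrected to a proper rotation) over
Cα atoms shared by `(chain, residue number)`; at least three pairs are
required. Note that displacing one of n atoms by d yields an optimal
RMSD of at most d/√n — re-centring gives exactly d·√(n−1)/n with the
identity rotation, converging to d/√n for large n — so closed-form
checks use large n.

## Synthetic generators

`SyntheticSpec` defaults encode the emulated study conditions: 123
sequences, a 206-residue domain, conserved fraction 0.20 (41 planted
identical columns), at most 2 exception rows per conserved column, and
47-event catalogs. Planted identical columns draw exception residues
from outside the consensus residue's similarity group so the planted
class is unambiguous; optional physicochemical columns draw rows from
one multi-residue group; all other columns are i.i.d. uniform over the
20 residues. Alignments are gap-free (the reference row must be, and
extending this to all rows keeps planted truth exact); the classifier's
gap conventions are tested directly on hand-built columns instead.
Catalog positions are drawn independently with weight 1 on
non-conserved and `enrichment_multiplier` on conserved residues
(multiplier 1 = uniform null); patient ids are unique so de-duplication
is a no-op on synthetic data.

What this does **not** emulate: phylogenetic covariance between rows,
lineage-specific rate variation, gapped ortholog alignments, realistic
mutational signatures (transition bias, CpG effects), or per-patient
mutation multiplicity. Passing tests therefore demonstrate the counting,
mapping and inferential machinery — not robustness to real evolutionary
or mutational structure.

Toy structures realize each requested interaction with one residue pair
whose interacting side-chain atoms sit exactly at the requested distance
(coordinates written at PDB precision, 10⁻³ Å); backbone scaffolds point
away from the partner and successive pairs are 20 Å apart, so no
unrequested contact exists within the 4 Å cutoff. Requests below 2 Å are
rejected as steric clashes; requests beyond the classifier bounds are
allowed as negative controls.

## Pipeline determinism and reporting

A run is a pure function of its config and input files: machine-readable
outputs carry no timestamps and reruns are byte-identical. Every stage
writes its intermediate (filtered catalog, per-residue counts,
conservation and logo tables, observed-vs-expected, lollipop export,
interaction and diff tables) so stages can be re-run in isolation; a
manifest records the package version, a hash of the config, and every
effective threshold and group table. The lollipop export keeps all
mutated positions plus all conserved (identical or physicochemical)
positions, so domain architecture remains visible at zero counts.
p-values are printed to three decimals in summaries, with full precision
in machine output.

## Problem sizes used in the checks

Monte-Carlo checks use 1000 replicates for enrichment calibration and
500 for K–S calibration; planted-recovery checks use the full default
123 × 206 configuration; geometry oracles use ≤ 200-atom random
clusters; superposition closed forms use 400 atoms. The acceptance
script completes in a few seconds on one CPU.

## Known limitations

- The K–S p-value is asymptotic and slightly anti-conservative under
  heavy ties (many events on few residues).
- The hydrogen-bond classifier has no angular term and will accept
  geometrically implausible donor–acceptor alignments that a
  hydrogen-aware method would reject.
- The chi-square test's discreteness at small event counts (see above)
  makes its true size deviate from nominal α; for very small expected
  cells prefer the binomial diagnostic.
- Conservation classes weight all alignment rows equally; over-sampled
  lineages inflate apparent conservation.
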