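# startscan

Evolutionary and structure–function analysis of somatic mutations in
protein domains, built around the DLC ("deleted in liver cancer")
START domains.

Tumor suppressors of the DLC family (DLC-1/2/3, also STARD12/13/8) carry
a StAR-related lipid transfer (START) domain whose functional residues
are largely uncharacterized. Somatic mutation catalogs such as COSMIC
record many missense events in these domains, but classical hotspot
scans find nothing: the signal is spread across *functionally conserved*
residues rather than concentrated at single positions. `startscan`
implements the full pipeline that detects this signature:

1. **catalog** — parse a COSMIC-style mutation table (HGVS `p.`
   notation), restrict it to a domain window in 1-based protein
   coordinates, drop non-missense classes, de-duplicate events per
   patient, and test positional uniformity with a one-sample
   Kolmogorov–Smirnov test.
2. **conservation** — classify every column of an ortholog multiple
   sequence alignment at a consensus threshold *t* (default 98%):
   *identical* if one residue reaches ⌈t·n⌉ rows, *physicochemical* if a
   similarity group does, else *non-conserved*; map columns to
   reference residue numbers and annotate mutation counts per class.
3. **enrichment** — test overrepresentation of mutations on conserved
   residues. With N events, C conserved residues and domain length L,
   the null expectation is E = N·C/L, and

       χ² = (E − O)²/E + ((N−E) − (N−O))²/(N−E),  df = 1

   (two-cell Pearson statistic, no continuity correction).
4. **structure** — enumerate residue environment contacts at a 4.0 Å
   cutoff from PDB/mmCIF models, classify hydrogen bonds (donor/acceptor
   N/O pairs at 2.4–3.6 Å) and cation–π interactions (Arg/Lys cationic
   group to Phe/Tyr/Trp ring atom at ≤ 4.0 Å), diff wild-type vs mutant
   interaction networks, and superpose structures (Kabsch, Cα RMSD).
5. **synthetic** — generators with planted ground truth (alignments with
   known conserved columns, catalogs with a controlled enrichment
   multiplier, toy structures realizing interactions at exact distances)
   so every stage is testable without external downloads.
6. **pipeline / CLI** — a YAML-configured end-to-end run producing
   deterministic TSV/JSON reports, plus `startscan` subcommands
   (`filter-catalog`, `conserve`, `enrich`, `contacts`, `diff`, `run`,
   `make-fixtures`).

## Worked example

Published counts for the DLC START domains — 47, 33 and 53 in-window
missense events, of which 17, 13 and 5 fall on the 41 identically
conserved residues:

```sh
python examples/enrichment_from_published_counts.py
```

```text
DLC-1: observed 17/47 (36.2%) on conserved residues, expected 9.446; chi2 = 7.560 (df=1), p = 0.006
DLC-2: observed 13/33 (39.4%) on conserved residues, expected 6.568; chi2 = 7.864 (df=1), p = 0.005
DLC-3: observed 5/53 (9.4%) on conserved residues, expected 10.549; chi2 = 3.644 (df=1), p = 0.056
```

Mutations are significantly overrepresented on conserved residues of
DLC-1 and DLC-2 (p < 0.01) but not DLC-3. The same analysis on synthetic
data with planted truth (`examples/conservation_and_hotspots.py`):

```text
alignment: 123 sequences x 206 columns
catalog:   47 missense events in SYN (903-1108)
conservation: 41 identical columns (19.9% of the domain) at the 98% consensus
K-S uniformity: D = 0.064, p = 0.990 (no positional hotspot)
enrichment: 20 observed vs 9.35 expected events on conserved residues; chi2 = 15.13, p = 0.0001
```

— enrichment on conserved residues without any positional hotspot,
exactly the signature the pipeline targets. Structural bookkeeping
(`examples/interaction_diff.py`) classifies planted contacts and diffs a
wild-type against a mutant network:

```text
wild-type interactions (4.0 A environment cutoff):
  cation_pi     ARG1 - PHE5 (NH1..CG, 3.30 A)
  hydrogen_bond SER11 - GLN15 (OG..OE1, 3.10 A)
  hydrogen_bond SER21 - GLN25 (OG..OE1, 2.90 A)

mutant vs wild type: lost=2 gained=0 retained=1
```

`examples/full_pipeline.py` runs everything from one YAML config and
leaves all intermediate tables (filtered catalog, conservation track,
lollipop export, interaction diffs, run manifest) on disk.

## Documentation

See `docs/methods.md` for the model, parameter and design details:
threshold semantics, gap handling, the K–S convention for discrete
positions, donor/acceptor tables, and what the synthetic generators do
and do not emulate.
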