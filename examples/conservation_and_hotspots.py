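"""Full sequence-level analysis on synthetic data with known truth.

Simulates a 123-sequence ortholog alignment over a 206-residue domain
with 41 planted identically conserved columns, draws a 47-event missense
catalog whose rate on conserved residues is 2.5x the background, then
runs every sequence stage: conservation classification, hotspot (K-S)
testing, mutation annotation and the enrichment test.
"""

from startscan import (
    DomainWindow,
    EnrichmentInput,
    SyntheticSpec,
    annotate_mutations,
    chi_square_test,
    classify_columns,
    ks_uniformity_test,
    map_columns_to_reference,
    per_residue_counts,
    simulate_alignment,
    simulate_catalog,
)

spec = SyntheticSpec(seed=7, enrichment_multiplier=2.5)
window = DomainWindow("SYN", 903, 1108)

aln, truth = simulate_alignment(spec)
catalog = simulate_catalog(spec, window, truth, reference_seq=aln.reference_row())
print(f"alignment: {aln.n_rows} sequences x {aln.n_cols} columns")
print(f"catalog:   {len(catalog)} missense events in {window.name} "
      f"({window.start}-{window.end})")

profile = classify_columns(aln, threshold=0.98)
print(f"conservation: {profile.n_identical()} identical columns "
      f"({profile.pct_identical():.1f}% of the domain) at the 98% consensus")

ks = ks_uniformity_test(catalog.positions(), window)
print(f"K-S uniformity: D = {ks.statistic:.3f}, p = {ks.p_value:.3f} "
      f"({'no' if ks.p_value > 0.05 else 'possible'} positional hotspot)")

rmap = map_columns_to_reference(aln, ref_start=window.start)
annotated = annotate_mutations(per_residue_counts(catalog, window), rmap, profile)
res = chi_square_test(
    EnrichmentInput(
        n_mutations=annotated.n_mutations,
        n_in_conserved=annotated.n_in_conserved,
        n_conserved=profile.n_identical(),
        domain_length=window.length(),
    )
)
print(
    f"enrichment: {annotated.n_in_conserved} observed vs "
    f"{res.expected_conserved:.2f} expected events on conserved residues; "
    f"chi2 = {res.chi_square:.2f}, p = {res.p_value:.4f}"
)
print(
    "\nThe events cluster on functionally conserved residues (small enrichment\n"
    "p-value) even though no single residue is a positional hotspot (large K-S\n"
    "p-value) - the signature the pipeline is designed to detect."
)
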