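"""Run the candidate filter cascade on a simulated bulk and print the funnel.

Each stage is a row predicate: EMS spectrum (G>A / C>T only), read depth
5-100, background subtraction against the parental variants and the library
allele-frequency panel, and the homozygosity cutoff (SNP ratio = 1). The
printed counts mirror the candidate funnel of a real mapping run.
"""

from allelicmap import (
    BackgroundPanel,
    FilterConfig,
    PoolSeqParams,
    calls_from_table,
    generate_parental_background,
    generate_reference,
    induce_ems_mutations,
    pool_and_sequence,
    run_filter_cascade,
    select_homozygous_mutants,
    simulate_f2,
)

genome, _ = generate_reference(seed=1, n_chrom=3, chrom_length_bp=100_000, n_genes=30)
muts = induce_ems_mutations(genome, 147, ems_fraction=0.95, seed=2)
background, panel_df = generate_parental_background(genome, 200, seed=5, avoid=muts.positions())
causal = muts.mutations[0]

f2 = simulate_f2(genome, muts, (causal.chrom, causal.pos), 160, seed=3)
bulk = select_homozygous_mutants(f2, 20)
table = pool_and_sequence(bulk, PoolSeqParams(seed=4), background)

panel = BackgroundPanel(
    parental=frozenset(s.key for s in background),
    population_af={(r.chrom, int(r.pos), r.ref, r.alt): float(r.af)
                   for r in panel_df.itertuples(index=False)},
)
candidates, report = run_filter_cascade(calls_from_table(table), FilterConfig(), panel)

print(report.to_frame().to_string(index=False))
print(f"\n{len(candidates)} homozygous candidates survive; the causal site "
      f"{causal.chrom}:{causal.pos} is "
      f"{'among them' if any(v.pos == causal.pos for v in candidates) else 'MISSING'}")
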