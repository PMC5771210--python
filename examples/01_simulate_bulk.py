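"""Simulate one bulked-segregant experiment and look at the SNP ratios.

Builds a toy genome, scatters EMS mutations over a mutant line, crosses it to
its isogenic wild type, selects 20 F2 plants homozygous for a chosen causal
mutation, and pool-sequences them at ~15x. The causal site should be fixed
(ratio 1); mutations on other chromosomes should hover around 0.5.
"""

import numpy as np

from allelicmap import (
    PoolSeqParams,
    generate_reference,
    induce_ems_mutations,
    pool_and_sequence,
    select_homozygous_mutants,
    simulate_f2,
)

genome, genes = generate_reference(seed=1, n_chrom=3, chrom_length_bp=100_000, n_genes=30)
muts = induce_ems_mutations(genome, n_mutations=147, ems_fraction=0.95, seed=2)
causal = muts.mutations[0]
print(f"causal mutation: {causal.chrom}:{causal.pos} {causal.ref}>{causal.alt}")

f2 = simulate_f2(genome, muts, (causal.chrom, causal.pos), n_plants=160, seed=3)
hom = (f2.dosages[:, f2.causal_index] == 2).mean()
print(f"homozygous-mutant fraction in the F2: {hom:.3f} (expect ~0.25)")

bulk = select_homozygous_mutants(f2, 20)
table = pool_and_sequence(bulk, PoolSeqParams(n_pooled=20, mean_depth=15, seed=4))

ratios = table.alt_depth / table.total_depth
causal_row = table[table.truth_label == "causal"].iloc[0]
unlinked = table[table.truth_label == "unlinked"]
print(f"causal-site SNP ratio: {causal_row.alt_depth}/{causal_row.total_depth} "
      f"= {causal_row.alt_depth / causal_row.total_depth:.2f} (expect 1.0)")
print(f"mean ratio over {len(unlinked)} unlinked sites: "
      f"{np.mean(unlinked.alt_depth / unlinked.total_depth):.3f} (expect ~0.5)")
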