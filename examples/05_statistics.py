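"""The side statistics: coincidence probability, segregation test, wax reduction.

With ~147 deleterious mutations per line over ~34,000 genes, a given gene is
hit by chance at rate ~0.004 per line, so two independent lines hitting the
same gene (~rate^2) is essentially impossible — the logic that lets an
allelic intersection stand in for a complementation test.
"""

from allelicmap import gene_mutation_rate, percent_reduction, segregation_test

est = gene_mutation_rate(147, 34_000)
print(f"per-gene hit rate: {est.rate:.6f} -> reported {est.reported_rate:g}")
print(f"two independent hits of one gene: {est.k_hit_probability(2):.3g} "
      f"(unrounded {est.k_hit_probability(2, as_published=False):.3g})")

res = segregation_test(25, 75)
print(f"\n25 mutant : 75 WT vs 1:3 -> chi2 = {res.statistic:.2f}, p = {res.pvalue:.3f} "
      "(perfect single-recessive fit)")
res = segregation_test(10, 90)
print(f"10 mutant : 90 WT vs 1:3 -> chi2 = {res.statistic:.2f}, p = {res.pvalue:.2g} "
      "(rejected)")

print(f"\nwax-load reduction, 2.12 -> 0.34 mg/cm2: {percent_reduction(2.12, 0.34):.2f}%")
print(f"wax-load reduction, 5.67 -> 0.44 mg/cm2: {percent_reduction(5.67, 0.44):.2f}%")
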