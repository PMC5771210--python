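"""Classify variant effects against gene models with the mini annotator.

Takes every possible EMS-type change inside one generated gene and tabulates
the resulting effect classes; the large-effect subset (missense, nonsense,
splice donor/acceptor) is what the mapping pipeline keeps as candidate
causal mutations.
"""

from collections import Counter

from allelicmap import EffectAnnotator, Snv, filter_large_effect, generate_reference

genome, genes = generate_reference(seed=1, n_chrom=2, chrom_length_bp=30_000, n_genes=10)
gene = genes[0]
annotator = EffectAnnotator(genome, genes)

annotations = []
for a, b in [*gene.cds, *gene.introns()]:
    for pos in range(a, b + 1):
        ref = genome.base(gene.chrom, pos)
        if ref not in "GC":
            continue
        alt = "A" if ref == "G" else "T"
        for ann in annotator.annotate(Snv(gene.chrom, pos, ref, alt)):
            if ann.gene_id == gene.gene_id:
                annotations.append(ann)

print(f"gene {gene.gene_id} ({gene.strand} strand, {len(gene.exons)} exons, "
      f"{gene.cds_length // 3} codons)")
print("EMS-reachable effect classes:")
for effect, n in Counter(a.effect.value for a in annotations).most_common():
    print(f"  {effect:20s} {n}")

large = filter_large_effect(annotations)
example = next(a for a in large if a.protein_change)
print(f"\n{len(large)} of {len(annotations)} changes are large-effect, e.g. "
      f"{example.chrom}:{example.pos} {example.ref}>{example.alt} -> "
      f"{example.effect.value} {example.protein_change_str}")
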