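# Methods

## Model overview

`allelicmap` implements isogenic bulked-segregant mapping with allelic
intersection. The analysis consumes per-site pooled variant calls (total
depth, alternate-supporting depth) for one bulk of phenotype-selected F2
plants per mutant population, plus a parental variant list, a library
allele-frequency panel, gene models, and the reference sequence. Its
simulator generates all of these with known truth labels so every claim the
pipeline makes can be scored against ground truth.

### Genetics of the pooled SNP ratio

All induced mutations of one line sit on the same parental homolog
(coupling phase), so the F1 of (mutant × isogenic wild type) is heterozygous
at every induced site. Selecting F2 plants homozygous at the causal locus
conditions each of their gametes on carrying the causal allele; a site at
recombination fraction *r* from it is then carried by each gamete with
probability 1 − r. The pool allele frequency — and hence the expected SNP
ratio — at that site is therefore **1 − r**: 1 at the causal site, 0.5 for
unlinked sites, decaying in between. This expectation is exercised by a
Monte Carlo test over r ∈ {0, 0.05, 0.1, 0.25, 0.5} (three-standard-error
agreement).

### Meiosis

Gametes are generated as a Markov chain along each chromosome: the first
site takes either haplotype with probability ½, and adjacent sites switch
haplotype with the recombination fraction given by **Haldane's map
function**, r = (1 − e^(−2d/100))/2 for map distance d in cM. Haldane (no
interference) was chosen as the simplest standard closed form; because it is
Markov-consistent (r(d₁+d₂) composes exactly), pairwise recombination
between any two sites is correct, not only between neighbours. Chromosomes
assort independently (r = 0.5).

### Pooled sequencing

Per emitted site, `total_depth ~ Poisson(mean_depth)` (default 15, the
coverage of a typical bulk run) and `alt_depth ~ Binomial(total_depth, p′)`
with `p′ = p(1−e) + (1−p)e`, where p is the pool allele frequency (mean
dosage / 2 over the pooled plants, default 20) and e a symmetric per-read
allele-flip error, default 0. The default e = 0 matches the regime the
ratio-cutoff-of-1 filter implicitly assumes (clean calls at the causal
site); e is configurable to probe how a relaxed cutoff behaves, and the
generator can also emit pure error sites (`n_error_sites`). The real
depth distribution and error handling of production variant callers are not
modelled; Poisson/binomial is the standard idealization for pooled data.

### Toy genomes

`generate_reference` produces a few short chromosomes (default 5 × 150 kb in
the pipeline; tests use 2–5 × 30–300 kb) carrying non-overlapping
single-transcript genes with ≥ 2 exons, 5′/3′ UTRs, a genuine ORF (ATG, no
internal stop, terminal stop) and canonical GT..AG introns, emitted as
FASTA + GFF3. Intergenic background is i.i.d. with configurable GC (default
0.44).

**Genetic map rescaling.** Each toy chromosome is assigned a *genetic*
length of ~100 cM (one Morgan, the order of a real crop chromosome) rather
than a realistic physical density in cM/Mb. At desk scale this is the choice
that preserves the method's behaviour: what governs the candidate funnel is
the probability (1 − r)⁴⁰ that a linked site stays fixed in all 40 gametes
of a 20-plant bulk, which depends on the genetic, not physical, distance
distribution of mutations around the causal site. With a physically
realistic 1–2 cM/Mb, a 300 kb chromosome would be one tightly linked block
and every mutation on it would survive the homozygosity filter — a regime
no real mapping run is in.

### Study conditions (generator defaults)

| parameter | default | rationale |
|---|---|---|
| mutations per line | 147 | mean deleterious load per line in the source mutant library |
| EMS fraction | 0.95 | EMS spectra are ~95–98% G:C→A:T; the remainder exercises the spectrum filter |
| pooled plants | 20 | bulk size used for each F2 population |
| mean depth | 15× | coverage of the real bulks |
| sequencing error | 0 | see above |
| F2 size | 160 | 20 homozygotes must exist among Binomial(n, ¼) plants with overwhelming probability |
| parental background SNPs | 400 | desk-scale stand-in for the ~80,000-SNP background panel; fixed in parent and pool, af ~ U(0.5, 1) in the library panel |
| genes / genome | 100 (500 in the headline experiment) | desk-scale stand-ins for a ~34,000-gene genome |

### Filter cascade

Order: EMS spectrum → depth → background subtraction → homozygosity. All
four are row-wise predicates, so the surviving set equals the intersection
of the individual filters (a tested invariant) and order affects only the
reported per-stage counts. Choices where the published description is
ambiguous: depth bounds 5–100 read as a closed interval; the population
panel threshold inclusive at 0.05; homozygosity as ratio ≥ cutoff (default
1.0, exactly "all reads mutant") so that sub-1 cutoffs remain usable when
sequencing error is simulated; EMS type judged on the reference strand, with
C>T accepted as the reverse-strand face of G>A. Non-SNV records are skipped
with a logged warning, never silently dropped; zero-depth sites have no
ratio and cannot pass the homozygosity stage.

### Effect annotation

A deliberately small effect predictor for biallelic SNVs against
single-transcript gene models: splice windows are the two intronic bases on
each side of every exon boundary (the canonical GT/AG positions), with
donor/acceptor defined in transcript orientation; splice assignment takes
precedence over plain intron. Coding changes rebuild only the affected codon
from the CDS stitched in transcript orientation (reverse-complemented for
minus-strand genes) and translate with the standard nuclear code. Classes:
missense / nonsense / synonymous / splice donor / splice acceptor / intron /
UTR / intergenic, plus start-loss and stop-loss; the large-effect set used
for candidate selection is the four classes missense, nonsense, splice
donor, splice acceptor, with start/stop-loss admitted only via an explicit
flag. Overlapping genes each receive their own call; a most-severe rule
(nonsense > splice > start/stop-loss > missense > synonymous) is available
for single-label summaries. Correctness is pinned to an independent oracle
that rebuilds the entire mutant transcript and diffs the translated
proteins, exhaustively over every CDS SNV of 20 random genes, and to a
mirror-image (reverse-complement) symmetry test.

### Allelic intersection and statistics

Intersection is at gene level: a gene qualifies if every population
contributes ≥ 1 surviving candidate. By default the candidate sets are
formed *after* the large-effect filter; a flag intersects all genic
homozygous candidates instead (the published description does not fix this
order). Populations contributing a lesion at an *identical* position are
flagged and warned about — a shared position suggests shared ancestry or
residual background, not independent alleles.

The side statistics: the per-gene chance hit rate is mutations-per-line /
gene count, reported both unrounded and rounded to one significant figure;
the k-hit coincidence probability is rate^k (with the rounded rate, 0.004² =
1.6 × 10⁻⁵, labelled "as published"; the unrounded square is ≈ 1.87 × 10⁻⁵
and both are exposed). Segregation against 1 mutant : 3 wild type uses the
plain Pearson chi-square (df = 1, no continuity correction) via
`scipy.stats.chisquare`. Percent trait reduction is (WT − mutant)/WT × 100,
always computed from the supplied means — published tables rounded from
unrounded inputs will differ in the second decimal, and no attempt is made
to match such cells.

## Numerical and engineering choices

* Coordinates are 1-based inclusive throughout the public API and on disk
  (VCF/GFF3 conventions); only internal array indexing is 0-based.
* One run seed feeds `numpy.random.SeedSequence.spawn` substreams (genome,
  background, then mutagenesis/meiosis/sequencing per population), so each
  stage is independently reproducible and reruns are byte-identical,
  manifest checksums included.
* VCF I/O uses pysam (site-only records, INFO `DP`/`AO`); GFF3 parsing uses
  gffutils; FASTA uses Biopython. The GFF3 writer emits gene/mRNA/exon/CDS
  features with correctly accumulated CDS phases.
* Degenerate inputs fail loudly: gene packing that does not fit, causal loci
  that are not induced mutations, selection shortfalls (with the shortfall
  count), reference-mismatching variants (with locus), malformed panels
  (with line number), truncated VCFs (with line number from a structural
  pre-scan; record-level errors carry record index and locus, which is what
  the underlying parser can report).

## What the simulation does and does not show

The generator reproduces the *statistical* structure the method assumes:
EMS-spectrum coupling-phase mutations, Mendelian F2 segregation with
interference-free linkage, selection on a single fully penetrant recessive
locus, binomial pooled sampling, and a background of pre-existing fixed
SNPs. It does not model read-level artifacts (mapping error, indels,
multi-allelic sites, reference errors), phenotyping error in the selected
bulk, crossover interference, or segregation distortion. Passing tests
therefore validate the pipeline's logic and its behaviour under the model's
assumptions — they do not certify performance on real sequencing data, where
the background panel and the depth filter carry more of the burden.

## Problem sizes used by the test suite

The replicated end-to-end check runs 20 seeded two-population studies on
500-gene, 1.5 Mb genomes with ~150 mutations per line — the whole suite
completes in well under a minute, and the acceptance script in seconds.
These sizes were chosen as the smallest at which the funnel behaves like a
real run (a handful of fixed linked candidates per population, single-gene
intersection), keeping the demonstration honest without requiring
crop-genome scale inputs.
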