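"""Effect classification: codon arithmetic, splice windows, strand handling."""

import numpy as np
import pytest

from allelicmap.annotation import (
    LARGE_EFFECTS,
    Effect,
    EffectAnnotator,
    ReferenceMismatchError,
    filter_large_effect,
    most_severe,
    translate_codon,
)
from allelicmap.genome import GeneModel, ToyGenome, revcomp
from allelicmap.simulate import Snv
from conftest import coding_effect_oracle


def _plus_gene_genome():
    """80 bp chromosome with one + strand gene of known sequence.

    exon1 5-10 (all UTR), intron 11-40 (GT..AG), exon2 41-70 = CDS:
    ATG GCT TGG CCG CCA AAA GGG TTT TAC TGA -> protein MAWPPKGFY*
    """
    seq = (
        "TTTT"            # 1-4 intergenic
        + "TTTTTT"        # 5-10 exon1, 5' UTR
        + "GT" + "T" * 26 + "AG"  # 11-40 intron
        + "ATGGCTTGGCCGCCAAAAGGGTTTTACTGA"  # 41-70 CDS
        + "T" * 10        # 71-80 intergenic
    )
    genome = ToyGenome.from_sequences({"c1": seq}, recomb_rate=1.0)
    gene = GeneModel("g1", "c1", "+", [(5, 10), (41, 70)], [(41, 70)])
    gene.validate()
    return genome, gene


class TestCodingClassification:
    @pytest.fixture()
    def annotator(self):
        genome, gene = _plus_gene_genome()
        return genome, gene, EffectAnnotator(genome, [gene])

    @pytest.mark.parametrize(
        "pos,ref,alt,effect,change",
        [
            (44, "G", "A", Effect.MISSENSE, "A2T"),    # GCT -> ACT, Ala -> Thr
            (48, "G", "A", Effect.NONSENSE, "W3*"),    # TGG -> TAG
            (52, "G", "A", Effect.SYNONYMOUS, "P4P"),  # CCG -> CCA
            (42, "T", "C", Effect.START_LOSS, "M1T"),  # ATG -> ACG
            (70, "A", "G", Effect.STOP_LOSS, "*10W"),  # TGA -> TGG
        ],
    )
    def test_codon_level_calls(self, annotator, pos, ref, alt, effect, change):
        genome, gene, ann = annotator
        (a,) = ann.annotate(Snv("c1", pos, ref, alt))
        assert a.gene_id == "g1"
        assert a.effect is effect
        assert a.protein_change_str == change
        assert coding_effect_oracle(genome, gene, pos, alt) is effect

    @pytest.mark.parametrize(
        "pos,effect",
        [
            (11, Effect.SPLICE_DONOR),     # first intronic base
            (12, Effect.SPLICE_DONOR),
            (39, Effect.SPLICE_ACCEPTOR),  # last two intronic bases
            (40, Effect.SPLICE_ACCEPTOR),
            (25, Effect.INTRON),
            (7, Effect.UTR),
            (2, Effect.INTERGENIC),
        ],
    )
    def test_regional_assignment(self, annotator, pos, effect):
        genome, _, ann = annotator
        ref = genome.base("c1", pos)
        alt = "A" if ref != "A" else "C"
        (a,) = ann.annotate(Snv("c1", pos, ref, alt))
        assert a.effect is effect
        assert a.protein_change is None

    def test_reference_mismatch_names_the_locus(self, annotator):
        _, _, ann = annotator
        with pytest.raises(ReferenceMismatchError, match="c1:44"):
            ann.annotate(Snv("c1", 44, "C", "A"))

    def test_position_beyond_chromosome_raises(self, annotator):
        _, _, ann = annotator
        with pytest.raises(ValueError, match="beyond"):
            ann.annotate(Snv("c1", 81, "T", "A"))


def test_minus_strand_donor_is_at_the_genomic_intron_end():
    # gene on -: transcript 5' exon is the genomic-rightmost one, so the donor
    # window sits at the genomic end of the intron (revcomp GT..AG = CT..AC)
    seq = "T" * 10 + "CT" + "T" * 26 + "AC" + "T" * 20
    genome = ToyGenome.from_sequences({"c1": seq}, recomb_rate=1.0)
    gene = GeneModel("g1", "c1", "-", [(2, 10), (41, 58)], [(2, 10), (41, 49)])
    gene.validate()
    ann = EffectAnnotator(genome, [gene])
    (donor,) = ann.annotate(Snv("c1", 40, genome.base("c1", 40), "T"))
    assert donor.effect is Effect.SPLICE_DONOR
    (acceptor,) = ann.annotate(Snv("c1", 11, genome.base("c1", 11), "T"))
    assert acceptor.effect is Effect.SPLICE_ACCEPTOR


def test_strand_symmetry_under_genome_mirroring(small_ref):
    """Annotating a gene equals annotating its reverse-complemented mirror image."""
    genome, genes = small_ref
    gene = next(g for g in genes if g.strand == "-")
    L = genome.length(gene.chrom)
    mirror_seq = revcomp(genome.chrom(gene.chrom).seq)
    mirror_genome = ToyGenome.from_sequences({gene.chrom: mirror_seq}, recomb_rate=1.0)

    def mirror_iv(iv):
        a, b = iv
        return (L - b + 1, L - a + 1)

    mirror_gene = GeneModel(
        gene.gene_id, gene.chrom, "+",
        sorted(mirror_iv(iv) for iv in gene.exons),
        sorted(mirror_iv(iv) for iv in gene.cds),
    )
    mirror_gene.validate()
    ann = EffectAnnotator(genome, [gene])
    mirror_ann = EffectAnnotator(mirror_genome, [mirror_gene])
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}

    rng = np.random.default_rng(7)
    span = np.arange(gene.start, gene.end + 1)
    for pos in rng.choice(span, size=80, replace=False):
        pos = int(pos)
        ref = genome.base(gene.chrom, pos)
        for alt in "ACGT".replace(ref, ""):
            (a,) = ann.annotate(Snv(gene.chrom, pos, ref, alt))
            (b,) = mirror_ann.annotate(
                Snv(gene.chrom, L - pos + 1, comp[ref], comp[alt])
            )
            assert a.effect is b.effect, f"{pos} {ref}>{alt}"
            assert a.protein_change == b.protein_change


def test_annotator_matches_oracle_on_random_genes(small_ref):
    """Codon-path calls equal the rebuild-and-translate oracle for two full genes."""
    genome, genes = small_ref
    for gene in (genes[0], next(g for g in genes if g.strand == "-")):
        ann = EffectAnnotator(genome, [gene])
        for a, b in gene.cds:
            for pos in range(a, b + 1):
                ref = genome.base(gene.chrom, pos)
                for alt in "ACGT".replace(ref, ""):
                    (call,) = ann.annotate(Snv(gene.chrom, pos, ref, alt))
                    assert call.effect is coding_effect_oracle(genome, gene, pos, alt)


class TestLargeEffectFilter:
    def _ann(self, effect, change=None):
        from allelicmap.annotation import AnnotatedVariant

        return AnnotatedVariant("c", 1, "G", "A", "g", effect, change)

    def test_retains_exactly_the_four_published_classes(self):
        annotations = [self._ann(e) for e in Effect]
        kept = {a.effect for a in filter_large_effect(annotations)}
        assert kept == set(LARGE_EFFECTS)
        assert Effect.SYNONYMOUS not in kept and Effect.INTERGENIC not in kept

    def test_start_and_stop_loss_admitted_only_by_flag(self):
        annotations = [self._ann(Effect.START_LOSS), self._ann(Effect.STOP_LOSS)]
        assert filter_large_effect(annotations) == []
        assert len(filter_large_effect(annotations, include_start_stop_loss=True)) == 2

    def test_most_severe_prefers_nonsense_over_missense(self):
        annotations = [self._ann(Effect.MISSENSE), self._ann(Effect.NONSENSE)]
        assert most_severe(annotations).effect is Effect.NONSENSE


def test_translate_codon_rejects_garbage():
    assert translate_codon("TGA") == "*"
    with pytest.raises(ValueError):
        translate_codon("TGN")
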