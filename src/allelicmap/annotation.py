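"""Miniature variant-effect predictor for SNVs against single-transcript gene models.

Classifies each SNV, per overlapping gene, as one of a closed set of effect
classes: missense / nonsense / synonymous (coding), splice-site donor /
acceptor (the two intronic bases flanking each exon boundary, the canonical
GT..AG positions), intron, UTR, or intergenic.  Start- and stop-codon losses
get their own classes; whether they count as "large effect" is a filter flag.

Coding changes are evaluated on the codon actually affected: the CDS is
stitched together in transcript orientation (reverse-complemented for minus
strand genes), the affected codon rebuilt with the alternate base, and both
codons translated with the standard nuclear code.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from Bio.Data import CodonTable

from .genome import GeneModel, ToyGenome, revcomp

logger = logging.getLogger(__name__)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_CODON_TO_AA = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:
    _CODON_TO_AA[_stop] = "*"


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a codon; ``*`` for stop."""
    try:
        return _CODON_TO_AA[codon.upper()]
    except KeyError:
        raise ValueError(f"not a valid codon: {codon!r}") from None


class Effect(str, Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    SYNONYMOUS = "synonymous"
    SPLICE_DONOR = "splice_site_donor"
    SPLICE_ACCEPTOR = "splice_site_acceptor"
    START_LOSS = "start_loss"
    STOP_LOSS = "stop_loss"
    INTRON = "intron"
    UTR = "utr"
    INTERGENIC = "intergenic"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: the four classes retained as candidate causal mutations
LARGE_EFFECTS = frozenset(
    {Effect.MISSENSE, Effect.NONSENSE, Effect.SPLICE_DONOR, Effect.SPLICE_ACCEPTOR}
)

#: most-severe-first ordering used to pick a single class per variant
SEVERITY: tuple[Effect, ...] = (
    Effect.NONSENSE,
    Effect.SPLICE_DONOR,
    Effect.SPLICE_ACCEPTOR,
    Effect.START_LOSS,
    Effect.STOP_LOSS,
    Effect.MISSENSE,
    Effect.SYNONYMOUS,
    Effect.UTR,
    Effect.INTRON,
    Effect.INTERGENIC,
)
_SEVERITY_RANK = {e: i for i, e in enumerate(SEVERITY)}

_CODING = {Effect.MISSENSE, Effect.NONSENSE, Effect.SYNONYMOUS, Effect.START_LOSS, Effect.STOP_LOSS}


class ReferenceMismatchError(ValueError):
    """Variant REF base disagrees with the reference genome."""


@dataclass(frozen=True)
class AnnotatedVariant:
    """One variant's effect call against one gene (or intergenic)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene_id: str | None
    effect: Effect
    protein_change: tuple[str, int, str] | None = None  # (ref AA, 1-based pos, alt AA)

    @property
    def protein_change_str(self) -> str | None:
        if self.protein_change is None:
            return None
        a, p, b = self.protein_change
        return f"{a}{p}{b}"

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


class _GeneCache:
    """Precomputed lookup structures for one gene model."""

    def __init__(self, gene: GeneModel, genome: ToyGenome):
        self.gene = gene
        self.cds_offsets: list[tuple[int, int, int]] = []  # (start, end, cum offset)
        off = 0
        parts = []
        for a, b in gene.cds:
            self.cds_offsets.append((a, b, off))
            off += b - a + 1
            parts.append(genome.subseq(gene.chrom, a, b))
        self.cds_len = off
        fwd = "".join(parts)
        self.cds_seq = fwd if gene.strand == "+" else revcomp(fwd)
        self.donor: set[int] = set()
        self.acceptor: set[int] = set()
        for istart, iend in gene.introns():
            if iend < istart:
                continue
            left = {istart, min(istart + 1, iend)}
            right = {max(iend - 1, istart), iend}
            if gene.strand == "+":
                self.donor |= left
                self.acceptor |= right
            else:
                self.donor |= right
                self.acceptor |= left

    def transcript_index(self, pos: int) -> int | None:
        for a, b, off in self.cds_offsets:
            if a <= pos <= b:
                fwd = off + (pos - a)
                return fwd if self.gene.strand == "+" else self.cds_len - 1 - fwd
        return None


class EffectAnnotator:
    """Annotate SNVs against a genome and a set of gene models."""

    def __init__(self, genome: ToyGenome, genes: Sequence[GeneModel]):
        self.genome = genome
        self._by_chrom: dict[str, list[GeneModel]] = {}
        for g in genes:
            self._by_chrom.setdefault(g.chrom, []).append(g)
        for lst in self._by_chrom.values():
            lst.sort(key=lambda g: g.start)
        self._cache: dict[str, _GeneCache] = {}

    def _gene_cache(self, gene: GeneModel) -> _GeneCache:
        c = self._cache.get(gene.gene_id)
        if c is None:
            c = self._cache[gene.gene_id] = _GeneCache(gene, self.genome)
        return c

    def annotate(self, variant) -> list[AnnotatedVariant]:
        """Effect calls for one SNV: one per overlapping gene, else intergenic.

        ``variant`` is anything with chrom / pos / ref / alt attributes
        (a filtering VariantCall, a simulated Snv, ...).
        """
        chrom, pos = variant.chrom, int(variant.pos)
        ref, alt = variant.ref.upper(), variant.alt.upper()
        length = self.genome.length(chrom)
        if not 1 <= pos <= length:
            raise ValueError(f"position {chrom}:{pos} beyond chromosome length {length}")
        genome_ref = self.genome.base(chrom, pos)
        if len(ref) == 1 and genome_ref != ref:
            raise ReferenceMismatchError(
                f"{chrom}:{pos}: REF {ref} does not match reference base {genome_ref}"
            )
        hits = [g for g in self._by_chrom.get(chrom, []) if g.contains(pos)]
        if not hits:
            return [AnnotatedVariant(chrom, pos, ref, alt, None, Effect.INTERGENIC)]
        return [self._annotate_gene(chrom, pos, ref, alt, g) for g in hits]

    def annotate_all(self, variants: Iterable) -> list[AnnotatedVariant]:
        out: list[AnnotatedVariant] = []
        for v in variants:
            out.extend(self.annotate(v))
        return out

    def _annotate_gene(self, chrom, pos, ref, alt, gene: GeneModel) -> AnnotatedVariant:
        cache = self._gene_cache(gene)
        if pos in cache.donor:
            return AnnotatedVariant(chrom, pos, ref, alt, gene.gene_id, Effect.SPLICE_DONOR)
        if pos in cache.acceptor:
            return AnnotatedVariant(chrom, pos, ref, alt, gene.gene_id, Effect.SPLICE_ACCEPTOR)
        t = cache.transcript_index(pos)
        if t is not None:
            effect, change = self._classify_coding(cache, t, alt, gene)
            return AnnotatedVariant(chrom, pos, ref, alt, gene.gene_id, effect, change)
        if any(a <= pos <= b for a, b in gene.exons):
            return AnnotatedVariant(chrom, pos, ref, alt, gene.gene_id, Effect.UTR)
        return AnnotatedVariant(chrom, pos, ref, alt, gene.gene_id, Effect.INTRON)

    @staticmethod
    def _classify_coding(cache: _GeneCache, t: int, alt: str, gene: GeneModel):
        ci, k = divmod(t, 3)
        ref_codon = cache.cds_seq[3 * ci : 3 * ci + 3]
        alt_t = alt if gene.strand == "+" else _COMP[alt]
        alt_codon = ref_codon[:k] + alt_t + ref_codon[k + 1 :]
        ref_aa = translate_codon(ref_codon)
        alt_aa = translate_codon(alt_codon)
        change = (ref_aa, ci + 1, alt_aa)
        if ref_aa == alt_aa:
            return Effect.SYNONYMOUS, change
        if ci == 0 and ref_codon == "ATG":
            return Effect.START_LOSS, change
        if alt_aa == "*":
            return Effect.NONSENSE, change
        if ref_aa == "*":
            return Effect.STOP_LOSS, change
        return Effect.MISSENSE, change


def most_severe(annotations: Sequence[AnnotatedVariant]) -> AnnotatedVariant:
    """Single most severe call among a variant's per-gene annotations."""
    if not annotations:
        raise ValueError("no annotations")
    return min(annotations, key=lambda a: _SEVERITY_RANK[a.effect])


def filter_large_effect(
    annotations: Iterable[AnnotatedVariant], include_start_stop_loss: bool = False
) -> list[AnnotatedVariant]:
    """Retain missense, nonsense, and splice-site donor/acceptor calls.

    ``include_start_stop_loss`` additionally admits start_loss / stop_loss,
    which are missense-equivalent in severity but form separate classes.
    """
    keep = set(LARGE_EFFECTS)
    if include_start_stop_loss:
        keep |= {Effect.START_LOSS, Effect.STOP_LOSS}
    return [a for a in annotations if a.effect in keep]
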