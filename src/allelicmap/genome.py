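"""Toy reference genomes and gene models.

A :class:`ToyGenome` is a desk-scale stand-in for a crop reference genome:
a handful of short chromosomes with explicit base sequence plus a constant
per-chromosome genetic-map density (cM/Mb) used to convert physical distance
into recombination fraction during F2 simulation.

:func:`generate_reference` additionally plants non-overlapping protein-coding
gene models (>=2 exons each, so canonical GT..AG splice sites exist), rewriting
the underlying sequence so that every CDS is a real open reading frame
(ATG start, no internal stop, terminal stop codon) and every intron carries
canonical splice dinucleotides. That makes the genome a valid substrate for
codon-level effect annotation, not just an interval bookkeeping exercise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: stop codons of the standard nuclear code
STOP_CODONS = ("TAA", "TAG", "TGA")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


class GenePackingError(ValueError):
    """Requested gene models do not fit on the requested chromosomes."""


@dataclass(frozen=True)
class Chromosome:
    name: str
    length_bp: int
    seq: str

    def __post_init__(self) -> None:
        if len(self.seq) != self.length_bp:
            raise ValueError(
                f"{self.name}: sequence length {len(self.seq)} != length_bp {self.length_bp}"
            )
        if set(self.seq) - set("ACGT"):
            raise ValueError(f"{self.name}: sequence contains non-ACGT characters")


@dataclass
class ToyGenome:
    """Multi-chromosome reference with a constant genetic-map density per chromosome.

    ``recomb_rate`` maps chromosome name -> cM per Mb (>= 0).
    """

    chromosomes: list[Chromosome]
    recomb_rate: dict[str, float]
    _index: dict[str, Chromosome] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {c.name: c for c in self.chromosomes}
        if len(self._index) != len(self.chromosomes):
            raise ValueError("duplicate chromosome names")
        for name in self._index:
            rate = self.recomb_rate.get(name)
            if rate is None:
                raise ValueError(f"no recombination rate for chromosome {name}")
            if rate < 0:
                raise ValueError(f"negative recombination rate for {name}")

    @classmethod
    def from_sequences(
        cls, sequences: dict[str, str], recomb_rate: float | dict[str, float] = 0.0
    ) -> "ToyGenome":
        if not isinstance(recomb_rate, dict):
            recomb_rate = {name: float(recomb_rate) for name in sequences}
        chroms = [Chromosome(n, len(s), s) for n, s in sequences.items()]
        return cls(chroms, recomb_rate)

    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def chrom(self, name: str) -> Chromosome:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"unknown chromosome {name!r}") from None

    def length(self, name: str) -> int:
        return self.chrom(name).length_bp

    def base(self, chrom: str, pos_1based: int) -> str:
        """Reference base at a 1-based position."""
        c = self.chrom(chrom)
        if not 1 <= pos_1based <= c.length_bp:
            raise ValueError(f"position {chrom}:{pos_1based} outside chromosome (1..{c.length_bp})")
        return c.seq[pos_1based - 1]

    def subseq(self, chrom: str, start_1based: int, end_1based: int) -> str:
        """Inclusive 1-based slice of a chromosome."""
        c = self.chrom(chrom)
        if not (1 <= start_1based <= end_1based <= c.length_bp):
            raise ValueError(f"bad interval {chrom}:{start_1based}-{end_1based}")
        return c.seq[start_1based - 1 : end_1based]

    def cm_between(self, chrom: str, pos_a: int, pos_b: int) -> float:
        """Genetic distance (cM) between two positions on one chromosome."""
        return abs(pos_a - pos_b) / 1e6 * self.recomb_rate[chrom]

    def gc_fraction(self) -> float:
        gc = total = 0
        for c in self.chromosomes:
            gc += c.seq.count("G") + c.seq.count("C")
            total += c.length_bp
        return gc / total


@dataclass
class GeneModel:
    """Single-transcript stranded gene model with 1-based inclusive intervals."""

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]

    def validate(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        for name, ivs in (("exons", self.exons), ("cds", self.cds)):
            if not ivs:
                raise ValueError(f"{self.gene_id}: empty {name}")
            for a, b in ivs:
                if a > b:
                    raise ValueError(f"{self.gene_id}: inverted {name} interval {a}-{b}")
            for (_, b0), (a1, _) in zip(ivs, ivs[1:]):
                if a1 <= b0:
                    raise ValueError(f"{self.gene_id}: overlapping/unsorted {name} intervals")
        for a, b in self.cds:
            if not any(ea <= a and b <= eb for ea, eb in self.exons):
                raise ValueError(f"{self.gene_id}: CDS {a}-{b} not contained in any exon")
        if self.cds_length % 3 != 0:
            raise ValueError(f"{self.gene_id}: CDS length {self.cds_length} not divisible by 3")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(b - a + 1 for a, b in self.cds)

    def introns(self) -> list[tuple[int, int]]:
        """Genomic intervals between consecutive exons (1-based inclusive)."""
        return [(b0 + 1, a1 - 1) for (_, b0), (a1, _) in zip(self.exons, self.exons[1:])]

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


def _nonstop_codons() -> list[str]:
    bases = "ACGT"
    return [
        a + b + c
        for a in bases
        for b in bases
        for c in bases
        if a + b + c not in STOP_CODONS
    ]


_NONSTOP = _nonstop_codons()


def _build_gene_structure(rng: np.random.Generator) -> tuple[list, list, int]:
    """Random exon/CDS layout in local transcript-forward coordinates.

    Returns (exon intervals, cds intervals, span) as 0-based half-open local
    intervals with the 5' UTR at local position 0.
    """
    n_ex = int(rng.integers(2, 5))
    exon_lens = rng.integers(90, 241, size=n_ex)
    intron_lens = rng.integers(60, 161, size=max(n_ex - 1, 0))
    u5 = int(rng.integers(20, 61))
    u3 = int(rng.integers(20, 61))
    coding = [int(x) for x in exon_lens]
    coding[0] -= u5
    coding[-1] -= u3
    rem = sum(coding) % 3
    coding[-1] -= rem
    u3 += rem

    exons, cds = [], []
    pos = 0
    for i, length in enumerate(int(x) for x in exon_lens):
        exons.append((pos, pos + length))
        s = pos + u5 if i == 0 else pos
        e = pos + length - u3 if i == n_ex - 1 else pos + length
        cds.append((s, e))
        pos += length
        if i < n_ex - 1:
            pos += int(intron_lens[i])
    return exons, cds, pos


def generate_reference(
    seed: int | None = None,
    n_chrom: int = 2,
    chrom_length_bp: int = 100_000,
    gc_content: float = 0.44,
    n_genes: int = 20,
    cm_per_chromosome: float = 100.0,
    rng: np.random.Generator | None = None,
) -> tuple[ToyGenome, list[GeneModel]]:
    """Generate a toy genome plus non-overlapping protein-coding gene models.

    Parameters
    ----------
    seed, rng
        Either a seed or an existing generator (``rng`` wins).
    n_chrom, chrom_length_bp
        Chromosome count and (uniform) physical length; >= 10 kb each.
    gc_content
        Target GC of the intergenic background sequence.
    n_genes
        Genes to place, distributed as evenly as possible over chromosomes.
    cm_per_chromosome
        Genetic length of each toy chromosome; the cM/Mb density stored on the
        genome is ``cm_per_chromosome / (chrom_length_bp / 1e6)``. Desk-scale
        chromosomes keep a realistic *genetic* length (about one Morgan) so
        linkage to a causal site decays over a few kilobases instead of
        spanning the whole chromosome.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    if chrom_length_bp < 10_000:
        raise ValueError("chrom_length_bp must be >= 10 kb")
    if not 0.0 < gc_content < 1.0:
        raise ValueError("gc_content must be in (0, 1)")

    p = np.array(
        [(1 - gc_content) / 2, gc_content / 2, gc_content / 2, (1 - gc_content) / 2]
    )
    base_bytes = np.frombuffer(b"ACGT", dtype=np.uint8)

    # even distribution of genes over chromosomes
    per_chrom = [n_genes // n_chrom] * n_chrom
    for i in range(n_genes % n_chrom):
        per_chrom[i] += 1

    chrom_names = [f"chr{i + 1:02d}" for i in range(n_chrom)]
    sequences: dict[str, np.ndarray] = {}
    genes: list[GeneModel] = []
    gid = 0
    for name, n_here in zip(chrom_names, per_chrom):
        arr = base_bytes[rng.choice(4, size=chrom_length_bp, p=p)].copy()
        cursor = int(rng.integers(150, 400))
        for _ in range(n_here):
            exons_l, cds_l, span = _build_gene_structure(rng)
            if cursor + span > chrom_length_bp - 150:
                raise GenePackingError(
                    f"gene gene{gid + 1:04d} (span {span} bp) does not fit on {name}: "
                    f"cursor {cursor}, length {chrom_length_bp}"
                )
            strand = "+" if rng.random() < 0.5 else "-"
            _write_gene_sequence(arr, cursor, span, strand, exons_l, cds_l, rng)
            genes.append(
                _to_genomic_model(f"gene{gid + 1:04d}", name, strand, cursor, span, exons_l, cds_l)
            )
            gid += 1
            cursor += span + int(rng.integers(150, 400))
        sequences[name] = arr

    chroms = [Chromosome(n, chrom_length_bp, s.tobytes().decode()) for n, s in sequences.items()]
    rate = cm_per_chromosome / (chrom_length_bp / 1e6)
    genome = ToyGenome(chroms, {n: rate for n in chrom_names})
    for g in genes:
        g.validate()
    return genome, genes


def _write_gene_sequence(arr, cursor, span, strand, exons_l, cds_l, rng) -> None:
    """Overwrite the chromosome so the gene has a real ORF and GT..AG introns."""
    cds_len = sum(e - s for s, e in cds_l)
    n_codons = cds_len // 3
    codon_idx = rng.integers(0, len(_NONSTOP), size=max(n_codons - 2, 0))
    cds_seq = "ATG" + "".join(_NONSTOP[i] for i in codon_idx) + STOP_CODONS[int(rng.integers(0, 3))]

    def put(local_x: int, base: str) -> None:
        # local transcript-forward coordinate -> genomic array index
        if strand == "+":
            arr[cursor + local_x] = ord(base)
        else:
            arr[cursor + span - 1 - local_x] = ord(base.translate(_COMPLEMENT))

    i = 0
    for s, e in cds_l:
        for x in range(s, e):
            put(x, cds_seq[i])
            i += 1
    # canonical splice dinucleotides, in transcript orientation
    for (_, e0), (s1, _) in zip(exons_l, exons_l[1:]):
        put(e0, "G")
        put(e0 + 1, "T")
        put(s1 - 2, "A")
        put(s1 - 1, "G")


def _to_genomic_model(gene_id, chrom, strand, cursor, span, exons_l, cds_l) -> GeneModel:
    def conv(ivs):
        out = []
        for a, b in ivs:  # 0-based half-open local -> 1-based inclusive genomic
            if strand == "+":
                out.append((cursor + a + 1, cursor + b))
            else:
                out.append((cursor + span - b + 1, cursor + span - a))
        return sorted(out)

    return GeneModel(gene_id, chrom, strand, conv(exons_l), conv(cds_l))
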