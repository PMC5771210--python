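"""Shared fixtures and the independent effect-classification oracle."""

from __future__ import annotations

import pytest
from Bio.Seq import Seq
from hypothesis import HealthCheck, settings

from allelicmap.annotation import Effect
from allelicmap.genome import GeneModel, ToyGenome, generate_reference, revcomp

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_ref() -> tuple[ToyGenome, list[GeneModel]]:
    """A 2 x 60 kb genome with 12 genes, reused across read-only tests."""
    return generate_reference(seed=101, n_chrom=2, chrom_length_bp=60_000, n_genes=12)


def coding_effect_oracle(genome: ToyGenome, gene: GeneModel, pos: int, alt: str) -> Effect:
    """Brute-force effect call: rebuild the whole mutant transcript and diff proteins.

    Deliberately shares no machinery with the annotator's codon arithmetic:
    it applies the SNV to the chromosome, re-extracts and (for minus-strand
    genes) reverse-complements the full CDS, translates both proteins with
    Biopython, and classifies from the first differing residue.
    """

    def transcript(chrom_seq: str) -> str:
        s = "".join(chrom_seq[a - 1 : b] for a, b in gene.cds)
        return s if gene.strand == "+" else revcomp(s)

    ref_seq = genome.chrom(gene.chrom).seq
    mut_seq = ref_seq[: pos - 1] + alt + ref_seq[pos:]
    p_ref = str(Seq(transcript(ref_seq)).translate())
    p_alt = str(Seq(transcript(mut_seq)).translate())
    if p_ref == p_alt:
        return Effect.SYNONYMOUS
    i = next(i for i, (a, b) in enumerate(zip(p_ref, p_alt)) if a != b)
    if i == 0 and p_ref[0] == "M":
        return Effect.START_LOSS
    if p_alt[i] == "*":
        return Effect.NONSENSE
    if p_ref[i] == "*":
        return Effect.STOP_LOSS
    return Effect.MISSENSE
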