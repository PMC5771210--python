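"""Simulation of EMS-mutagenized lines, segregating F2 populations, and pooled sequencing.

The generative model mirrors the assumptions of isogenic bulked-segregant
mapping (MutMap):

* a mutant line carries ~150 induced point mutations, overwhelmingly
  G:C -> A:T transitions (the EMS spectrum), all in coupling phase;
* the line is crossed to an isogenic wild type, so only the induced
  mutations (plus pre-existing parental background SNPs, fixed in both
  parents) segregate in the F2;
* meiosis is interference-free: crossovers between adjacent sites follow
  the recombination fraction given by Haldane's map function applied to the
  genetic map, and different chromosomes assort independently;
* homozygous-mutant F2 plants are selected on the causal locus and pooled;
* pooled sequencing draws a Poisson total depth per site and a binomial
  alternate-read count at the pool allele frequency, with an optional
  symmetric per-read error that flips allele identity.

Under this model, among plants selected homozygous at the causal locus every
gamete carries a site linked at recombination fraction r with probability
1 - r, so the expected SNP ratio at that site is 1 - r: exactly 1 at the
causal site, 0.5 at unlinked sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import LARGE_EFFECTS, Effect, EffectAnnotator
from .genome import GeneModel, ToyGenome

logger = logging.getLogger(__name__)

TRUTH_LABELS = ("causal", "linked", "unlinked", "parental_background", "error")

#: non-EMS alternate alleles available per reference base (EMS-type = G>A, C>T)
_NON_EMS_ALTS = {"A": "CGT", "C": "AG", "G": "CT", "T": "ACG"}


def _resolve_rng(rng: np.random.Generator | None, seed) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(seed)


@dataclass(frozen=True, order=True)
class Snv:
    """A single-nucleotide variant keyed by (chrom, 1-based pos, ref, alt)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


def is_ems_type(ref: str, alt: str) -> bool:
    """True for the canonical EMS changes: G>A, or C>T (its reverse-strand face)."""
    return (ref, alt) in (("G", "A"), ("C", "T"))


@dataclass
class InducedMutationSet:
    """The induced mutations of one mutagenized line (coupling phase)."""

    line_id: str
    mutations: list[Snv]
    ems_fraction: float

    def __post_init__(self) -> None:
        positions = [(m.chrom, m.pos) for m in self.mutations]
        if len(set(positions)) != len(positions):
            raise ValueError(f"{self.line_id}: duplicate mutation positions")

    def positions(self) -> set[tuple[str, int]]:
        return {(m.chrom, m.pos) for m in self.mutations}

    def with_mutation(self, snv: Snv) -> "InducedMutationSet":
        """Copy with ``snv`` added, replacing any mutation at the same position."""
        kept = [m for m in self.mutations if (m.chrom, m.pos) != (snv.chrom, snv.pos)]
        return InducedMutationSet(self.line_id, sorted(kept + [snv]), self.ems_fraction)


def induce_ems_mutations(
    genome: ToyGenome,
    n_mutations: int,
    ems_fraction: float = 1.0,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
    line_id: str = "mutant",
    avoid: set[tuple[str, int]] = frozenset(),
) -> InducedMutationSet:
    """Scatter ``n_mutations`` SNVs over the genome.

    Exactly ``round(ems_fraction * n_mutations)`` are EMS-type (G>A or C>T at
    reference G/C sites); the remainder are non-EMS substitutions so the
    downstream EMS-spectrum filter has something to remove.
    """
    rng = _resolve_rng(rng, seed)
    if not 0.0 <= ems_fraction <= 1.0:
        raise ValueError("ems_fraction must be in [0, 1]")
    if n_mutations < 0:
        raise ValueError("n_mutations must be >= 0")
    n_ems = int(round(ems_fraction * n_mutations))

    names = genome.names()
    lengths = np.array([genome.length(n) for n in names], dtype=float)
    gc_sites = sum(
        genome.chrom(n).seq.count("G") + genome.chrom(n).seq.count("C") for n in names
    )
    if gc_sites - len(avoid) < n_ems:
        raise ValueError(
            f"not enough G/C sites for {n_ems} EMS-type mutations (have {gc_sites})"
        )
    if lengths.sum() - len(avoid) < n_mutations:
        raise ValueError("n_mutations exceeds available sites")

    weights = lengths / lengths.sum()
    taken: set[tuple[str, int]] = set(avoid)
    ems: list[Snv] = []
    other: list[Snv] = []
    max_attempts = 1000 * max(n_mutations, 1) + 10_000
    attempts = 0
    while len(ems) < n_ems or len(other) < n_mutations - n_ems:
        attempts += 1
        if attempts > max_attempts:  # pragma: no cover - pathological genomes only
            raise RuntimeError("mutagenesis failed to place mutations; genome too constrained")
        chrom = names[int(rng.choice(len(names), p=weights))]
        pos = int(rng.integers(1, genome.length(chrom) + 1))
        if (chrom, pos) in taken:
            continue
        ref = genome.base(chrom, pos)
        if ref in "GC" and len(ems) < n_ems:
            alt = "A" if ref == "G" else "T"
            ems.append(Snv(chrom, pos, ref, alt))
            taken.add((chrom, pos))
        elif len(other) < n_mutations - n_ems:
            alts = _NON_EMS_ALTS[ref]
            alt = alts[int(rng.integers(0, len(alts)))]
            other.append(Snv(chrom, pos, ref, alt))
            taken.add((chrom, pos))
    return InducedMutationSet(line_id, sorted(ems + other), ems_fraction)


# ---------------------------------------------------------------------------
# genetic map


def map_distance_to_r(d_cm):
    """Haldane map function: r = (1 - exp(-2 d / 100)) / 2 for distance in cM.

    Interference-free crossovers; r approaches 0.5 as distance grows. Accepts
    scalars or arrays.
    """
    d = np.asarray(d_cm, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be >= 0")
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return float(r) if np.isscalar(d_cm) else r


def r_to_map_distance(r: float) -> float:
    """Inverse Haldane: cM distance giving recombination fraction ``r`` (< 0.5)."""
    if not 0.0 <= r < 0.5:
        raise ValueError("r must be in [0, 0.5)")
    return -50.0 * float(np.log(1.0 - 2.0 * r))


def expected_snp_ratio(r: float) -> float:
    """Expected pooled SNP ratio at recombination fraction ``r`` from the causal locus.

    Selection keeps only plants homozygous mutant at the causal locus, so each
    of their gametes carries the linked allele with probability 1 - r.
    """
    if not 0.0 <= r <= 0.5:
        raise ValueError("recombination fraction must be in [0, 0.5]")
    return 1.0 - r


# ---------------------------------------------------------------------------
# F2 simulation


@dataclass
class F2Population:
    """Diploid alt-allele dosages (plants x sites) for all segregating sites."""

    sites: list[Snv]
    dosages: np.ndarray  # shape (n_plants, n_sites), values 0/1/2
    causal_locus: tuple[str, int]
    map_function: str = "haldane"

    def __post_init__(self) -> None:
        if self.dosages.shape[1] != len(self.sites):
            raise ValueError("dosage matrix does not match site list")
        if not np.isin(self.dosages, (0, 1, 2)).all():
            raise ValueError("dosages must be 0, 1 or 2")

    @property
    def n_plants(self) -> int:
        return self.dosages.shape[0]

    def site_index(self, chrom: str, pos: int) -> int:
        for i, s in enumerate(self.sites):
            if (s.chrom, s.pos) == (chrom, pos):
                return i
        raise KeyError(f"no segregating site at {chrom}:{pos}")

    @property
    def causal_index(self) -> int:
        return self.site_index(*self.causal_locus)

    def pool_allele_frequencies(self) -> np.ndarray:
        """Mean dosage / 2 per site: the allele frequency of a balanced pool."""
        return self.dosages.mean(axis=0) / 2.0


def simulate_f2(
    genome: ToyGenome,
    mutation_set: InducedMutationSet,
    causal_locus: tuple[str, int],
    n_plants: int,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
) -> F2Population:
    """Simulate an F2 from (mutant line x isogenic wild type).

    The F1 is heterozygous at every induced site, with all mutant alleles on
    one homolog (coupling). Each F2 plant is two independent F1 gametes;
    within a gamete, adjacent sites on one chromosome recombine with the
    Haldane fraction for their map distance, and chromosomes assort
    independently.
    """
    rng = _resolve_rng(rng, seed)
    if causal_locus not in mutation_set.positions():
        raise ValueError(f"causal locus {causal_locus} is not an induced mutation")
    if n_plants < 1:
        raise ValueError("n_plants must be >= 1")

    order = {name: i for i, name in enumerate(genome.names())}
    sites = sorted(mutation_set.mutations, key=lambda m: (order[m.chrom], m.pos))
    n_sites = len(sites)
    n_gametes = 2 * n_plants
    haplo = np.empty((n_gametes, n_sites), dtype=bool)

    start = 0
    while start < n_sites:
        chrom = sites[start].chrom
        end = start
        while end < n_sites and sites[end].chrom == chrom:
            end += 1
        pos = np.array([s.pos for s in sites[start:end]])
        d_cm = np.diff(pos) / 1e6 * genome.recomb_rate[chrom]
        r = np.atleast_1d(map_distance_to_r(d_cm))
        u = rng.random((n_gametes, end - start))
        haplo[:, start] = u[:, 0] < 0.5
        for j in range(1, end - start):
            haplo[:, start + j] = haplo[:, start + j - 1] ^ (u[:, j] < r[j - 1])
        start = end

    dosages = haplo[0::2].astype(np.int8) + haplo[1::2].astype(np.int8)
    return F2Population(sites, dosages, causal_locus)


def select_homozygous_mutants(pop: F2Population, k: int) -> F2Population:
    """First ``k`` plants homozygous for the causal mutation."""
    if k < 0:
        raise ValueError("k must be >= 0")
    idx = np.flatnonzero(pop.dosages[:, pop.causal_index] == 2)
    if len(idx) < k:
        raise ValueError(
            f"only {len(idx)} homozygous-mutant plants available, need {k} "
            f"(shortfall {k - len(idx)}); simulate a larger F2"
        )
    return F2Population(pop.sites, pop.dosages[idx[:k]], pop.causal_locus, pop.map_function)


# ---------------------------------------------------------------------------
# pooled sequencing


@dataclass
class PoolSeqParams:
    """Pooled-sequencing model: 20 plants at ~15x with optional per-read error."""

    n_pooled: int = 20
    mean_depth: float = 15.0
    seq_error: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_pooled < 1:
            raise ValueError("n_pooled must be >= 1")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if not 0.0 <= self.seq_error < 0.5:
            raise ValueError("seq_error must be in [0, 0.5)")


def generate_parental_background(
    genome: ToyGenome,
    n_sites: int = 400,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
    ems_like_fraction: float = 0.5,
    avoid: set[tuple[str, int]] = frozenset(),
) -> tuple[list[Snv], pd.DataFrame]:
    """Pre-existing SNPs of the parental line relative to the reference.

    These are fixed in both cross parents, hence appear at allele frequency 1
    in the bulk, and (being shared across the whole mutant library) at high
    frequency in the population allele-frequency panel. Returns the site list
    plus a panel DataFrame (chrom, pos, ref, alt, af) with af ~ U(0.5, 1).

    ``ems_like_fraction`` of the sites are G>A / C>T look-alikes, so background
    subtraction (not the EMS-spectrum filter) is what must remove them.
    """
    rng = _resolve_rng(rng, seed)
    muts = induce_ems_mutations(
        genome,
        n_sites,
        ems_fraction=ems_like_fraction,
        rng=rng,
        line_id="parental_background",
        avoid=avoid,
    )
    sites = muts.mutations
    af = rng.uniform(0.5, 1.0, size=len(sites))
    panel = pd.DataFrame(
        {
            "chrom": [s.chrom for s in sites],
            "pos": [s.pos for s in sites],
            "ref": [s.ref for s in sites],
            "alt": [s.alt for s in sites],
            "af": np.round(af, 4),
        }
    )
    return sites, panel


def pool_and_sequence(
    pop: F2Population,
    params: PoolSeqParams,
    background: list[Snv] | None = None,
    *,
    rng: np.random.Generator | None = None,
    n_error_sites: int = 0,
    genome: ToyGenome | None = None,
) -> pd.DataFrame:
    """Sequence a balanced pool of the population's plants.

    Per site: ``total_depth ~ Poisson(mean_depth)`` and
    ``alt_depth ~ Binomial(total_depth, p')`` where ``p'`` folds the symmetric
    per-read error into the pool allele frequency
    (p' = p(1-e) + (1-p)e). Parental background sites are emitted at pool
    frequency 1; optional ``n_error_sites`` adds non-variant positions whose
    alternate reads arise purely from sequencing error (requires ``genome``).

    Returns a truth-labelled variant table with columns
    chrom, pos, ref, alt, total_depth, alt_depth, truth_label.
    """
    rng = _resolve_rng(rng, params.seed)
    causal_chrom, causal_pos = pop.causal_locus
    rows: list[tuple] = []

    freqs = pop.pool_allele_frequencies()
    for site, p in zip(pop.sites, freqs):
        if (site.chrom, site.pos) == (causal_chrom, causal_pos):
            label = "causal"
        elif site.chrom == causal_chrom:
            label = "linked"
        else:
            label = "unlinked"
        rows.append((site, float(p), label))

    for site in background or []:
        rows.append((site, 1.0, "parental_background"))

    if n_error_sites:
        if genome is None:
            raise ValueError("n_error_sites > 0 requires the genome")
        taken = {(s.chrom, s.pos) for s, _, _ in rows}
        err = induce_ems_mutations(
            genome, n_error_sites, ems_fraction=1.0, rng=rng,
            line_id="error", avoid=taken,
        )
        for site in err.mutations:
            rows.append((site, 0.0, "error"))

    e = params.seq_error
    total = rng.poisson(params.mean_depth, size=len(rows))
    p_obs = np.array([p * (1 - e) + (1 - p) * e for _, p, _ in rows])
    alt = rng.binomial(total, p_obs)

    df = pd.DataFrame(
        {
            "chrom": [s.chrom for s, _, _ in rows],
            "pos": [s.pos for s, _, _ in rows],
            "ref": [s.ref for s, _, _ in rows],
            "alt": [s.alt for s, _, _ in rows],
            "total_depth": total.astype(int),
            "alt_depth": alt.astype(int),
            "truth_label": [lab for _, _, lab in rows],
        }
    )
    df.sort_values(["chrom", "pos"], inplace=True, ignore_index=True)
    return df


# ---------------------------------------------------------------------------
# causal-site placement


def pick_large_effect_site(
    genome: ToyGenome,
    gene: GeneModel,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
    wanted: frozenset[Effect] = LARGE_EFFECTS,
    avoid: set[tuple[str, int]] = frozenset(),
) -> Snv:
    """An EMS-type SNV in ``gene`` whose effect class is in ``wanted``.

    Scans CDS and splice-window positions in random order for a G or C whose
    G>A / C>T change annotates to a wanted class; used to plant causal lesions
    (distinct ones per allelic population, via ``avoid``).
    """
    rng = _resolve_rng(rng, seed)
    annotator = EffectAnnotator(genome, [gene])
    candidates: list[int] = []
    for a, b in gene.cds:
        candidates.extend(range(a, b + 1))
    for istart, iend in gene.introns():
        candidates.extend([istart, istart + 1, iend - 1, iend])
    candidates = [p for p in dict.fromkeys(candidates) if (gene.chrom, p) not in avoid]
    for pos in rng.permutation(candidates):
        pos = int(pos)
        ref = genome.base(gene.chrom, pos)
        if ref not in "GC":
            continue
        alt = "A" if ref == "G" else "T"
        snv = Snv(gene.chrom, pos, ref, alt)
        for ann in annotator.annotate(snv):
            if ann.gene_id == gene.gene_id and ann.effect in wanted:
                return snv
    raise ValueError(
        f"no EMS-type site with effect in {sorted(e.value for e in wanted)} "
        f"found in {gene.gene_id}"
    )
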