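"""Allelic intersection and the supporting statistics.

The headline inference: two (or more) independent mutants with the same
phenotype are each mapped by bulked-segregant analysis, and their surviving
large-effect homozygous candidate genes are intersected. A gene hit by
distinct lesions in every population is, with overwhelming probability, the
causal gene: with ~147 deleterious mutations per line over ~34,000 genes the
per-gene hit rate is ~0.004, and an accidental double hit of one gene across
independent lines ~0.004^2 = 1.6e-5.

Also here: the 1:3 Mendelian segregation goodness-of-fit test used to confirm
single recessive mutants, the percent-reduction arithmetic used for the wax
phenotype table, and the per-chromosome SNP-ratio profile.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import AnnotatedVariant
from .genome import ToyGenome
from .simulate import expected_snp_ratio, map_distance_to_r

logger = logging.getLogger(__name__)


@dataclass
class CandidateSet:
    """Per-population surviving candidates grouped by gene."""

    population_id: str
    genes: dict[str, list[AnnotatedVariant]] = field(default_factory=dict)

    def gene_ids(self) -> set[str]:
        return set(self.genes)

    @property
    def n_variants(self) -> int:
        return sum(len(v) for v in self.genes.values())


def build_candidate_set(population_id: str, annotations: list[AnnotatedVariant]) -> CandidateSet:
    """Group a population's surviving annotated variants by gene (genic only)."""
    genes: dict[str, list[AnnotatedVariant]] = {}
    for a in annotations:
        if a.gene_id is None:
            continue
        genes.setdefault(a.gene_id, []).append(a)
    return CandidateSet(population_id, genes)


@dataclass
class IntersectionResult:
    """Genes with >= 1 surviving candidate in every population."""

    populations: list[str]
    genes: dict[str, dict[str, list[AnnotatedVariant]]]  # gene -> pop -> variants
    distinct_positions: dict[str, bool]

    def gene_ids(self) -> set[str]:
        return set(self.genes)

    def summary(self) -> pd.DataFrame:
        rows = []
        for gene, per_pop in sorted(self.genes.items()):
            for pop, variants in per_pop.items():
                for v in variants:
                    rows.append(
                        (gene, pop, v.chrom, v.pos, v.ref, v.alt, v.effect.value,
                         v.protein_change_str or "", self.distinct_positions[gene])
                    )
        return pd.DataFrame(
            rows,
            columns=["gene_id", "population", "chrom", "pos", "ref", "alt",
                     "effect", "protein_change", "distinct_positions"],
        )


def intersect_candidates(candidate_sets: list[CandidateSet]) -> IntersectionResult:
    """Genes present in all populations, with each population's lesion(s).

    Order of populations is irrelevant. A gene whose putatively independent
    alleles actually share a position is flagged (``distinct_positions``
    False) and a warning logged: identical lesions suggest shared ancestry or
    residual background, not independent confirmation.
    """
    if len(candidate_sets) < 2:
        raise ValueError("allelic intersection needs at least two candidate sets")
    pops = [c.population_id for c in candidate_sets]
    if len(set(pops)) != len(pops):
        raise ValueError("duplicate population ids")
    shared = set.intersection(*(c.gene_ids() for c in candidate_sets))
    genes: dict[str, dict[str, list[AnnotatedVariant]]] = {}
    distinct: dict[str, bool] = {}
    for gene in shared:
        per_pop = {c.population_id: list(c.genes[gene]) for c in candidate_sets}
        pos_sets = [{(v.chrom, v.pos) for v in vs} for vs in per_pop.values()]
        shared_positions = set.intersection(*pos_sets)
        distinct[gene] = not shared_positions
        if shared_positions:
            logger.warning(
                "gene %s: identical variant position(s) %s across populations; "
                "not independent alleles", gene, sorted(shared_positions),
            )
        genes[gene] = per_pop
    return IntersectionResult(pops, genes, distinct)


# ---------------------------------------------------------------------------
# mutation-rate arithmetic


def round_to_one_significant(x: float) -> float:
    """Round to one significant figure (0 stays 0)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))))


@dataclass
class MutationRateEstimate:
    """Per-gene, per-line deleterious mutation rate and its published rounding."""

    n_deleterious_per_line: float
    n_genes: int
    rate: float
    reported_rate: float

    def k_hit_probability(self, k: int = 2, as_published: bool = True) -> float:
        """Probability of k independent lines hitting one given gene by chance."""
        return multi_hit_probability(self.reported_rate if as_published else self.rate, k)


def gene_mutation_rate(n_deleterious_per_line: float, n_genes: int) -> MutationRateEstimate:
    """Chance rate of a given gene being hit in one line: mutations / genes."""
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    if n_deleterious_per_line < 0:
        raise ValueError("n_deleterious_per_line must be >= 0")
    rate = n_deleterious_per_line / n_genes
    if rate >= 1:
        raise ValueError("rate must be < 1; more mutations than genes")
    return MutationRateEstimate(
        n_deleterious_per_line, n_genes, rate, round_to_one_significant(rate)
    )


def multi_hit_probability(rate: float, k: int) -> float:
    """``rate ** k``: chance of k independent hits landing in the same gene."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    if k < 1:
        raise ValueError("k must be >= 1")
    return rate**k


# ---------------------------------------------------------------------------
# segregation test


@dataclass
class SegregationTest:
    n_mutant: int
    n_wt: int
    statistic: float
    pvalue: float
    df: int = 1
    expected_ratio: tuple[int, int] = (1, 3)


def segregation_test(
    n_mutant: int, n_wt: int, expected_ratio: tuple[int, int] = (1, 3)
) -> SegregationTest:
    """Chi-square goodness of fit of observed counts against 1 mutant : 3 WT.

    Plain Pearson statistic, df = 1, no continuity correction.
    """
    n = n_mutant + n_wt
    if n <= 0:
        raise ValueError("no plants scored")
    a, b = expected_ratio
    exp = np.array([a, b], dtype=float) * n / (a + b)
    stat, p = stats.chisquare([n_mutant, n_wt], f_exp=exp)
    return SegregationTest(n_mutant, n_wt, float(stat), float(p), 1, expected_ratio)


def percent_reduction(wt_value: float, mutant_value: float) -> float:
    """Percent reduction relative to wild type: (WT - mutant) / WT * 100."""
    if wt_value <= 0:
        raise ValueError("wild-type value must be positive")
    return (wt_value - mutant_value) / wt_value * 100.0


# ---------------------------------------------------------------------------
# SNP-ratio profile


def snp_ratio_profile(
    table: pd.DataFrame,
    genome: ToyGenome | None = None,
    causal_locus: tuple[str, int] | None = None,
) -> pd.DataFrame:
    """Ordered per-chromosome series of observed SNP ratios for plotting.

    Input is any frame with chrom, pos, total_depth, alt_depth. When the
    genome and the (simulated) causal locus are known, an ``expected`` column
    overlays 1 - r from the genetic map; sites on other chromosomes expect 0.5.
    Zero-depth sites yield NaN ratios.
    """
    if table.empty:
        cols = ["chrom", "pos", "snp_ratio"]
        if genome is not None and causal_locus is not None:
            cols.append("expected")
        return pd.DataFrame(columns=cols)
    df = table.loc[:, ["chrom", "pos", "total_depth", "alt_depth"]].copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        df["snp_ratio"] = np.where(
            df["total_depth"] > 0, df["alt_depth"] / df["total_depth"], np.nan
        )
    df = df.sort_values(["chrom", "pos"], ignore_index=True)
    if genome is not None and causal_locus is not None:
        c_chrom, c_pos = causal_locus
        exp = []
        for chrom, pos in zip(df["chrom"], df["pos"]):
            if chrom == c_chrom:
                r = map_distance_to_r(genome.cm_between(chrom, pos, c_pos))
                exp.append(expected_snp_ratio(min(float(r), 0.5)))
            else:
                exp.append(0.5)
        df["expected"] = exp
    return df.drop(columns=["total_depth", "alt_depth"])


def plot_ratio_profile(profile: pd.DataFrame, path) -> None:
    """Per-chromosome scatter of observed SNP ratio (and expected overlay) to file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = list(dict.fromkeys(profile["chrom"])) or ["(empty)"]
    fig, axes = plt.subplots(
        1, len(chroms), figsize=(4 * len(chroms), 3), sharey=True, squeeze=False
    )
    for ax, chrom in zip(axes[0], chroms):
        sub = profile[profile["chrom"] == chrom] if not profile.empty else profile
        if not sub.empty:
            ax.scatter(sub["pos"] / 1e3, sub["snp_ratio"], s=12, label="observed")
            if "expected" in sub:
                ax.plot(sub["pos"] / 1e3, sub["expected"], "r-", lw=1, label="expected 1-r")
        ax.set_title(chrom)
        ax.set_xlabel("position (kb)")
        ax.set_ylim(-0.05, 1.05)
    axes[0][0].set_ylabel("SNP ratio")
    axes[0][-1].legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
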