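"""The candidate-mutation filter cascade for a bulked homozygous-mutant pool.

Four row-wise predicates, applied in a fixed order with per-stage counts:

1. EMS spectrum — keep G>A / C>T SNVs (reference strand; C>T is the
   reverse-strand face of G>A);
2. read depth — keep sites supported by 5-100 reads (closed interval);
3. background subtraction — drop sites present in the parental line's own
   variant calls or at high frequency (>= 0.05) across the sequenced mutant
   library;
4. homozygosity — keep sites whose SNP ratio (alt reads / all reads) meets
   the cutoff, 1.0 by default, i.e. every read supports the mutant allele.

Because each stage is a pure predicate on one variant, the cascade output
equals the intersection of the individual filters; only the per-stage counts
in the report depend on the order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .simulate import is_ems_type

logger = logging.getLogger(__name__)


class UndefinedRatioError(ZeroDivisionError):
    """SNP ratio requested at a site with zero mapped reads."""


def compute_snp_ratio(alt_depth: int, total_depth: int) -> float:
    """SNP ratio: reads supporting the mutant allele over all mapped reads."""
    if total_depth <= 0:
        raise UndefinedRatioError("SNP ratio undefined at zero total depth")
    if not 0 <= alt_depth <= total_depth:
        raise ValueError(f"alt_depth {alt_depth} outside [0, {total_depth}]")
    return alt_depth / total_depth


@dataclass(frozen=True)
class VariantCall:
    """One pooled-sample variant call with its depth support."""

    chrom: str
    pos: int
    ref: str
    alt: str
    total_depth: int
    alt_depth: int

    def __post_init__(self) -> None:
        if self.total_depth < 0 or not 0 <= self.alt_depth <= self.total_depth:
            raise ValueError(
                f"{self.chrom}:{self.pos}: alt_depth {self.alt_depth} / "
                f"total_depth {self.total_depth} inconsistent"
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def snp_ratio(self) -> float:
        return compute_snp_ratio(self.alt_depth, self.total_depth)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


def calls_from_table(df: pd.DataFrame) -> list[VariantCall]:
    """VariantCalls from a simulator variant table (or any frame with the columns)."""
    return [
        VariantCall(str(r.chrom), int(r.pos), str(r.ref), str(r.alt),
                    int(r.total_depth), int(r.alt_depth))
        for r in df.itertuples(index=False)
    ]


@dataclass
class FilterConfig:
    """Defaults reproduce the published cascade: depth 5-100, ratio cutoff 1, af >= 0.05."""

    min_depth: int = 5
    max_depth: int = 100
    ratio_cutoff: float = 1.0
    af_threshold: float = 0.05
    ems_only: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.min_depth <= self.max_depth:
            raise ValueError("need 0 < min_depth <= max_depth")
        if not 0.0 < self.ratio_cutoff <= 1.0:
            raise ValueError("ratio_cutoff must be in (0, 1]")
        if not 0.0 <= self.af_threshold <= 1.0:
            raise ValueError("af_threshold must be in [0, 1]")


@dataclass
class BackgroundPanel:
    """Parental variant keys plus population allele frequencies for subtraction."""

    parental: frozenset[tuple[str, int, str, str]] = frozenset()
    population_af: dict[tuple[str, int, str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = [k for k, v in self.population_af.items() if not 0.0 <= v <= 1.0]
        if bad:
            raise ValueError(f"allele frequencies outside [0, 1] for {bad[:3]}")

    def __len__(self) -> int:
        return len(self.parental | set(self.population_af))


@dataclass(frozen=True)
class StageCount:
    stage: str
    n_in: int
    n_out: int

    def __post_init__(self) -> None:
        if self.n_out > self.n_in:
            raise ValueError(f"stage {self.stage}: output {self.n_out} exceeds input {self.n_in}")


@dataclass
class FilterReport:
    """Ordered per-stage candidate counts (the funnel)."""

    stages: list[StageCount]

    def __post_init__(self) -> None:
        for a, b in zip(self.stages, self.stages[1:]):
            if b.n_in != a.n_out:
                raise ValueError(
                    f"stage {b.stage} input {b.n_in} != previous stage output {a.n_out}"
                )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.stage, s.n_in, s.n_out) for s in self.stages],
            columns=["stage", "n_in", "n_out"],
        )

    @property
    def n_final(self) -> int:
        return self.stages[-1].n_out if self.stages else 0


# ---------------------------------------------------------------------------
# individual filters


def filter_ems_type(variants: Iterable[VariantCall]) -> list[VariantCall]:
    """Keep EMS-spectrum SNVs (G>A, C>T); non-SNV records are skipped with a warning."""
    out = []
    for v in variants:
        if not v.is_snv:
            logger.warning("skipping non-SNV record at %s:%s (%s>%s)", v.chrom, v.pos, v.ref, v.alt)
            continue
        if is_ems_type(v.ref, v.alt):
            out.append(v)
    return out


def filter_depth(
    variants: Iterable[VariantCall], min_depth: int = 5, max_depth: int = 100
) -> list[VariantCall]:
    """Keep variants supported by min_depth..max_depth reads, inclusive."""
    if min_depth > max_depth:
        raise ValueError("min_depth must be <= max_depth")
    return [v for v in variants if min_depth <= v.total_depth <= max_depth]


def filter_homozygous(
    variants: Iterable[VariantCall], ratio_cutoff: float = 1.0
) -> list[VariantCall]:
    """Keep variants with SNP ratio >= cutoff; zero-depth sites cannot qualify."""
    out = []
    for v in variants:
        if v.total_depth == 0:
            logger.warning("zero-depth site %s:%s has no ratio; dropped", v.chrom, v.pos)
            continue
        if v.snp_ratio >= ratio_cutoff:
            out.append(v)
    return out


def subtract_background(
    variants: Iterable[VariantCall],
    panel: BackgroundPanel,
    af_threshold: float = 0.05,
) -> list[VariantCall]:
    """Drop parental variants and library variants at frequency >= threshold.

    Variants absent from both panel components are retained.
    """
    out = []
    for v in variants:
        if v.key in panel.parental:
            continue
        af = panel.population_af.get(v.key)
        if af is not None and af >= af_threshold:
            continue
        out.append(v)
    return out


def run_filter_cascade(
    variants: Sequence[VariantCall],
    config: FilterConfig | None = None,
    panel: BackgroundPanel | None = None,
) -> tuple[list[VariantCall], FilterReport]:
    """EMS spectrum -> depth -> background subtraction -> homozygosity."""
    config = config or FilterConfig()
    panel = panel or BackgroundPanel()
    stages: list[StageCount] = []
    cur = list(variants)

    if config.ems_only:
        nxt = filter_ems_type(cur)
        stages.append(StageCount("ems_type", len(cur), len(nxt)))
        cur = nxt
    nxt = filter_depth(cur, config.min_depth, config.max_depth)
    stages.append(StageCount("depth", len(cur), len(nxt)))
    cur = nxt
    nxt = subtract_background(cur, panel, config.af_threshold)
    stages.append(StageCount("background", len(cur), len(nxt)))
    cur = nxt
    nxt = filter_homozygous(cur, config.ratio_cutoff)
    stages.append(StageCount("homozygous", len(cur), len(nxt)))
    cur = nxt

    report = FilterReport(stages)
    for s in stages:
        logger.info("filter stage %-12s %6d -> %d", s.stage, s.n_in, s.n_out)
    return cur, report
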