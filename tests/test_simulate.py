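"""EMS mutagenesis, F2 meiosis, pooled sequencing, and the expected-ratio model."""

import numpy as np
import pandas as pd
import pytest

from allelicmap.annotation import LARGE_EFFECTS, EffectAnnotator
from allelicmap.genome import ToyGenome
from allelicmap.simulate import (
    InducedMutationSet,
    PoolSeqParams,
    Snv,
    expected_snp_ratio,
    generate_parental_background,
    induce_ems_mutations,
    is_ems_type,
    map_distance_to_r,
    pick_large_effect_site,
    pool_and_sequence,
    r_to_map_distance,
    select_homozygous_mutants,
    simulate_f2,
)


# ---------------------------------------------------------------------------
# mutagenesis


class TestEmsMutagenesis:
    def test_pure_ems_spectrum_sits_on_gc_sites(self, small_ref):
        genome, _ = small_ref
        muts = induce_ems_mutations(genome, 147, ems_fraction=1.0, seed=2)
        assert len(muts.mutations) == 147
        for m in muts.mutations:
            assert genome.base(m.chrom, m.pos) == m.ref
            assert m.ref in "GC"
            assert is_ems_type(m.ref, m.alt)

    def test_ems_quota_is_exact(self, small_ref):
        genome, _ = small_ref
        muts = induce_ems_mutations(genome, 100, ems_fraction=0.9, seed=3)
        n_ems = sum(is_ems_type(m.ref, m.alt) for m in muts.mutations)
        assert n_ems == 90
        assert len(muts.mutations) - n_ems == 10

    def test_zero_mutations_gives_empty_set(self, small_ref):
        genome, _ = small_ref
        assert induce_ems_mutations(genome, 0, seed=1).mutations == []

    def test_positions_are_unique_and_avoid_is_respected(self, small_ref):
        genome, _ = small_ref
        avoid = {("chr01", 17), ("chr02", 99)}
        muts = induce_ems_mutations(genome, 300, ems_fraction=0.8, seed=4, avoid=avoid)
        positions = muts.positions()
        assert len(positions) == 300
        assert not positions & avoid

    def test_demand_beyond_available_sites_raises(self):
        genome = ToyGenome.from_sequences({"c1": "ATATATAT"}, recomb_rate=1.0)
        with pytest.raises(ValueError):
            induce_ems_mutations(genome, 2, ems_fraction=1.0, seed=1)  # no G/C at all

    def test_duplicate_positions_rejected_by_the_container(self):
        with pytest.raises(ValueError):
            InducedMutationSet("x", [Snv("c", 5, "G", "A"), Snv("c", 5, "C", "T")], 1.0)


# ---------------------------------------------------------------------------
# genetic map and ratio model


class TestMapFunction:
    def test_haldane_closed_form(self):
        assert map_distance_to_r(0.0) == 0.0
        assert map_distance_to_r(50.0) == pytest.approx(0.3161, abs=1e-4)
        assert map_distance_to_r(1e6) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            map_distance_to_r(-1.0)

    def test_inverse_roundtrip(self):
        for r in (0.0, 0.05, 0.25, 0.49):
            assert map_distance_to_r(r_to_map_distance(r)) == pytest.approx(r)

    @pytest.mark.parametrize("r,expected", [(0.0, 1.0), (0.5, 0.5), (0.25, 0.75)])
    def test_expected_snp_ratio_is_one_minus_r(self, r, expected):
        assert expected_snp_ratio(r) == pytest.approx(expected)

    @pytest.mark.parametrize("r", [-0.01, 0.51])
    def test_expected_snp_ratio_rejects_invalid_r(self, r):
        with pytest.raises(ValueError):
            expected_snp_ratio(r)


# ---------------------------------------------------------------------------
# F2 simulation


def _flat_genome(n_chrom=2, length=200_000, rate=0.0):
    seqs = {f"c{i}": "ACGT" * (length // 4) for i in range(1, n_chrom + 1)}
    return ToyGenome.from_sequences(seqs, recomb_rate=rate)


class TestF2Simulation:
    def test_single_site_segregates_one_two_one(self):
        genome = _flat_genome(1, rate=2.0)
        muts = InducedMutationSet("m", [Snv("c1", 1000, "A", "T")], 0.0)
        pop = simulate_f2(genome, muts, ("c1", 1000), 10_000, seed=11)
        n = pop.n_plants
        counts = np.bincount(pop.dosages[:, 0], minlength=3)
        for k, p in [(0, 0.25), (1, 0.5), (2, 0.25)]:
            se = np.sqrt(p * (1 - p) / n)
            assert abs(counts[k] / n - p) < 3 * se

    def test_fully_linked_site_cosegregates_with_causal(self):
        genome = _flat_genome(1, rate=0.0)  # r = 0 everywhere on the chromosome
        muts = InducedMutationSet(
            "m", [Snv("c1", 1000, "A", "T"), Snv("c1", 150_000, "G", "A")], 0.0
        )
        pop = simulate_f2(genome, muts, ("c1", 1000), 500, seed=12)
        assert (pop.dosages[:, 0] == pop.dosages[:, 1]).all()

    def test_unlinked_chromosomes_assort_independently(self):
        genome = _flat_genome(2, rate=0.0)
        muts = InducedMutationSet(
            "m", [Snv("c1", 1000, "A", "T"), Snv("c2", 1000, "A", "T")], 0.0
        )
        pop = simulate_f2(genome, muts, ("c1", 1000), 8_000, seed=13)
        hom = pop.dosages[pop.dosages[:, 0] == 2]
        # among causal homozygotes the other chromosome still segregates 1:2:1
        frac_het = (hom[:, 1] == 1).mean()
        se = np.sqrt(0.5 * 0.5 / len(hom))
        assert abs(frac_het - 0.5) < 3 * se

    def test_causal_must_be_an_induced_mutation(self):
        genome = _flat_genome(1)
        muts = InducedMutationSet("m", [Snv("c1", 1000, "A", "T")], 0.0)
        with pytest.raises(ValueError):
            simulate_f2(genome, muts, ("c1", 999), 10, seed=1)


class TestSelection:
    @pytest.fixture()
    def f2(self):
        genome = _flat_genome(2, rate=2.0)
        muts = InducedMutationSet(
            "m", [Snv("c1", 1000, "A", "T"), Snv("c2", 5000, "G", "A")], 0.0
        )
        return simulate_f2(genome, muts, ("c1", 1000), 120, seed=21)

    def test_selected_plants_are_all_homozygous_causal(self, f2):
        sel = select_homozygous_mutants(f2, 20)
        assert sel.n_plants == 20
        assert (sel.dosages[:, sel.causal_index] == 2).all()
        assert sel.pool_allele_frequencies()[sel.causal_index] == 1.0

    def test_zero_selection_is_empty(self, f2):
        assert select_homozygous_mutants(f2, 0).n_plants == 0

    def test_shortfall_is_reported(self, f2):
        with pytest.raises(ValueError, match="shortfall"):
            select_homozygous_mutants(f2, 1000)


# ---------------------------------------------------------------------------
# pooled sequencing


class TestPooledSequencing:
    @pytest.fixture()
    def bulk(self, small_ref):
        genome, _ = small_ref
        muts = induce_ems_mutations(genome, 120, seed=31)
        causal = muts.mutations[0]
        pop = simulate_f2(genome, muts, (causal.chrom, causal.pos), 160, seed=32)
        sel = select_homozygous_mutants(pop, 20)
        background, _ = generate_parental_background(
            genome, 50, seed=33, avoid=muts.positions()
        )
        return genome, sel, background

    def test_error_free_causal_site_has_ratio_one(self, bulk):
        _, sel, background = bulk
        table = pool_and_sequence(sel, PoolSeqParams(seed=34), background)
        causal = table[table.truth_label == "causal"]
        assert len(causal) == 1
        row = causal.iloc[0]
        assert row.alt_depth == row.total_depth > 0

    def test_truth_labels_partition_all_emitted_sites(self, bulk):
        _, sel, background = bulk
        table = pool_and_sequence(sel, PoolSeqParams(seed=34), background)
        assert set(table.truth_label) <= {"causal", "linked", "unlinked", "parental_background"}
        emitted = set(zip(table.chrom, table.pos))
        induced = {(s.chrom, s.pos) for s in sel.sites}
        parental = {(s.chrom, s.pos) for s in background}
        assert emitted == induced | parental
        assert len(table) == len(induced) + len(parental)
        assert (table[table.truth_label == "parental_background"].groupby(["chrom", "pos"]).size() == 1).all()

    def test_unlinked_sites_average_near_half(self, bulk):
        _, sel, background = bulk
        table = pool_and_sequence(sel, PoolSeqParams(seed=34), background)
        unlinked = table[table.truth_label == "unlinked"]
        ratios = unlinked.alt_depth / unlinked.total_depth
        assert abs(ratios.mean() - 0.5) < 3 * ratios.std() / np.sqrt(len(ratios))

    def test_parental_background_reads_are_all_alternate(self, bulk):
        _, sel, background = bulk
        table = pool_and_sequence(sel, PoolSeqParams(seed=34), background)
        par = table[table.truth_label == "parental_background"]
        assert (par.alt_depth == par.total_depth).all()

    def test_same_seed_reproduces_the_table(self, bulk):
        _, sel, background = bulk
        t1 = pool_and_sequence(sel, PoolSeqParams(seed=99), background)
        t2 = pool_and_sequence(sel, PoolSeqParams(seed=99), background)
        pd.testing.assert_frame_equal(t1, t2)

    def test_sequencing_error_perturbs_fixed_sites(self, bulk):
        _, sel, background = bulk
        table = pool_and_sequence(sel, PoolSeqParams(seq_error=0.1, seed=35), background)
        par = table[table.truth_label == "parental_background"]
        frac = par.alt_depth.sum() / par.total_depth.sum()
        assert 0.85 < frac < 0.95  # expected 0.9 under a 10% symmetric flip


# ---------------------------------------------------------------------------
# causal-site placement


def test_pick_large_effect_site_is_ems_type_and_large_effect(small_ref):
    genome, genes = small_ref
    gene = genes[0]
    snv = pick_large_effect_site(genome, gene, seed=41)
    assert is_ems_type(snv.ref, snv.alt)
    annotator = EffectAnnotator(genome, [gene])
    effects = {a.effect for a in annotator.annotate(snv) if a.gene_id == gene.gene_id}
    assert effects & LARGE_EFFECTS
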