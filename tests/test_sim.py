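"""Breeding/methylation/sequence/coverage generator unit tests."""

import numpy as np
import pytest

from vmiap.sim import (
    BedElement,
    EnrichmentSpec,
    MethylationModel,
    MotifSpec,
    Strain,
    assign_methylation,
    breed_backcross,
    cast_fraction,
    cross,
    default_genome,
    enrichment_block,
    evolve_ltr_family,
    genotype_individual,
    meiosis,
    simulate_founder,
    synth_coverage,
)
from vmiap.sim.ltr import reverse_complement
from vmiap.methylation import threshold_classify


class TestFounders:
    def test_founder_purity(self, genome):
        b6 = simulate_founder("B6", genome)
        for h0, h1 in b6.haplotypes.values():
            assert set(h0.strains) == {Strain.B6}
            assert set(h1.strains) == {Strain.B6}
        assert b6.modifier_alleles == 0

    def test_cast_founder_carries_modifier(self, genome):
        assert simulate_founder("CAST", genome).modifier_alleles == 2

    def test_unknown_strain_rejected(self, genome):
        with pytest.raises(ValueError, match="unknown strain"):
            simulate_founder("DBA", genome)

    def test_f1_heterozygous_at_every_marker(self, genome, rng):
        dam = simulate_founder("B6", genome, "d")
        sire = simulate_founder("CAST", genome, "s", "M")
        (f1,) = cross(dam, sire, 1, genome, rng)
        calls = genotype_individual(f1, genome)
        for chrom_calls in calls.values():
            assert np.all(chrom_calls == 1)


class TestMeiosis:
    def test_zero_genetic_length_transmits_whole_haplotype(self, small_genome, rng):
        import dataclasses

        spec = dataclasses.replace(small_genome.chromosomes[0], genetic_length_morgans=0.0)
        g = dataclasses.replace(small_genome, chromosomes=[spec])
        dam = simulate_founder("B6", g, "d")
        sire = simulate_founder("CAST", g, "s", "M")
        (f1,) = cross(dam, sire, 1, g, rng)
        gam = meiosis(f1, g, rng)["chr4"]
        assert len(gam.strains) == 1  # intact parental haplotype

    def test_homozygous_parent_gamete_equals_painting(self, genome, rng):
        b6 = simulate_founder("B6", genome)
        gam = meiosis(b6, genome, rng)
        for chrom, painting in gam.items():
            assert set(painting.strains) == {Strain.B6}
            assert painting.length == genome.chromosome(chrom).length_bp

    def test_poisson_crossover_mean(self, rng):
        """At 1 Morgan the mean realized crossover count is within 3 SE of 1.

        For an F1 parent every crossover switches strain of origin, so the
        number of painting switches equals the crossover count.
        """
        import dataclasses

        g = default_genome()
        spec = dataclasses.replace(g.chromosomes[0], genetic_length_morgans=1.0)
        n = 10_000
        dam = simulate_founder("B6", g, "d")
        sire = simulate_founder("CAST", g, "s", "M")
        (f1,) = cross(dam, sire, 1, g, np.random.default_rng(0))
        gdash = dataclasses.replace(g, chromosomes=[spec] + g.chromosomes[1:])
        xo = [len(meiosis(f1, gdash, rng)[spec.name].strains) - 1 for _ in range(n)]
        se = np.std(xo, ddof=1) / np.sqrt(n)
        assert abs(np.mean(xo) - 1.0) < 3 * se

    def test_paintings_tile_chromosome(self, genome, rng):
        dam = simulate_founder("B6", genome, "d")
        sire = simulate_founder("CAST", genome, "s", "M")
        (f1,) = cross(dam, sire, 1, genome, rng)
        for _ in range(50):
            for chrom, p in meiosis(f1, genome, rng).items():
                assert p.ends[-1] == genome.chromosome(chrom).length_bp
                assert np.all(np.diff(p.ends) > 0)


class TestCross:
    def test_f1_family_metadata(self, genome, rng):
        dam = simulate_founder("B6", genome, "d")
        sire = simulate_founder("CAST", genome, "s", "M")
        kids = cross(dam, sire, 5, genome, rng)
        assert len(kids) == 5
        assert all(k.generation == "F1" for k in kids)
        assert all(k.dam_strain == "B6" for k in kids)
        assert all(k.modifier_alleles == 1 for k in kids)

    def test_mendelian_carrier_fraction(self, small_genome, rng):
        dam = simulate_founder("B6", small_genome, "d")
        sire = simulate_founder("CAST", small_genome, "s", "M")
        (f1,) = cross(dam, sire, 1, small_genome, rng)
        f1.sex = "M"
        n = 10_000
        kids = cross(dam, f1, n, small_genome, rng)
        frac = np.mean([k.modifier_alleles >= 1 for k in kids])
        se = np.sqrt(0.25 / n)
        assert abs(frac - 0.5) < 3 * se

    def test_noncarrier_cross_gives_no_carriers(self, small_genome, rng):
        dam = simulate_founder("B6", small_genome, "d")
        sire = simulate_founder("B6", small_genome, "s", "M")
        kids = cross(dam, sire, 20, small_genome, rng)
        assert all(k.modifier_alleles == 0 for k in kids)

    def test_backcross_cast_fraction_halves(self, genome):
        """Expected CAST genome fraction: N1 25%, N2 12.5%, N3 6.25%."""
        rng = np.random.default_rng(5)
        ped = breed_backcross(genome, rng, n_n1=60, n_n2_per_family=10, n_n3=60)
        for gen, expected in (("N1", 0.25), ("N2", 0.125), ("N3", 0.0625)):
            fr = np.array([cast_fraction(i, genome) for i in ped.by_generation(gen)])
            se = fr.std(ddof=1) / np.sqrt(fr.size)
            assert abs(fr.mean() - expected) < 3 * se + 1e-9

    def test_genotype_recoverable_from_paintings(self, genome, rng):
        ped = breed_backcross(genome, rng, n_n3=10)
        carrier_code = Strain.code(genome.modifier_strain)
        for ind in list(ped)[:20]:
            calls = genotype_individual(ind, genome)
            for chrom, pos_arr in genome.marker_positions.items():
                h0, h1 = ind.haplotypes[chrom]
                for j, pos in enumerate(pos_arr[::7]):  # subsample for speed
                    expect = int(h0.ancestry_at(pos) == carrier_code) + int(
                        h1.ancestry_at(pos) == carrier_code
                    )
                    assert calls[chrom][::7][j] == expect

    def test_fixed_seed_reproducibility(self, genome):
        out = []
        for _ in range(2):
            rng = np.random.default_rng(123)
            ped = breed_backcross(genome, rng, n_n3=5)
            out.append(
                [(i.id, i.modifier_alleles, tuple(map(tuple, (h.ends for h in i.haplotypes["chr4"]))))
                 for i in ped]
            )
        assert out[0] == out[1]


class TestMethylationModel:
    def test_noncarrier_draws_baseline(self, small_genome, rng):
        ind = simulate_founder("B6", small_genome)
        model = MethylationModel(effect_mode="zygotic")
        draws = np.array([assign_methylation(ind, model, rng).mean() for _ in range(500)])
        assert abs(draws.mean() - 45.0) < 2.0  # Beta(9,11) mean

    def test_carrier_classified_high(self, small_genome, rng):
        """Non-overlapping index model: carriers above the 60% cutoff with
        probability > 0.99."""
        dam = simulate_founder("B6", small_genome, "d")
        sire = simulate_founder("CAST", small_genome, "s", "M")
        (f1,) = cross(dam, sire, 1, small_genome, rng)
        model = MethylationModel(
            baseline=(54.0, 66.0), high_state=(96.0, 24.0), effect_mode="zygotic"
        )
        highs = [
            threshold_classify(assign_methylation(f1, model, rng).mean()) == "high"
            for _ in range(1000)
        ]
        assert np.mean(highs) > 0.99

    def test_zero_noise_gives_identical_cpgs(self, small_genome, rng):
        ind = simulate_founder("B6", small_genome)
        model = MethylationModel(measurement_noise_sd=0.0, n_cpgs=4)
        vals = assign_methylation(ind, model, rng)
        assert len(vals) == 4
        assert np.all(vals == vals[0])

    def test_maternal_mode_follows_dam_strain(self, small_genome, rng):
        dam = simulate_founder("CAST", small_genome, "d")
        sire = simulate_founder("B6", small_genome, "s", "M")
        (cb,) = cross(dam, sire, 1, small_genome, rng)
        model = MethylationModel(effect_mode="maternal", measurement_noise_sd=0.0)
        vals = np.array([assign_methylation(cb, model, rng).mean() for _ in range(200)])
        assert vals.mean() > 70  # high state

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="unknown effect mode"):
            MethylationModel(effect_mode="paternal")


class TestLtrFamily:
    def test_zero_rates_give_consensus_targets(self):
        rng = np.random.default_rng(0)
        spec = MotifSpec(clade_divergence=0.0, leaf_divergence=0.0,
                         background_divergence=0.0, revcomp_prob=0.0)
        fam = evolve_ltr_family(3, 1, 1, spec, rng)
        targets = [r.seq for r in fam if r.label == "VM"]
        background = [r.seq for r in fam if r.label == "background"]
        assert targets[0] == targets[1] == targets[2] == background[0]

    def test_nontarget_length_includes_insertion(self):
        rng = np.random.default_rng(1)
        spec = MotifSpec(revcomp_prob=0.0)
        fam = evolve_ltr_family(1, 2, 0, spec, rng)
        for r in fam:
            expected = spec.consensus_length + (spec.insertion_length if r.label == "nontarget" else 0)
            assert len(r.seq) == expected

    def test_vm_clade_closer_than_background(self):
        from vmiap.targets import percent_identity

        rng = np.random.default_rng(2)
        fam = evolve_ltr_family(4, 2, 4, MotifSpec(revcomp_prob=0.0), rng)
        vm = [r.seq for r in fam if r.label in ("VM", "nontarget")]
        bg = [r.seq for r in fam if r.label == "background"]
        within = np.mean(
            [percent_identity(a, b) for i, a in enumerate(vm) for b in vm[i + 1:]]
        )
        across = np.mean([percent_identity(a, b) for a in vm for b in bg])
        assert within > across

    def test_orientation_flag_matches_sequence(self):
        rng = np.random.default_rng(3)
        spec = MotifSpec(leaf_divergence=0.0, clade_divergence=0.0, revcomp_prob=1.0)
        fam = evolve_ltr_family(2, 0, 0, spec, rng)
        # both targets identical pre-orientation; flags say '-'
        assert all(r.orientation == "-" for r in fam)
        assert reverse_complement(fam[0].seq) == reverse_complement(fam[1].seq)

    def test_disruption_must_edit_segment(self):
        with pytest.raises(ValueError, match="at least one position"):
            MotifSpec(insertion_length=0, substitution_offsets=())


class TestCoverage:
    def test_zero_enrichment_is_pure_background(self):
        els = [BedElement("c", 100, 200, "e", 0, "+")]
        spec = EnrichmentSpec(enrichment_height=0.0)
        t1 = synth_coverage(els, {"c": 400}, spec, np.random.default_rng(9))
        t2 = {"c": np.random.default_rng(9).poisson(spec.background_mean, 400).astype(float)}
        assert np.array_equal(t1["c"], t2["c"])

    def test_minus_strand_block_abuts_lower_end(self):
        el = BedElement("c", 1000, 2000, "e", 0, "-")
        lo, hi = enrichment_block(el, 0.4)
        assert lo == 1000 and hi == 1400

    def test_plus_strand_block_abuts_upper_end(self):
        el = BedElement("c", 1000, 2000, "e", 0, "+")
        assert enrichment_block(el, 0.4) == (1600, 2000)

    def test_block_additivity(self):
        els = [BedElement("c", 500, 1500, "e", 0, "+")]
        spec = EnrichmentSpec(background_mean=5.0, enrichment_height=20.0,
                              three_prime_fraction=0.5)
        track = synth_coverage(els, {"c": 2000}, spec, np.random.default_rng(4))
        block = track["c"][1000:1500]
        assert abs(block.mean() - (5.0 + 20.0)) < 3 * np.sqrt(5.0 / 500)
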