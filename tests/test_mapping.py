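"""SNP-intersection mapping, intervals, segregation and pedigree rules."""

import numpy as np
import pandas as pd
import pytest

from vmiap.mapping import (
    CALL_HET,
    CALL_HOM_B6,
    CALL_MISSING,
    GenomicInterval,
    GenotypeMatrix,
    MappingConflictError,
    assemble_interval,
    candidate_snps,
    combine_experiments,
    interval_length_mb,
    pedigree_consistency,
    segregation_test,
)
from vmiap.sim import breed_backcross, default_genome
from vmiap.sim.io import genotype_frame

CALLS = {0: "BB", 1: "BC", 2: "CC", -1: "NA"}


def matrix_from_codes(codes, individuals, positions=None, chrom="chr1"):
    codes = np.asarray(codes, dtype=np.int8)
    n_markers = codes.shape[0]
    positions = positions if positions is not None else (np.arange(n_markers) + 1) * 1000
    markers = pd.DataFrame(
        {"chrom": [chrom] * n_markers, "pos": positions,
         "marker": [f"m{i}" for i in range(n_markers)]}
    )
    return GenotypeMatrix(markers, codes, individuals)


def oracle_filter(codes, high_idx, low_idx):
    """Explicit double loop over markers and individuals."""
    keep = []
    for m in range(codes.shape[0]):
        ok = all(codes[m, i] == CALL_HET for i in high_idx) and all(
            codes[m, i] == CALL_HOM_B6 for i in low_idx
        )
        missing = any(codes[m, i] == CALL_MISSING for i in high_idx + low_idx)
        keep.append(ok and not missing)
    return np.array(keep)


class TestCandidateSnps:
    def test_perfect_cosegregation_retained(self):
        codes = [[1, 1, 1, 0, 0, 0]]
        m = matrix_from_codes(codes, list("abcdef"))
        labels = dict(zip("abcdef", ["high"] * 3 + ["low"] * 3))
        cands, _ = candidate_snps(m, labels)
        assert list(cands["marker"]) == ["m0"]

    def test_one_discordant_low_rejects(self):
        codes = [[1, 1, 1, 1, 0, 0]]
        m = matrix_from_codes(codes, list("abcdef"))
        labels = dict(zip("abcdef", ["high"] * 3 + ["low"] * 3))
        cands, _ = candidate_snps(m, labels)
        assert cands.empty

    def test_missing_call_blocks_candidacy(self):
        codes = [[1, 1, -1, 0, 0, 0]]
        m = matrix_from_codes(codes, list("abcdef"))
        labels = dict(zip("abcdef", ["high"] * 3 + ["low"] * 3))
        cands, report = candidate_snps(m, labels)
        assert cands.empty
        # non-missing calls are consistent with the filter, so the marker
        # is not a usable outer bound either
        assert not report["bound_failing"].iloc[0]

    def test_empty_group_rejected(self):
        m = matrix_from_codes([[1, 1]], ["a", "b"])
        with pytest.raises(ValueError):
            candidate_snps(m, {"a": "high", "b": "high"})

    def test_matches_double_loop_oracle(self, rng):
        """Random 50-marker x 12-individual matrices agree with the
        explicit double-loop filter."""
        for _ in range(200):
            codes = rng.choice([-1, 0, 1, 2], size=(50, 12), p=[0.05, 0.5, 0.4, 0.05])
            inds = [f"i{k}" for k in range(12)]
            m = matrix_from_codes(codes, inds)
            labels = {f"i{k}": ("high" if k < 6 else "low") for k in range(12)}
            cands, _ = candidate_snps(m, labels)
            expect = oracle_filter(codes, list(range(6)), list(range(6, 12)))
            assert list(cands["marker"]) == [f"m{i}" for i in np.nonzero(expect)[0]]

    def test_invariant_under_individual_permutation(self, rng):
        codes = rng.choice([0, 1], size=(30, 10))
        inds = [f"i{k}" for k in range(10)]
        labels = {f"i{k}": ("high" if k % 2 else "low") for k in range(10)}
        m1 = matrix_from_codes(codes, inds)
        perm = rng.permutation(10)
        m2 = matrix_from_codes(codes[:, perm], [inds[j] for j in perm])
        c1, _ = candidate_snps(m1, labels)
        c2, _ = candidate_snps(m2, labels)
        assert list(c1["marker"]) == list(c2["marker"])


class TestIntervals:
    def _report(self, positions, candidate_mask):
        return pd.DataFrame(
            {"chrom": ["chr1"] * len(positions), "pos": positions,
             "marker": [f"m{i}" for i in range(len(positions))],
             "candidate": candidate_mask,
             "bound_failing": [not c for c in candidate_mask]}
        )

    def test_inner_and_outer_bounds(self):
        pos = [5000, 10000, 20000, 30000, 40000]
        report = self._report(pos, [False, True, True, True, False])
        cands = report[report["candidate"]]
        iv = assemble_interval(cands, report)["chr1"]
        assert (iv["inner"].start, iv["inner"].end) == (10000, 30000)
        assert (iv["outer"].start, iv["outer"].end) == (5000, 40000)

    def test_single_candidate_widened_to_1bp(self):
        report = self._report([5000, 10000, 40000], [False, True, False])
        cands = report[report["candidate"]]
        iv = assemble_interval(cands, report)["chr1"]
        assert (iv["inner"].start, iv["inner"].end) == (10000, 10001)

    def test_outer_contains_inner(self, rng):
        for _ in range(50):
            mask = rng.random(20) < 0.3
            if not mask.any():
                continue
            pos = np.sort(rng.choice(np.arange(1, 10_000) * 100, size=20, replace=False))
            report = self._report(pos, list(mask))
            iv = assemble_interval(report[report["candidate"]], report)["chr1"]
            assert iv["outer"].start <= iv["inner"].start
            assert iv["outer"].end >= iv["inner"].end

    def test_combined_window_from_printed_coordinates(self):
        a = GenomicInterval.from_printed("chr4:141964197-149000000")
        b = GenomicInterval.from_printed("chr4:140000000-148393136")
        c = combine_experiments(a, b)
        assert c.to_printed() == "chr4:141964197-148393136"

    def test_combine_idempotent_and_nested(self):
        a = GenomicInterval("chr4", 100, 200)
        b = GenomicInterval("chr4", 120, 180)
        assert combine_experiments(a, a) == GenomicInterval("chr4", 100, 200, "inner")
        assert combine_experiments(a, b).start == 120
        assert combine_experiments(a, b).end == 180

    def test_disjoint_intervals_conflict(self):
        a = GenomicInterval("chr4", 100, 200)
        b = GenomicInterval("chr4", 300, 400)
        with pytest.raises(MappingConflictError):
            combine_experiments(a, b)
        with pytest.raises(MappingConflictError):
            combine_experiments(a, GenomicInterval("chr5", 100, 200))

    def test_printed_round_trip(self):
        iv = GenomicInterval.from_printed("chr4:141964197-148393136")
        assert iv.start == 141964196 and iv.end == 148393136
        assert GenomicInterval.from_printed(iv.to_printed()) == iv


class TestIntervalLength:
    def test_combined_window_is_6_4_mb(self):
        iv = GenomicInterval.from_printed("chr4:141964197-148393136")
        assert interval_length_mb(iv) == 6.4

    def test_kzfp_cluster_is_2_5_mb(self):
        iv = GenomicInterval.from_printed("chr4:145383918-147853419")
        assert interval_length_mb(iv) == 2.5

    def test_degenerate_1bp_interval_rounds_to_zero(self):
        assert interval_length_mb(GenomicInterval("chr1", 100, 101)) == 0.0

    def test_round_half_up(self):
        assert interval_length_mb(GenomicInterval("chr1", 0, 6_450_000)) == 6.5


class TestSegregation:
    def test_balanced_split(self):
        r = segregation_test(10, 10)
        assert r.p_value == 1.0 and r.consistent

    def test_all_high_rejected(self):
        r = segregation_test(20, 0)
        assert r.p_value == pytest.approx(2 * 0.5**20, rel=1e-9)
        assert not r.consistent

    def test_23_24_split_consistent(self):
        assert segregation_test(23, 24).consistent


class TestPedigreeConsistency:
    @pytest.fixture
    def phenotyped_backcross(self):
        genome = default_genome()
        ped = breed_backcross(genome, np.random.default_rng(17), n_n3=40)
        classes = {
            i.id: ("high" if i.modifier_alleles >= 1 else "low")
            for i in ped
            if i.generation in ("F1", "N1", "N2", "N3")
        }
        return ped, classes

    def test_dominant_model_consistent(self, phenotyped_backcross):
        ped, classes = phenotyped_backcross
        res = pedigree_consistency(ped, classes)
        assert res.consistent
        assert len(res.families) > 0

    def test_phenotyping_error_breaks_low_families(self, phenotyped_backcross, rng):
        ped, classes = phenotyped_backcross
        noisy = {
            k: (("low" if v == "high" else "high") if rng.random() < 0.2 else v)
            for k, v in classes.items()
        }
        res = pedigree_consistency(ped, noisy)
        assert not res.consistent

    def test_untyped_parent_offspring_excluded(self, phenotyped_backcross):
        ped, classes = phenotyped_backcross
        res = pedigree_consistency(ped, classes)
        # F1 individuals' sire is an untyped CAST founder
        assert all(ped[i].generation == "F1" for i in res.excluded)


class TestGenotypeCsv:
    def test_round_trip_through_frame(self, rng):
        genome = default_genome()
        ped = breed_backcross(genome, rng, n_n3=6)
        n3 = ped.by_generation("N3")
        df = genotype_frame(n3, genome)
        m = GenotypeMatrix.from_frame(df)
        pd.testing.assert_frame_equal(m.to_frame(), df)
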