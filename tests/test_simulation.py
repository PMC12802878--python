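import numpy as np
import pytest
from hypothesis import given, strategies as st

from proteasim.digestion import PeptideFilter, digest_proteome
from proteasim.prep import AbundanceModel, ProteinRecord, assign_groups, sample_abundances
from proteasim.proteases import get_protease
from proteasim.simulation import (
    PeptideEntity,
    SamplingConfig,
    allocate_mc_bins,
    build_protein_info,
    infer_proteins,
    merge_intervals,
    run_monte_carlo,
    weighted_sample,
)


class TestAllocateMcBins:
    def test_five_percent_one_mc_split(self):
        assert allocate_mc_bins(10_000, [0.95, 0.05]).tolist() == [9500, 500]

    def test_single_bin(self):
        assert allocate_mc_bins(10, [1.0]).tolist() == [10]

    def test_largest_remainder_rounding(self):
        assert allocate_mc_bins(7, [0.5, 0.3, 0.2]).tolist() == [4, 2, 1]

    @given(
        total=st.integers(0, 100_000),
        raw=st.lists(st.floats(0.01, 1.0), min_size=1, max_size=6),
    )
    def test_allocation_conserves_total(self, total, raw):
        fractions = np.array(raw) / np.sum(raw)
        assert allocate_mc_bins(total, fractions).sum() == total

    def test_empty_pool_reallocated_proportionally(self):
        alloc = allocate_mc_bins(100, [0.5, 0.3, 0.2], pool_sizes=[200, 0, 200])
        assert alloc.tolist() == [71, 0, 29]
        assert alloc.sum() == 100

    def test_partial_pool_capped_and_redistributed(self):
        alloc = allocate_mc_bins(100, [0.9, 0.1], pool_sizes=[50, 100])
        assert alloc.tolist() == [50, 50]

    def test_all_pools_empty_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            allocate_mc_bins(10, [0.5, 0.5], pool_sizes=[0, 0])

    def test_overall_shortfall_returns_whole_pool(self):
        alloc = allocate_mc_bins(100, [0.5, 0.5], pool_sizes=[10, 20])
        assert alloc.tolist() == [10, 20]

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            allocate_mc_bins(10, [0.5, 0.4])


class TestWeightedSample:
    def test_exhaustion_returns_exactly_positive_set(self):
        rng = np.random.default_rng(0)
        pool = ["a", "b", "c", "d"]
        out = weighted_sample(pool, [1.0, 0.0, 2.0, 3.0], 3, rng)
        assert sorted(out) == ["a", "c", "d"]

    def test_zero_weight_never_sampled(self):
        rng = np.random.default_rng(1)
        seen = set()
        for _ in range(10_000):
            seen.update(weighted_sample(["a", "b", "c"], [1.0, 0.0, 1.0], 1, rng))
        assert "b" not in seen

    def test_nine_to_one_single_draw_frequency(self):
        rng = np.random.default_rng(2)
        n_trials = 100_000
        hits = sum(
            weighted_sample(["x", "y"], [9.0, 1.0], 1, rng)[0] == "x"
            for _ in range(n_trials)
        )
        # binomial SE at p=0.9, n=1e5 is ~0.001; allow 0.01 band
        assert abs(hits / n_trials - 0.9) < 0.01

    def test_reproducible_under_fixed_seed(self):
        pool = list(range(100))
        w = np.linspace(0.1, 2.0, 100)
        a = weighted_sample(pool, w, 20, np.random.default_rng(7))
        b = weighted_sample(pool, w, 20, np.random.default_rng(7))
        assert a == b

    def test_without_replacement_draws_distinct(self):
        rng = np.random.default_rng(3)
        out = weighted_sample(list(range(50)), np.ones(50), 30, rng)
        assert len(set(out)) == 30

    def test_with_replacement_can_repeat(self):
        rng = np.random.default_rng(4)
        out = weighted_sample(["a", "b"], [1.0, 1.0], 10, rng, with_replacement=True)
        assert len(out) == 10

    def test_negative_n_rejected(self):
        with pytest.raises(ValueError):
            weighted_sample(["a"], [1.0], -1, np.random.default_rng(0))


def entity(seq, protein, start, protease="trypsin", unique=True, extra_occ=()):
    occ = [(protein, start, start + len(seq))] + list(extra_occ)
    return PeptideEntity(
        sequence=seq,
        protease=protease,
        mc_count=0,
        occurrences=occ,
        is_unique=unique and len(occ) == 1,
    )


class TestInferProteins:
    @pytest.fixture
    def proteome(self):
        return assign_groups(
            [ProteinRecord("A", "MKTAYIAKQR"), ProteinRecord("B", "M" * 80)]
        )

    def test_two_unique_peptides_identify_under_strict_rule(self, proteome):
        sampled = [entity("MK", "A", 0), entity("TAYIAK", "A", 2)]
        res = infer_proteins(sampled, 2, proteome)
        assert res.identified_proteins == {"A"}

    def test_one_unique_peptide_fails_strict_rule(self, proteome):
        sampled = [entity("TAYIAK", "A", 2)]
        assert infer_proteins(sampled, 2, proteome).identified_proteins == set()
        assert infer_proteins(sampled, 1, proteome).identified_proteins == {"A"}

    def test_coverage_from_interval_union(self, proteome):
        sampled = [entity("MK", "A", 0), entity("TAYIAK", "A", 2)]
        res = infer_proteins(sampled, 1, proteome)
        (ent,) = res.entities
        assert ent.coverage == pytest.approx(0.8)

    def test_overlapping_peptides_do_not_double_count_coverage(self, proteome):
        sampled = [entity("MKTAYI", "A", 0), entity("TAYIAK", "A", 2)]
        res = infer_proteins(sampled, 1, proteome)
        assert res.entities[0].coverage == pytest.approx(0.8)

    def test_full_length_peptide_gives_coverage_one(self, proteome):
        sampled = [entity("MKTAYIAKQR", "A", 0)]
        res = infer_proteins(sampled, 1, proteome)
        assert res.entities[0].coverage == 1.0

    def test_strict_rule_subset_of_lenient(self, proteome):
        rng = np.random.default_rng(5)
        pool = [entity("MK", "A", 0), entity("TAYIAK", "A", 2), entity("M" * 7, "B", 0)]
        for _ in range(20):
            k = int(rng.integers(0, len(pool) + 1))
            sampled = [pool[i] for i in rng.choice(len(pool), size=k, replace=False)]
            one = infer_proteins(sampled, 1, proteome).identified_proteins
            two = infer_proteins(sampled, 2, proteome).identified_proteins
            assert two <= one

    def test_n_pep_counts_only_identified_proteins(self, proteome):
        sampled = [
            entity("MK", "A", 0),
            entity("TAYIAK", "A", 2),
            entity("M" * 7, "B", 0),  # one peptide only: not identified at rule 2
        ]
        res = infer_proteins(sampled, 2, proteome)
        assert res.metrics_by_group(["small", "large"]) == {
            "small": (1, 2.0, pytest.approx(0.8)),
            "large": (0, 0.0, 0.0),
        }


class TestSharedPeptideMode:
    def test_indistinguishable_proteins_form_group_with_medians(self):
        # A and B are identical twins; peptide maps to both
        proteome = assign_groups(
            [ProteinRecord("A", "MKTAYIAKQR"), ProteinRecord("B", "MKTAYIAKQR")]
        )
        shared = PeptideEntity(
            "TAYIAK", "trypsin", 0,
            occurrences=[("A", 2, 8), ("B", 2, 8)], is_unique=False,
        )
        res = infer_proteins([shared], 1, proteome, shared_mode=True)
        (ent,) = res.entities
        assert ent.members == ("A", "B")
        assert ent.coverage == pytest.approx(0.6)
        assert ent.n_pep == 1.0

    def test_group_unique_peptide_respects_outside_occurrence(self):
        proteome = assign_groups(
            [
                ProteinRecord("A", "MKTAYIAKQR"),
                ProteinRecord("B", "MKTAYIAKQR"),
                ProteinRecord("C", "GGTAYIAKGG"),
            ]
        )
        shared = PeptideEntity(
            "TAYIAK", "trypsin", 0,
            occurrences=[("A", 2, 8), ("B", 2, 8), ("C", 2, 8)], is_unique=False,
        )
        # peptide also occurs in C, so the {A,B,C} proteins all share it and
        # form one group in which it is group-unique
        res = infer_proteins([shared], 1, proteome, shared_mode=True)
        (ent,) = res.entities
        assert ent.members == ("A", "B", "C")


def build_run(n_samples=3, peptides=300, names=("trypsin", "lys-c", "glu-c"), seed=5):
    import proteasim.synthetic as syn

    records = assign_groups(syn.generate_synthetic_proteome(120, seed=3))
    model = AbundanceModel(undetectable_fraction=0.2)
    samples = [sample_abundances(records, model, i, seed) for i in range(n_samples)]
    proteases = [get_protease(n) for n in names]
    table = digest_proteome(records, proteases, 3, PeptideFilter())
    cfg = SamplingConfig(
        peptides_per_protease={p.name: peptides for p in proteases},
        n_samples=n_samples,
        master_seed=seed,
    )
    return run_monte_carlo(cfg, records, samples, table, proteases), records


@pytest.fixture(scope="module")
def run_and_records():
    return build_run()


class TestRunMonteCarlo:
    def test_singleton_combination_equals_protease_result(self, run_and_records):
        run, _ = run_and_records
        single = run.combination_inference(0, ("trypsin",), 1)
        stats = run.stats[(0, "trypsin")]
        identified = {pid for pid, st in stats.items() if st.n_unique >= 1}
        assert single.identified_proteins == identified

    def test_combination_monotonic_in_members(self, run_and_records):
        run, _ = run_and_records
        for sample in run.sample_indices:
            for rule in (1, 2):
                solo = run.combination_inference(sample, ("trypsin",), rule)
                pair = run.combination_inference(sample, ("trypsin", "lys-c"), rule)
                trio = run.combination_inference(
                    sample, ("trypsin", "lys-c", "glu-c"), rule
                )
                assert solo.identified_proteins <= pair.identified_proteins
                assert pair.identified_proteins <= trio.identified_proteins
                solo_cov = {e.members[0]: e.coverage for e in solo.entities}
                trio_cov = {e.members[0]: e.coverage for e in trio.entities}
                for pid, cov in solo_cov.items():
                    assert trio_cov[pid] >= cov - 1e-12

    def test_coverage_bounds(self, run_and_records):
        run, _ = run_and_records
        for sample in run.sample_indices:
            res = run.combination_inference(sample, ("trypsin", "glu-c"), 1)
            for ent in res.entities:
                assert 0.0 < ent.coverage <= 1.0

    def test_strict_rule_subset_everywhere(self, run_and_records):
        run, _ = run_and_records
        combos = [("trypsin",), ("lys-c", "trypsin"), ("glu-c", "lys-c", "trypsin")]
        for sample in run.sample_indices:
            for combo in combos:
                one = run.combination_inference(sample, combo, 1).identified_proteins
                two = run.combination_inference(sample, combo, 2).identified_proteins
                assert two <= one

    def test_fixed_seed_reproduces_run(self):
        run_a, _ = build_run(n_samples=2, peptides=150, names=("trypsin",))
        run_b, _ = build_run(n_samples=2, peptides=150, names=("trypsin",))
        peps_a = [p.sequence for p in run_a.sampled[(0, "trypsin")]]
        peps_b = [p.sequence for p in run_b.sampled[(0, "trypsin")]]
        assert peps_a == peps_b

    def test_requested_count_sampled_when_pool_ample(self, run_and_records):
        run, _ = run_and_records
        for sample in run.sample_indices:
            assert len(run.sampled[(sample, "trypsin")]) == 300


class TestMergeIntervals:
    @given(
        ivs=st.lists(
            st.tuples(st.integers(0, 50), st.integers(1, 20)).map(
                lambda t: (t[0], t[0] + t[1])
            ),
            max_size=20,
        )
    )
    def test_union_size_matches_point_set(self, ivs):
        merged = merge_intervals(ivs)
        points = set()
        for s, e in ivs:
            points.update(range(s, e))
        assert sum(e - s for s, e in merged) == len(points)
        for (s1, e1), (s2, e2) in zip(merged, merged[1:]):
            assert e1 < s2
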