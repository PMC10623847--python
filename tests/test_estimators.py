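"""Tests for the two EM estimators and the pruning driver."""

import itertools

import numpy as np
import pytest

from mhfreq import (
    ALT,
    REF,
    EmSettings,
    ErrorModel,
    Haplotype,
    MicrohapLocus,
    ReadObservation,
    SnpSite,
    SkipReason,
    em_individual,
    em_pool,
    expected_heterozygosity,
    prune_and_estimate,
)

import oracle


def make_locus(n_sites, chrom="c", start=100, step=2, window=60):
    sites = tuple(
        SnpSite(chrom, start + i * step, "A", "G") for i in range(n_sites)
    )
    return MicrohapLocus(chrom, sites, window)


def full_read(states, q=40, source="s"):
    return ReadObservation(source, {i: (a, q) for i, a in enumerate(states)})


def assert_monotone(history, atol=1e-9):
    diffs = np.diff(np.asarray(history))
    assert (diffs >= -atol).all(), f"log-likelihood decreased: min diff {diffs.min()}"


class TestExpectedHeterozygosity:
    @pytest.mark.parametrize(
        "pi, expected",
        [((1.0,), 0.0), ((0.5, 0.5), 0.5), ((0.25,) * 4, 0.75)],
    )
    def test_examples(self, pi, expected):
        assert expected_heterozygosity(pi) == pytest.approx(expected, abs=1e-12)


class TestEmSettings:
    def test_validation(self):
        with pytest.raises(ValueError):
            EmSettings(prune_x=0)
        with pytest.raises(ValueError):
            EmSettings(prune_c=1.0)
        with pytest.raises(ValueError):
            EmSettings(tol=0)


class TestEmPool:
    def test_empirical_proportions_at_zero_error(self):
        # 3 fully-informative error-free reads of A, 1 of B -> (0.75, 0.25)
        model = ErrorModel(0.0)
        haps = [Haplotype((REF, REF)), Haplotype((ALT, ALT))]
        reads = [full_read((REF, REF), q=10_000)] * 3 + [
            full_read((ALT, ALT), q=10_000)
        ]
        res = em_pool(reads, haps, model, EmSettings(tol=1e-12))
        assert res.freqs == pytest.approx([0.75, 0.25], abs=1e-9)
        assert_monotone(res.ll_history)

    def test_symmetry_gives_half_half(self):
        model = ErrorModel(0.01)
        haps = [Haplotype((REF,)), Haplotype((ALT,))]
        reads = [full_read((REF,), q=25), full_read((ALT,), q=25)]
        res = em_pool(reads, haps, model, EmSettings())
        assert res.freqs == pytest.approx([0.5, 0.5], abs=1e-9)

    def test_disjoint_coverage_matches_grid_oracle(self):
        # reads covering disjoint SNP subsets of two haplotypes
        model = ErrorModel(0.01)
        haps = [Haplotype((REF, ALT)), Haplotype((ALT, REF))]
        reads = [
            ReadObservation("s", {0: (REF, 25)}),
            ReadObservation("s", {0: (REF, 30)}),
            ReadObservation("s", {1: (REF, 25)}),
            ReadObservation("s", {0: (ALT, 28)}),
            ReadObservation("s", {1: (ALT, 30)}),
        ]
        res = em_pool(reads, haps, model, EmSettings(tol=1e-10))
        expected = oracle.grid_mle_pool(
            [r.calls for r in reads], [h.states for h in haps], 0.01
        )
        assert res.freqs == pytest.approx(expected, abs=1e-3)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="at least one read"):
            em_pool([], [Haplotype((REF,))], ErrorModel(), EmSettings())


class TestEmIndividual:
    def test_degenerate_mle_all_reads_one_haplotype(self):
        model = ErrorModel(0.0)
        haps = [Haplotype((REF, REF)), Haplotype((ALT, ALT))]
        reads = {"i1": [full_read((REF, REF), q=60) for _ in range(6)]}
        res = em_individual(reads, haps, model, EmSettings(tol=1e-12))
        assert res.freqs[0] == pytest.approx(1.0, abs=1e-6)
        assert_monotone(res.ll_history)

    def test_matches_grid_oracle_small_instance(self):
        # 3 individuals, <= 2 reads each, 2 haplotypes: EM optimum equals
        # a dense grid search over p in [0, 1]
        model = ErrorModel(0.01)
        haps = [Haplotype((REF, ALT)), Haplotype((ALT, REF))]
        by_ind = {
            "a": [full_read((REF, ALT), q=25), full_read((ALT, REF), q=25)],
            "b": [full_read((REF, ALT), q=30)],
            "c": [ReadObservation("c", {1: (REF, 20)})],
        }
        res = em_individual(by_ind, haps, model, EmSettings(tol=1e-10))
        expected = oracle.grid_mle_individual(
            [[r.calls for r in rs] for rs in by_ind.values()],
            [h.states for h in haps],
            0.01,
        )
        assert res.freqs == pytest.approx(expected, abs=1e-3)
        assert_monotone(res.ll_history)

    def test_hwe_recovery_under_simulation(self):
        # N individuals under HWE at p = (0.7, 0.3), shallow coverage:
        # mean estimate over replicates should be close to the truth
        rng = np.random.default_rng(11)
        model = ErrorModel(0.01)
        haps = [Haplotype((REF, REF)), Haplotype((ALT, ALT))]
        n_reps, n_ind, p_true = 60, 50, 0.7
        errors = []
        for _ in range(n_reps):
            by_ind = {}
            for i in range(n_ind):
                g = rng.random(2) < p_true  # two gene copies under HWE
                n_reads = rng.poisson(2)
                reads = []
                for _ in range(n_reads):
                    hap = haps[0] if g[rng.integers(2)] else haps[1]
                    states = [
                        s if rng.random() > 0.0198 else 1 - s for s in hap.states
                    ]
                    reads.append(full_read(states, q=20, source=f"i{i}"))
                if reads:
                    by_ind[f"i{i}"] = reads
            res = em_individual(by_ind, haps, model, EmSettings())
            errors.append(p_true - res.freqs[0])
        mean_err = np.mean(errors)
        se = np.std(errors, ddof=1) / np.sqrt(n_reps)
        assert abs(mean_err) < max(3 * se, 0.02)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="at least one individual"):
            em_individual({}, [Haplotype((REF,))], ErrorModel(), EmSettings())


class TestPruneAndEstimate:
    def test_single_snp_locus_never_drops(self):
        locus = make_locus(1)
        reads = [full_read((REF,), q=40) for _ in range(5)]
        est = prune_and_estimate(locus, reads, "pool")
        # final iteration never drops, so the rare ALT haplotype remains
        assert len(est.haplotypes) == 2
        assert est.pi.sum() == pytest.approx(1.0, abs=1e-9)
        assert est.he == pytest.approx(
            expected_heterozygosity(est.pi), abs=1e-9
        )

    def test_pruning_recovers_sparse_truth(self):
        # only 2 of 8 haplotypes exist; abundant error-free reads
        locus = make_locus(3)
        true_haps = [Haplotype((REF, REF, REF)), Haplotype((ALT, ALT, ALT))]
        reads = [full_read(true_haps[0].states, q=10_000) for _ in range(30)]
        reads += [full_read(true_haps[1].states, q=10_000) for _ in range(10)]
        model = ErrorModel(0.0)
        est = prune_and_estimate(locus, reads, "pool", model)
        surviving = {h for h, p in zip(est.haplotypes, est.pi) if p > 0.001}
        assert surviving == set(true_haps)
        # frequencies agree with the unpruned full-enumeration fit
        full = em_pool(
            reads,
            sorted(Haplotype(s) for s in oracle.all_haplotypes(3)),
            model,
            EmSettings(),
        )
        by_hap = dict(zip(est.haplotypes, est.pi))
        all_haps = sorted(Haplotype(s) for s in oracle.all_haplotypes(3))
        for hap, p_full in zip(all_haps, full.freqs):
            assert by_hap.get(hap, 0.0) == pytest.approx(p_full, abs=1e-6)

    @pytest.mark.parametrize("method", ["individual", "pool"])
    def test_c_zero_identical_to_full_enumeration(self, method):
        rng = np.random.default_rng(3)
        locus = make_locus(3)
        model = ErrorModel(0.01)
        reads = []
        for k in range(25):
            states = tuple(int(rng.integers(2)) for _ in range(3))
            reads.append(full_read(states, q=30, source=f"i{k % 5}"))
        s0 = EmSettings(prune_c=0.0)
        all_haps = sorted(Haplotype(s) for s in oracle.all_haplotypes(3))
        if method == "pool":
            est = prune_and_estimate(locus, reads, method, model, s0)
            full = em_pool(reads, all_haps, model, s0)
        else:
            grouped = {}
            for r in reads:
                grouped.setdefault(r.source_id, []).append(r)
            est = prune_and_estimate(locus, grouped, method, model, s0)
            full = em_individual(grouped, all_haps, model, s0)
        assert est.haplotypes == all_haps
        assert est.pi == pytest.approx(full.freqs / full.freqs.sum(), abs=1e-9)

    def test_default_pruning_matches_full_enumeration(self):
        # no true haplotype below c, so pruning must not change the optimum
        rng = np.random.default_rng(5)
        locus = make_locus(2)
        model = ErrorModel(0.01)
        true_haps = [Haplotype((REF, REF)), Haplotype((ALT, REF))]
        reads = []
        for k in range(40):
            hap = true_haps[int(rng.random() < 0.4)]
            reads.append(full_read(hap.states, q=35, source=f"i{k % 8}"))
        est = prune_and_estimate(locus, reads, "pool", model, EmSettings())
        full = em_pool(
            reads,
            sorted(Haplotype(s) for s in oracle.all_haplotypes(2)),
            model,
            EmSettings(),
        )
        all_haps = sorted(Haplotype(s) for s in oracle.all_haplotypes(2))
        by_hap = dict(zip(est.haplotypes, est.pi))
        for hap, p_full in zip(all_haps, full.freqs):
            assert by_hap.get(hap, 0.0) == pytest.approx(p_full, abs=1e-3)

    def test_zero_depth_skip(self):
        locus = make_locus(2)
        reads = [ReadObservation("s", {0: (REF, 30)})]  # site 1 uncovered
        est = prune_and_estimate(locus, reads, "pool")
        assert est.skip_reason is SkipReason.ZERO_DEPTH
        assert est.haplotypes == [] and est.pi.size == 0

    @pytest.mark.parametrize(
        "method, n_snps, skipped", [("individual", 8, True), ("pool", 8, False),
                                    ("pool", 9, True)],
    )
    def test_allele_cap_skip(self, method, n_snps, skipped):
        # with c = 0 nothing is pruned: candidates double per iteration and
        # reach 2^n_snps at the last iteration
        locus = make_locus(n_snps, step=1)
        reads = [full_read((REF,) * n_snps, q=30, source=f"i{k}") for k in range(4)]
        data = {r.source_id: [r] for r in reads} if method == "individual" else reads
        est = prune_and_estimate(
            locus, data, method, ErrorModel(0.01), EmSettings(prune_c=0.0)
        )
        if skipped:
            assert est.skip_reason is SkipReason.TOO_MANY_ALLELES
            assert est.pi.size == 0
        else:
            assert est.skip_reason is None

    def test_survivors_subset_of_candidates(self):
        rng = np.random.default_rng(9)
        locus = make_locus(4)
        reads = [
            full_read(tuple(int(rng.integers(2)) for _ in range(4)), q=30)
            for _ in range(30)
        ]
        est = prune_and_estimate(locus, reads, "pool")
        assert len(set(est.haplotypes)) == len(est.haplotypes)
        universe = set(itertools.product((0, 1), repeat=4))
        assert {h.states for h in est.haplotypes} <= universe

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="method"):
            prune_and_estimate(make_locus(1), [], "bogus")
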