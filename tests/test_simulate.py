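import numpy as np
import pytest

from batchvar import (
    ExclusionMask,
    KnownVariant,
    MixtureSpec,
    TruthSet,
    VariantCall,
    build_pileup,
    call_sample,
    estimate_bias,
    evaluate,
    make_haplotypes,
    observed_fraction,
    run_benchmark,
    simulate_reads,
    synthetic_reference,
    write_sam,
)


def truth_variants(truth):
    return [KnownVariant(p, r, a) for p, r, a in truth.records]


class TestMakeHaplotypes:
    def test_k_zero_identity(self):
        ref = synthetic_reference(length=200, seed=0)
        hap_a, hap_b, truth = make_haplotypes(ref, k=0, seed=1)
        assert hap_a == hap_b == ref.sequence and len(truth) == 0

    def test_hamming_distance_equals_k(self):
        ref = synthetic_reference(length=500, seed=0)
        hap_a, hap_b, truth = make_haplotypes(ref, k=60, seed=1)
        diff = sum(a != b for a, b in zip(hap_a, hap_b))
        assert diff == 60 == len(truth)

    def test_seeded_determinism(self):
        ref = synthetic_reference(length=500, seed=0)
        t1 = make_haplotypes(ref, k=60, seed=9)[2]
        t2 = make_haplotypes(ref, k=60, seed=9)[2]
        assert t1.records == t2.records

    def test_contains_run_of_adjacent_differences(self):
        ref = synthetic_reference(length=500, seed=0)
        _, _, truth = make_haplotypes(ref, k=10, seed=4)
        positions = sorted(truth.positions)
        runs = max(
            len(list(g))
            for g in _group_consecutive(positions)
        )
        assert 2 <= runs <= 10

    def test_masked_positions_avoided(self):
        ref = synthetic_reference(length=300, seed=0)
        mask = ExclusionMask(intervals=((100, 200),))
        _, _, truth = make_haplotypes(ref, k=40, seed=5, mask=mask)
        assert not (truth.positions & set(range(100, 201)))

    def test_k_too_large_rejected(self):
        ref = synthetic_reference(length=50, seed=0)
        with pytest.raises(ValueError, match="exceeds"):
            make_haplotypes(ref, k=60, seed=0)


def _group_consecutive(positions):
    group = [positions[0]]
    for p in positions[1:]:
        if p == group[-1] + 1:
            group.append(p)
        else:
            yield group
            group = [p]
    yield group


class TestBiasTransform:
    def test_zero_fraction_stays_zero(self):
        assert observed_fraction(0.0, 0.5) == 0.0

    def test_unbiased_identity(self):
        assert observed_fraction(0.37, 1.0) == pytest.approx(0.37)

    def test_halved_efficiency_at_even_mix(self):
        assert observed_fraction(0.5, 0.5) == pytest.approx(1 / 3)


class TestSimulateReads:
    def _spec(self, **kwargs):
        ref = synthetic_reference(length=300, seed=0)
        _, _, truth = make_haplotypes(ref, k=8, seed=1)
        defaults = dict(
            reference=ref,
            haplotype_b_variants=truth_variants(truth),
            mix_fraction=0.5,
            coverage_per_strand=500,
            read_length=100,
            seed=2,
        )
        defaults.update(kwargs)
        return MixtureSpec(**defaults), truth

    def test_pure_reference_mix_yields_no_calls(self):
        spec, truth = self._spec(mix_fraction=0.0, coverage_per_strand=300)
        metrics, calls, _ = run_benchmark(spec)
        assert not {c.pos for c in calls} & truth.positions
        assert metrics.tp == 0

    def test_strands_balanced(self):
        spec, _ = self._spec()
        reads, _ = simulate_reads(spec)
        n_rev = sum(1 for r in reads if r.is_reverse)
        assert n_rev == len(reads) - n_rev

    def test_empirical_fraction_within_binomial_bounds(self):
        spec, truth = self._spec(coverage_per_strand=1000)
        reads, _ = simulate_reads(spec)
        pileup = build_pileup(reads, spec.reference)
        for pos, _ref, alt in truth.records:
            site = pileup.site(pos)
            counts = site.base_counts("+") + site.base_counts("-")
            depth = counts.sum()
            frac = counts["ACGT".index(alt)] / depth
            sigma = np.sqrt(0.5 * 0.5 / depth)
            assert abs(frac - 0.5) < 4 * sigma + 0.01

    def test_bias_shifts_observed_fraction(self):
        spec, truth = self._spec(amplification_bias=0.5, coverage_per_strand=1000)
        assert spec.observed_mix_fraction == pytest.approx(1 / 3)
        reads, _ = simulate_reads(spec)
        pileup = build_pileup(reads, spec.reference)
        fracs = []
        for pos, _ref, alt in truth.records:
            counts = pileup.site(pos).base_counts("+") + pileup.site(pos).base_counts("-")
            fracs.append(counts["ACGT".index(alt)] / counts.sum())
        assert np.mean(fracs) == pytest.approx(1 / 3, abs=0.02)

    def test_seeded_sam_determinism(self, tmp_path):
        spec, _ = self._spec(coverage_per_strand=50)
        a, b = tmp_path / "a.sam", tmp_path / "b.sam"
        reads1, header1 = simulate_reads(spec)
        reads2, header2 = simulate_reads(spec)
        write_sam(reads1, header1, a)
        write_sam(reads2, header2, b)
        assert a.read_bytes() == b.read_bytes()

    def test_level_concordance_across_truth_positions(self):
        # all planted differences sit on one molecule: their called levels
        # scatter only by binomial sampling around the mix fraction
        spec, truth = self._spec(coverage_per_strand=1000)
        _, calls, _ = run_benchmark(spec)
        levels = [c.level for c in calls if (c.pos, c.alt) in
                  {(p, a) for p, _r, a in truth.records}]
        assert len(levels) == len(truth)
        binom_sd = np.sqrt(0.5 * 0.5 / 2000)
        assert np.std(levels) < 5 * binom_sd


class TestEvaluate:
    TRUTH = TruthSet(records=tuple((p, "A", "G") for p in range(10, 70)))

    def _call(self, pos, alt="G"):
        return VariantCall(pos=pos, ref="A", alt=alt, level=0.5, level_fwd=0.5,
                           level_rev=0.5, lrt_fwd=9.0, lrt_rev=9.0,
                           depth_fwd=500, depth_rev=500)

    def test_perfect_calls(self):
        calls = [self._call(p) for p, _r, _a in self.TRUTH.records]
        m = evaluate(calls, self.TRUTH, range(1, 1001))
        assert (m.precision, m.sensitivity, m.specificity) == (100.0, 100.0, 100.0)

    def test_one_missed_variant(self):
        calls = [self._call(p) for p, _r, _a in self.TRUTH.records[:-1]]
        m = evaluate(calls, self.TRUTH, range(1, 1001))
        assert m.sensitivity == pytest.approx(98.33, abs=0.01)

    def test_one_extra_false_call(self):
        calls = [self._call(p) for p, _r, _a in self.TRUTH.records] + [self._call(500)]
        m = evaluate(calls, self.TRUTH, range(1, 1001))
        assert m.precision == pytest.approx(98.36, abs=0.01)
        assert m.specificity == pytest.approx(100 * 939 / 940, abs=0.01)

    def test_wrong_allele_at_truth_position_not_tp(self):
        calls = [self._call(10, alt="T")]
        m = evaluate(calls, self.TRUTH, range(1, 1001))
        assert m.tp == 0 and m.fp == 1

    def test_empty_callable_set_rejected(self):
        with pytest.raises(ValueError, match="empty callable"):
            evaluate([], self.TRUTH, [])


class TestBiasRecovery:
    def test_beta_recovered_from_called_levels(self):
        ref = synthetic_reference(length=400, seed=3)
        _, _, truth = make_haplotypes(ref, k=20, seed=3)
        spec = MixtureSpec(
            reference=ref,
            haplotype_b_variants=truth_variants(truth),
            mix_fraction=0.10,
            coverage_per_strand=5000,
            amplification_bias=0.5,
            seed=7,
        )
        _, calls, _ = run_benchmark(spec)
        truth_keys = {(p, a) for p, _r, a in truth.records}
        levels = [c.level for c in calls if (c.pos, c.alt) in truth_keys]
        beta = estimate_bias(levels, 0.10)
        assert beta == pytest.approx(0.5, rel=0.10)

    def test_estimate_bias_closed_form(self):
        x_obs = observed_fraction(0.2, 0.7)
        assert estimate_bias([x_obs], 0.2) == pytest.approx(0.7, rel=1e-9)
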