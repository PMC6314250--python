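import math

import numpy as np
import pytest

from batchvar import (
    CallerConfig,
    ReferenceRepeat,
    call_sample,
    call_site,
    mle_level,
    site_loglik,
    strand_bias_test,
)
from batchvar.pileup import PileupSite, PileupTable


def grid_oracle(observations, major, minor, step=1e-4):
    """Exhaustive grid search over the minor fraction: the independent
    oracle for the likelihood maximiser."""
    obs_e = np.array([e for _b, e in observations])
    is_minor = np.array([b == minor for b, _e in observations])
    is_major = np.array([b == major for b, _e in observations])
    grid = np.arange(0.0, 1.0 + step / 2, step)[:, None]
    p = np.where(
        is_minor[None, :],
        grid * (1 - obs_e) + (1 - grid) * obs_e / 3,
        np.where(
            is_major[None, :],
            (1 - grid) * (1 - obs_e) + grid * obs_e / 3,
            obs_e / 3,
        ),
    )
    ll = np.log(p).sum(axis=1)
    i = int(np.argmax(ll))
    f_hat = float(grid[i, 0])
    d = 2.0 * (ll[i] - ll[0])
    return f_hat, max(d, 0.0)


def random_observations(rng, n_max=400):
    n = int(rng.integers(20, n_max))
    f_true = float(rng.uniform(0, 0.4))
    quals = rng.choice([20, 25, 30, 35], size=n)
    e = 10.0 ** (-quals / 10.0)
    bases = np.where(rng.random(n) < f_true, "G", "A")
    flip = rng.random(n) < e
    other = rng.choice(list("ACGT"), size=n)
    bases = np.where(flip, other, bases)
    return [(str(b), float(ei)) for b, ei in zip(bases, e)]


class TestLikelihood:
    def test_all_major_closed_form(self):
        obs = [("A", 0.001)] * 10
        assert site_loglik(obs, "A", "G", 0.0) == pytest.approx(10 * math.log(0.999))

    def test_symmetry_all_minor_at_f1(self):
        obs = [("G", 0.001)] * 10
        assert site_loglik(obs, "A", "G", 1.0) == pytest.approx(10 * math.log(0.999))

    def test_other_base_probability(self):
        obs = [("T", 0.01)]
        assert site_loglik(obs, "A", "G", 0.3) == pytest.approx(math.log(0.01 / 3))

    def test_empty_observations_signalled(self):
        with pytest.raises(ValueError, match="empty"):
            site_loglik([], "A", "G", 0.0)

    def test_grid_oracle_agreement(self):
        """MLE and LRT statistic agree with an exhaustive 1e-4 grid search
        on 100 random pileups."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            obs = random_observations(rng)
            f_hat, d = mle_level(obs, "A", "G")
            f_ref, d_ref = grid_oracle(obs, "A", "G")
            assert abs(f_hat - f_ref) <= 1e-4
            assert abs(d - d_ref) <= 1e-3

    def test_all_major_gives_zero(self):
        f_hat, d = mle_level([("A", 0.001)] * 50, "A", "G")
        assert f_hat == pytest.approx(0.0, abs=1e-6) and d == pytest.approx(0.0, abs=1e-9)

    def test_low_fraction_recovered(self):
        obs = [("G", 0.01)] * 15 + [("A", 0.01)] * 985
        f_hat, d = mle_level(obs, "A", "G")
        assert 0.010 <= f_hat <= 0.020
        f_ref, d_ref = grid_oracle(obs, "A", "G")
        assert abs(f_hat - f_ref) <= 1e-4 and abs(d - d_ref) <= 1e-3

    def test_saturation(self):
        f_hat, _ = mle_level([("G", 0.001)] * 1000, "A", "G")
        assert f_hat >= 0.99

    def test_level_symmetry(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            obs = random_observations(rng, n_max=200)
            f_ab, _ = mle_level(obs, "A", "G")
            f_ba, _ = mle_level(obs, "G", "A")
            assert f_ab == pytest.approx(1.0 - f_ba, abs=2e-6)


class TestStrandBias:
    def test_one_sided_alt_is_biased(self):
        p, biased = strand_bias_test(500, 500, 30, 0)
        # oracle: exhaustive hypergeometric two-sided p for this table
        from scipy.stats import hypergeom

        n_fwd, n_alt = 530, 30
        total = 1030
        pmf = hypergeom.pmf(np.arange(0, n_alt + 1), total, n_alt, n_fwd)
        p_ref = float(pmf[pmf <= pmf[30] * (1 + 1e-7)].sum())
        assert p == pytest.approx(p_ref, rel=1e-6)
        assert biased

    def test_symmetric_not_biased(self):
        _, biased = strand_bias_test(500, 500, 15, 15)
        assert not biased

    def test_all_zero_degenerate(self):
        assert strand_bias_test(0, 0, 0, 0) == (1.0, False)


def site_with_alt(alt_fwd, alt_rev, depth_fwd, depth_rev, quality=30, alt="G", pos=1):
    return PileupSite.from_counts(
        pos,
        fwd={"A": depth_fwd - alt_fwd, alt: alt_fwd},
        rev={"A": depth_rev - alt_rev, alt: alt_rev},
        quality=quality,
    )


class TestCallSite:
    def test_clear_low_level_variant_passes(self):
        site = site_with_alt(15, 15, 1000, 1000)
        (call,) = call_site(site, "A")
        assert call.is_pass
        assert call.level == pytest.approx(0.015, abs=0.003)

    def test_coverage_boundary_780(self):
        # ~1% level, evenly split: PASS at 780 total, LOW_COVERAGE at 779
        # (Q40 so the error-corrected level estimate stays above the floor)
        at_780 = site_with_alt(4, 4, 390, 390, quality=40)
        at_779 = site_with_alt(4, 4, 390, 389, quality=40)
        (call_hi,) = call_site(at_780, "A")
        (call_lo,) = call_site(at_779, "A")
        assert call_hi.is_pass
        assert call_lo.filter_flags == ("LOW_COVERAGE",)

    def test_below_floor_pruned_at_any_coverage(self):
        # 0.9% at huge coverage: statistically overwhelming, still pruned
        site = site_with_alt(225, 225, 25000, 25000)
        assert call_site(site, "A") == []

    def test_hard_floor_never_crossed(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            n = int(rng.integers(400, 3000))
            k = int(rng.integers(2, max(3, int(0.03 * n))))
            calls = call_site(site_with_alt(k, k, n, n), "A")
            for c in calls:
                assert c.level >= 0.01

    def test_both_strand_confirmation_required(self):
        without_rev = site_with_alt(30, 0, 1000, 1000)
        assert call_site(without_rev, "A") == []
        single_rev = site_with_alt(30, 1, 1000, 1000)
        assert call_site(single_rev, "A") == []

    def test_multiallelic_site(self):
        site = PileupSite.from_counts(
            7,
            fwd={"A": 900, "G": 50, "T": 50},
            rev={"A": 900, "G": 50, "T": 50},
            quality=30,
        )
        calls = call_site(site, "A")
        assert [c.alt for c in calls] == ["G", "T"]
        assert all(c.multiallelic for c in calls)

    def test_level_above_half_allowed(self):
        site = site_with_alt(800, 800, 1000, 1000)
        (call,) = call_site(site, "A")
        assert call.level > 0.5 and call.is_pass

    def test_masked_site_rejected(self):
        site = PileupSite.from_counts(1, {"A": 10}, {"A": 10}, masked=True)
        with pytest.raises(ValueError, match="masked"):
            call_site(site, "A")

    def test_strand_biased_candidate_suppressed(self):
        # alt levels differ ~25-fold between strands but both pass the LRT
        site = site_with_alt(300, 12, 1000, 1000)
        assert call_site(site, "A") == []
        config = CallerConfig(keep_strand_biased=True)
        calls = call_site(site, "A", config)
        assert calls and "STRAND_BIAS" in calls[0].filter_flags


class TestCallSample:
    def _table_with_variants(self, reference, variant_positions, level=0.5, depth=500):
        table = PileupTable(reference)
        for pos in range(1, reference.length + 1):
            ref_base = reference.base(pos)
            alt = "G" if ref_base != "G" else "T"
            k = int(depth * level) if pos in variant_positions else 0
            site = table.site(pos)
            idx_ref = "ACGT".index(ref_base)
            idx_alt = "ACGT".index(alt)
            for s in range(2):
                site.counts[s, idx_ref, 30] = depth - k
                site.counts[s, idx_alt, 30] = k
        return table

    def test_all_reference_pileup_is_quiet(self, small_reference):
        table = self._table_with_variants(small_reference, set())
        assert call_sample(table) == []

    def test_planted_variants_all_called(self, small_reference):
        planted = {3, 10, 17, 25, 38}
        table = self._table_with_variants(small_reference, planted)
        calls = call_sample(table)
        assert {c.pos for c in calls} == planted
        assert all(c.is_pass for c in calls)

    def test_output_sorted_by_pos_then_alt(self, small_reference):
        planted = {17, 3, 25}
        calls = call_sample(self._table_with_variants(small_reference, planted))
        keys = [(c.pos, c.alt) for c in calls]
        assert keys == sorted(keys)

    def test_masked_variant_absent(self):
        reference = ReferenceRepeat("unit", "A" * 40)
        from batchvar import ExclusionMask

        table = PileupTable(reference, ExclusionMask(intervals=((10, 12),)))
        for pos in (5, 11):
            site = table.site(pos)
            for s in range(2):
                site.counts[s, 0, 30] = 250
                site.counts[s, 2, 30] = 250
        calls = call_sample(table)
        assert {c.pos for c in calls} == {5}
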