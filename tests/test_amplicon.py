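"""Editing-profile quantification, windows, purity and perfect/dual metrics."""

import numpy as np
import pytest

from bequant import (
    AmpliconSimConfig, aggregate_mean_profile, align_reads, editing_window,
    perfect_and_dual_fractions, purity_metrics, quantify_site, revcomp,
    simulate_amplicon_reads, summarize_site,
)
from bequant.align import AlignedRead


def _read(site, edits=None, has_indel=False):
    """Synthetic AlignedRead: protospacer bases with optional {pos: base} edits."""
    bases = np.array(list(site.protospacer), dtype="<U1")
    for pos, b in (edits or {}).items():
        bases[pos - 1] = b
    return AlignedRead(read_id="r", score=0.0, has_indel=has_indel,
                       bases=bases)


class TestQuantify:
    def test_direct_count(self, polya_site):
        reads = [_read(polya_site, {5: "G"}) for _ in range(40)]
        reads += [_read(polya_site) for _ in range(60)]
        prof = quantify_site(reads, polya_site)
        assert prof.a2g[4] == pytest.approx(0.40)
        assert prof.indel_fraction == 0.0
        assert prof.coverage[4] == 100

    def test_indel_reads_excluded_from_denominator(self, polya_site):
        reads = [_read(polya_site, has_indel=True) for _ in range(10)]
        reads += [_read(polya_site, {5: "G"}) for _ in range(45)]
        reads += [_read(polya_site) for _ in range(45)]
        prof = quantify_site(reads, polya_site)
        assert prof.a2g[4] == pytest.approx(0.50)
        assert prof.indel_fraction == pytest.approx(0.10)
        # configurable denominator: indel reads carry no base calls here,
        # so including them leaves counts unchanged
        prof2 = quantify_site(reads, polya_site, include_indel_reads=True)
        assert prof2.n_indel_reads == 10

    def test_n_bases_never_count_as_edits(self, polya_site):
        reads = [_read(polya_site, {5: "N"}) for _ in range(10)]
        reads += [_read(polya_site, {5: "G"}) for _ in range(10)]
        prof = quantify_site(reads, polya_site)
        assert prof.coverage[4] == 10          # N dropped from denominator
        assert prof.a2g[4] == pytest.approx(1.0)

    def test_count_matrix_rows_sum_to_covering_reads(self, mixed_site):
        rng = np.random.default_rng(3)
        reads = [_read(mixed_site,
                       {int(rng.integers(1, 21)): "ACGT"[rng.integers(4)]})
                 for _ in range(50)]
        prof = quantify_site(reads, mixed_site)
        assert (prof.counts.sum(axis=(1, 2)) == 50).all()

    def test_zero_coverage_flagged(self, polya_site):
        bases = np.array(list(polya_site.protospacer), dtype="<U1")
        bases[19] = ""
        reads = [AlignedRead("r", 0.0, False, bases.copy()) for _ in range(5)]
        prof = quantify_site(reads, polya_site)
        assert prof.flagged_positions == [20]
        assert np.isnan(prof.a2g[19])

    def test_c_edit_frequency(self, mixed_site):
        # position 3 is a C; edit it to T in 30% of reads
        reads = [_read(mixed_site, {3: "T"}) for _ in range(30)]
        reads += [_read(mixed_site) for _ in range(70)]
        prof = quantify_site(reads, mixed_site)
        assert prof.c_edit[2] == pytest.approx(0.30)
        assert np.isnan(prof.c_edit[4])  # position 5 is an A


class TestAggregate:
    def test_single_profile_is_identity(self, polya_site):
        prof = quantify_site([_read(polya_site, {5: "G"})] * 10, polya_site)
        mean = aggregate_mean_profile([prof])
        np.testing.assert_allclose(mean.mean_a2g, prof.a2g, equal_nan=True)

    def test_two_site_mean(self, polya_site):
        p1 = quantify_site([_read(polya_site, {5: "G"})] * 2 +
                           [_read(polya_site)] * 8, polya_site)   # 0.2
        p2 = quantify_site([_read(polya_site, {5: "G"})] * 6 +
                           [_read(polya_site)] * 4, polya_site)   # 0.6
        mean = aggregate_mean_profile([p1, p2])
        assert mean.mean_a2g[4] == pytest.approx(0.4)
        assert mean.n_sites_a[4] == 2

    def test_non_a_positions_contribute_nothing(self, polya_site, mixed_site):
        p_a = quantify_site([_read(polya_site)] * 5, polya_site)
        p_m = quantify_site([_read(mixed_site)] * 5, mixed_site)
        mean = aggregate_mean_profile([p_a, p_m])
        # position 1: A only in the polyA site -> n=1
        assert mean.n_sites_a[0] == 1
        assert mean.n_sites_a[4] == 2

    def test_recovers_truth_across_102_sites(self, polya_site):
        """Across-site means track the truth: peak within 2 SEM, all 20
        positions within 3 SEM (simultaneous comparison)."""
        from bequant import gaussian_profile
        truth = gaussian_profile(20, 0.44)
        rng = np.random.default_rng(5)
        profiles = []
        n = 200
        for _ in range(102):
            hits = rng.random((n, 20)) < truth
            counts = np.zeros((20, 4, 4), dtype=np.int64)
            counts[:, 0, 2] = hits.sum(axis=0)
            counts[:, 0, 0] = n - hits.sum(axis=0)
            from bequant import EditingProfile
            profiles.append(EditingProfile("s", "A" * 20, n, 0, counts))
        mean = aggregate_mean_profile(profiles)
        sem = np.sqrt(truth * (1 - truth) / n) / np.sqrt(102)
        assert abs(mean.mean_a2g[4] - truth[4]) <= 2 * sem[4]
        assert (np.abs(mean.mean_a2g - truth) <= 3 * sem + 1e-12).all()


class TestWindow:
    def test_single_nonzero_position(self):
        v = np.zeros(20)
        v[4] = 0.5
        w = editing_window(v)
        assert w.window_positions == (5,)
        assert w.peak_position == 5

    def test_uniform_profile_includes_everything(self):
        w = editing_window(np.full(20, 0.3))
        assert w.window_positions == tuple(range(1, 21))
        assert w.peak_position == 1  # tie broken toward smallest index

    def test_threshold_scan_example(self):
        v = np.array([5, 10, 20, 40, 50, 45, 30, 14, 10, 5], dtype=float) / 100
        w = editing_window(v)
        assert w.peak_position == 5
        assert w.peak_value == pytest.approx(0.50)
        assert w.window_positions == (3, 4, 5, 6, 7)
        assert w.contiguous_window() == (3, 4, 5, 6, 7)

    def test_all_zero_profile_gives_empty_window(self):
        w = editing_window(np.zeros(20))
        assert w.window_positions == ()
        assert w.peak_value == 0.0

    def test_invariant_under_uniform_scaling(self):
        rng = np.random.default_rng(9)
        v = rng.random(20)
        for scale in (0.01, 0.5, 7.0):
            assert editing_window(v * scale).window_positions == \
                editing_window(v).window_positions

    def test_noncontiguous_set_vs_contiguous_view(self):
        v = np.array([0.5, 0.05, 0.4, 0.0, 0.0, 0.0], dtype=float)
        w = editing_window(v)
        assert w.window_positions == (1, 3)
        assert w.contiguous_window() == (1,)


class TestPurity:
    def test_bystander_sum_arithmetic(self, polya_site):
        reads = [_read(polya_site, {2: "G", 5: "G"})] * 5 \
            + [_read(polya_site, {5: "G"})] * 45 \
            + [_read(polya_site, {8: "G"})] * 4 \
            + [_read(polya_site)] * 46
        prof = quantify_site(reads, polya_site)
        s = purity_metrics(prof)
        assert s.a2_over_a5 == pytest.approx(0.05 / 0.50)
        assert s.a8_over_a5 == pytest.approx(0.04 / 0.50)
        assert s.bystander_sum == pytest.approx(0.18)

    def test_zero_c_edit_gives_zero_ratio(self, polya_site):
        reads = [_read(polya_site, {5: "G"})] * 4 + [_read(polya_site)] * 6
        s = purity_metrics(quantify_site(reads, polya_site))
        assert s.c5_over_a5 == 0.0

    def test_zero_a5_yields_nan_with_warning(self, polya_site):
        reads = [_read(polya_site)] * 10
        with pytest.warns(UserWarning, match="zero or undefined"):
            s = purity_metrics(quantify_site(reads, polya_site))
        assert np.isnan(s.a2_over_a5) and np.isnan(s.c5_over_a5)

    def test_simulated_ratios_recovered(self, polya_site):
        """Configured A2/A5 and A8/A5 recovered within 3 SD at 5000 reads."""
        p = np.zeros(20)
        p[1], p[4], p[7] = 0.05, 0.50, 0.04
        cfg = AmpliconSimConfig(seed=21, n_reads=5000, p_profile=p)
        reads, _ = simulate_amplicon_reads(polya_site, cfg)
        aligned, _ = align_reads(reads, polya_site)
        prof = quantify_site(aligned, polya_site)
        n = 5000
        for pos, truth in ((2, 0.05), (5, 0.50), (8, 0.04)):
            sd = np.sqrt(truth * (1 - truth) / n)
            assert abs(prof.a2g[pos - 1] - truth) <= 3 * sd
        s = purity_metrics(prof)
        assert s.bystander_sum == pytest.approx(0.18, abs=0.03)


class TestPerfectDual:
    def test_all_intended_only_reads_are_perfect(self, polya_site):
        reads = [_read(polya_site, {5: "G"})] * 10
        perfect, dual = perfect_and_dual_fractions(reads, polya_site)
        assert perfect == 1.0
        assert np.isnan(dual)  # single intended position

    def test_bystander_disqualifies_perfect(self, polya_site):
        reads = [_read(polya_site, {5: "G", 7: "G"})] * 10
        perfect, _ = perfect_and_dual_fractions(reads, polya_site)
        assert perfect == 0.0

    def test_indel_disqualifies_perfect(self, polya_site):
        reads = [_read(polya_site, {5: "G"}, has_indel=True)] * 4 \
            + [_read(polya_site, {5: "G"})] * 6
        perfect, _ = perfect_and_dual_fractions(reads, polya_site)
        assert perfect == pytest.approx(0.6)

    def test_dual_ignores_bystanders(self, dual_site):
        reads = [_read(dual_site, {4: "G", 7: "G", 9: "G"})] * 3 \
            + [_read(dual_site, {4: "G", 7: "G"})] * 3 \
            + [_read(dual_site, {4: "G"})] * 4
        perfect, dual = perfect_and_dual_fractions(reads, dual_site)
        assert dual == pytest.approx(0.6)
        assert perfect == pytest.approx(0.3)

    def test_independent_edits_give_product_dual_fraction(self, dual_site):
        """p4=p7=0.6 independent -> dual fraction ~ 0.36 (3 SD at 10k reads)."""
        p = np.zeros(20)
        p[3] = p[6] = 0.6
        cfg = AmpliconSimConfig(seed=33, n_reads=10_000, p_profile=p)
        reads, _ = simulate_amplicon_reads(dual_site, cfg)
        aligned, _ = align_reads(reads, dual_site)
        _, dual = perfect_and_dual_fractions(aligned, dual_site)
        sd = np.sqrt(0.36 * 0.64 / 10_000)
        assert abs(dual - 0.36) <= 3 * sd

    def test_perfect_bounded_by_min_intended_a2g(self, dual_site):
        rng = np.random.default_rng(8)
        reads = []
        for _ in range(300):
            edits = {}
            for pos in (4, 7, 10):
                if rng.random() < 0.5:
                    edits[pos] = "G"
            reads.append(_read(dual_site, edits,
                               has_indel=bool(rng.random() < 0.1)))
        prof = quantify_site(reads, dual_site)
        perfect, _ = perfect_and_dual_fractions(reads, dual_site)
        bound = min(prof.a2g[3], prof.a2g[6]) + prof.indel_fraction
        assert perfect <= bound + 1e-9


class TestStrandSymmetry:
    def test_minus_strand_quantification_matches_mirror(self, mixed_site):
        """Mirrored amplicon with mirrored reads yields identical profiles."""
        cfg = AmpliconSimConfig(seed=13, n_reads=400,
                                p_profile=np.full(20, 0.3),
                                c_edit_rate=0.1, indel_rate=0.05,
                                err_rate=0.002)
        reads, _ = simulate_amplicon_reads(mixed_site, cfg)
        mirror = mixed_site.mirrored()
        reads_rc = [(rid, revcomp(s)) for rid, s in reads]
        prof_fwd = quantify_site(align_reads(reads, mixed_site)[0], mixed_site)
        prof_rev = quantify_site(align_reads(reads_rc, mirror)[0], mirror)
        assert np.array_equal(prof_fwd.counts, prof_rev.counts)
        assert prof_fwd.n_indel_reads == prof_rev.n_indel_reads


def test_summarize_site_combines_all_metrics(polya_site):
    reads = [_read(polya_site, {5: "G"})] * 6 + [_read(polya_site)] * 4
    s = summarize_site(reads, polya_site)
    assert s.perfect_fraction == pytest.approx(0.6)
    assert s.indel_fraction == 0.0
    assert s.a2_over_a5 == 0.0
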