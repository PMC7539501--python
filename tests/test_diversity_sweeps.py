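import itertools
import math

import numpy as np
import pytest

from svorchard import (SweepRegion, region_overlap, rod_sweeps, site_pi,
                       sweep_summary, windowed_pi)
from svorchard.diversity_sweeps import WindowStat, _window_grid

from conftest import make_matrix


def pairwise_pi_oracle(dosages):
    """Average pairwise difference over every haplotype pair, enumerated
    explicitly from the dosage-implied haplotypes."""
    haplotypes = []
    for d in dosages:
        if d < 0:
            continue
        haplotypes += {0: [0, 0], 1: [0, 1], 2: [1, 1]}[d]
    pairs = list(itertools.combinations(haplotypes, 2))
    return sum(a != b for a, b in pairs) / len(pairs)


class TestSitePi:
    def test_two_hets_four_haplotypes(self):
        assert site_pi([1, 1]) == pytest.approx(2 / 3)

    def test_monomorphic(self):
        assert site_pi([0, 0, 0]) == 0.0
        assert site_pi([2, 2, 2]) == 0.0

    def test_allele_swap_symmetry(self):
        assert site_pi([0, 1, 2]) == site_pi([2, 1, 0])

    def test_needs_two_genotypes(self):
        with pytest.raises(ValueError):
            site_pi([1, -1])

    def test_equals_pairwise_enumeration_up_to_eight_haplotypes(self):
        for n_geno in range(2, 5):  # 4..8 haplotypes
            for dosages in itertools.product((0, 1, 2), repeat=n_geno):
                assert site_pi(list(dosages)) == pytest.approx(
                    pairwise_pi_oracle(dosages)), dosages


class TestWindowedPi:
    def test_single_site_window(self):
        m = make_matrix(np.array([[1], [1]]), ["wild", "wild"],
                        positions=[500])
        (w,) = windowed_pi(m, "wild", {"contig1": 1000},
                           window=1000, step=1000)
        assert w.pi["wild"] == pytest.approx((2 / 3) / 1000)
        assert w.n_sites == 1

    def test_empty_window_is_zero(self):
        m = make_matrix(np.array([[1], [1]]), ["wild", "wild"],
                        positions=[500])
        stats = windowed_pi(m, "wild", {"contig1": 3000},
                            window=1000, step=1000)
        assert [w.pi["wild"] for w in stats[1:]] == [0.0, 0.0]

    def test_tiling_and_truncation(self):
        starts = [s for s, _ in _window_grid(300, 100, 10)]
        assert starts == list(range(1, 301, 10))
        m = make_matrix(np.zeros((2, 1), dtype=np.int8), ["wild", "wild"],
                        positions=[10])
        stats = windowed_pi(m, "wild", {"contig1": 300}, window=100, step=10)
        assert not stats[0].truncated and stats[-1].truncated

    def test_single_window_limit_equals_whole_contig_pi(self):
        rng = np.random.default_rng(8)
        geno = rng.integers(0, 3, size=(6, 40)).astype(np.int8)
        positions = sorted(rng.choice(np.arange(1, 10_001), 40,
                                      replace=False).tolist())
        m = make_matrix(geno, ["wild"] * 6, positions=positions)
        (w,) = windowed_pi(m, "wild", {"contig1": 10_000},
                           window=10_000, step=10_000)
        expected = sum(site_pi(geno[:, j]) for j in range(40)) / 10_000
        assert w.pi["wild"] == pytest.approx(expected)

    def test_site_in_overlapping_windows_counts_in_all(self):
        m = make_matrix(np.array([[1], [1]]), ["wild", "wild"],
                        positions=[150])
        stats = windowed_pi(m, "wild", {"contig1": 300}, window=200, step=100)
        hit = [w.n_sites for w in stats]
        assert hit[0] == 1 and hit[1] == 1  # windows 1-200 and 101-300


def _windows(rods, group, chrom="c1", window=100_000, step=10_000):
    out = []
    for i, r in enumerate(rods):
        s = 1 + i * step
        out.append(WindowStat(chrom=chrom, start=s, end=s + window - 1,
                              n_sites=10, pi={group: r}))
    return out


class TestRodSweeps:
    def test_exactly_top_five_of_hundred(self):
        rng = np.random.default_rng(1)
        later = rng.uniform(0.5, 1.5, size=100)
        earlier = later * rng.permutation(np.linspace(1, 3, 100))
        we = _windows(earlier, "wild")
        wl = _windows(later, "landrace")
        flagged, _ = rod_sweeps(we, wl, top_fraction=0.05)
        rods = np.array([w.rod for w in flagged])
        assert sum(w.is_sweep for w in flagged) == 5
        assert set(np.array([w.start for w in flagged])[np.argsort(-rods)[:5]]) \
            == {w.start for w in flagged if w.is_sweep}

    def test_ties_resolve_in_genomic_order(self):
        flagged, _ = rod_sweeps(_windows([1.0] * 100, "wild"),
                                _windows([1.0] * 100, "landrace"))
        sweeps = [w.start for w in flagged if w.is_sweep]
        assert len(sweeps) == 5 and sweeps == sorted(sweeps)
        assert sweeps[0] == 1

    def test_zero_later_diversity_ranks_first(self):
        earlier = [1.0, 1.0, 1.0, 1.0]
        later = [1.0, 0.0, 1.0, 1.0]
        flagged, _ = rod_sweeps(_windows(earlier, "wild"),
                                _windows(later, "landrace"),
                                top_fraction=0.25)
        assert [w.is_sweep for w in flagged] == [False, True, False, False]
        assert math.isinf(flagged[1].rod)

    def test_both_zero_windows_excluded(self):
        flagged, _ = rod_sweeps(_windows([0.0, 1.0], "wild"),
                                _windows([0.0, 0.5], "landrace"),
                                top_fraction=0.5)
        assert math.isnan(flagged[0].rod) and not flagged[0].is_sweep
        assert flagged[1].is_sweep

    def test_overlapping_flagged_windows_merge(self):
        # windows 1-100k and 50,001-150k both flagged -> one region
        we = [WindowStat("c1", 1, 100_000, 5, {"wild": 3.0}),
              WindowStat("c1", 50_001, 150_000, 5, {"wild": 3.0}),
              WindowStat("c1", 500_001, 600_000, 5, {"wild": 0.1})]
        wl = [WindowStat("c1", 1, 100_000, 5, {"landrace": 1.0}),
              WindowStat("c1", 50_001, 150_000, 5, {"landrace": 1.0}),
              WindowStat("c1", 500_001, 600_000, 5, {"landrace": 1.0})]
        _, regions = rod_sweeps(we, wl, top_fraction=2 / 3, step=50_000)
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (1, 150_000)
        assert regions[0].n_windows == 2

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            rod_sweeps(_windows([1.0], "wild"), _windows([1.0, 2.0], "landrace"))


class TestRegionOverlap:
    def r(self, start, end, chrom="c1"):
        return SweepRegion(chrom=chrom, start=start, end=end, n_windows=1)

    def test_partial_overlap(self):
        assert region_overlap([self.r(1, 100)], [self.r(51, 150)]) == 50

    def test_disjoint_and_identical(self):
        assert region_overlap([self.r(1, 100)], [self.r(200, 300)]) == 0
        assert region_overlap([self.r(1, 100)], [self.r(1, 100)]) == 100

    def test_symmetric(self):
        a = [self.r(1, 100), self.r(500, 900)]
        b = [self.r(50, 600)]
        assert region_overlap(a, b) == region_overlap(b, a)

    def test_summary_fractions(self):
        s = sweep_summary([self.r(1, 1_000_000)], genome_length=10_000_000)
        assert s["n_regions"] == 1
        assert s["total_mb"] == pytest.approx(1.0)
        assert s["pct_genome"] == pytest.approx(10.0)
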