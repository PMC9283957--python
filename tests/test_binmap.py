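"""Bin construction, filters, recombination fractions, Kosambi distances,
map assembly and summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from binqtl import binmap, reference_tables
from binqtl.binmap import (
    BinMarker,
    LinkageGroup,
    aggregate_map_table,
    assemble_map,
    build_bins,
    collinearity,
    detect_breakpoints,
    estimate_rf,
    filter_bins,
    kosambi_cm,
    kosambi_inverse,
    map_summary,
)
from binqtl.core import AA, AB, BB, MISSING, SnpCallMatrix


def _matrix(tracks, positions, chrom="A01"):
    """tracks: list per individual of call lists."""
    arr = np.asarray(tracks, dtype=np.int8).T
    return SnpCallMatrix(
        np.asarray([chrom] * arr.shape[0], dtype=object),
        np.asarray(positions, dtype=np.int64),
        arr,
        [f"i{k}" for k in range(arr.shape[1])],
        "ril",
    )


class TestBreakpoints:
    def test_uniform_track_has_none(self):
        calls = _matrix([[AA] * 5], [10, 20, 30, 40, 50])
        bps = detect_breakpoints(calls)
        assert bps[0]["A01"].size == 0

    def test_midpoint_convention(self):
        calls = _matrix([[AA, AA, AA, BB, BB]], [10_000, 20_000, 30_000, 40_000, 50_000])
        bps = detect_breakpoints(calls)
        assert list(bps[0]["A01"]) == [35_000]

    def test_het_run_crossed_by_single_midpoint_breakpoint(self):
        calls = _matrix([[AA, AA, AB, AB, BB, BB]], [10, 20, 30, 40, 50, 60])
        bps = detect_breakpoints(calls)
        assert list(bps[0]["A01"]) == [(20 + 50) // 2]

    def test_recovers_simulated_breakpoints(self, clean_ril, dense_map):
        calls, truth, _, _ = clean_ril
        bps = detect_breakpoints(calls)
        spacing = np.diff(dense_map.snp_positions["A01"]).max()
        for i in range(50):
            for c in ("A01", "A02"):
                true_bp = truth.breakpoints(i, c)
                pos = dense_map.snp_positions[c]
                # keep truth junctions that are detectable at SNP resolution
                visible = true_bp[(true_bp > pos[0]) & (true_bp < pos[-1])]
                got = bps[i][c]
                # genotype-changing junctions only (AB segments can merge)
                if visible.size == got.size:
                    assert (np.abs(np.sort(visible) - np.sort(got)) <= spacing + 1).all()


class TestBins:
    def test_no_breakpoints_single_bin(self):
        calls = _matrix([[AA] * 4, [BB] * 4], [10, 20, 30, 40])
        bins = build_bins(calls, detect_breakpoints(calls))
        assert len(bins) == 1
        assert (bins[0].start, bins[0].end) == (0, 41)

    def test_union_of_breakpoints_partition(self):
        # ind 1 breaks at 100 kb, ind 2 at 200 kb on a 300 kb chromosome
        pos = [50_000, 90_000, 110_000, 190_000, 210_000, 290_000]
        t1 = [AA, AA, BB, BB, BB, BB]
        t2 = [AA, AA, AA, AA, BB, BB]
        calls = _matrix([t1, t2], pos)
        bins = build_bins(calls, detect_breakpoints(calls))
        assert [(b.start, b.end) for b in bins] == [
            (0, 100_000), (100_000, 200_000), (200_000, 290_001),
        ]

    def test_no_homozygous_transition_inside_any_bin(self, corrected_groups, noisy_ril):
        calls, _, _, _ = noisy_ril
        from binqtl.genocorrect import slide_correct

        corrected = slide_correct(calls)
        bins = build_bins(corrected, detect_breakpoints(corrected))
        for b in bins:
            idx = corrected.chrom_index(b.chrom)
            inside = idx[(corrected.pos[idx] >= b.start) & (corrected.pos[idx] < b.end)]
            block = corrected.calls[inside]
            for k in range(block.shape[1]):
                hom = block[:, k][(block[:, k] == AA) | (block[:, k] == BB)]
                assert hom.size == 0 or (hom == hom[0]).all()


class TestFilters:
    def _bin(self, length, n_aa, n_bb, chrom="A01", start=0):
        geno = np.array([AA] * n_aa + [BB] * n_bb, dtype=np.int8)
        return BinMarker(chrom, start, start + length, 5, geno)

    def test_short_bin_removed_for_length(self):
        bins = [self._bin(9_999, 79, 79), self._bin(20_000, 79, 79, start=9_999)]
        kept, log = filter_bins(bins, rescue_density_per_bp=None)
        assert len(kept) == 1
        assert log.iloc[0]["reason"] == "length"

    def test_balanced_segregation_retained(self):
        kept, _ = filter_bins([self._bin(20_000, 79, 79)], rescue_density_per_bp=None)
        assert len(kept) == 1

    def test_distorted_segregation_removed(self):
        # chi2 = (120-79)^2/79 + (38-79)^2/79 = 42.56, p << 0.001
        chi2, p = stats.chisquare([120, 38])
        assert abs(chi2 - 42.56) < 0.02 and p < 0.001
        kept, log = filter_bins([self._bin(20_000, 120, 38)], rescue_density_per_bp=None)
        assert len(kept) == 0
        assert log.iloc[0]["reason"] == "segregation"

    def test_order_independence(self):
        rng = np.random.default_rng(0)
        bins = [
            self._bin(int(rng.integers(5_000, 50_000)), int(rng.integers(50, 110)),
                      int(rng.integers(50, 110)), start=i * 60_000)
            for i in range(20)
        ]
        kept1, _ = filter_bins(list(bins), rescue_density_per_bp=None)
        perm = [bins[i] for i in rng.permutation(len(bins))]
        kept2, _ = filter_bins(perm, rescue_density_per_bp=None)
        assert {id(b) for b in kept1} == {id(b) for b in kept2}

    def test_rescue_pass_restores_low_density_chromosome(self):
        bins = [self._bin(9_000, 79, 79, start=i * 9_000) for i in range(4)]
        kept, _ = filter_bins(bins, rescue_density_per_bp=1.0 / 20_000)
        assert len(kept) >= 2  # floor = ceil(36000 / 20000) = 2


class TestRecombination:
    def test_identical_vectors_zero(self):
        g = np.array([AA, BB] * 20, dtype=np.int8)
        r, n, low = estimate_rf(g, g)
        assert r == 0.0 and n == 40 and not low

    def test_ril_inversion(self):
        # R = 1/3 -> r = (1/3) / (2 * 2/3) = 0.25
        g1 = np.array([AA] * 6, dtype=np.int8)
        g2 = np.array([AA, AA, AA, AA, BB, BB], dtype=np.int8)
        r, n, low = estimate_rf(g1, g2)
        assert abs(r - 0.25) < 1e-12 and low  # 6 scorable -> low confidence

    def test_simulation_recovery(self):
        from binqtl.simpop import ChromosomeSpec, GeneticMapSpec, SimConfig, simulate_ril_population

        d = -50.0 * np.log(1.0 - 2 * 0.1)  # Haldane distance for r = 0.1
        gmap = GeneticMapSpec(
            [ChromosomeSpec("A01", 1_000_000, d)],
            {"A01": np.array([1, 999_999])}, "haldane")  # markers span the map
        cfg = SimConfig(seed=17, n_ril=2000, genotyping_error_rate=0, missing_rate=0)
        calls, _ = simulate_ril_population(gmap, cfg)
        r, n, _ = estimate_rf(calls.calls[0], calls.calls[1])
        se_big_r = np.sqrt((1 / 6) * (5 / 6) / n)
        # propagate through the inversion: dr/dR at R=1/6 is ~0.72
        assert abs(r - 0.1) < 3 * 0.72 * se_big_r

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        g1 = rng.choice([AA, BB, AB, MISSING], 100).astype(np.int8)
        g2 = rng.choice([AA, BB, AB, MISSING], 100).astype(np.int8)
        assert estimate_rf(g1, g2)[0] == estimate_rf(g2, g1)[0]


class TestKosambi:
    @pytest.mark.parametrize(
        "r,expected",
        [(0.0, 0.0), (0.2, 25 * np.log(1.4 / 0.6)), (0.49, 25 * np.log(99.0))],
    )
    def test_closed_form(self, r, expected):
        assert abs(kosambi_cm(r) - expected) < 1e-9
        assert abs(kosambi_cm(0.2) - 21.18) < 0.01
        assert abs(kosambi_cm(0.49) - 114.88) < 0.01

    def test_round_trip(self):
        r = np.linspace(0.0, 0.49, 50)
        assert np.abs(kosambi_inverse(kosambi_cm(r)) - r).max() < 1e-10

    def test_monotone_and_domain(self):
        d = kosambi_cm(np.linspace(0, 0.49, 100))
        assert (np.diff(d) > 0).all()
        with pytest.raises(ValueError):
            kosambi_cm(0.5)


class TestMapAssembly:
    def _groups_from_vectors(self, vectors):
        bins = [
            BinMarker("A01", i * 100_000, (i + 1) * 100_000, 10, np.asarray(v, dtype=np.int8))
            for i, v in enumerate(vectors)
        ]
        return assemble_map(bins)

    def test_zero_rf_collapses_to_zero_cm(self):
        g = [AA] * 20 + [BB] * 20
        groups = self._groups_from_vectors([g, g, g])
        assert np.allclose(groups[0].cm, 0.0)

    def test_cumulative_kosambi_positions(self):
        # adjacent r = 0.1 then 0.2 -> cumulative 0, 10.14, 31.32 cM
        n = 42
        base = np.array([AA] * 21 + [BB] * 21, dtype=np.int8)
        v2 = base.copy()
        v2[:7] = np.where(base[:7] == AA, BB, AA)  # R = 7/42 = 1/6 -> r = 0.1
        v3 = v2.copy()
        v3[n - 12:] = np.where(v2[n - 12:] == AA, BB, AA)  # R = 12/42 = 2/7 -> r = 0.2
        groups = self._groups_from_vectors([base, v2, v3])
        assert np.allclose(groups[0].cm, [0.0, 10.136628, 31.319074], atol=1e-4)
        assert groups[0].cm[2] == pytest.approx(kosambi_cm(0.1) + kosambi_cm(0.2))

    def test_simulated_map_length_within_15_percent(self, clean_groups):
        for g in clean_groups:
            assert abs(g.cm[-1] - 50.0) / 50.0 < 0.15

    def test_map_summary_single_group(self):
        g = LinkageGroup(
            "A01",
            [BinMarker("A01", 0, 10, 1, np.array([AA], dtype=np.int8)),
             BinMarker("A01", 10, 20, 1, np.array([AA], dtype=np.int8))],
            np.array([0.0, 10.0]),
        )
        per = binmap.group_table([g])
        row = per.iloc[0]
        assert row["total_cm"] == 10.0 and row["avg_cm"] == 5.0
        assert row["max_gap_cm"] == 10.0 and row["gaps_lt5_frac"] == 0.0


class TestPublishedMapTable:
    def test_subgenome_aggregates(self):
        rows = reference_tables.linkage_map_characteristics()
        agg = aggregate_map_table(rows)
        assert agg["A"]["n_bins"] == 1577
        assert agg["A"]["total_cm"] == 968.89
        assert agg["C"]["n_bins"] == 1222
        assert agg["C"]["total_cm"] == 866.32
        assert agg["genome"]["n_bins"] == 2799
        assert agg["genome"]["avg_cm"] == 0.66

    def test_per_group_average_convention(self):
        rows = reference_tables.linkage_map_characteristics()
        # the printed per-group averages follow total distance / bin count
        recomputed = (rows["total_cm"] / rows["n_bins"]).round(2)
        assert (np.abs(recomputed - rows["avg_cm"]) <= 0.005 + 1e-9).all()


class TestCollinearity:
    def _group_with_cm(self, cm):
        bins = [
            BinMarker("A01", i * 1000, (i + 1) * 1000, 1, np.array([AA], dtype=np.int8))
            for i in range(len(cm))
        ]
        return LinkageGroup("A01", bins, np.asarray(cm, dtype=float))

    def test_perfect_and_reversed_order(self):
        g = self._group_with_cm(np.arange(10.0))
        assert collinearity([g])["spearman_rho"].iloc[0] == pytest.approx(1.0)
        # reversed genetic order against physical order
        bins = list(reversed(g.bins))
        rev = LinkageGroup("A01", bins, np.arange(10.0))
        assert collinearity([rev])["spearman_rho"].iloc[0] == pytest.approx(-1.0)

    def test_random_permutation_near_zero(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            cm = np.sort(rng.uniform(0, 100, 50))
            bins = [
                BinMarker("A01", int(s) * 1000, int(s) * 1000 + 500, 1,
                          np.array([AA], dtype=np.int8))
                for s in rng.permutation(50)
            ]
            g = LinkageGroup("A01", bins, cm)
            rho = collinearity([g])["spearman_rho"].iloc[0]
            assert abs(rho) < 0.4

    def test_small_groups_skipped(self):
        g = self._group_with_cm([0.0, 1.0])
        assert len(collinearity([g])) == 0
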