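"""Composite interval mapping: regression identities, permutation thresholds,
QTL calling, the multi-environment scan and the flanking-marker test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from binqtl import qtlscan
from binqtl.binmap import BinMarker, LinkageGroup
from binqtl.core import AA, BB
from binqtl.qtlscan import (
    QtlScanResult,
    ScanSettings,
    call_qtl,
    cim_scan,
    flanking_group_test,
    multi_env_scan,
    permutation_threshold,
)


def _single_bin_group(geno, cm=0.0):
    b = BinMarker("A01", 0, 100_000, 10, np.asarray(geno, dtype=np.int8))
    return LinkageGroup("A01", [b], np.array([cm]))


def _chain_group(genos, cms, chrom="A01"):
    bins = [
        BinMarker(chrom, i * 100_000, (i + 1) * 100_000, 10, np.asarray(g, dtype=np.int8))
        for i, g in enumerate(genos)
    ]
    return LinkageGroup(chrom, bins, np.asarray(cms, dtype=float))


def brute_single_marker_lod(x, y):
    """Independent oracle: single-marker regression LOD."""
    X = np.column_stack([np.ones_like(y), x])
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    rss_full = float(((y - X @ beta) ** 2).sum())
    rss_red = float(((y - y.mean()) ** 2).sum())
    return (len(y) / 2.0) * np.log10(rss_red / rss_full)


class TestCimScan:
    def test_lod_matches_single_marker_regression_at_bins(self):
        rng = np.random.default_rng(0)
        n = 120
        genos = [rng.choice([AA, BB], n).astype(np.int8) for _ in range(5)]
        group = _chain_group(genos, [0.0, 5.0, 10.0, 15.0, 20.0])
        x = np.where(np.asarray(genos[2]) == AA, 1.0, -1.0)
        y = 40 + 0.8 * x + rng.normal(0, 2, n)
        st = ScanSettings(n_cofactors=0, step=5.0)
        scan = cim_scan([group], y, st)
        at_bin = np.flatnonzero(np.isclose(scan.cm, 10.0))[0]
        assert abs(scan.lod[at_bin] - brute_single_marker_lod(x, y)) < 1e-8

    def test_lod_affine_invariant(self, clean_groups, clean_ril):
        _, _, pheno, _ = clean_ril
        y = pheno["value"].to_numpy()
        st = ScanSettings()
        lod1 = cim_scan(clean_groups, y, st).lod
        lod2 = cim_scan(clean_groups, 3.0 * y - 17.0, st).lod
        assert np.abs(lod1 - lod2).max() < 1e-8

    def test_constant_phenotype_gives_zero_lod(self, clean_groups):
        n = len(clean_groups[0].bins[0].genotypes)
        scan = cim_scan(clean_groups, np.full(n, 40.0))
        assert (scan.lod == 0).all()

    def test_additive_effect_is_half_homozygote_difference(self):
        geno = np.array([AA] * 30 + [BB] * 30, dtype=np.int8)
        y = np.where(geno == AA, 41.0, 39.0)  # AA mean - BB mean = 2 exactly
        scan = cim_scan([_single_bin_group(geno)], y, ScanSettings(n_cofactors=0))
        assert scan.add[0] == pytest.approx(1.0, abs=1e-9)

    def test_planted_qtl_recovered(self, corrected_groups, noisy_ril):
        calls, truth, pheno, _ = noisy_ril
        y = (
            pheno.groupby("individual", sort=False)["value"].mean()
            .reindex(calls.samples).to_numpy()
        )
        scan = cim_scan(corrected_groups, y)
        i = int(scan.lod.argmax())
        g0 = next(g for g in corrected_groups if g.id == "A01")
        true_cm = next(
            cm for b, cm in zip(g0.bins, g0.cm) if b.start <= 10_000_000 < b.end
        )
        assert scan.group[i] == "A01"
        assert abs(scan.cm[i] - true_cm) < 10.0
        assert scan.add[i] > 0  # planted effect is +1 on the parent-1 allele


class TestPermutationThreshold:
    def test_alpha_one_is_minimum_and_monotone(self):
        rng = np.random.default_rng(1)
        group = _single_bin_group(rng.choice([AA, BB], 80).astype(np.int8))
        y = rng.normal(40, 3, 80)
        st1 = ScanSettings(n_cofactors=0, n_permutations=200, alpha=1.0)
        thr1, maxima = permutation_threshold([group], y, st1, seed=5)
        assert thr1 == maxima.min()
        thrs = []
        for alpha in (0.5, 0.2, 0.05, 0.01):
            st = ScanSettings(n_cofactors=0, n_permutations=200, alpha=alpha)
            t, _ = permutation_threshold([group], y, st, seed=5)
            thrs.append(t)
        assert (np.diff(thrs) >= 0).all()

    def test_single_marker_null_matches_f_distribution(self):
        rng = np.random.default_rng(2)
        n = 120
        group = _single_bin_group(rng.choice([AA, BB], n).astype(np.int8))
        y = rng.normal(40, 3, n)
        st = ScanSettings(n_cofactors=0, n_permutations=2000, alpha=0.05)
        thr, _ = permutation_threshold([group], y, st, seed=3)
        f_crit = stats.f.ppf(0.95, 1, n - 2)
        lod_closed = (n / 2.0) * np.log10((n - 2 + f_crit) / (n - 2))
        assert abs(thr - lod_closed) < 0.15

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(4)
        group = _single_bin_group(rng.choice([AA, BB], 60).astype(np.int8))
        y = rng.normal(0, 1, 60)
        st = ScanSettings(n_cofactors=0, n_permutations=150)
        t1, m1 = permutation_threshold([group], y, st, seed=9)
        t2, m2 = permutation_threshold([group], y, st, seed=9)
        assert t1 == t2 and np.array_equal(m1, m2)

    def test_warns_on_few_permutations(self):
        rng = np.random.default_rng(5)
        group = _single_bin_group(rng.choice([AA, BB], 40).astype(np.int8))
        with pytest.warns(UserWarning):
            permutation_threshold(
                [group], rng.normal(0, 1, 40),
                ScanSettings(n_cofactors=0, n_permutations=50), seed=1,
            )


class TestCallQtl:
    def test_empty_above_threshold(self):
        scan = QtlScanResult(
            group=np.array(["A01"] * 5, dtype=object),
            cm=np.arange(5.0), lod=np.ones(5), add=np.zeros(5), pve=np.zeros(5), n=100,
        )
        assert call_qtl(scan, threshold=2.0) == []

    def test_peak_interval_and_disjointness(self):
        lod = np.array([0.5, 1, 4, 6, 4, 1, 0.5, 1, 3.5, 5, 3.5, 1, 0.5])
        scan = QtlScanResult(
            group=np.array(["A01"] * 13, dtype=object),
            cm=np.arange(13.0) * 2,  # peaks at 6 cM and 18 cM, >= window apart
            lod=lod, add=np.ones(13), pve=np.ones(13), n=100,
        )
        recs = call_qtl(scan, threshold=3.0, settings=ScanSettings(cofactor_window=10))
        assert len(recs) == 2
        r1, r2 = recs
        assert r1.interval_lo <= r1.peak_cm <= r1.interval_hi
        assert r1.interval_hi < r2.interval_lo  # disjoint within group
        # 1-LOD drop: first peak LOD 6 -> interval covers LOD >= 5
        assert (r1.interval_lo, r1.peak_cm, r1.interval_hi) == (6.0, 6.0, 6.0)

    def test_interval_covers_true_position(self, corrected_groups, noisy_ril):
        calls, _, pheno, _ = noisy_ril
        y = (
            pheno.groupby("individual", sort=False)["value"].mean()
            .reindex(calls.samples).to_numpy()
        )
        scan = cim_scan(corrected_groups, y)
        recs = call_qtl(scan, threshold=3.0)
        assert any(r.group == "A01" for r in recs)


class TestMultiEnv:
    def test_replicated_phenotype_has_no_interaction(self, corrected_groups, noisy_ril):
        calls, _, pheno, _ = noisy_ril
        env1 = pheno[pheno["environment"] == "E1"]
        twice = pd.concat(
            [env1, env1.assign(environment="E2")], ignore_index=True
        )
        joint = multi_env_scan(corrected_groups, twice, samples=calls.samples)
        single = cim_scan(
            corrected_groups,
            env1.set_index("individual")["value"].reindex(calls.samples).to_numpy(),
        )
        assert joint.pve_interaction.max() < 1e-6
        i_j, i_s = int(joint.lod.argmax()), int(single.lod.argmax())
        assert joint.group[i_j] == single.group[i_s]
        assert abs(joint.cm[i_j] - single.cm[i_s]) <= 2.0

    def test_gxe_contrast(self, dense_map):
        from binqtl import binmap, genocorrect, simpop

        results = {}
        for tag, (a, dev) in {"equal": (1.0, None), "opposite": (0.0, (1.0, -1.0))}.items():
            cfg = simpop.SimConfig(
                seed=9, n_ril=200, n_environments=2, target_h2=0.3,
                qtl_spec=[simpop.QtlSpec("A01", 10_000_000, a, dev)],
                genotyping_error_rate=0.0, missing_rate=0.0,
            )
            calls, truth = simpop.simulate_ril_population(dense_map, cfg)
            pheno = simpop.simulate_phenotypes(truth, calls, cfg)
            bins = binmap.build_bins(calls, binmap.detect_breakpoints(calls))
            retained, _ = binmap.filter_bins(bins)
            groups = binmap.assemble_map(retained)
            joint = multi_env_scan(groups, pheno, samples=calls.samples)
            i = int(joint.lod.argmax())
            results[tag] = (joint.pve[i], joint.pve_interaction[i])
        assert results["equal"][0] > results["equal"][1]
        assert results["opposite"][1] > results["opposite"][0]


class TestFlankingGroupTest:
    def test_equal_constant_groups(self):
        g = np.array([AA, AA, BB, BB], dtype=np.int8)
        out = flanking_group_test(g, g, np.array([40.0, 40.0, 40.0, 40.0]))
        assert out["t"] == 0.0 and out["p"] == 1.0

    def test_hand_computed_welch(self):
        g1 = np.array([AA, AA, AA, BB, BB, BB], dtype=np.int8)
        out = flanking_group_test(g1, g1, np.array([40.0, 41, 42, 36, 37, 38]))
        assert out["mean_aa"] - out["mean_bb"] == pytest.approx(4.0)
        assert out["t"] == pytest.approx(4.899, abs=0.01)
        assert out["p"] < 0.05

    def test_mixed_genotypes_excluded_and_small_groups_reported_only(self):
        b1 = np.array([AA, AA, BB, BB, AA], dtype=np.int8)
        b2 = np.array([AA, BB, BB, BB, AA], dtype=np.int8)
        y = np.array([40.0, 41, 39, 38, 42])
        out = flanking_group_test(b1, b2, y)
        assert out["n_aa"] == 2 and out["n_bb"] == 2
        out2 = flanking_group_test(b1[:3], b2[:3], y[:3])
        assert np.isnan(out2["t"])  # one group has < 2 members

    def test_recovers_twice_additive_effect(self, corrected_groups, noisy_ril):
        calls, truth, pheno, cfg = noisy_ril
        y = (
            pheno.groupby("individual", sort=False)["value"].mean()
            .reindex(calls.samples).to_numpy()
        )
        g0 = next(g for g in corrected_groups if g.id == "A01")
        k = next(i for i, b in enumerate(g0.bins) if b.start <= 10_000_000 < b.end)
        left, right = g0.bins[max(k - 1, 0)], g0.bins[min(k + 1, len(g0.bins) - 1)]
        out = flanking_group_test(left.genotypes, right.genotypes, y)
        diff = out["mean_aa"] - out["mean_bb"]
        se = np.sqrt(4.0 / out["n_aa"])  # rough scale guard
        assert abs(diff - 2.0 * cfg.qtl_spec[0].a) < 4 * se + 0.5
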