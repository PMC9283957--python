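"""Association stack: MAF filter, kinship, EMMAX identities and calibration,
LD decay and haplotype grouping."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from binqtl import mlmgwas, simpop
from binqtl.core import AA, AB, BB, MISSING, SnpCallMatrix
from binqtl.mlmgwas import (
    KinshipMatrix,
    emmax_assoc,
    haplotype_test,
    kinship,
    ld_decay,
    maf_filter,
    pairwise_r2,
    significance_threshold,
    snp_maf,
)


def _panel_from_dosage(dos, chrom="A01"):
    """dos: m x n array in {0, 2} (inbred) or {0,1,2}."""
    codes = np.where(dos == 0, AA, np.where(dos == 1, AB, BB)).astype(np.int8)
    m = codes.shape[0]
    return SnpCallMatrix(
        np.asarray([chrom] * m, dtype=object),
        (np.arange(m) + 1) * 10_000,
        codes,
        [f"a{k}" for k in range(codes.shape[1])],
        "panel",
    )


class TestMafFilter:
    def test_monomorphic_removed(self):
        calls = _panel_from_dosage(np.zeros((3, 50)))
        assert maf_filter(calls).n_markers == 0

    def test_boundary_at_panel_size(self):
        # 11 minor homozygotes among 204 inbreds: MAF = 11/204 = 0.0539 > 0.05
        row = np.zeros((1, 204))
        row[0, :11] = 2
        assert maf_filter(_panel_from_dosage(row)).n_markers == 1
        row10 = np.zeros((1, 204))
        row10[0, :10] = 2  # 10/204 = 0.049 <= 0.05 -> removed
        assert maf_filter(_panel_from_dosage(row10)).n_markers == 0

    def test_matches_brute_force_recount(self, structured_panel):
        calls, _ = structured_panel
        kept = maf_filter(calls, 0.05)
        expected = []
        for i in range(calls.n_markers):
            row = calls.calls[i]
            alleles = []
            for g in row:
                if g == AA:
                    alleles += [0, 0]
                elif g == AB:
                    alleles += [0, 1]
                elif g == BB:
                    alleles += [1, 1]
            f = np.mean(alleles)
            if min(f, 1 - f) > 0.05:
                expected.append(i)
        assert kept.n_markers == len(expected)
        assert np.array_equal(kept.pos, calls.pos[expected])


class TestKinship:
    def test_duplicated_accession(self):
        rng = np.random.default_rng(0)
        dos = rng.choice([0, 2], size=(200, 30)).astype(float)
        dos[:, 1] = dos[:, 0]
        K = kinship(_panel_from_dosage(dos))
        assert K.values[0, 1] == pytest.approx(K.values[0, 0], abs=1e-10)

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(1)
        dos = rng.choice([0, 1, 2], size=(100, 15)).astype(float)
        calls = _panel_from_dosage(dos)
        K = kinship(calls)
        p = dos.mean(axis=1) / 2.0
        z = dos - 2 * p[:, None]
        denom = 2 * np.sum(p * (1 - p))
        for i in range(15):
            for j in range(15):
                assert K.values[i, j] == pytest.approx(float(z[:, i] @ z[:, j]) / denom, abs=1e-10)

    def test_invariant_to_snp_order_and_duplication(self):
        rng = np.random.default_rng(2)
        dos = rng.choice([0, 2], size=(150, 25)).astype(float)
        K1 = kinship(_panel_from_dosage(dos)).values
        K2 = kinship(_panel_from_dosage(dos[rng.permutation(150)])).values
        assert np.allclose(K1, K2, atol=1e-12)
        K3 = kinship(_panel_from_dosage(np.vstack([dos, dos]))).values
        assert np.allclose(K1, K3, atol=1e-12)

    def test_relative_kinship_separates_within_from_between_subpops(self, structured_panel):
        # in a structured panel the floored "relative kinship" is zero for
        # most cross-subpopulation pairs and positive within subpopulations;
        # the bulk of all pairs reports zero, as in large diversity panels
        calls, labels = structured_panel
        k = kinship(maf_filter(calls)).relative()
        n = k.shape[0]
        iu = np.triu_indices(n, 1)
        same = labels[iu[0]] == labels[iu[1]]
        zero_cross = (k[iu][~same] == 0).mean()
        zero_within = (k[iu][same] == 0).mean()
        assert zero_cross > 0.7
        assert zero_within < 0.1
        assert (k[iu] == 0).mean() > 0.5


def exact_reml_p(y, x, K):
    """Independent oracle: full REML refit per SNP via the generic
    log-likelihood (log det V + log det X'V^-1X + profiled quadratic)."""
    n = len(y)
    X = np.column_stack([np.ones(n), x])
    q = X.shape[1]

    def negll(log_delta):
        V = K + np.exp(log_delta) * np.eye(n)
        Vi = np.linalg.inv(V)
        XtViX = X.T @ Vi @ X
        beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
        r = y - X @ beta
        _, ld = np.linalg.slogdet(V)
        _, ld2 = np.linalg.slogdet(XtViX)
        return 0.5 * ((n - q) * np.log(float(r @ Vi @ r)) + ld + ld2)

    res = optimize.minimize_scalar(negll, bounds=(-10, 10), method="bounded")
    V = K + np.exp(res.x) * np.eye(n)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    sg2 = float(r @ Vi @ r) / (n - q)
    se_b = np.sqrt(sg2 * np.linalg.inv(XtViX)[1, 1])
    return 2 * stats.t.sf(abs(beta[1] / se_b), n - q)


@pytest.fixture(scope="module")
def toy_panel():
    cfg = simpop.SimConfig(seed=13, panel=simpop.PanelConfig(
        n_accessions=50, k_subpops=2, fst=0.15,
        chromosomes=(("A01", 5_000_000, 200),), ld_decay_bp=50_000))
    panel, _ = simpop.simulate_structured_panel(cfg)
    filt = maf_filter(panel)
    return filt, kinship(filt)


class TestEmmax:
    def test_identity_kinship_equals_ols(self, toy_panel):
        filt, _ = toy_panel
        n = filt.n_individuals
        rng = np.random.default_rng(3)
        y = rng.normal(40, 2, n)
        res = emmax_assoc(y, filt, KinshipMatrix(np.eye(n), filt.samples))
        d = filt.dosage()
        mu = np.nanmean(d, axis=1)
        d = np.where(np.isnan(d), mu[:, None], d)
        for j in range(0, filt.n_markers, 17):
            x = d[j]
            if x.std() == 0:
                continue
            X = np.column_stack([np.ones(n), x])
            beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
            rss = float(((y - X @ beta) ** 2).sum())
            tss = float(((y - y.mean()) ** 2).sum())
            f = (tss - rss) / (rss / (n - 2))
            p_ols = stats.f.sf(f, 1, n - 2)
            assert res.table["p"].iloc[j] == pytest.approx(p_ols, abs=1e-6)

    def test_agrees_with_exact_per_snp_reml(self, toy_panel):
        filt, K = toy_panel
        y = simpop.simulate_polygenic_phenotype(filt, 0.6, seed=13, causal=[5], effect=1.0)
        res = emmax_assoc(y, filt, K)
        d = filt.dosage()
        mu = np.nanmean(d, axis=1)
        d = np.where(np.isnan(d), mu[:, None], d)
        p_exact = np.array(
            [exact_reml_p(y.to_numpy(), d[j], K.values) for j in range(filt.n_markers)]
        )
        lp_emmax = -np.log10(res.table["p"].to_numpy())
        lp_exact = -np.log10(p_exact)
        assert np.abs(lp_emmax - lp_exact).max() < 1.0
        assert stats.spearmanr(lp_emmax, lp_exact).statistic > 0.99

    def test_p_values_affine_invariant(self, toy_panel):
        filt, K = toy_panel
        y = simpop.simulate_polygenic_phenotype(filt, 0.5, seed=14)
        p1 = emmax_assoc(y, filt, K).table["p"].to_numpy()
        p2 = emmax_assoc(2.5 * y + 7.0, filt, K).table["p"].to_numpy()
        assert np.abs(-np.log10(p1) + np.log10(p2)).max() < 1e-6

    def test_type_one_error_controlled_where_ols_inflates(self):
        cfg = simpop.SimConfig(seed=21, panel=simpop.PanelConfig(
            n_accessions=200, k_subpops=3, fst=0.2,
            chromosomes=(("A01", 10_000_000, 1000),), ld_decay_bp=50_000))
        panel, _ = simpop.simulate_structured_panel(cfg)
        filt = maf_filter(panel)
        K = kinship(filt)
        d = filt.dosage()
        mu = np.nanmean(d, axis=1)
        z = np.where(np.isnan(d), mu[:, None], d) - mu[:, None]
        m, n = z.shape
        rng = np.random.default_rng(3)
        odd, even = np.arange(1, m, 2), np.arange(0, m, 2)
        beta = rng.normal(0, 1 / np.sqrt(len(odd)), len(odd))
        g = beta @ z[odd]  # polygenic background, h2 = 0.5
        y = 40 + g + rng.normal(0, np.sqrt(np.var(g)), n)
        p_mm = emmax_assoc(y, filt, K).table["p"].to_numpy()[even]
        yc = y - y.mean()
        p_ols = []
        for j in even:
            x = z[j]
            if x.std() == 0:
                continue
            b = (x @ yc) / (x @ x)
            r = yc - b * x
            t = b / np.sqrt((r @ r) / (n - 2) / (x @ x))
            p_ols.append(2 * stats.t.sf(abs(t), n - 2))
        rate_mm = float((p_mm < 0.05).mean())
        rate_ols = float((np.asarray(p_ols) < 0.05).mean())
        assert rate_mm < 0.09
        assert rate_ols > rate_mm + 0.03


class TestThreshold:
    @pytest.mark.parametrize(
        "n,p_expected,neglog",
        [(10**6, 1e-6, 6.0), (2_340_881, 1 / 2_340_881, 6.37), (1, 1.0, 0.0)],
    )
    def test_reciprocal_rule(self, n, p_expected, neglog):
        p, nl = significance_threshold(n)
        assert p == pytest.approx(p_expected)
        assert nl == pytest.approx(neglog, abs=0.005)


class TestLdDecay:
    def test_duplicated_snp_r2_one(self):
        rng = np.random.default_rng(4)
        col = rng.choice([0.0, 2.0], 100)
        assert pairwise_r2(col, col) == pytest.approx(1.0)

    def test_two_snp_phased_counts(self):
        # haplotypes AB x45, ab x45, Ab x5, aB x5:
        # D = 0.45*0.45 - 0.05*0.05 = 0.2, all freqs 0.5 -> r2 = 0.64
        a = np.array([1.0] * 45 + [0.0] * 45 + [1.0] * 5 + [0.0] * 5)
        b = np.array([1.0] * 45 + [0.0] * 45 + [0.0] * 5 + [1.0] * 5)
        assert pairwise_r2(2 * a, 2 * b) == pytest.approx(0.64)

    def test_decay_distance_monotone_in_generator_length(self):
        decays = []
        for L in (25_000, 100_000, 400_000):
            cfg = simpop.SimConfig(seed=7, panel=simpop.PanelConfig(
                n_accessions=204, k_subpops=4, fst=0.15,
                chromosomes=(("A01", 10_000_000, 1200),), ld_decay_bp=L))
            panel, _ = simpop.simulate_structured_panel(cfg)
            curve = ld_decay(maf_filter(panel), max_dist=1_500_000, bin_width=25_000)
            assert curve.decay_distance_bp is not None
            decays.append(curve.decay_distance_bp)
        assert decays[0] < decays[1] < decays[2]

    def test_empty_range(self):
        calls = _panel_from_dosage(np.array([[0.0, 2.0, 0.0, 2.0]]))
        curve = ld_decay(calls, max_dist=100, bin_width=10)
        assert np.isnan(curve.mean_r2).all()


class TestHaplotypes:
    def test_single_group_no_test(self):
        calls = _panel_from_dosage(np.zeros((3, 30)))
        out = haplotype_test(calls, [0, 1, 2], np.random.default_rng(0).normal(40, 3, 30))
        assert out.test == "none" and len(out.group_means) == 1

    def test_two_group_power_at_stated_effect(self):
        # two haplotype groups from Normal(40.6, 3.2^2), true difference 2.0,
        # n = 100 each: reject at 0.05 in >= 17 of 20 replicates
        rejections = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            dos = np.zeros((2, 200))
            dos[:, 100:] = 2
            calls = _panel_from_dosage(dos)
            y = np.concatenate([
                rng.normal(40.6, 3.2, 100), rng.normal(42.6, 3.2, 100)
            ])
            out = haplotype_test(calls, [0, 1], y)
            assert out.test == "welch-t"
            rejections += out.p < 0.05
        assert rejections >= 17

    def test_grouping_matches_brute_force_strings(self, structured_panel):
        calls, _ = structured_panel
        y = simpop.simulate_polygenic_phenotype(calls, 0.5, seed=5)
        idxs = [0, 3, 7]
        out = haplotype_test(calls, idxs, y, min_group=1)
        expected = {}
        for k, s in enumerate(calls.samples):
            key = "".join({AA: "A", AB: "H", BB: "B"}[int(calls.calls[i, k])] for i in idxs)
            expected.setdefault(key, []).append(s)
        for hap, members in expected.items():
            assert set(out.labels[out.labels == hap].index) == set(members)

    def test_missing_calls_excluded(self):
        dos = np.zeros((1, 10))
        dos[0, 5:] = 2
        calls = _panel_from_dosage(dos)
        calls.calls[0, 0] = MISSING
        out = haplotype_test(calls, [0], np.arange(10.0), min_group=2)
        assert out.labels.size == 9
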