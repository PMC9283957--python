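"""Shared fixtures: simulated populations reused across test modules."""

import numpy as np
import pytest

from binqtl import binmap, genocorrect, simpop


@pytest.fixture(scope="session")
def dense_map():
    """Two 50-cM chromosomes at a realistic SNP density (100 SNPs / cM)."""
    return simpop.uniform_map(2, 20_000_000, 50.0, 5000)


@pytest.fixture(scope="session")
def clean_ril(dense_map):
    """Error-free 158-line RIL population with one planted QTL."""
    cfg = simpop.SimConfig(
        seed=11,
        n_ril=158,
        genotyping_error_rate=0.0,
        missing_rate=0.0,
        qtl_spec=[simpop.QtlSpec("A01", 10_000_000, 1.0)],
        n_environments=1,
        target_h2=0.3,
    )
    calls, truth = simpop.simulate_ril_population(dense_map, cfg)
    pheno = simpop.simulate_phenotypes(truth, calls, cfg)
    return calls, truth, pheno, cfg


@pytest.fixture(scope="session")
def noisy_ril(dense_map):
    """Same design with 1% genotyping error and 2% missingness."""
    cfg = simpop.SimConfig(
        seed=11,
        n_ril=158,
        genotyping_error_rate=0.01,
        missing_rate=0.02,
        qtl_spec=[simpop.QtlSpec("A01", 10_000_000, 1.0)],
        n_environments=1,
        target_h2=0.3,
    )
    calls, truth = simpop.simulate_ril_population(dense_map, cfg)
    pheno = simpop.simulate_phenotypes(truth, calls, cfg)
    return calls, truth, pheno, cfg


@pytest.fixture(scope="session")
def clean_groups(clean_ril):
    calls, _truth, _pheno, _cfg = clean_ril
    bins = binmap.build_bins(calls, binmap.detect_breakpoints(calls))
    retained, _log = binmap.filter_bins(bins)
    return binmap.assemble_map(retained)


@pytest.fixture(scope="session")
def corrected_groups(noisy_ril):
    calls, _truth, _pheno, _cfg = noisy_ril
    corrected = genocorrect.slide_correct(calls)
    bins = binmap.build_bins(corrected, binmap.detect_breakpoints(corrected))
    retained, _log = binmap.filter_bins(bins)
    return binmap.assemble_map(retained)


@pytest.fixture(scope="session")
def structured_panel():
    cfg = simpop.SimConfig(
        seed=7,
        panel=simpop.PanelConfig(
            n_accessions=204,
            k_subpops=4,
            fst=0.15,
            chromosomes=(("A01", 10_000_000, 1200), ("C01", 10_000_000, 800)),
            ld_decay_bp=100_000,
        ),
    )
    calls, labels = simpop.simulate_structured_panel(cfg)
    return calls, labels


def random_call_matrix(rng, n_chrom=2, n_snps=100, n_ind=20, p_missing=0.05):
    """Small random SnpCallMatrix for oracle comparisons."""
    from binqtl.core import MISSING, SnpCallMatrix

    chroms, pos, rows = [], [], []
    for c in range(n_chrom):
        cp = np.sort(rng.choice(np.arange(1, 10_000_000), size=n_snps, replace=False))
        chroms.extend([f"A{c + 1:02d}"] * n_snps)
        pos.append(cp)
    calls = rng.choice([0, 1, 2], size=(n_chrom * n_snps, n_ind), p=[0.45, 0.1, 0.45])
    calls[rng.random(calls.shape) < p_missing] = MISSING
    return SnpCallMatrix(
        np.asarray(chroms, dtype=object),
        np.concatenate(pos),
        calls.astype(np.int8),
        [f"i{k}" for k in range(n_ind)],
        "ril",
    )
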