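"""Panel-side association: MAF filter, kinship, EMMAX-style mixed model,
significance threshold, LD decay and haplotype-group analysis.

The association model is y = X beta + g snp + u + e with u ~ N(0, sg2 K) and
e ~ N(0, se2 I).  Following the EMMAX approximation, the variance-component
ratio delta = se2 / sg2 is estimated once by restricted maximum likelihood
under the no-SNP null via the spectral decomposition of K, then every SNP is
tested by generalized least squares with the covariance held fixed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import AA, AB, BB, MISSING, SnpCallMatrix

# --------------------------------------------------------------------------
# MAF filter and kinship
# --------------------------------------------------------------------------


def snp_maf(calls: SnpCallMatrix) -> np.ndarray:
    """Minor allele frequency per SNP over non-missing calls (homozygotes
    count two alleles, heterozygotes one of each)."""
    n_aa = (calls.calls == AA).sum(axis=1)
    n_ab = (calls.calls == AB).sum(axis=1)
    n_bb = (calls.calls == BB).sum(axis=1)
    tot = 2 * (n_aa + n_ab + n_bb)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = (2 * n_bb + n_ab) / tot
    p_alt = np.where(tot > 0, p_alt, 0.0)
    return np.minimum(p_alt, 1.0 - p_alt)


def maf_filter(calls: SnpCallMatrix, maf_min: float = 0.05) -> SnpCallMatrix:
    """Drop SNPs with MAF <= ``maf_min`` (strict > retained)."""
    keep = snp_maf(calls) > maf_min
    return SnpCallMatrix(
        calls.chrom[keep], calls.pos[keep], calls.calls[keep],
        list(calls.samples), calls.population,
    )


@dataclass(eq=False)
class KinshipMatrix:
    """VanRaden centred genomic relationship matrix with accession ids."""

    values: np.ndarray
    samples: list[str]

    def relative(self) -> np.ndarray:
        """The 'relative kinship' convention: negative entries floored at 0
        (unrelated pairs report zero)."""
        return np.maximum(self.values, 0.0)

    def zero_fraction(self) -> float:
        """Fraction of off-diagonal pairs whose relative kinship is zero."""
        k = self.relative()
        n = k.shape[0]
        off = k[np.triu_indices(n, 1)]
        return float((off == 0.0).mean())


def kinship(calls: SnpCallMatrix) -> KinshipMatrix:
    """VanRaden centred GRM: K = Z Z' / (2 sum p_k (1 - p_k)) with Z the
    allele-frequency-centred dosage matrix (missing imputed to the mean)."""
    if calls.n_individuals < 2:
        raise ValueError("kinship needs at least 2 accessions")
    d = calls.dosage()  # m x n in {0,1,2}
    p = np.nanmean(d, axis=1) / 2.0
    z = np.where(np.isnan(d), 2.0 * p[:, None], d) - 2.0 * p[:, None]
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom == 0:
        raise ValueError("no polymorphic SNPs for kinship")
    k = (z.T @ z) / denom
    return KinshipMatrix(k, list(calls.samples))


# --------------------------------------------------------------------------
# EMMAX association
# --------------------------------------------------------------------------


@dataclass(eq=False)
class AssocResult:
    table: pd.DataFrame  # chrom, pos, maf, beta, se, p
    delta: float  # se2 / sg2
    sigma_g2: float
    sigma_e2: float
    threshold_p: float | None = None


def _reml_delta(y: np.ndarray, X: np.ndarray, K: np.ndarray) -> tuple[float, float, float]:
    """Restricted ML of the null model y = X b + u + e, u ~ N(0, sg2 K):
    profile the REML log-likelihood over delta = se2/sg2 on the spectrum of
    the projected kinship (the EMMA parameterization)."""
    n, q = X.shape
    Qx, _ = np.linalg.qr(X)
    P = np.eye(n) - Qx @ Qx.T
    M = P @ K @ P
    xi, U = np.linalg.eigh(M)
    keep = np.argsort(xi)[q:]  # n - q informative directions
    xi = np.maximum(xi[keep], 0.0)
    eta = U[:, keep].T @ y

    def neg_restricted_ll(log_delta: float) -> float:
        delta = math.exp(log_delta)
        denom = xi + delta
        s = float(np.sum(eta**2 / denom))
        return 0.5 * ((n - q) * math.log(s) + float(np.sum(np.log(denom))))

    grid = np.linspace(-10.0, 10.0, 21)
    best = min(grid, key=neg_restricted_ll)
    res = optimize.minimize_scalar(
        neg_restricted_ll, bracket=(best - 1.0, best, best + 1.0), method="brent"
    )
    delta = float(math.exp(res.x))
    sg2 = float(np.sum(eta**2 / (xi + delta)) / (n - q))
    se2 = delta * sg2
    return delta, sg2, se2


def emmax_assoc(
    phenotype,
    calls: SnpCallMatrix,
    K: KinshipMatrix,
    covariates: np.ndarray | None = None,
) -> AssocResult:
    """EMMAX mixed-model association of every SNP against the phenotype.

    Variance components are estimated once under the no-SNP null; each SNP is
    then tested by GLS with V = sg2 K + se2 I fixed, reporting the dosage
    effect, its standard error and the t-test p-value.
    """
    if isinstance(phenotype, pd.Series):
        y = phenotype.reindex(calls.samples).to_numpy(dtype=float)
    else:
        y = np.asarray(phenotype, dtype=float)
    n = y.size
    if n != calls.n_individuals:
        raise ValueError("phenotype not aligned to accessions")
    X = np.ones((n, 1))
    if covariates is not None:
        X = np.column_stack([X, np.asarray(covariates, dtype=float)])

    Kv = (K.values + K.values.T) / 2.0
    evals = np.linalg.eigvalsh(Kv)
    if evals[0] < -1e-8:
        warnings.warn("kinship not PSD; flooring eigenvalues at 0", stacklevel=2)
        w, U = np.linalg.eigh(Kv)
        Kv = (U * np.maximum(w, 0.0)) @ U.T

    delta, sg2, se2 = _reml_delta(y, X, Kv)

    # rotate once: V^{-1} = U diag(1/(d + delta)) U' / sg2
    d, U = np.linalg.eigh(Kv)
    d = np.maximum(d, 0.0)
    wts = 1.0 / (d + delta)
    ys = U.T @ y
    Xs = U.T @ X

    dos = calls.dosage()
    mu = np.nanmean(dos, axis=1)
    dos = np.where(np.isnan(dos), mu[:, None], dos)
    Gs = U.T @ dos.T  # n x m rotated dosages

    sw = np.sqrt(wts)
    yw = ys * sw
    Xw = Xs * sw[:, None]
    Gw = Gs * sw[:, None]
    # residualize SNPs and phenotype against fixed covariates (weighted)
    Qx, _ = np.linalg.qr(Xw)
    ry = yw - Qx @ (Qx.T @ yw)
    RG = Gw - Qx @ (Qx.T @ Gw)
    norms = np.einsum("ij,ij->j", RG, RG)
    dot = RG.T @ ry
    ok = norms > 1e-12
    beta = np.where(ok, dot / np.where(ok, norms, 1.0), 0.0)
    rss0 = float(ry @ ry)
    rss = np.maximum(rss0 - np.where(ok, dot**2 / np.where(ok, norms, 1.0), 0.0), 1e-300)
    df = n - X.shape[1] - 1
    sigma2 = rss / df
    se = np.sqrt(np.where(ok, sigma2 / np.where(ok, norms, 1.0), np.nan))
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = beta / se
    p = np.where(ok, 2.0 * stats.t.sf(np.abs(tstat), df), 1.0)
    table = pd.DataFrame(
        {
            "chrom": calls.chrom,
            "pos": calls.pos,
            "maf": snp_maf(calls),
            "beta": beta,
            "se": se,
            "p": np.clip(p, np.finfo(float).tiny, 1.0),
        }
    )
    return AssocResult(table, delta=delta, sigma_g2=sg2, sigma_e2=se2)


def significance_threshold(n_snps: int) -> tuple[float, float]:
    """GWAS threshold p* = 1 / n_snps; returns (p*, -log10 p*)."""
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    p = 1.0 / n_snps
    return p, -math.log10(p) if p < 1.0 else 0.0


# --------------------------------------------------------------------------
# LD decay
# --------------------------------------------------------------------------


@dataclass(eq=False)
class LdDecayCurve:
    bin_centers_bp: np.ndarray
    mean_r2: np.ndarray
    n_pairs: np.ndarray
    decay_distance_bp: float | None  # first crossing of the reference level
    ref_level: float


def pairwise_r2(dos_i: np.ndarray, dos_j: np.ndarray) -> float:
    """Squared dosage correlation between two SNPs (inbred panels: dosage
    correlation equals haplotype correlation)."""
    ok = ~np.isnan(dos_i) & ~np.isnan(dos_j)
    if ok.sum() < 2:
        return float("nan")
    a, b = dos_i[ok], dos_j[ok]
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def ld_decay(
    calls: SnpCallMatrix,
    max_dist: int = 1_000_000,
    bin_width: int = 10_000,
    ref_level: float = 0.2,
    chromosomes: list[str] | None = None,
) -> LdDecayCurve:
    """Mean pairwise r2 in physical-distance bins for intra-chromosomal SNP
    pairs within ``max_dist``, with the decay distance interpolated where the
    binned curve first drops below ``ref_level``."""
    chroms = chromosomes or calls.chromosomes
    n_bins = int(np.ceil(max_dist / bin_width))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    for c in chroms:
        idx = calls.chrom_index(c)
        pos = calls.pos[idx]
        d = calls.dosage()[idx]
        mu = np.nanmean(d, axis=1, keepdims=True)
        z = np.where(np.isnan(d), mu, d)
        sd = z.std(axis=1)
        z = (z - z.mean(axis=1, keepdims=True))
        m = pos.size
        for i in range(m - 1):
            if sd[i] == 0:
                continue
            j_hi = int(np.searchsorted(pos, pos[i] + max_dist, "right"))
            if j_hi <= i + 1:
                continue
            js = np.arange(i + 1, j_hi)
            valid = sd[js] > 0
            js = js[valid]
            if js.size == 0:
                continue
            r = (z[js] @ z[i]) / (z.shape[1] * sd[js] * sd[i])
            r2 = r**2
            b = ((pos[js] - pos[i]) - 1) // bin_width
            np.add.at(sums, b, r2)
            np.add.at(counts, b, 1)
    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.where(counts > 0, counts, 1), np.nan)
    centers = (np.arange(n_bins) + 0.5) * bin_width
    decay = None
    prev_c, prev_v = None, None
    for c_, v in zip(centers, mean_r2):
        if np.isnan(v):
            continue
        if v < ref_level:
            if prev_v is None or prev_v <= ref_level:
                decay = float(c_)
            else:
                frac = (prev_v - ref_level) / (prev_v - v)
                decay = float(prev_c + frac * (c_ - prev_c))
            break
        prev_c, prev_v = c_, v
    return LdDecayCurve(centers, mean_r2, counts, decay, ref_level)


# --------------------------------------------------------------------------
# haplotype analysis
# --------------------------------------------------------------------------


@dataclass(eq=False)
class HaplotypeGroups:
    labels: pd.Series  # haplotype string per accession (tested groups only)
    group_means: pd.Series
    group_sizes: pd.Series
    statistic: float
    p: float
    test: str  # "welch-t", "anova-f" or "none"


def haplotype_test(
    calls: SnpCallMatrix,
    snp_indices: list[int],
    phenotype,
    min_group: int = 5,
) -> HaplotypeGroups:
    """Group accessions by the joint allele string at the defining SNPs and
    test phenotype differences between groups (Welch t for two groups, one-
    way ANOVA F beyond).  Accessions missing any defining call are excluded;
    groups smaller than ``min_group`` are dropped from testing."""
    if not snp_indices:
        raise ValueError("need at least one defining SNP")
    if isinstance(phenotype, pd.Series):
        y = phenotype.reindex(calls.samples).to_numpy(dtype=float)
    else:
        y = np.asarray(phenotype, dtype=float)
    sub = calls.calls[np.asarray(snp_indices)]
    ok = (sub != MISSING).all(axis=0) & ~np.isnan(y)
    strings = np.array(
        ["".join("AHB"[g] if g in (AA, AB, BB) else "?" for g in sub[:, i]) for i in range(sub.shape[1])],
        dtype=object,
    )
    lab = pd.Series(strings[ok], index=np.asarray(calls.samples, dtype=object)[ok])
    yv = pd.Series(y[ok], index=lab.index)
    sizes = lab.value_counts()
    big = sizes[sizes >= min_group].index
    tested = lab[lab.isin(big)]
    yt = yv[tested.index]
    groups = [yt[tested == h].to_numpy() for h in big]
    means = pd.Series({h: float(yt[tested == h].mean()) for h in big})
    if len(big) < 2:
        return HaplotypeGroups(tested, means, sizes[big], float("nan"), float("nan"), "none")
    if len(big) == 2:
        t, p = stats.ttest_ind(groups[0], groups[1], equal_var=False)
        return HaplotypeGroups(tested, means, sizes[big], float(t), float(p), "welch-t")
    f, p = stats.f_oneway(*groups)
    return HaplotypeGroups(tested, means, sizes[big], float(f), float(p), "anova-f")
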