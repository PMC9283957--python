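"""Synthetic populations with planted truth.

Three generators cover the data shapes the downstream stages consume:

* a biparental recombinant-inbred-line (RIL) population built by explicit
  generational selfing from two fully inbred founders, with crossovers from a
  Poisson process on the genetic map, plus genotyping error and missingness;
* multi-environment phenotypes with additive QTL effects, genotype-by-
  environment interaction and a target entry-mean narrow-sense heritability;
* a structured diversity panel of inbred accessions with Balding-Nichols
  subpopulation allele frequencies and distance-dependent linkage
  disequilibrium.

A deterministic fixture reproducing a 24-gene candidate-interval triage
scenario (expression, differential expression, variant effects and
inter-subgenome synteny) is also provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .core import AA, AB, BB, MISSING, SnpCallMatrix

# --------------------------------------------------------------------------
# configuration types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ChromosomeSpec:
    id: str
    bp_length: int
    cm_length: float

    def __post_init__(self) -> None:
        if self.bp_length <= 0 or self.cm_length < 0:
            raise ValueError("chromosome lengths must be positive")


@dataclass
class GeneticMapSpec:
    """Coordinate frame for simulation: physical and genetic lengths plus
    SNP positions per chromosome.

    ``map_function`` names the distance convention used when converting
    between cM and recombination fractions downstream; the crossover process
    itself is Poisson with rate equal to the genetic length in Morgans
    (no interference).
    """

    chromosomes: list[ChromosomeSpec]
    snp_positions: dict[str, np.ndarray]
    map_function: str = "kosambi"

    def __post_init__(self) -> None:
        if self.map_function not in ("kosambi", "haldane"):
            raise ValueError("map_function must be 'kosambi' or 'haldane'")
        if not self.chromosomes:
            raise ValueError("need at least one chromosome")
        for c in self.chromosomes:
            p = np.asarray(self.snp_positions.get(c.id, ()), dtype=np.int64)
            if p.size == 0:
                raise ValueError(f"chromosome {c.id} has no SNPs")
            if not (np.diff(p) > 0).all():
                raise ValueError(f"SNP positions not strictly increasing on {c.id}")
            if p[0] < 1 or p[-1] >= c.bp_length:
                raise ValueError(f"SNP positions outside chromosome {c.id}")
            self.snp_positions[c.id] = p


def uniform_map(
    n_chrom: int = 2,
    bp_length: int = 20_000_000,
    cm_length: float = 80.0,
    snps_per_chrom: int = 2000,
    prefix: str = "A",
    map_function: str = "kosambi",
) -> GeneticMapSpec:
    """Convenience factory: evenly spaced SNPs on identical chromosomes."""
    chroms = [
        ChromosomeSpec(f"{prefix}{i + 1:02d}", bp_length, cm_length)
        for i in range(n_chrom)
    ]
    step = bp_length / (snps_per_chrom + 1)
    pos = np.round(np.arange(1, snps_per_chrom + 1) * step).astype(np.int64)
    return GeneticMapSpec(chroms, {c.id: pos.copy() for c in chroms}, map_function)


class QtlSpec(NamedTuple):
    """A planted additive QTL: chromosome, bp position, additive effect ``a``
    in trait units (half the difference between homozygote means), and
    optional per-environment deviations added to ``a``."""

    chrom: str
    pos: int
    a: float
    env_dev: tuple[float, ...] | None = None


@dataclass(frozen=True)
class PanelConfig:
    """Structured-panel settings (defaults mirror a 204-accession
    B. napus diversity panel split into four subpopulations)."""

    n_accessions: int = 204
    k_subpops: int = 4
    fst: float = 0.15
    maf_floor: float = 0.05
    chromosomes: tuple[tuple[str, int, int], ...] = (("A01", 10_000_000, 1500),)
    ld_decay_bp: float = 100_000.0


@dataclass
class SimConfig:
    """Study-condition knobs for the RIL generator and phenotype model.

    Defaults echo the mapping study being emulated: 158 F2:11 lines
    (10 selfing generations), nine environments, entry-mean narrow-sense
    heritability near 0.785.  Genotyping error (1%) and missingness (2%)
    are nominal resequencing rates; the source study states neither.
    """

    seed: int = 0
    n_ril: int = 158
    n_self_generations: int = 10
    genotyping_error_rate: float = 0.01
    missing_rate: float = 0.02
    qtl_spec: list[QtlSpec] = field(default_factory=list)
    n_environments: int = 9
    n_replicates: int = 1
    target_h2: float = 0.785
    ge_variance_fraction: float = 0.25
    residual_sd: float = 1.0
    panel: PanelConfig = field(default_factory=PanelConfig)

    def __post_init__(self) -> None:
        for p in (self.genotyping_error_rate, self.missing_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if not 0.0 <= self.target_h2 <= 1.0:
            raise ValueError("target_h2 must lie in (0, 1]")
        if self.n_ril < 2:
            raise ValueError("n_ril must be >= 2")
        if not 0.0 <= self.ge_variance_fraction <= 1.0:
            raise ValueError("ge_variance_fraction must lie in [0, 1]")


@dataclass
class TruthRecord:
    """Ground truth retained by the generators.

    ``mosaics`` gives, per individual and chromosome, the diplotype mosaic as
    (breakpoints, states): ``states`` are genotype codes (AA/AB/BB) on the
    segments [0, b1), [b1, b2), ..., [bk, length); ``breakpoints`` are exact
    (float) bp coordinates.  ``true_calls`` is the uncorrupted call matrix.
    """

    mosaics: list[dict[str, tuple[np.ndarray, np.ndarray]]]
    true_calls: SnpCallMatrix
    map: GeneticMapSpec
    qtl: list[QtlSpec] = field(default_factory=list)
    realized_h2_per_env: dict[str, float] = field(default_factory=dict)

    def breakpoints(self, ind: int, chrom: str) -> np.ndarray:
        return self.mosaics[ind][chrom][0]

    def state_at(self, ind: int, chrom: str, pos: float | np.ndarray) -> np.ndarray:
        """Genotype code(s) of the true mosaic at bp position(s)."""
        breaks, states = self.mosaics[ind][chrom]
        return states[np.searchsorted(breaks, np.asarray(pos, dtype=float), "right")]


# --------------------------------------------------------------------------
# meiosis on founder-origin mosaics
# --------------------------------------------------------------------------

_Hap = tuple[np.ndarray, np.ndarray]  # (breaks, origins); origins in {1, 2}


def _const_hap(origin: int) -> _Hap:
    return np.empty(0), np.full(1, origin, dtype=np.int8)


def _eval_hap(hap: _Hap, pos: np.ndarray) -> np.ndarray:
    breaks, origins = hap
    return origins[np.searchsorted(breaks, pos, "right")]


def _compress(breaks: np.ndarray, origins: np.ndarray) -> _Hap:
    if origins.size <= 1:
        return breaks, origins
    keep = np.flatnonzero(origins[1:] != origins[:-1])
    return breaks[keep], origins[np.concatenate(([0], keep + 1))]


def _gamete(rng: np.random.Generator, hap1: _Hap, hap2: _Hap, spec: ChromosomeSpec) -> _Hap:
    """One meiotic product: Poisson(cM/100) crossovers, positions uniform on
    the (linear) genetic map, mapped proportionally to bp; no interference."""
    n_x = rng.poisson(spec.cm_length / 100.0)
    start = int(rng.integers(2))
    if n_x == 0:
        return (hap1, hap2)[start]
    xs = np.sort(rng.uniform(0.0, spec.bp_length, n_x))
    grid = np.unique(np.concatenate((hap1[0], hap2[0], xs)))
    mids = np.concatenate((grid, [spec.bp_length])) - np.diff(
        np.concatenate(([0.0], grid, [spec.bp_length]))
    ) / 2.0
    which = (start + np.searchsorted(xs, mids, "right")) % 2
    o1, o2 = _eval_hap(hap1, mids), _eval_hap(hap2, mids)
    origins = np.where(which == 0, o1, o2).astype(np.int8)
    return _compress(grid, origins)


def _diplotype_mosaic(hap1: _Hap, hap2: _Hap, spec: ChromosomeSpec) -> tuple[np.ndarray, np.ndarray]:
    grid = np.unique(np.concatenate((hap1[0], hap2[0])))
    mids = np.concatenate((grid, [spec.bp_length])) - np.diff(
        np.concatenate(([0.0], grid, [spec.bp_length]))
    ) / 2.0
    o1, o2 = _eval_hap(hap1, mids), _eval_hap(hap2, mids)
    states = np.where((o1 == 1) & (o2 == 1), AA, np.where((o1 == 2) & (o2 == 2), BB, AB))
    return _compress(grid, states.astype(np.int8))


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------


def simulate_ril_population(
    gmap: GeneticMapSpec, cfg: SimConfig
) -> tuple[SnpCallMatrix, TruthRecord]:
    """Simulate an F2-derived RIL population by ``cfg.n_self_generations``
    rounds of selfing from the F1 of two inbred founders.

    Founder 1 contributes the AA allele, founder 2 the BB allele.  Residual
    heterozygosity per locus is ~0.5**g before corruption.  Calls are then
    corrupted by symmetric genotyping error (random substitution among the
    three codes) and masked by missingness; the returned :class:`TruthRecord`
    keeps the clean mosaics and calls.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    n = cfg.n_ril
    # per individual, per chromosome: the two haplotypes
    pop: list[dict[str, list[_Hap]]] = [
        {c.id: [_const_hap(1), _const_hap(2)] for c in gmap.chromosomes}
        for _ in range(n)
    ]
    for _ in range(cfg.n_self_generations):
        for ind in pop:
            for c in gmap.chromosomes:
                h1, h2 = ind[c.id]
                ind[c.id] = [_gamete(rng, h1, h2, c), _gamete(rng, h1, h2, c)]

    chrom_col, pos_col, rows = [], [], []
    mosaics: list[dict[str, tuple[np.ndarray, np.ndarray]]] = [{} for _ in range(n)]
    for c in gmap.chromosomes:
        snps = gmap.snp_positions[c.id].astype(float)
        chrom_col.extend([c.id] * snps.size)
        pos_col.append(gmap.snp_positions[c.id])
        block = np.empty((snps.size, n), dtype=np.int8)
        for i, ind in enumerate(pop):
            dip = _diplotype_mosaic(ind[c.id][0], ind[c.id][1], c)
            mosaics[i][c.id] = dip
            breaks, states = dip
            block[:, i] = states[np.searchsorted(breaks, snps, "right")]
        rows.append(block)
    chrom_arr = np.asarray(chrom_col, dtype=object)
    pos_arr = np.concatenate(pos_col)
    clean = np.concatenate(rows, axis=0)
    samples = [f"RIL{i + 1:03d}" for i in range(n)]
    true_calls = SnpCallMatrix(chrom_arr, pos_arr, clean.copy(), samples, "ril")

    noisy = clean.copy()
    if cfg.genotyping_error_rate > 0:
        err = rng.random(noisy.shape) < cfg.genotyping_error_rate
        shift = rng.integers(1, 3, size=noisy.shape).astype(np.int8)
        noisy[err] = (noisy[err] + shift[err]) % 3
    if cfg.missing_rate > 0:
        noisy[rng.random(noisy.shape) < cfg.missing_rate] = MISSING
    calls = SnpCallMatrix(chrom_arr.copy(), pos_arr.copy(), noisy, list(samples), "ril")
    truth = TruthRecord(mosaics=mosaics, true_calls=true_calls, map=gmap, qtl=list(cfg.qtl_spec))
    return calls, truth


def _qtl_dosage(truth: TruthRecord, q: QtlSpec) -> np.ndarray:
    """Signed true dosage at a QTL: AA -> +1, BB -> -1, AB -> 0."""
    chrom_ids = {c.id: c for c in truth.map.chromosomes}
    if q.chrom not in chrom_ids or not (0 <= q.pos < chrom_ids[q.chrom].bp_length):
        raise ValueError(f"QTL at {q.chrom}:{q.pos} is off the simulated map")
    states = np.array(
        [truth.state_at(i, q.chrom, q.pos) for i in range(len(truth.mosaics))]
    )
    return np.where(states == AA, 1.0, np.where(states == BB, -1.0, 0.0))


def simulate_phenotypes(
    truth: TruthRecord, genotypes: SnpCallMatrix, cfg: SimConfig
) -> pd.DataFrame:
    """Multi-environment phenotypes with additive QTL effects, G x E and a
    target entry-mean narrow-sense heritability.

    The model is ``y_ijr = mu + sum_q (a_q + dev_qj) x_iq + env_j + ge_ij +
    eps_ijr`` with x in {-1, 0, +1} from the true QTL genotype.  Random G x E
    and residual variances are scaled so that the entry-mean heritability
    h2 = V_G / (V_G + V_GE/nE + V_e/(nE*nR)) matches ``cfg.target_h2``.
    Returns a tidy table (individual, environment, replicate, value).
    """
    rng = np.random.default_rng([cfg.seed, 2])
    n = len(truth.mosaics)
    n_env, n_rep = cfg.n_environments, cfg.n_replicates
    if n_env < 1 or n_rep < 1:
        raise ValueError("need at least one environment and replicate")
    qtl = list(cfg.qtl_spec)
    for q in qtl:
        if q.env_dev is not None and len(q.env_dev) != n_env:
            raise ValueError("env_dev length must equal n_environments")
    if qtl and cfg.target_h2 == 0.0:
        raise ValueError("target_h2 = 0 with nonzero QTL effects requested")

    # genetic values per individual x environment
    g = np.zeros((n, n_env))
    for q in qtl:
        x = _qtl_dosage(truth, q)
        dev = np.zeros(n_env) if q.env_dev is None else np.asarray(q.env_dev, float)
        g += x[:, None] * (q.a + dev)[None, :]

    g_mean = g.mean(axis=1)  # across-environment genetic value
    v_g = float(np.var(g_mean))
    v_ge_qtl = float(np.var(g - g_mean[:, None]))
    mu = 40.0

    if v_g > 0:
        needed = v_g * (1.0 - cfg.target_h2) / cfg.target_h2
        deficit = max(needed - v_ge_qtl / n_env, 0.0)
        f = cfg.ge_variance_fraction if n_env > 1 else 0.0
        v_ge_rand = f * deficit * n_env
        v_e = (1.0 - f) * deficit * n_env * n_rep
    else:
        v_ge_rand, v_e = 0.0, cfg.residual_sd**2

    env_sd = math.sqrt(max(v_g, 1.0))
    env_eff = rng.normal(0.0, env_sd, n_env)
    ge = rng.normal(0.0, math.sqrt(v_ge_rand), (n, n_env)) if v_ge_rand > 0 else 0.0
    gxe = g + (ge if np.ndim(ge) else 0.0)

    records = []
    realized: dict[str, float] = {}
    env_ids = [f"E{j + 1}" for j in range(n_env)]
    for j, env in enumerate(env_ids):
        eps = rng.normal(0.0, math.sqrt(v_e), (n, n_rep)) if v_e > 0 else np.zeros((n, n_rep))
        y = mu + env_eff[j] + gxe[:, j][:, None] + eps
        tot = float(np.var(y.mean(axis=1)))
        realized[env] = float(np.var(gxe[:, j]) / tot) if tot > 0 else float("nan")
        for r in range(n_rep):
            records.append(
                pd.DataFrame(
                    {
                        "individual": genotypes.samples,
                        "environment": env,
                        "replicate": r + 1,
                        "value": y[:, r],
                    }
                )
            )
    truth.qtl = qtl
    truth.realized_h2_per_env = realized
    return pd.concat(records, ignore_index=True)


def simulate_structured_panel(cfg: SimConfig) -> tuple[SnpCallMatrix, np.ndarray]:
    """Inbred diversity panel with k subpopulations and distance-dependent LD.

    Subpopulation allele frequencies follow the Balding-Nichols model around
    uniform ancestral frequencies.  Each accession carries one haplotype
    (doubled to a homozygous genotype) generated by thresholding a latent
    Gaussian AR(1) process whose autocorrelation decays as
    exp(-distance / ld_decay_bp), which yields a monotone r2-vs-distance
    decay while keeping the marginal subpopulation frequencies exact.
    Returns the call matrix and the per-accession subpopulation labels.
    """
    p = cfg.panel
    rng = np.random.default_rng([cfg.seed, 3])
    if p.maf_floor >= 0.5:
        raise ValueError("maf_floor must be < 0.5")
    if p.k_subpops < 1:
        raise ValueError("k_subpops must be >= 1")
    if not 0.0 <= p.fst < 1.0:
        raise ValueError("Fst must lie in [0, 1)")
    n = p.n_accessions
    labels = np.repeat(np.arange(p.k_subpops), math.ceil(n / p.k_subpops))[:n]

    chrom_col, pos_col, blocks = [], [], []
    from scipy.stats import beta as beta_dist, norm

    def ar1(n_series: int, phi: np.ndarray) -> np.ndarray:
        """m x n_series latent Gaussian AR(1) sheets along the chromosome."""
        m = phi.size + 1
        u = np.empty((m, n_series))
        u[0] = rng.standard_normal(n_series)
        for j in range(1, m):
            u[j] = phi[j - 1] * u[j - 1] + math.sqrt(1.0 - phi[j - 1] ** 2) * rng.standard_normal(n_series)
        return u

    for cid, length, m in p.chromosomes:
        pos = np.sort(rng.choice(np.arange(1, length), size=m, replace=False))
        phi = np.exp(-np.diff(pos) / p.ld_decay_bp)
        # ancestral frequencies: locally correlated, Uniform(maf_floor, ..)
        # marginals through a Gaussian copula
        q_anc = norm.cdf(ar1(1, phi)[:, 0])
        p_anc = p.maf_floor + (1.0 - 2.0 * p.maf_floor) * q_anc
        if p.fst > 0:
            # Balding-Nichols subpopulation frequencies, again with locally
            # correlated copula draws so that nearby SNPs share their drift
            a = p_anc * (1.0 - p.fst) / p.fst
            b = (1.0 - p_anc) * (1.0 - p.fst) / p.fst
            q_sub = norm.cdf(ar1(p.k_subpops, phi))  # m x k
            p_sub = beta_dist.ppf(q_sub, a[:, None], b[:, None]).T  # k x m
        else:
            p_sub = np.tile(p_anc, (p.k_subpops, 1))
        thresh = norm.ppf(np.clip(p_sub, 1e-12, 1 - 1e-12))  # k x m
        u = ar1(n, phi)  # accession haplotypes share the decay length
        alt = u < thresh[labels].T  # m x n: True -> alt (parent-2-like) allele
        block = np.where(alt, BB, AA).astype(np.int8)
        chrom_col.extend([cid] * m)
        pos_col.append(pos.astype(np.int64))
        blocks.append(block)

    samples = [f"ACC{i + 1:03d}" for i in range(n)]
    calls = SnpCallMatrix(
        np.asarray(chrom_col, dtype=object),
        np.concatenate(pos_col),
        np.concatenate(blocks, axis=0),
        samples,
        "panel",
    )
    return calls, labels


def simulate_polygenic_phenotype(
    calls: SnpCallMatrix,
    h2: float,
    seed: int,
    causal: Sequence[int] | None = None,
    effect: float = 0.0,
    mu: float = 40.0,
) -> pd.Series:
    """Single-environment panel phenotype: a polygenic background drawn from
    all SNPs plus optional fixed-effect causal SNPs, scaled to heritability
    ``h2``.  Utility plumbing for association tests."""
    rng = np.random.default_rng([seed, 4])
    z = calls.dosage()
    col_mean = np.nanmean(z, axis=1, keepdims=True)
    z = np.where(np.isnan(z), col_mean, z) - col_mean
    m = z.shape[0]
    beta = rng.normal(0.0, 1.0 / math.sqrt(m), m)
    g = beta @ z
    if causal:
        for idx in causal:
            g = g + effect * z[idx]
    v_g = float(np.var(g))
    if h2 <= 0 or v_g == 0:
        y = mu + rng.standard_normal(z.shape[1])
    else:
        v_e = v_g * (1.0 - h2) / h2
        y = mu + g + rng.normal(0.0, math.sqrt(v_e), z.shape[1])
    return pd.Series(y, index=calls.samples, name="value")


# --------------------------------------------------------------------------
# triage fixture
# --------------------------------------------------------------------------

CANDIDATE_INTERVAL = ("A07", 11_378_925, 11_559_658)

_UNEXPRESSED = [
    "BnaA07g12660D", "BnaA07g12670D", "BnaA07g12740D", "BnaA07g12750D",
    "BnaA07g12760D", "BnaA07g12840D", "BnaA07g12850D", "BnaA07g12870D",
]
_DEGS = ["BnaA07g12790D", "BnaA07g12810D", "BnaA07g12830D", "BnaA07g12880D"]


class TriageFixture(NamedTuple):
    genes: pd.DataFrame
    expression: pd.DataFrame
    de_stats: pd.DataFrame
    variants: pd.DataFrame
    synteny: pd.DataFrame


def make_triage_fixture() -> TriageFixture:
    """Deterministic tables for the 180-kb, 24-gene candidate interval.

    Encodes: 8 genes unexpressed in developed seeds; 4 differentially
    expressed genes; syntenic partners BnaA07g12810D <-> BnaC07g16850D (with
    coincident expression and no coding-sequence variant) and BnaA07g12830D
    <-> {BnaC07g16870D, BnaC04g17300D} (non-coincident); no partner for
    BnaA07g12790D or BnaA07g12880D; exactly one missense variant, in
    BnaA07g12790D.  Every other expressed interval gene carries a coincident
    syntenic partner, so rule-based triage retains exactly the three
    candidates.
    """
    ids = [f"BnaA07g{12650 + 10 * i}D" for i in range(24)]
    chrom, lo, _hi = CANDIDATE_INTERVAL
    genes = pd.DataFrame(
        {
            "gene_id": ids,
            "chrom": chrom,
            "start": [11_380_000 + 7_500 * i for i in range(24)],
            "end": [11_380_000 + 7_500 * i + 3_000 for i in range(24)],
        }
    )

    samples = [f"{par}_{t}DAF" for par in ("GRD328", "GRG2462") for t in (35, 40, 45, 50)]
    fillers = [g for g in ids if g not in _UNEXPRESSED and g not in _DEGS]
    expr: dict[str, list[float]] = {}

    base = np.array([10.0, 12.0, 14.0, 16.0])
    for g in _UNEXPRESSED:
        expr[g] = [0.05, 0.1, 0.05, 0.2, 0.1, 0.05, 0.15, 0.1]
    for i, g in enumerate(fillers):
        prof = base * (1.0 + 0.06 * i)
        expr[g] = list(np.concatenate((prof, prof * 1.04)))
    expr["BnaA07g12790D"] = [30, 40, 50, 60, 10, 12, 15, 18]
    expr["BnaA07g12810D"] = [5, 10, 20, 40, 1, 2, 4, 8]
    expr["BnaA07g12830D"] = [25, 25, 30, 35, 8, 9, 10, 12]
    expr["BnaA07g12880D"] = [3, 4, 5, 6, 12, 16, 20, 24]

    # syntenic partners: the two documented pairs plus one coincident partner
    # per remaining expressed non-DEG gene
    partner_of: dict[str, list[str]] = {
        "BnaA07g12810D": ["BnaC07g16850D"],
        "BnaA07g12830D": ["BnaC07g16870D", "BnaC04g17300D"],
    }
    for i, g in enumerate(fillers):
        partner_of[g] = [f"BnaC07g{16700 + 10 * i}D"]

    # partner expression: coincident (scaled copy) except for the partners of
    # BnaA07g12830D, which are flat and not differentially expressed
    for g, partners in partner_of.items():
        for pid in partners:
            if g == "BnaA07g12830D":
                expr[pid] = [15.0] * 8
            else:
                expr[pid] = list(np.asarray(expr[g]) * 0.9 + 0.2)

    expression = pd.DataFrame.from_dict(expr, orient="index", columns=samples)
    expression.index.name = "gene_id"
    expression = expression.reset_index()

    def _l2fc(prof: Sequence[float]) -> float:
        a, b = np.mean(prof[:4]), np.mean(prof[4:])
        return float(np.log2((a + 0.01) / (b + 0.01)))

    de_rows = []
    for g in expression["gene_id"]:
        prof = expr[g]
        l2 = _l2fc(prof)
        is_deg = g in _DEGS or (g == "BnaC07g16850D")
        de_rows.append(
            {
                "gene_id": g,
                "contrast": "GRD328_vs_GRG2462",
                "log2fc": l2,
                "padj": 1e-4 if is_deg else 0.9,
            }
        )
    de_stats = pd.DataFrame(de_rows)

    variants = pd.DataFrame(
        {
            "gene_id": [
                "BnaA07g12790D", "BnaA07g12790D", "BnaA07g12810D",
                "BnaA07g12810D", "BnaA07g12830D", "BnaA07g12880D",
                "BnaA07g12650D", "BnaA07g12700D",
            ],
            "effect": [
                "missense", "upstream", "upstream", "downstream",
                "upstream", "downstream", "upstream", "downstream",
            ],
            "pos": [
                11_485_210, 11_484_100, 11_500_950, 11_504_400,
                11_515_300, 11_553_000, 11_379_500, 11_417_800,
            ],
        }
    )

    syn_rows = [
        {"gene_id": g, "partner_id": pid}
        for g, partners in partner_of.items()
        for pid in partners
    ]
    synteny = pd.DataFrame(syn_rows)
    return TriageFixture(genes, expression, de_stats, variants, synteny)
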