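"""Recombination-defined bin markers and linkage-map assembly.

A bin marker is a genomic interval within which no individual of the RIL
population exhibits a recombination breakpoint; all SNPs inside share one
genotype pattern per individual, so the interval acts as a single marker.
Bins are delimited by the union over individuals of detected breakpoints,
filtered on physical length and segregation distortion, then strung into
per-chromosome linkage groups with Kosambi map distances computed from
RIL-corrected recombination fractions between adjacent bins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import AA, AB, BB, MISSING, SnpCallMatrix
from .simpop import GeneticMapSpec

# --------------------------------------------------------------------------
# types
# --------------------------------------------------------------------------


@dataclass(eq=False)
class BinMarker:
    """Half-open physical interval [start, end) with one genotype call per
    individual (AA / AB / BB / missing)."""

    chrom: str
    start: int
    end: int
    snp_count: int
    genotypes: np.ndarray  # int8, length n_ril

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("bin end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(eq=False)
class LinkageGroup:
    """Ordered bins of one chromosome with cumulative cM positions
    (physical order; position 0 at the first bin)."""

    id: str
    bins: list[BinMarker]
    cm: np.ndarray
    low_confidence: np.ndarray | None = None  # per-interval flag (n_bins - 1)

    def __post_init__(self) -> None:
        self.cm = np.asarray(self.cm, dtype=float)
        if len(self.bins) != self.cm.size:
            raise ValueError("one cM position per bin required")
        if self.cm.size and (np.diff(self.cm) < -1e-9).any():
            raise ValueError("cM positions must be non-decreasing")


# --------------------------------------------------------------------------
# breakpoints and bins
# --------------------------------------------------------------------------


def detect_breakpoints(calls: SnpCallMatrix) -> list[dict[str, np.ndarray]]:
    """Per-individual recombination breakpoints.

    For each individual and chromosome, a breakpoint is recorded at the
    midpoint (bp) between consecutive informative (homozygous) SNPs whose
    state flips AA <-> BB; intervening AB or missing runs are crossed by a
    single breakpoint at the run midpoint.
    """
    out: list[dict[str, np.ndarray]] = [dict() for _ in range(calls.n_individuals)]
    for c in calls.chromosomes:
        idx = calls.chrom_index(c)
        pos = calls.pos[idx]
        block = calls.calls[idx]
        for i in range(calls.n_individuals):
            track = block[:, i]
            hom = (track == AA) | (track == BB)
            hp, hs = pos[hom], track[hom]
            if hp.size < 2:
                out[i][c] = np.empty(0, dtype=np.int64)
                continue
            flip = np.flatnonzero(hs[1:] != hs[:-1])
            out[i][c] = ((hp[flip] + hp[flip + 1]) // 2).astype(np.int64)
    return out


def build_bins(
    calls: SnpCallMatrix, breakpoints: list[dict[str, np.ndarray]]
) -> list[BinMarker]:
    """Tile each chromosome with bins delimited by the union of all
    individuals' breakpoints (plus the chromosome ends, taken as position 0
    and one past the last SNP).

    Each bin's genotype per individual is the consensus homozygous state of
    its SNPs (AB if only heterozygous calls are present, missing if no call
    is informative; conflicting homozygous calls fall back to the majority,
    ties to AB).
    """
    bins: list[BinMarker] = []
    n = calls.n_individuals
    for c in calls.chromosomes:
        idx = calls.chrom_index(c)
        pos = calls.pos[idx]
        block = calls.calls[idx]
        cuts = np.unique(np.concatenate([bp[c] for bp in breakpoints if c in bp]))
        edges = np.concatenate(([0], cuts, [pos[-1] + 1])).astype(np.int64)
        edges = np.unique(edges)
        for lo, hi in zip(edges[:-1], edges[1:]):
            inside = (pos >= lo) & (pos < hi)
            sub = block[inside]
            geno = np.full(n, MISSING, dtype=np.int8)
            n_aa = (sub == AA).sum(axis=0)
            n_bb = (sub == BB).sum(axis=0)
            n_ab = (sub == AB).sum(axis=0)
            geno[(n_aa > 0) & (n_aa > n_bb)] = AA
            geno[(n_bb > 0) & (n_bb > n_aa)] = BB
            geno[(n_aa > 0) & (n_aa == n_bb)] = AB
            geno[(n_aa == 0) & (n_bb == 0) & (n_ab > 0)] = AB
            bins.append(BinMarker(c, int(lo), int(hi), int(inside.sum()), geno))
    return bins


def filter_bins(
    bins: list[BinMarker],
    min_len_bp: int = 10_000,
    seg_alpha: float = 0.001,
    rescue_density_per_bp: float | None = 1.0 / 2_000_000,
) -> tuple[list[BinMarker], pd.DataFrame]:
    """Remove bins shorter than ``min_len_bp`` or with severe segregation
    distortion (chi-square goodness of fit against 1:1 AA:BB at
    p < ``seg_alpha``; AB and missing calls are excluded from the test).

    A rescue pass restores rejected bins (longest first) on any chromosome
    whose retained-bin density falls below ``rescue_density_per_bp``.
    Returns the retained bins (input order) and a rejection log.
    """
    keep: list[bool] = []
    log_rows = []
    for b in bins:
        reason = None
        if b.length < min_len_bp:
            reason = "length"
        else:
            n_aa = int((b.genotypes == AA).sum())
            n_bb = int((b.genotypes == BB).sum())
            if n_aa + n_bb > 0:
                chi2, p = stats.chisquare([n_aa, n_bb])
                if p < seg_alpha:
                    reason = "segregation"
        keep.append(reason is None)
        if reason is not None:
            log_rows.append(
                {"chrom": b.chrom, "start": b.start, "end": b.end, "reason": reason}
            )
    retained = [b for b, k in zip(bins, keep) if k]

    if rescue_density_per_bp:
        spans: dict[str, int] = {}
        for b in bins:
            spans[b.chrom] = max(spans.get(b.chrom, 0), b.end)
        rescued: list[BinMarker] = []
        for c, span in spans.items():
            floor = math.ceil(span * rescue_density_per_bp)
            have = [b for b in retained if b.chrom == c]
            if len(have) >= floor:
                continue
            pool = sorted(
                (b for b, k in zip(bins, keep) if not k and b.chrom == c),
                key=lambda b: -b.length,
            )
            need = floor - len(have)
            rescued.extend(pool[:need])
        if rescued:
            keep_ids = {id(b) for b in retained} | {id(b) for b in rescued}
            retained = [b for b in bins if id(b) in keep_ids]
            log_rows = [
                r
                for r in log_rows
                if not any(
                    r["chrom"] == b.chrom and r["start"] == b.start for b in rescued
                )
            ]
    log = pd.DataFrame(log_rows, columns=["chrom", "start", "end", "reason"])
    return retained, log


# --------------------------------------------------------------------------
# recombination fractions and map distances
# --------------------------------------------------------------------------


def estimate_rf(
    geno_i: np.ndarray, geno_j: np.ndarray
) -> tuple[float, int, bool]:
    """Meiotic recombination fraction between two bin genotype vectors.

    Individuals homozygous and non-missing at both bins are scorable; the
    observed RIL recombinant fraction R is inverted to the per-meiosis value
    r = R / (2 (1 - R)) (selfed-RIL expectation R = 2r / (1 + 2r)) and
    clamped to [0, 0.4999].  Returns (r, scorable count, low-confidence flag
    set when fewer than 10 individuals are scorable).
    """
    hom_i = (geno_i == AA) | (geno_i == BB)
    hom_j = (geno_j == AA) | (geno_j == BB)
    ok = hom_i & hom_j
    n_scorable = int(ok.sum())
    if n_scorable == 0:
        return 0.4999, 0, True
    big_r = float((geno_i[ok] != geno_j[ok]).mean())
    if big_r >= 1.0:
        r = 0.4999
    else:
        r = big_r / (2.0 * (1.0 - big_r))
    return float(np.clip(r, 0.0, 0.4999)), n_scorable, n_scorable < 10


def kosambi_cm(r: float | np.ndarray) -> float | np.ndarray:
    """Kosambi map distance d = 25 ln((1 + 2r) / (1 - 2r)) in cM."""
    r = np.asarray(r, dtype=float)
    if (r < 0).any() or (r >= 0.5).any():
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    d = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    return float(d) if d.ndim == 0 else d


def kosambi_inverse(d_cm: float | np.ndarray) -> float | np.ndarray:
    """Inverse of :func:`kosambi_cm`: r = 0.5 tanh(d / 50)."""
    d = np.asarray(d_cm, dtype=float)
    r = 0.5 * np.tanh(d / 50.0)
    return float(r) if r.ndim == 0 else r


def haldane_cm(r: float | np.ndarray) -> float | np.ndarray:
    """Haldane map distance d = -50 ln(1 - 2r) in cM."""
    r = np.asarray(r, dtype=float)
    d = -50.0 * np.log(1.0 - 2.0 * r)
    return float(d) if d.ndim == 0 else d


def haldane_inverse(d_cm: float | np.ndarray) -> float | np.ndarray:
    d = np.asarray(d_cm, dtype=float)
    r = 0.5 * (1.0 - np.exp(-d / 50.0))
    return float(r) if r.ndim == 0 else r


def assemble_map(bins: list[BinMarker]) -> list[LinkageGroup]:
    """String retained bins into linkage groups: bins keep physical order
    within each chromosome; cumulative cM is the running sum of Kosambi
    distances between adjacent-bin recombination fractions."""
    groups: list[LinkageGroup] = []
    by_chrom: dict[str, list[BinMarker]] = {}
    for b in bins:
        by_chrom.setdefault(b.chrom, []).append(b)
    for c, bl in by_chrom.items():
        bl = sorted(bl, key=lambda b: b.start)
        cm = np.zeros(len(bl))
        flags = np.zeros(max(len(bl) - 1, 0), dtype=bool)
        for k in range(1, len(bl)):
            r, _, low = estimate_rf(bl[k - 1].genotypes, bl[k].genotypes)
            cm[k] = cm[k - 1] + kosambi_cm(r)
            flags[k - 1] = low
        groups.append(LinkageGroup(c, bl, cm, flags))
    return groups


# --------------------------------------------------------------------------
# map summaries
# --------------------------------------------------------------------------


def group_table(groups: list[LinkageGroup]) -> pd.DataFrame:
    """Per-group map characteristics: bin count, total distance, average
    adjacent-marker distance (total / count), fraction of gaps < 5 cM, and
    the largest gap."""
    rows = []
    for g in groups:
        gaps = np.diff(g.cm)
        rows.append(
            {
                "group": g.id,
                "n_bins": len(g.bins),
                "total_cm": float(g.cm[-1]) if g.cm.size else 0.0,
                "avg_cm": (float(g.cm[-1]) / len(g.bins)) if g.bins else float("nan"),
                "gaps_lt5_frac": float((gaps < 5.0).mean()) if gaps.size else float("nan"),
                "max_gap_cm": float(gaps.max()) if gaps.size else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def aggregate_map_table(per_group: pd.DataFrame) -> dict:
    """Genome and per-subgenome aggregates from a per-group table with
    columns ``group``, ``n_bins``, ``total_cm`` (A vs C subgenome decided by
    the group id's leading letter).  Average distance is total distance over
    bin count, the convention the per-group rows follow."""
    out: dict = {}
    for label, sub in (
        ("genome", per_group),
        ("A", per_group[per_group["group"].str.startswith("A")]),
        ("C", per_group[per_group["group"].str.startswith("C")]),
    ):
        n = int(sub["n_bins"].sum())
        dist = float(sub["total_cm"].sum())
        out[label] = {
            "n_bins": n,
            "total_cm": round(dist, 2),
            "avg_cm": round(dist / n, 2) if n else float("nan"),
        }
    return out


def map_summary(groups: list[LinkageGroup]) -> dict:
    """Full map summary: the per-group table plus genome / subgenome totals."""
    per_group = group_table(groups)
    summary = aggregate_map_table(per_group)
    summary["per_group"] = per_group
    return summary


def collinearity(groups: list[LinkageGroup]) -> pd.DataFrame:
    """Spearman rank correlation between genetic (cM) and physical (bp
    midpoint) bin order per group; groups with fewer than 3 bins are skipped.
    The cross-group average is appended as row ``mean``."""
    rows = []
    for g in groups:
        if len(g.bins) < 3:
            continue
        bp = np.array([(b.start + b.end) / 2.0 for b in g.bins])
        rho = stats.spearmanr(g.cm, bp).statistic
        rows.append({"group": g.id, "spearman_rho": float(rho)})
    df = pd.DataFrame(rows, columns=["group", "spearman_rho"])
    if len(df):
        df = pd.concat(
            [df, pd.DataFrame([{"group": "mean", "spearman_rho": df["spearman_rho"].mean()}])],
            ignore_index=True,
        )
    return df


def bins_table(bins: list[BinMarker], samples: list[str] | None = None) -> pd.DataFrame:
    """Bins as a TSV-ready table (chrom, start, end, snp_count, genotypes)."""
    from .core import CODE_TO_LABEL

    rows = []
    for b in bins:
        rows.append(
            {
                "chrom": b.chrom,
                "start": b.start,
                "end": b.end,
                "snp_count": b.snp_count,
                "genotypes": "".join(
                    {AA: "a", AB: "h", BB: "b", MISSING: "-"}[int(g)] for g in b.genotypes
                ),
            }
        )
    return pd.DataFrame(rows)
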