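"""Composite interval mapping over bin-marker linkage groups.

The single-environment scan is composite interval mapping by Haley-Knott
regression: background bin cofactors are chosen by forward stepwise
regression, then at every grid position the expected signed QTL dosage given
the flanking bins (RIL-corrected transition probabilities) is regressed on
the phenotype together with the cofactors, masking any cofactor within a
window of the test position.  LOD = (n/2) log10(RSS_reduced / RSS_full).
Genome-wide significance comes from a phenotype-permutation test.  The
multi-environment scan stacks environments and partitions the QTL signal
into a shared additive term and QTL-by-environment interaction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .binmap import LinkageGroup, kosambi_inverse

# --------------------------------------------------------------------------
# settings / results
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ScanSettings:
    """CIM parameters: 1 cM walking step, 10 cM cofactor masking window,
    five background cofactors, 1,000 permutations at alpha = 0.05."""

    step: float = 1.0
    cofactor_window: float = 10.0
    n_cofactors: int = 5
    n_permutations: int = 1000
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.step <= 0 or self.cofactor_window < 0 or self.n_cofactors < 0:
            raise ValueError("invalid scan settings")


@dataclass(eq=False)
class QtlScanResult:
    group: np.ndarray  # group id per grid position
    cm: np.ndarray
    lod: np.ndarray
    add: np.ndarray  # additive effect (dosage coefficient)
    pve: np.ndarray  # % phenotypic variance explained at each position
    n: int
    environment: str = ""
    threshold: float | None = None
    pve_interaction: np.ndarray | None = None  # multi-environment scans only


@dataclass(eq=False)
class QtlRecord:
    name: str
    group: str
    peak_cm: float
    interval_lo: float
    interval_hi: float
    lod: float
    add: float
    pve: float
    environment: str = ""


# --------------------------------------------------------------------------
# engine: precomputed dosages + fast repeated scans
# --------------------------------------------------------------------------


def _ril_big_r(r: np.ndarray) -> np.ndarray:
    """Selfed-RIL observed recombinant fraction R = 2r / (1 + 2r)."""
    return 2.0 * r / (1.0 + 2.0 * r)


class _ScanEngine:
    """Precomputes bin dosages and the grid of expected QTL dosages so that
    permutation scans only redo the cheap regression sweeps."""

    def __init__(self, groups: list[LinkageGroup], settings: ScanSettings):
        self.settings = settings
        self.bin_dosage: list[np.ndarray] = []  # signed +-1/0/NaN per bin
        self.bin_cm: list[float] = []
        self.bin_group: list[str] = []
        grid_group, grid_cm = [], []
        for g in groups:
            for b, cm in zip(g.bins, g.cm):
                d = np.full(b.genotypes.shape, np.nan)
                d[b.genotypes == 0] = 1.0  # AA
                d[b.genotypes == 2] = -1.0  # BB
                d[b.genotypes == 1] = 0.0  # AB
                self.bin_dosage.append(d)
                self.bin_cm.append(float(cm))
                self.bin_group.append(g.id)
            last = float(g.cm[-1]) if g.cm.size else 0.0
            pts = np.arange(0.0, last + settings.step * 0.5, settings.step)
            if pts.size == 0 or pts[-1] < last - 1e-9:
                pts = np.append(pts, last)
            grid_group.extend([g.id] * pts.size)
            grid_cm.append(pts)
        self.grid_group = np.asarray(grid_group, dtype=object)
        self.grid_cm = np.concatenate(grid_cm) if grid_cm else np.empty(0)
        self.n_ind = self.bin_dosage[0].size
        self._build_expected_dosage(groups)
        # mean-imputed cofactor candidate matrix
        D = np.column_stack(self.bin_dosage)
        mu = np.nanmean(D, axis=0)
        mu = np.where(np.isnan(mu), 0.0, mu)
        self.D = np.where(np.isnan(D), mu[None, :], D)
        self.bin_cm_arr = np.asarray(self.bin_cm)
        self.bin_group_arr = np.asarray(self.bin_group, dtype=object)

    def _build_expected_dosage(self, groups: list[LinkageGroup]) -> None:
        cols = []
        for g in groups:
            cm = np.asarray(g.cm)
            dos = np.column_stack(
                [self.bin_dosage[i] for i in range(len(self.bin_cm)) if self.bin_group[i] == g.id]
            )
            last = float(cm[-1]) if cm.size else 0.0
            pts = self.grid_cm[self.grid_group == g.id]
            for p in pts:
                li = int(np.searchsorted(cm, p + 1e-12)) - 1
                ri = int(np.searchsorted(cm, p - 1e-12))
                f_plus = np.full(self.n_ind, 1.0)
                f_minus = np.full(self.n_ind, 1.0)
                for side, idx, dist in (
                    ("L", li, p - (cm[li] if 0 <= li < cm.size else 0.0)),
                    ("R", ri, (cm[ri] if 0 <= ri < cm.size else 0.0) - p),
                ):
                    if not (0 <= idx < cm.size):
                        continue
                    big_r = _ril_big_r(np.asarray(kosambi_inverse(max(dist, 0.0))))
                    x = dos[:, idx]
                    hom = ~np.isnan(x) & (x != 0.0)
                    fp = np.where(x[hom] > 0, 1.0 - big_r, big_r)
                    f_plus[hom] *= fp
                    f_minus[hom] *= 1.0 - fp
                tot = f_plus + f_minus
                e = np.where(tot > 0, (f_plus - f_minus) / np.where(tot > 0, tot, 1.0), 0.0)
                cols.append(e)
        self.E = np.column_stack(cols) if cols else np.empty((self.n_ind, 0))

    # -- regression sweeps ------------------------------------------------

    def select_cofactors(self, y: np.ndarray, mask: np.ndarray) -> list[int]:
        """Forward stepwise selection of up to n_cofactors bins by largest
        RSS reduction (equivalently largest partial F)."""
        k = self.settings.n_cofactors
        if k == 0:
            return []
        D = self.D[mask]
        yv = y[mask]
        n = yv.size
        X = np.ones((n, 1))
        chosen: list[int] = []
        for _ in range(k):
            Q, _r = np.linalg.qr(X)
            ry = yv - Q @ (Q.T @ yv)
            RD = D - Q @ (Q.T @ D)
            norms = np.einsum("ij,ij->j", RD, RD)
            scores = np.where(norms > 1e-10, (RD.T @ ry) ** 2 / np.where(norms > 0, norms, 1.0), -1.0)
            scores[chosen] = -1.0
            j = int(np.argmax(scores))
            if scores[j] <= 0:
                break
            chosen.append(j)
            X = np.column_stack([X, D[:, j]])
        return chosen

    def scan(self, y: np.ndarray) -> QtlScanResult:
        """One CIM pass: returns LOD / additive effect / PVE on the grid."""
        mask = ~np.isnan(y)
        yv = y[mask]
        n = int(mask.sum())
        G = self.grid_cm.size
        lod = np.zeros(G)
        add = np.zeros(G)
        pve = np.zeros(G)
        if n < 3 or np.ptp(yv) == 0:
            return QtlScanResult(self.grid_group, self.grid_cm.copy(), lod, add, pve, n)
        cof = self.select_cofactors(y, mask)
        tss = float(((yv - yv.mean()) ** 2).sum())
        Dm = self.D[mask]
        Em = self.E[mask]
        w = self.settings.cofactor_window
        # group grid positions by which cofactors are masked
        patterns: dict[tuple[int, ...], list[int]] = {}
        for gidx in range(G):
            p, grp = self.grid_cm[gidx], self.grid_group[gidx]
            keep = tuple(
                j
                for j in cof
                if not (self.bin_group_arr[j] == grp and abs(self.bin_cm_arr[j] - p) < w)
            )
            patterns.setdefault(keep, []).append(gidx)
        for keep, idxs in patterns.items():
            X = np.column_stack([np.ones(n)] + [Dm[:, j] for j in keep])
            Q, _r = np.linalg.qr(X)
            ry = yv - Q @ (Q.T @ yv)
            rss_red = float(ry @ ry)
            Esub = Em[:, idxs]
            RE = Esub - Q @ (Q.T @ Esub)
            norms = np.einsum("ij,ij->j", RE, RE)
            dot = RE.T @ ry
            ok = norms > 1e-10
            beta = np.where(ok, dot / np.where(ok, norms, 1.0), 0.0)
            rss_full = np.maximum(rss_red - np.where(ok, dot**2 / np.where(ok, norms, 1.0), 0.0), 1e-300)
            lod[idxs] = np.where(ok, (n / 2.0) * np.log10(np.maximum(rss_red, 1e-300) / rss_full), 0.0)
            add[idxs] = beta
            pve[idxs] = np.where(ok & (tss > 0), 100.0 * (rss_red - rss_full) / tss, 0.0)
        return QtlScanResult(self.grid_group, self.grid_cm.copy(), lod, add, pve, n)


def _align_phenotype(groups: list[LinkageGroup], phenotype, samples: list[str] | None) -> np.ndarray:
    n = len(groups[0].bins[0].genotypes)
    if isinstance(phenotype, pd.Series) and samples is not None:
        y = phenotype.reindex(samples).to_numpy(dtype=float)
    else:
        y = np.asarray(phenotype, dtype=float)
    if y.size != n:
        raise ValueError("phenotype length does not match genotype columns")
    return y


# --------------------------------------------------------------------------
# public operations
# --------------------------------------------------------------------------


def cim_scan(
    groups: list[LinkageGroup],
    phenotype,
    settings: ScanSettings = ScanSettings(),
    samples: list[str] | None = None,
    environment: str = "",
    _engine: _ScanEngine | None = None,
) -> QtlScanResult:
    """Composite interval mapping of one environment's phenotype."""
    engine = _engine or _ScanEngine(groups, settings)
    y = _align_phenotype(groups, phenotype, samples)
    res = engine.scan(y)
    res.environment = environment
    return res


def permutation_threshold(
    groups: list[LinkageGroup],
    phenotype,
    settings: ScanSettings = ScanSettings(),
    seed: int = 0,
    samples: list[str] | None = None,
    _engine: _ScanEngine | None = None,
) -> tuple[float, np.ndarray]:
    """Genome-wide LOD threshold: the empirical (1 - alpha) quantile of the
    maximum LOD over ``n_permutations`` phenotype permutations (cofactors are
    re-selected for every permuted phenotype).  Returns (threshold, the
    permutation maxima)."""
    import warnings

    if settings.n_permutations < 100:
        warnings.warn("fewer than 100 permutations: unstable quantile", stacklevel=2)
    engine = _engine or _ScanEngine(groups, settings)
    y = _align_phenotype(groups, phenotype, samples)
    rng = np.random.default_rng(seed)
    maxima = np.empty(settings.n_permutations)
    for b in range(settings.n_permutations):
        maxima[b] = engine.scan(rng.permutation(y)).lod.max()
    threshold = float(np.quantile(maxima, 1.0 - settings.alpha, method="higher"))
    return threshold, maxima


def call_qtl(
    scan: QtlScanResult,
    threshold: float,
    settings: ScanSettings = ScanSettings(),
    name_prefix: str = "q",
) -> list[QtlRecord]:
    """Call QTL peaks: local maxima above threshold separated by at least the
    cofactor window, with 1-LOD-drop support intervals and peak PVE."""
    records: list[QtlRecord] = []
    for grp in pd.unique(scan.group):
        sel = scan.group == grp
        cm, lod = scan.cm[sel], scan.lod[sel]
        add, pve = scan.add[sel], scan.pve[sel]
        order = np.argsort(-lod)
        peaks: list[int] = []
        for i in order:
            if lod[i] < threshold:
                break
            if all(abs(cm[i] - cm[j]) >= settings.cofactor_window for j in peaks):
                peaks.append(int(i))
        for k, i in enumerate(sorted(peaks, key=lambda i: cm[i])):
            drop = lod[i] - 1.0
            lo = i
            while lo > 0 and lod[lo - 1] >= drop:
                lo -= 1
            hi = i
            while hi < lod.size - 1 and lod[hi + 1] >= drop:
                hi += 1
            records.append(
                QtlRecord(
                    name=f"{name_prefix}{grp}-{k + 1}",
                    group=str(grp),
                    peak_cm=float(cm[i]),
                    interval_lo=float(cm[lo]),
                    interval_hi=float(cm[hi]),
                    lod=float(lod[i]),
                    add=float(add[i]),
                    pve=float(pve[i]),
                    environment=scan.environment,
                )
            )
    return records


def qtl_table(records: list[QtlRecord]) -> pd.DataFrame:
    """QTL records as a table with the conventional report columns."""
    return pd.DataFrame(
        [
            {
                "QTL": r.name,
                "Chr": r.group,
                "Position (cM)": r.peak_cm,
                "LOD": r.lod,
                "Interval (cM)": f"{r.interval_lo:g}-{r.interval_hi:g}",
                "Add": r.add,
                "PVE (%)": r.pve,
                "Environment": r.environment,
            }
            for r in records
        ]
    )


# --------------------------------------------------------------------------
# multi-environment joint scan
# --------------------------------------------------------------------------


def multi_env_scan(
    groups: list[LinkageGroup],
    phenotypes: pd.DataFrame,
    settings: ScanSettings = ScanSettings(),
    samples: list[str] | None = None,
) -> QtlScanResult:
    """Two-stage inclusive scan across environments.

    Stage 1 selects marker cofactors by stepwise regression on the
    environment-centred stacked phenotype.  Stage 2 fits, at every grid
    position, a joint model with environment main effects, the shared QTL
    dosage, and QTL x environment interactions; the joint LOD compares the
    full model against the no-QTL model, and the QTL variance is partitioned
    into additive (``pve``) and interaction (``pve_interaction``) parts.
    Phenotypes arrive tidy: individual, environment, value (replicates are
    averaged).  Single-environment input delegates to :func:`cim_scan`.
    """
    envs = sorted(phenotypes["environment"].unique())
    if samples is None:
        samples = list(pd.unique(phenotypes["individual"]))
    wide = (
        phenotypes.groupby(["individual", "environment"])["value"]
        .mean()
        .unstack("environment")
        .reindex(index=samples, columns=envs)
    )
    if len(envs) < 2:
        return cim_scan(groups, wide.iloc[:, 0].to_numpy(), settings, environment=envs[0])

    engine = _ScanEngine(groups, settings)
    Y = wide.to_numpy(dtype=float)  # n x nE
    n, ne = Y.shape
    row_ok = ~np.isnan(Y).any(axis=1)
    Y = Y[row_ok]
    n = int(row_ok.sum())

    # stage 1: cofactors from the environment-centred stacked phenotype
    yc = (Y - Y.mean(axis=0, keepdims=True)).ravel(order="F")
    D = engine.D[row_ok]
    Dstack = np.tile(D, (ne, 1))
    saved = engine.D
    engine.D = Dstack
    cof = engine.select_cofactors(yc, np.ones(yc.size, dtype=bool))
    engine.D = saved

    # stage 2: joint model per grid position
    env_dummies = np.kron(np.eye(ne)[:, 1:], np.ones((n, 1)))  # (n*ne) x (ne-1)
    ones = np.ones((n * ne, 1))
    ystack = Y.ravel(order="F")
    tss = float(((ystack - ystack.mean()) ** 2).sum())
    E = engine.E[row_ok]
    G = engine.grid_cm.size
    lod = np.zeros(G)
    add = np.zeros(G)
    pve_add = np.zeros(G)
    pve_int = np.zeros(G)
    w = settings.cofactor_window
    for gidx in range(G):
        p, grp = engine.grid_cm[gidx], engine.grid_group[gidx]
        keep = [
            j
            for j in cof
            if not (engine.bin_group_arr[j] == grp and abs(engine.bin_cm_arr[j] - p) < w)
        ]
        Xred = np.column_stack([ones, env_dummies] + [np.tile(D[:, j], ne) for j in keep])
        dq = np.tile(E[:, gidx], ne)
        if np.ptp(dq) == 0:
            continue
        Xmid = np.column_stack([Xred, dq])
        inter = env_dummies * dq[:, None]
        Xfull = np.column_stack([Xmid, inter])
        rss_red = _rss(Xred, ystack)
        rss_mid, beta_mid = _rss(Xmid, ystack, coef_index=Xmid.shape[1] - 1)
        rss_full = _rss(Xfull, ystack)
        rss_full = max(rss_full, 1e-300)
        lod[gidx] = (ystack.size / 2.0) * math.log10(max(rss_red, 1e-300) / rss_full)
        add[gidx] = beta_mid
        pve_add[gidx] = 100.0 * max(rss_red - rss_mid, 0.0) / tss
        pve_int[gidx] = 100.0 * max(rss_mid - rss_full, 0.0) / tss
    return QtlScanResult(
        engine.grid_group,
        engine.grid_cm.copy(),
        lod,
        add,
        pve_add,
        n=n * ne,
        environment="joint:" + "+".join(map(str, envs)),
        pve_interaction=pve_int,
    )


def _rss(X: np.ndarray, y: np.ndarray, coef_index: int | None = None):
    beta, res, rank, _sv = np.linalg.lstsq(X, y, rcond=None)
    if res.size:
        rss = float(res[0])
    else:
        e = y - X @ beta
        rss = float(e @ e)
    if coef_index is None:
        return rss
    return rss, float(beta[coef_index])


def multi_env_permutation_threshold(
    groups: list[LinkageGroup],
    phenotypes: pd.DataFrame,
    settings: ScanSettings = ScanSettings(),
    seed: int = 0,
    samples: list[str] | None = None,
) -> tuple[float, np.ndarray]:
    """Permutation threshold for the joint scan: individuals are permuted
    jointly across environments, preserving the G x E structure under the
    null."""
    rng = np.random.default_rng(seed)
    envs = sorted(phenotypes["environment"].unique())
    if samples is None:
        samples = list(pd.unique(phenotypes["individual"]))
    wide = (
        phenotypes.groupby(["individual", "environment"])["value"]
        .mean()
        .unstack("environment")
        .reindex(index=samples, columns=envs)
    )
    maxima = np.empty(settings.n_permutations)
    idx = np.arange(len(samples))
    for b in range(settings.n_permutations):
        perm = rng.permutation(idx)
        shuffled = wide.iloc[perm].reset_index(drop=True)
        shuffled.index = pd.Index(samples, name="individual")
        tidy = shuffled.reset_index().melt(
            id_vars="individual", var_name="environment", value_name="value"
        )
        maxima[b] = multi_env_scan(groups, tidy, settings, samples=samples).lod.max()
    threshold = float(np.quantile(maxima, 1.0 - settings.alpha, method="higher"))
    return threshold, maxima


# --------------------------------------------------------------------------
# flanking-marker two-group test
# --------------------------------------------------------------------------


def flanking_group_test(
    geno_bin1: np.ndarray, geno_bin2: np.ndarray, phenotype: np.ndarray
) -> dict:
    """Welch two-sample test between individuals homozygous parent-1 type at
    BOTH flanking bins (AA group) and homozygous parent-2 type at both (BB
    group); all other individuals are excluded."""
    y = np.asarray(phenotype, dtype=float)
    in_aa = (geno_bin1 == 0) & (geno_bin2 == 0) & ~np.isnan(y)
    in_bb = (geno_bin1 == 2) & (geno_bin2 == 2) & ~np.isnan(y)
    ya, yb = y[in_aa], y[in_bb]
    out = {
        "n_aa": int(ya.size),
        "n_bb": int(yb.size),
        "mean_aa": float(ya.mean()) if ya.size else float("nan"),
        "mean_bb": float(yb.mean()) if yb.size else float("nan"),
        "t": float("nan"),
        "p": float("nan"),
    }
    if ya.size < 2 or yb.size < 2:
        return out
    if ya.mean() == yb.mean() and ya.std() == 0 and yb.std() == 0:
        out["t"], out["p"] = 0.0, 1.0
        return out
    t, p = stats.ttest_ind(ya, yb, equal_var=False)
    out["t"], out["p"] = float(t), float(p)
    return out
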